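"""Tiered guide selection, ranking, element assembly, and synthesis oligos."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualguide import (
    DesignConfig,
    DualElement,
    GuideRecord,
    assemble_dual_oligo,
    assign_tier,
    build_library,
    discriminant_scores,
    filter_bsmbi,
    olfactory_thresholds,
    parse_dual_oligo,
    rank_guides,
    relative_phenotypes,
)
from dualguide.library_design import n_controls, zscore_phenotypes


def make_guide(gid, gene, seq, score=0.5):
    return GuideRecord(guide_id=gid, gene=gene, protospacer=seq, predicted_score=score)

proto20 = st.text(alphabet="ACGT", min_size=20, max_size=20)


class TestBsmbiFilter:
    def test_site_containing_guide_removed(self):
        guides = [
            make_guide("g1", "A", "ACGTCTCAACGGTTAACCGG"),
            make_guide("g2", "A", "AAAAAAAAAAAAAAAAAAAA"),
            make_guide("g3", "A", "TTTTTTTGAGACGTTTTTTT"),
        ]
        kept = filter_bsmbi(guides)
        assert [g.guide_id for g in kept] == ["g2"]
        assert len(guides) == 3  # input untouched

    def test_non_acgt_rejected_at_construction(self):
        with pytest.raises(ValueError, match="gX"):
            make_guide("gX", "A", "ACGTACGTACGTACGTACGX")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(proto20, min_size=1, max_size=10, unique=True))
    def test_output_never_contains_site(self, seqs):
        guides = [make_guide(f"g{i}", "A", s) for i, s in enumerate(seqs)]
        for g in filter_bsmbi(guides):
            assert "CGTCTC" not in g.protospacer
            assert "GAGACG" not in g.protospacer


class TestRelativePhenotypes:
    @pytest.mark.parametrize(
        "phen,expected",
        [
            ({"g1": -0.5, "g2": -0.25}, {"g1": 1.0, "g2": 0.5}),
            ({"g1": -0.4, "g2": 0.1}, {"g1": 1.0, "g2": -0.25}),
            ({"g1": -0.9}, {"g1": 1.0}),
        ],
    )
    def test_examples(self, phen, expected):
        assert relative_phenotypes(phen) == pytest.approx(expected)

    def test_all_zero_warns_and_maps_to_zero(self):
        with pytest.warns(UserWarning):
            out = relative_phenotypes({"g1": 0.0, "g2": 0.0})
        assert out == {"g1": 0.0, "g2": 0.0}


def _brute_force_discriminant(gene_stats, guide_stats_z, guide_genes, hit_fdr=0.05):
    """Explicit-loop recomputation, independent of the vectorized path."""
    scores = {}
    genes = sorted(set(gene_stats["gene"]))
    for gene in genes:
        total, n_hit = 0.0, 0
        for screen in sorted(set(gene_stats["screen_id"])):
            recs = gene_stats[
                (gene_stats["gene"] == gene)
                & (gene_stats["screen_id"] == screen)
                & (gene_stats["gene_fdr"] <= hit_fdr)
            ]
            if recs.empty:
                continue
            zs = []
            for _, row in guide_stats_z[guide_stats_z["screen_id"] == screen].iterrows():
                if guide_genes.get(row["guide_id"]) == gene and np.isfinite(row["z"]):
                    zs.append(row["z"])
            if not zs:
                continue
            zs.sort(key=abs, reverse=True)
            zbar = sum(zs[:3]) / len(zs[:3])
            best = max(abs(-math.log10(p) * zbar) for p in recs["p_value"])
            total += best
            n_hit += 1
        if n_hit:
            scores[gene] = (n_hit, total)
    return scores


class TestDiscriminantScore:
    def test_single_screen_forced_arithmetic(self, gene_stats_frame, guide_stats_frame):
        gene_stats = gene_stats_frame([("s1", "G1", 1e-4, 0.01, np.nan)])
        # three guides whose z-scores average to -2.0
        gz = pd.DataFrame(
            {
                "screen_id": ["s1"] * 3,
                "guide_id": ["a", "b", "c"],
                "z": [-1.0, -2.0, -3.0],
            }
        )
        out = discriminant_scores(gene_stats, gz, {"a": "G1", "b": "G1", "c": "G1"})
        assert out.loc["G1", "score"] == pytest.approx(8.0)
        assert out.loc["G1", "n_hit_screens"] == 1

    def test_two_hit_screens_sum_of_magnitudes(self, gene_stats_frame):
        gene_stats = gene_stats_frame(
            [("s1", "G1", 1e-4, 0.01, np.nan), ("s2", "G1", 10**-1.75, 0.01, np.nan)]
        )
        gz = pd.DataFrame(
            {
                "screen_id": ["s1", "s2"],
                "guide_id": ["a", "a"],
                "z": [-2.0, 2.0],
            }
        )
        out = discriminant_scores(gene_stats, gz, {"a": "G1"})
        # |(-4)*(-2)| + |1.75*2| = 8 + 3.5
        assert out.loc["G1", "score"] == pytest.approx(11.5)

    def test_fewer_than_three_guides_use_all(self, gene_stats_frame):
        gene_stats = gene_stats_frame([("s1", "G1", 0.01, 0.01, np.nan)])
        gz = pd.DataFrame(
            {"screen_id": ["s1", "s1"], "guide_id": ["a", "b"], "z": [-1.0, -3.0]}
        )
        out = discriminant_scores(gene_stats, gz, {"a": "G1", "b": "G1"})
        assert out.loc["G1", "score"] == pytest.approx(4.0)  # |2 * (-2)|

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(6)]
        screens = [f"s{i}" for i in range(4)]
        guide_genes = {f"g{i}": genes[i % 6] for i in range(24)}
        gene_rows, guide_rows = [], []
        for s in screens:
            for g in genes:
                if rng.random() < 0.7:
                    gene_rows.append(
                        (s, g, 10 ** -rng.uniform(0.5, 6), rng.choice([0.01, 0.2]))
                    )
            for gid in guide_genes:
                if rng.random() < 0.8:
                    guide_rows.append((s, gid, rng.normal(), rng.random()))
        gene_stats = pd.DataFrame(
            gene_rows, columns=["screen_id", "gene", "p_value", "gene_fdr"]
        )
        guide_stats = pd.DataFrame(
            guide_rows, columns=["screen_id", "guide_id", "phenotype", "guide_fdr"]
        )
        gz = zscore_phenotypes(guide_stats)
        got = discriminant_scores(gene_stats, gz, guide_genes)
        expected = _brute_force_discriminant(gene_stats, gz, guide_genes)
        assert set(got.index) == set(expected)
        for gene, (n_hit, score) in expected.items():
            assert got.loc[gene, "n_hit_screens"] == n_hit
            assert got.loc[gene, "score"] == pytest.approx(score)


class TestOlfactoryThresholds:
    def test_max_rule(self):
        scores = {"o1": (1, 2.0), "o2": (1, 3.1), "o3": (2, 4.0)}
        thr = olfactory_thresholds(scores)
        assert thr[1] == 3.1
        assert thr[2] == 4.0

    def test_fallback_to_lower_k(self):
        scores = {"o1": (1, 2.0), "o2": (1, 3.1), "o3": (2, 4.0)}
        thr = olfactory_thresholds(scores)
        assert thr[3] == 4.0  # no olfactory gene with exactly 3 hits
        assert thr[4] == 4.0

    def test_empty_set_gives_infinite_thresholds(self):
        thr = olfactory_thresholds({})
        assert all(math.isinf(thr[k]) for k in (1, 2, 3, 4))


class TestAssignTier:
    cfg = DesignConfig(k562_screen="k562")

    def _disc(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "n_hit_screens", "score"]
        ).set_index("gene")

    def test_k562_essential_is_tier1(self, gene_stats_frame):
        gs = gene_stats_frame([("k562", "G1", 1e-5, 0.001, -0.5)])
        t = assign_tier("G1", gs, self._disc([]), {}, self.cfg)
        assert t.tier == 1

    def test_five_screen_hit_is_tier2(self, gene_stats_frame):
        gs = gene_stats_frame([("k562", "G1", 0.5, 0.9, 0.0)])
        t = assign_tier("G1", gs, self._disc([("G1", 6, 1.0)]), {}, self.cfg)
        assert t.tier == 2

    def test_score_above_threshold_is_tier2(self, gene_stats_frame):
        gs = gene_stats_frame([("k562", "G1", 0.5, 0.9, 0.0)])
        thr = {2: 4.0}
        t = assign_tier("G1", gs, self._disc([("G1", 2, 5.0)]), thr, self.cfg)
        assert t.tier == 2
        assert t.discriminant_score == 5.0 and t.threshold_used == 4.0

    def test_no_hits_is_tier3(self, gene_stats_frame):
        gs = gene_stats_frame([("k562", "G1", 0.5, 0.9, 0.0)])
        t = assign_tier("G1", gs, self._disc([]), {}, self.cfg)
        assert t.tier == 3

    def test_absent_from_k562_falls_through(self, gene_stats_frame):
        gs = gene_stats_frame([])
        t = assign_tier("G1", gs, self._disc([]), {}, self.cfg)
        assert t.tier == 3

    def test_every_gene_gets_exactly_one_tier(self, gene_stats_frame):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(20)]
        rows = []
        for g in genes:
            if rng.random() < 0.5:
                rows.append(("k562", g, 10 ** -rng.uniform(0, 6), 0.01, rng.normal(-0.2, 0.2)))
        gs = gene_stats_frame(rows)
        disc = self._disc(
            [(g, int(rng.integers(1, 8)), float(rng.uniform(0, 10)))
             for g in genes if rng.random() < 0.5]
        )
        thr = {k: 3.0 for k in range(1, 5)}
        tiers = [assign_tier(g, gs, disc, thr, self.cfg).tier for g in genes]
        assert all(t in (1, 2, 3) for t in tiers)
        assert len(tiers) == len(genes)


class TestRankGuides:
    cfg = DesignConfig(k562_screen="k562")

    def test_tier3_sorted_by_predicted_score(self, gene_stats_frame, guide_stats_frame):
        guides = [
            make_guide("g1", "G", "A" * 19 + "C", 0.9),
            make_guide("g2", "G", "A" * 19 + "G", 0.7),
            make_guide("g3", "G", "A" * 19 + "T", 0.8),
        ]
        out = rank_guides("G", 3, guides, gene_stats_frame([]), guide_stats_frame([]), self.cfg)
        assert [g.guide_id for g in out] == ["g1", "g3", "g2"]

    def test_tier2_eligible_guides_first(self, gene_stats_frame, guide_stats_frame):
        guides = [
            make_guide("g1", "G", "A" * 19 + "C", 0.1),
            make_guide("g2", "G", "A" * 19 + "G", 0.99),
        ]
        gene_stats = gene_stats_frame([("s1", "G", 1e-3, 0.01, np.nan)])
        guide_stats = guide_stats_frame(
            [("s1", "g1", -0.1, 0.005), ("s1", "g2", -0.9, 0.5)]
        )
        out = rank_guides("G", 2, guides, gene_stats, guide_stats, self.cfg)
        assert [g.guide_id for g in out] == ["g1", "g2"]

    def test_tier1_ranked_by_mean_relative_phenotype(self, gene_stats_frame, guide_stats_frame):
        guides = [
            make_guide("g1", "G", "A" * 19 + "C"),
            make_guide("g2", "G", "A" * 19 + "G"),
        ]
        gene_stats = gene_stats_frame([("k562", "G", 1e-5, 0.001, -0.5)])
        guide_stats = guide_stats_frame(
            [("k562", "g1", -0.2, 0.001), ("k562", "g2", -0.8, 0.001)]
        )
        out = rank_guides("G", 1, guides, gene_stats, guide_stats, self.cfg)
        assert [g.guide_id for g in out] == ["g2", "g1"]

    def test_ties_broken_by_protospacer(self, gene_stats_frame, guide_stats_frame):
        guides = [
            make_guide("g1", "G", "C" * 20, 0.5),
            make_guide("g2", "G", "A" * 20, 0.5),
        ]
        out = rank_guides("G", 3, guides, gene_stats_frame([]), guide_stats_frame([]), self.cfg)
        assert [g.protospacer[0] for g in out] == ["A", "C"]


def _ranked_gene(gene, n_guides):
    return [
        make_guide(f"{gene}_g{i}", gene, f"{'ACGT'[i % 4]}" * 10 + f"{'ACGT'[i // 4]}" * 10)
        for i in range(n_guides)
    ]


class TestBuildLibrary:
    controls = [("G" * 10 + "T" * 10, "T" * 10 + "G" * 10)] + [
        ("".join("ACGT"[(i + j) % 4] for j in range(20)),
         "".join("TGCA"[(i + j) % 4] for j in range(20)))
        for i in range(120)
    ]

    def test_950_targeting_gives_exactly_5_percent_controls(self):
        ranked = {f"G{i:03d}": _ranked_gene(f"G{i:03d}", 2) for i in range(950)}
        lib = build_library(ranked, self.controls, 0.05, rank_pairs=("1_2",))
        elems = lib["1_2"]
        n_ctrl = sum(1 for e in elems if e.is_control)
        assert n_ctrl == 50
        assert len(elems) == 1000
        assert n_ctrl / len(elems) == 0.05

    def test_ceil_arithmetic_at_1000(self):
        assert n_controls(1000, 0.05) == 53

    def test_gene_with_four_guides_absent_from_5_6(self):
        ranked = {"GA": _ranked_gene("GA", 4)}
        lib = build_library(ranked, self.controls, 0.05)
        assert any(e.gene == "GA" for e in lib["1_2"])
        assert any(e.gene == "GA" for e in lib["3_4"])
        assert not any(e.gene == "GA" for e in lib["5_6"])

    def test_insufficient_controls_error_names_count(self):
        ranked = {f"G{i}": _ranked_gene(f"G{i}", 2) for i in range(100)}
        with pytest.raises(ValueError, match="6 control pairs required"):
            build_library(ranked, self.controls[:2], 0.05, rank_pairs=("1_2",))

    def test_control_fraction_within_one_element(self):
        for n_genes in (7, 33, 100, 431):
            ranked = {f"G{i:03d}": _ranked_gene(f"G{i:03d}", 2) for i in range(n_genes)}
            lib = build_library(ranked, self.controls, 0.05, rank_pairs=("1_2",))
            elems = lib["1_2"]
            n_ctrl = sum(1 for e in elems if e.is_control)
            # one fewer control would fall below the requested fraction
            assert n_ctrl / len(elems) >= 0.05
            assert (n_ctrl - 1) / (len(elems) - 1) < 0.05


class TestDualOligo:
    def test_bit_exact_concatenation(self):
        e = DualElement("E", "G", "A" * 20, "C" * 20, "1_2")
        oligo = assemble_dual_oligo(e)
        assert len(oligo) == 20 + 11 + 44 + 20 + 17 == 112
        assert oligo.startswith("CCACCTTGTTG" + "A" * 20)
        assert oligo == (
            "CCACCTTGTTG" + "A" * 20
            + "GTTTCAGAGCGAGACGTGCCTGCAGGATACGTCTCAGAAACATG"
            + "C" * 20 + "GTTTAAGAGCTAAGCTG"
        )

    def test_adaptors_add_length(self):
        e = DualElement("E", "G", "A" * 20, "C" * 20, "1_2")
        oligo = assemble_dual_oligo(e, "G" * 15, "T" * 15)
        assert len(oligo) == 142

    @settings(max_examples=100, deadline=None)
    @given(proto20, proto20)
    def test_round_trip_identity(self, a, b):
        if a == b:
            b = b[:-1] + ("A" if b[-1] != "A" else "C")
        e = DualElement("E", "G", a, b, "1_2")
        oligo = assemble_dual_oligo(e, "GATTACAGATTACA", "TACCATTACCAT")
        assert parse_dual_oligo(oligo, "GATTACAGATTACA", "TACCATTACCAT") == (a, b)
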