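"""Empirical tiered sgRNA selection and dual-sgRNA element assembly.

A compact CRISPRi library targets each gene with a single element
carrying two sgRNAs expressed from tandem U6 cassettes. Guides are
chosen per gene by a three-tier scheme that prefers empirical screen
activity over predicted activity:

* **Tier 1** — genes essential for growth in the K562 reference screen
  (p < 0.001 and gene-level growth phenotype gamma < -0.2): guides are
  ranked by their growth phenotypes, expressed relative to the
  best-performing guide for that gene in each qualifying screen.
* **Tier 2** — genes with reproducible empirical phenotypes elsewhere:
  either a significant hit (gene FDR <= 0.05) in five or more screens,
  or hit in one to four screens with a cross-screen discriminant score
  exceeding a null threshold derived from olfactory-receptor genes
  (a gene family expected to be phenotypically inert in cell lines).
  Guides that were themselves hits (guide FDR < 0.01) in at least one
  hit screen are ranked by their mean relative phenotype across hit
  screens; remaining guides follow, ordered by predicted activity.
* **Tier 3** — all other genes: guides are ranked by the predicted
  activity score supplied with the input table (consumed as-is, never
  recomputed here).

Guides containing a BsmBI recognition site are removed before ranking
because the site would be cut during Golden Gate cloning of the tandem
cassette.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BSMBI_SITES, validate_dna

logger = logging.getLogger(__name__)

#: gene label used for non-targeting control elements
CONTROL_LABEL = "non-targeting"

#: sublibrary labels, pairing guide ranks (1,2), (3,4), (5,6)
RANK_PAIRS = ("1_2", "3_4", "5_6")

# Constant regions of the dual-sgRNA synthesis oligo: the sequence
# 5' of guide A, the inter-guide linker carrying the BsmBI cut sites
# used to insert the second promoter cassette, and the scaffold start
# 3' of guide B.
OLIGO_5_CONST = "CCACCTTGTTG"
OLIGO_LINKER = "GTTTCAGAGCGAGACGTGCCTGCAGGATACGTCTCAGAAACATG"
OLIGO_3_CONST = "GTTTAAGAGCTAAGCTG"


@dataclass(frozen=True)
class GuideRecord:
    """One candidate protospacer for one gene."""

    guide_id: str
    gene: str
    protospacer: str
    predicted_score: float
    transcript: Optional[str] = None

    def __post_init__(self):
        seq = validate_dna(self.protospacer, name=f"guide {self.guide_id}")
        if len(seq) not in (19, 20):
            raise ValueError(
                f"guide {self.guide_id}: protospacer length {len(seq)} not in (19, 20)"
            )
        object.__setattr__(self, "protospacer", seq)


@dataclass
class TierAssignment:
    gene: str
    tier: int
    n_hit_screens: int
    discriminant_score: Optional[float] = None
    threshold_used: Optional[float] = None


@dataclass(frozen=True)
class DualElement:
    """An ordered pair of guides targeting one gene, or an NTC pair."""

    element_id: str
    gene: str
    protospacer_a: str
    protospacer_b: str
    rank_pair: str
    ibc: Optional[str] = None

    def __post_init__(self):
        a = validate_dna(self.protospacer_a, name=f"{self.element_id} guide A")
        b = validate_dna(self.protospacer_b, name=f"{self.element_id} guide B")
        if a == b:
            raise ValueError(f"{self.element_id}: guide A and guide B are identical")
        object.__setattr__(self, "protospacer_a", a)
        object.__setattr__(self, "protospacer_b", b)

    @property
    def is_control(self) -> bool:
        return self.gene == CONTROL_LABEL


@dataclass
class DesignConfig:
    """Thresholds of the tiering scheme (all overridable)."""

    k562_screen: str = "k562_growth"
    tier1_max_p: float = 0.001
    tier1_max_gamma: float = -0.2
    hit_fdr: float = 0.05
    guide_hit_fdr: float = 0.01
    min_hit_screens: int = 5
    control_fraction: float = 0.05


# ---------------------------------------------------------------------------
# guide filtering and per-screen transforms


def filter_bsmbi(guides: Sequence[GuideRecord]) -> list[GuideRecord]:
    """Drop guides whose protospacer contains a BsmBI site on either strand.

    The two literal substrings are mutual reverse complements, so scanning
    the protospacer string for both covers both strands. Order is
    preserved; the input is untouched.
    """
    return [
        g for g in guides if not any(site in g.protospacer for site in BSMBI_SITES)
    ]


def relative_phenotypes(phenotypes: Mapping[str, float]) -> dict[str, float]:
    """Phenotypes of one gene's guides in one screen, relative to the best.

    Each phenotype is divided by the phenotype of largest absolute value
    among the gene's guides in that screen, so the best guide maps to 1.0
    and sign is preserved relative to it.
    """
    if not phenotypes:
        return {}
    finite = {g: p for g, p in phenotypes.items() if np.isfinite(p)}
    if not finite:
        raise ValueError("relative_phenotypes: no finite phenotype supplied")
    best = max(finite.values(), key=abs)
    if best == 0:
        warnings.warn(
            "all phenotypes are zero; relative phenotypes set to 0", stacklevel=2
        )
        return {g: 0.0 for g in phenotypes}
    return {g: p / best for g, p in phenotypes.items()}


def zscore_phenotypes(guide_stats: pd.DataFrame) -> pd.DataFrame:
    """Z-score guide phenotypes within each screen (mean 0, sd 1).

    Expects columns ``screen_id, guide_id, phenotype``; returns a copy
    with a ``z`` column. The sd is the population sd across all guides
    measured in the screen.
    """
    out = guide_stats.copy()
    grp = out.groupby("screen_id")["phenotype"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=0))
    out["z"] = (out["phenotype"] - mean) / sd.replace(0.0, np.nan)
    return out


# ---------------------------------------------------------------------------
# discriminant score and olfactory null thresholds


def _top3_mean_z(z_values: np.ndarray) -> float:
    """Signed mean of the (up to) three z-scores of largest magnitude."""
    z = z_values[np.isfinite(z_values)]
    if z.size == 0:
        return np.nan
    top = z[np.argsort(-np.abs(z), kind="stable")][:3]
    return float(top.mean())


def discriminant_scores(
    gene_stats: pd.DataFrame,
    guide_stats_z: pd.DataFrame,
    guide_genes: Mapping[str, str],
    hit_fdr: float = 0.05,
) -> pd.DataFrame:
    """Cross-screen discriminant score for every gene with 1+ hit screens.

    Per screen in which a gene is a hit (gene FDR <= ``hit_fdr``), the
    per-screen score is ``d = (-log10 p) * mean z of the top-3 guides``
    (top by absolute z; the sign of the mean is kept). When a screen
    carries multiple records for the gene (e.g. per transcript), the
    record maximizing ``|d|`` is used. The gene score is the sum of
    ``|d|`` over hit screens.

    Returns a DataFrame indexed by gene with columns
    ``n_hit_screens, score``; genes with no hit screen are absent.
    """
    hits = gene_stats[gene_stats["gene_fdr"] <= hit_fdr]
    if hits.empty:
        return pd.DataFrame(columns=["n_hit_screens", "score"])

    gz = guide_stats_z.copy()
    gz["gene"] = gz["guide_id"].map(guide_genes)
    z_lookup: dict[tuple[str, str], float] = {}
    for (screen, gene), sub in gz.groupby(["screen_id", "gene"], sort=False):
        z_lookup[(screen, gene)] = _top3_mean_z(sub["z"].to_numpy())

    rows = []
    for gene, sub in hits.groupby("gene", sort=False):
        total = 0.0
        n_screens = 0
        for screen, screc in sub.groupby("screen_id", sort=False):
            zbar = z_lookup.get((screen, gene), np.nan)
            if not np.isfinite(zbar):
                continue
            d = (-np.log10(screc["p_value"].to_numpy())) * zbar
            total += float(np.max(np.abs(d)))
            n_screens += 1
        if n_screens:
            rows.append((gene, n_screens, total))
    return pd.DataFrame(
        rows, columns=["gene", "n_hit_screens", "score"]
    ).set_index("gene")


def olfactory_thresholds(
    olfactory_scores: Mapping[str, tuple[int, float]], max_k: int = 4
) -> dict[int, float]:
    """Null-score thresholds from the olfactory-receptor gene set.

    ``threshold(k)`` is the maximum discriminant score among olfactory
    genes hit in exactly ``k`` screens. If no olfactory gene was hit in
    exactly ``k`` screens, fall back to the maximum over olfactory genes
    with at most ``k`` hits; if the set is empty up to ``k``, the
    threshold is +inf (no gene can pass via score at that k). Using the
    maximum (not a quantile) guarantees no olfactory gene itself would
    pass.
    """
    by_k: dict[int, list[float]] = defaultdict(list)
    for _gene, (k, score) in olfactory_scores.items():
        by_k[int(k)].append(float(score))
    out: dict[int, float] = {}
    for k in range(1, max_k + 1):
        exact = by_k.get(k, [])
        if exact:
            out[k] = max(exact)
            continue
        upto = [s for kk, ss in by_k.items() if 1 <= kk <= k for s in ss]
        out[k] = max(upto) if upto else math.inf
    return out


def assign_tier(
    gene: str,
    gene_stats: pd.DataFrame,
    disc: pd.DataFrame,
    thresholds: Mapping[int, float],
    cfg: DesignConfig,
) -> TierAssignment:
    """Place one gene into tier 1, 2, or 3 (precedence strictly 1 > 2 > 3)."""
    k562 = gene_stats[
        (gene_stats["screen_id"] == cfg.k562_screen) & (gene_stats["gene"] == gene)
    ]
    if k562.empty:
        logger.debug("gene %s absent from K562 reference screen", gene)
    else:
        gam = k562.get("k562_gamma")
        meets = (
            (k562["p_value"] < cfg.tier1_max_p)
            & gam.notna()
            & (gam < cfg.tier1_max_gamma)
        )
        if bool(meets.any()):
            n_hits = int(disc.loc[gene, "n_hit_screens"]) if gene in disc.index else 0
            return TierAssignment(gene, 1, n_hits)

    if gene in disc.index:
        n_hits = int(disc.loc[gene, "n_hit_screens"])
        score = float(disc.loc[gene, "score"])
        if n_hits >= cfg.min_hit_screens:
            return TierAssignment(gene, 2, n_hits)
        if 1 <= n_hits <= 4:
            thr = thresholds.get(n_hits, math.inf)
            if score > thr:
                return TierAssignment(gene, 2, n_hits, score, thr)
            return TierAssignment(gene, 3, n_hits, score, thr)
    return TierAssignment(gene, 3, 0)


def assign_tiers(
    genes: Iterable[str],
    gene_stats: pd.DataFrame,
    disc: pd.DataFrame,
    thresholds: Mapping[int, float],
    cfg: DesignConfig,
) -> dict[str, TierAssignment]:
    return {g: assign_tier(g, gene_stats, disc, thresholds, cfg) for g in genes}


# ---------------------------------------------------------------------------
# guide ranking


def _mean_relative_phenotype(
    guides: Sequence[GuideRecord],
    guide_stats: pd.DataFrame,
    screens: Sequence[str],
) -> dict[str, float]:
    """Mean of per-screen relative phenotypes for each guide, over screens."""
    ids = {g.guide_id for g in guides}
    per_guide: dict[str, list[float]] = defaultdict(list)
    for screen in screens:
        sub = guide_stats[
            (guide_stats["screen_id"] == screen) & guide_stats["guide_id"].isin(ids)
        ]
        if sub.empty:
            continue
        rel = relative_phenotypes(
            dict(zip(sub["guide_id"], sub["phenotype"]))
        )
        for gid, v in rel.items():
            per_guide[gid].append(v)
    return {gid: float(np.mean(v)) for gid, v in per_guide.items() if v}


def rank_guides(
    gene: str,
    tier: int,
    guides: Sequence[GuideRecord],
    gene_stats: pd.DataFrame,
    guide_stats: pd.DataFrame,
    cfg: DesignConfig,
) -> list[GuideRecord]:
    """Order one gene's (BsmBI-filtered) guides by the tier's rule.

    Ties are broken by ascending protospacer lexicographic order so that
    output is byte-stable across runs.
    """
    gsub = gene_stats[gene_stats["gene"] == gene]
    hit_screens = sorted(
        gsub.loc[gsub["gene_fdr"] <= cfg.hit_fdr, "screen_id"].unique()
    )

    if tier == 1:
        screens = hit_screens if hit_screens else [cfg.k562_screen]
        mean_rel = _mean_relative_phenotype(guides, guide_stats, screens)
        return sorted(
            guides,
            key=lambda g: (
                -mean_rel.get(g.guide_id, -math.inf),
                g.protospacer,
            ),
        )

    if tier == 2:
        mean_rel = _mean_relative_phenotype(guides, guide_stats, hit_screens)
        ids = {g.guide_id for g in guides}
        elig_rows = guide_stats[
            guide_stats["guide_id"].isin(ids)
            & guide_stats["screen_id"].isin(hit_screens)
            & (guide_stats["guide_fdr"] < cfg.guide_hit_fdr)
        ]
        eligible = set(elig_rows["guide_id"])
        return sorted(
            guides,
            key=lambda g: (
                0 if g.guide_id in eligible else 1,
                -mean_rel.get(g.guide_id, -math.inf)
                if g.guide_id in eligible
                else -g.predicted_score,
                g.protospacer,
            ),
        )

    # tier 3: predicted activity only
    return sorted(guides, key=lambda g: (-g.predicted_score, g.protospacer))


# ---------------------------------------------------------------------------
# element construction


def n_controls(n_targeting: int, control_fraction: float) -> int:
    """Control count so controls make up ``control_fraction`` of the library.

    ``n = ceil(T * f / (1 - f))`` for T targeting elements and fraction f.
    """
    if not 0 <= control_fraction < 1:
        raise ValueError("control_fraction must be in [0, 1)")
    return math.ceil(n_targeting * control_fraction / (1.0 - control_fraction))


def build_library(
    ranked: Mapping[str, Sequence[GuideRecord]],
    control_pairs: Sequence[tuple[str, str]],
    control_fraction: float = 0.05,
    rank_pairs: Sequence[str] = RANK_PAIRS,
    ibcs: Optional[Sequence[str]] = None,
) -> dict[str, list[DualElement]]:
    """Assemble per-sublibrary dual-sgRNA elements from ranked guides.

    Sublibrary ``1_2`` pairs each gene's rank-1 and rank-2 guides, ``3_4``
    ranks 3 and 4, ``5_6`` ranks 5 and 6; a gene appears in as many
    sublibraries as its guide count allows (a gene with fewer than two
    guides is skipped with a warning). Non-targeting control pairs are
    appended to each sublibrary, taken in order from ``control_pairs``,
    at ``control_fraction`` of the sublibrary's total size. If an
    ``ibcs`` pool is given, barcodes are assigned to elements by cycling
    through the pool in order.
    """
    out: dict[str, list[DualElement]] = {}
    for i, rp in enumerate(rank_pairs):
        lo = 2 * i
        elements: list[DualElement] = []
        for gene in sorted(ranked):
            gl = ranked[gene]
            if len(gl) < lo + 2:
                if i == 0:
                    warnings.warn(
                        f"gene {gene} has {len(gl)} usable guide(s); "
                        "needs >= 2 for a dual element",
                        stacklevel=2,
                    )
                continue
            elements.append(
                DualElement(
                    element_id=f"{gene}_{rp}",
                    gene=gene,
                    protospacer_a=gl[lo].protospacer,
                    protospacer_b=gl[lo + 1].protospacer,
                    rank_pair=rp,
                )
            )
        need = n_controls(len(elements), control_fraction)
        if need > len(control_pairs):
            raise ValueError(
                f"sublibrary {rp}: {need} control pairs required, "
                f"{len(control_pairs)} supplied"
            )
        for j in range(need):
            a, b = control_pairs[j]
            elements.append(
                DualElement(
                    element_id=f"NTC_{rp}_{j:04d}",
                    gene=CONTROL_LABEL,
                    protospacer_a=a,
                    protospacer_b=b,
                    rank_pair="control",
                )
            )
        if ibcs is not None:
            elements = [
                DualElement(
                    e.element_id, e.gene, e.protospacer_a, e.protospacer_b,
                    e.rank_pair, ibcs[k % len(ibcs)],
                )
                for k, e in enumerate(elements)
            ]
        out[rp] = elements
    return out


# ---------------------------------------------------------------------------
# synthesis oligos


def assemble_dual_oligo(
    element: DualElement, adaptor_5: str = "", adaptor_3: str = ""
) -> str:
    """Synthesis oligo for one dual-sgRNA element.

    Exact concatenation of the 5' PCR adaptor, the constant region
    upstream of guide A, guide A, the BsmBI-bearing linker, guide B, the
    scaffold start, and the 3' PCR adaptor — uppercase and invertible
    (the guides can be recovered by splitting on the constant regions).
    """
    oligo = (
        adaptor_5.upper()
        + OLIGO_5_CONST
        + element.protospacer_a
        + OLIGO_LINKER
        + element.protospacer_b
        + OLIGO_3_CONST
        + adaptor_3.upper()
    )
    try:
        recovered = parse_dual_oligo(oligo, adaptor_5, adaptor_3)
    except ValueError:
        recovered = None
    if recovered != (element.protospacer_a, element.protospacer_b):
        warnings.warn(
            f"{element.element_id}: oligo is not invertible (a protospacer "
            "collides with a constant region)",
            stacklevel=2,
        )
    return oligo


def parse_dual_oligo(
    oligo: str, adaptor_5: str = "", adaptor_3: str = ""
) -> tuple[str, str]:
    """Recover (guide A, guide B) from a synthesis oligo."""
    up = oligo.upper()
    a5, a3 = adaptor_5.upper(), adaptor_3.upper()
    if not (up.startswith(a5) and up.endswith(a3 if a3 else "")):
        raise ValueError("oligo does not carry the expected PCR adaptors")
    core = up[len(a5) : len(up) - len(a3)] if a3 else up[len(a5) :]
    if not (core.startswith(OLIGO_5_CONST) and core.endswith(OLIGO_3_CONST)):
        raise ValueError("oligo does not match the constant cassette regions")
    middle = core[len(OLIGO_5_CONST) : len(core) - len(OLIGO_3_CONST)]
    parts = middle.split(OLIGO_LINKER)
    if len(parts) != 2:
        raise ValueError("oligo linker is absent or ambiguous")
    return parts[0], parts[1]


# ---------------------------------------------------------------------------
# end-to-end driver


def design_library(
    guides: Sequence[GuideRecord],
    guide_stats: pd.DataFrame,
    gene_stats: pd.DataFrame,
    olfactory_genes: Iterable[str],
    control_pairs: Sequence[tuple[str, str]],
    cfg: Optional[DesignConfig] = None,
    ibcs: Optional[Sequence[str]] = None,
) -> tuple[dict[str, TierAssignment], dict[str, list[DualElement]]]:
    """Run the full selection pipeline: filter, tier, rank, assemble."""
    cfg = cfg or DesignConfig()
    kept = filter_bsmbi(guides)
    by_gene: dict[str, list[GuideRecord]] = defaultdict(list)
    for g in kept:
        by_gene[g.gene].append(g)

    guide_genes = {g.guide_id: g.gene for g in guides}
    gz = zscore_phenotypes(guide_stats)
    disc = discriminant_scores(gene_stats, gz, guide_genes, cfg.hit_fdr)

    olf = set(olfactory_genes)
    olf_scores = {
        g: (int(disc.loc[g, "n_hit_screens"]), float(disc.loc[g, "score"]))
        for g in olf
        if g in disc.index
    }
    thresholds = olfactory_thresholds(olf_scores)

    target_genes = [g for g in sorted(by_gene) if g not in olf]
    tiers = assign_tiers(target_genes, gene_stats, disc, thresholds, cfg)
    ranked = {
        gene: rank_guides(gene, tiers[gene].tier, by_gene[gene], gene_stats,
                          guide_stats, cfg)
        for gene in target_genes
    }
    elements = build_library(
        ranked, control_pairs, cfg.control_fraction, ibcs=ibcs
    )
    return tiers, elements
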