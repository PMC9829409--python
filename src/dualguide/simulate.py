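"""Synthetic dual-sgRNA screens with complete ground truth.

The simulator emulates the data-generating process of a pooled
dual-sgRNA CRISPRi growth screen end to end:

1. **Library** — one dual-guide element per gene plus a proportion of
   non-targeting control (NTC) pairs, with deterministic guide
   sequences whose 19-nt prefixes are pairwise distinct.
2. **Packaging and integration** — each cell receives one integration
   derived from a virion carrying two genomes drawn i.i.d. from the
   library pool. With probability ``p_switch`` the reverse
   transcriptase template-switches in the invariant region between the
   two guide cassettes, so the integrated cassette carries guide A of
   genome 1 and guide B of genome 2. Switching is sequence-independent
   (the invariant region dwarfs the 20-bp variable regions). A switch
   is *detectable* only when the two genomes differ in target gene (or
   differ at all, for NTC pairs), so the expected detectable fraction
   is ``p_switch * (1 - sum of squared element frequencies)``.
3. **Growth** — over ``doublings`` population doublings, the abundance
   of an integration changes by ``2**(gamma * doublings)`` relative to
   NTCs, where gamma is the per-doubling growth phenotype of the
   targeted gene (configurable attribution for chimeras).
4. **Sequencing** — reads are drawn multinomially at a fixed depth per
   sample and written as the four FASTQ streams of the screen layout
   (19-nt R1 = guide A, 19-nt R2 = guide B on the opposite strand, 8-nt
   I1 = sample index, 8-nt I2 = integration barcode).

All randomness flows from the single ``seed``; identical configs
produce byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BSMBI_SITES, DNA_ALPHABET, reverse_complement
from .ibc import generate_ibcs
from .library_design import CONTROL_LABEL, DualElement, n_controls

READ_LEN = 19
QUAL_CHAR = "I"  # constant Q40

#: sample indices handed out to samples in order (8-nt, distance >= 3)
DEFAULT_SAMPLE_INDEXES = (
    "AAGGCCTT", "CCTTAAGG", "GGAACCAA", "TTCCGGAA",
    "ACACGTGT", "GTGTACAC", "CAGTTGAC", "TGACCAGT",
)


@dataclass
class SimConfig:
    """Study conditions for one simulated screen."""

    n_genes: int
    seed: int
    ntc_fraction: float = 0.05
    p_switch: float = 0.0
    fitness: Mapping[str, float] = field(default_factory=dict)
    doublings: float = 10.0
    depth: int = 1_000_000
    n_cells: int = 100_000
    read2_revcomp: bool = True
    chimera_fitness: str = "guide_a"  # guide_a | mean | zero
    error_rate: float = 0.0
    pool_freqs: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not (0.0 <= self.p_switch <= 1.0):
            raise ValueError("p_switch must be in [0, 1]")
        if not (0.0 <= self.ntc_fraction < 1.0):
            raise ValueError("ntc_fraction must be in [0, 1)")
        if self.depth <= 0 or self.n_cells <= 0 or self.n_genes < 1:
            raise ValueError("depth, n_cells and n_genes must be positive")
        if self.chimera_fitness not in ("guide_a", "mean", "zero"):
            raise ValueError("chimera_fitness must be guide_a, mean, or zero")


@dataclass
class SimTruth:
    """Ground truth of integrations for recovery tests."""

    a_element: np.ndarray  # per cell: element index providing guide A
    b_element: np.ndarray  # per cell: element index providing guide B
    switched: np.ndarray  # per cell: template switch occurred
    recombined: np.ndarray  # per cell: switch detectable (genes differ)
    true_gamma: dict[str, float]  # element_id -> per-doubling phenotype

    @property
    def realized_recombined_fraction(self) -> float:
        return float(self.recombined.mean())


@dataclass
class SimSequencing:
    """Emitted FASTQ paths and the count table they should produce."""

    fastq: dict[str, dict[str, Path]]  # sample -> {r1, r2, i1, i2}
    expected_counts: pd.DataFrame  # element × sample, matched reads only
    sample_index: dict[str, str]  # sample -> 8-nt index sequence


# ---------------------------------------------------------------------------
# library


def _guide_stream():
    """Deterministic 20-nt guides with distinct 19-nt prefixes, no BsmBI site."""
    k = 0
    while True:
        digits = []
        v = k
        for _ in range(READ_LEN):
            digits.append(DNA_ALPHABET[v & 3])
            v >>= 2
        seq = "".join(reversed(digits)) + "A"
        k += 1
        if any(site in seq for site in BSMBI_SITES):
            continue
        yield seq


@lru_cache(maxsize=1)
def _default_ibcs() -> tuple[str, ...]:
    return tuple(generate_ibcs(max_n=215))


def make_library(cfg: SimConfig) -> list[DualElement]:
    """One targeting element per gene plus NTC pairs at ``ntc_fraction``."""
    n_ntc = n_controls(cfg.n_genes, cfg.ntc_fraction)
    stream = _guide_stream()
    ibcs = _default_ibcs()
    elements: list[DualElement] = []
    for i in range(cfg.n_genes):
        elements.append(
            DualElement(
                element_id=f"GENE{i:04d}_1_2",
                gene=f"GENE{i:04d}",
                protospacer_a=next(stream),
                protospacer_b=next(stream),
                rank_pair="1_2",
                ibc=ibcs[i % len(ibcs)],
            )
        )
    for j in range(n_ntc):
        elements.append(
            DualElement(
                element_id=f"NTC_{j:04d}",
                gene=CONTROL_LABEL,
                protospacer_a=next(stream),
                protospacer_b=next(stream),
                rank_pair="control",
                ibc=ibcs[(cfg.n_genes + j) % len(ibcs)],
            )
        )
    return elements


# ---------------------------------------------------------------------------
# packaging / integration


def simulate_integrations(cfg: SimConfig, library: Sequence[DualElement]) -> SimTruth:
    """Draw one integration per cell from two co-packaged genomes."""
    rng = np.random.default_rng([cfg.seed, 1])
    n_elem = len(library)
    if cfg.pool_freqs is not None:
        freqs = np.asarray(cfg.pool_freqs, dtype=float)
        if freqs.size != n_elem or not math.isclose(freqs.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("pool_freqs must sum to 1 with one entry per element")
        g1 = rng.choice(n_elem, size=cfg.n_cells, p=freqs)
        g2 = rng.choice(n_elem, size=cfg.n_cells, p=freqs)
    else:
        g1 = rng.integers(n_elem, size=cfg.n_cells)
        g2 = rng.integers(n_elem, size=cfg.n_cells)
    switched = rng.random(cfg.n_cells) < cfg.p_switch

    genes = np.array([e.gene for e in library])
    is_ntc = genes == CONTROL_LABEL
    diff_gene = genes[g1] != genes[g2]
    diff_ntc = is_ntc[g1] & is_ntc[g2] & (g1 != g2)
    recombined = switched & (diff_gene | diff_ntc)

    b_element = np.where(switched, g2, g1)
    true_gamma = {
        e.element_id: (0.0 if e.is_control else float(cfg.fitness.get(e.gene, 0.0)))
        for e in library
    }
    return SimTruth(g1, b_element, switched, recombined, true_gamma)


def expected_detectable_fraction(cfg: SimConfig, library: Sequence[DualElement]) -> float:
    """Closed-form ``p_switch * (1 - sum f^2)`` for the configured pool."""
    n_elem = len(library)
    if cfg.pool_freqs is not None:
        f = np.asarray(cfg.pool_freqs, dtype=float)
    else:
        f = np.full(n_elem, 1.0 / n_elem)
    # NTC × NTC pairs of distinct elements are detectable as well, so
    # the collision term is per element, not per gene.
    return cfg.p_switch * (1.0 - float((f**2).sum()))


# ---------------------------------------------------------------------------
# growth and sequencing


def _integration_gamma(
    cfg: SimConfig, truth: SimTruth, library: Sequence[DualElement]
) -> np.ndarray:
    gam = np.array([truth.true_gamma[e.element_id] for e in library])
    ga = gam[truth.a_element]
    if cfg.chimera_fitness == "guide_a":
        return ga
    gb = gam[truth.b_element]
    chim = truth.switched & (truth.a_element != truth.b_element)
    if cfg.chimera_fitness == "mean":
        return np.where(chim, 0.5 * (ga + gb), ga)
    return np.where(chim, 0.0, ga)  # zero


def _apply_errors(seqs: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return seqs
    out = seqs.copy()
    for i, s in enumerate(out):
        mask = rng.random(len(s)) < rate
        if mask.any():
            chars = list(s)
            for j in np.nonzero(mask)[0]:
                choices = [c for c in DNA_ALPHABET if c != chars[j]]
                chars[j] = choices[rng.integers(3)]
            out[i] = "".join(chars)
    return out


def _write_fastq(path: Path, ids: Sequence[str], seqs: Sequence[str]) -> None:
    with open(path, "w") as fh:
        chunks = []
        for rid, seq in zip(ids, seqs):
            chunks.append(f"@{rid}\n{seq}\n+\n{QUAL_CHAR * len(seq)}\n")
            if len(chunks) >= 100_000:
                fh.write("".join(chunks))
                chunks = []
        fh.write("".join(chunks))


def simulate_growth_and_sequencing(
    cfg: SimConfig,
    truth: SimTruth,
    library: Sequence[DualElement],
    out_dir,
    samples: Sequence[str] = ("T0", "Tfinal"),
) -> SimSequencing:
    """Sample reads at T0 and Tfinal and write the four FASTQ streams.

    The first sample in ``samples`` is the pre-growth population (every
    integration at equal abundance); all later samples are post-growth
    (abundance multiplied by ``2**(gamma * doublings)``). Reads are
    drawn multinomially at ``cfg.depth`` per sample.

    Returns the written paths plus the element × sample table of
    matched (same-gene) reads that a mismatch-free counter should
    reproduce exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 2])

    gam = _integration_gamma(cfg, truth, library)
    w_t0 = np.ones(len(gam))
    w_tf = np.exp2(gam * cfg.doublings)

    seq_a = np.array([e.protospacer_a[:READ_LEN] for e in library], dtype=object)
    b_read = [e.protospacer_b[:READ_LEN] for e in library]
    if cfg.read2_revcomp:
        b_read = [reverse_complement(s) for s in b_read]
    seq_b = np.array(b_read, dtype=object)
    ibc_arr = np.array([e.ibc or "ACGTACGT" for e in library], dtype=object)
    element_ids = [e.element_id for e in library]

    fastq: dict[str, dict[str, Path]] = {}
    sample_index: dict[str, str] = {}
    expected = pd.DataFrame(0, index=element_ids, columns=list(samples), dtype=int)

    for si, sample in enumerate(samples):
        weights = w_t0 if si == 0 else w_tf
        p = weights / weights.sum()
        per_cell = rng.multinomial(cfg.depth, p)
        cell_idx = np.repeat(np.arange(len(p)), per_cell)
        rng.shuffle(cell_idx)

        a = truth.a_element[cell_idx]
        b = truth.b_element[cell_idx]
        r1 = seq_a[a]
        r2 = seq_b[b]
        if cfg.error_rate > 0:
            r1 = _apply_errors(r1, cfg.error_rate, rng)
            r2 = _apply_errors(r2, cfg.error_rate, rng)
        idx_seq = DEFAULT_SAMPLE_INDEXES[si % len(DEFAULT_SAMPLE_INDEXES)]
        sample_index[sample] = idx_seq
        ids = [f"{sample}:{i}" for i in range(len(cell_idx))]

        paths = {
            "r1": out_dir / f"{sample}_R1.fastq",
            "r2": out_dir / f"{sample}_R2.fastq",
            "i1": out_dir / f"{sample}_I1.fastq",
            "i2": out_dir / f"{sample}_I2.fastq",
        }
        _write_fastq(paths["r1"], ids, r1)
        _write_fastq(paths["r2"], ids, r2)
        _write_fastq(paths["i1"], ids, [idx_seq] * len(ids))
        _write_fastq(paths["i2"], ids, ibc_arr[a])
        fastq[sample] = paths

        matched_reads = ~truth.recombined[cell_idx]
        cnt = np.bincount(a[matched_reads], minlength=len(library))
        expected[sample] = cnt

    return SimSequencing(fastq, expected, sample_index)


# ---------------------------------------------------------------------------
# single-cell readout


def simulate_perturbseq(
    library: Sequence[DualElement],
    knockdown_truth: Mapping[str, float],
    cells_per_element: int,
    base_expression: float,
    seed: int,
    nonresponder_fraction: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, bool]]:
    """Poisson cell × gene counts with programmed per-element knockdown.

    Every cell carries one unambiguous element assignment. In a cell
    assigned to a targeting element, the target gene's Poisson mean is
    scaled by ``knockdown_truth[element]`` (fraction of mRNA
    remaining); NTC cells are unscaled. A ``nonresponder_fraction`` of
    each element's cells escape knockdown entirely (mean unscaled).

    Returns (counts DataFrame, cell -> element assignments,
    cell -> is_nonresponder truth).
    """
    rng = np.random.default_rng([seed, 3])
    genes = sorted({e.gene for e in library if not e.is_control})
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    cell_names = []
    assignments: dict[str, str] = {}
    nonresponder: dict[str, bool] = {}
    for e in library:
        frac = 1.0 if e.is_control else float(knockdown_truth.get(e.element_id, 1.0))
        for c in range(cells_per_element):
            cell = f"{e.element_id}:cell{c}"
            escape = (not e.is_control) and rng.random() < nonresponder_fraction
            mean = np.full(len(genes), base_expression)
            if not e.is_control and not escape:
                mean[gene_pos[e.gene]] = base_expression * frac
            rows.append(rng.poisson(mean))
            cell_names.append(cell)
            assignments[cell] = e.element_id
            nonresponder[cell] = escape
    expr = pd.DataFrame(np.vstack(rows), index=cell_names, columns=genes)
    return expr, assignments, nonresponder
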