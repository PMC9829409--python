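"""Growth-phenotype (gamma) statistics for pooled screens.

The growth phenotype of a library element is

    gamma = [log2(n_Tf / n_T0) - median_NTC log2(n_Tf / n_T0)] / doublings

where counts are depth-normalized (reads per million of matched reads
per sample), the median is over non-targeting control (NTC) elements in
the same replicate, and doublings is the replicate's total population
doublings. NTC centering puts the null phenotype at exactly 0; the
per-doubling scaling makes gamma comparable across screens of different
length. Gene-level gamma is the mean over a gene's elements.

Filtering follows the counting conventions of growth screens: elements
with zero reads receive a pseudocount of one read (after the coverage
filter is evaluated on raw counts), and elements with fewer than 50
reads at both T0 and Tfinal of any replicate are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FilterConfig:
    pseudocount: int = 1
    min_reads: int = 50

    def __post_init__(self):
        if self.pseudocount < 0 or self.min_reads < 0:
            raise ValueError("pseudocount and min_reads must be >= 0")


@dataclass(frozen=True)
class ReplicateInfo:
    replicate_id: str
    t0_sample: str
    tfinal_sample: str
    doublings: float

    def __post_init__(self):
        if not (np.isfinite(self.doublings) and self.doublings > 0):
            raise ValueError(
                f"replicate {self.replicate_id}: doublings must be finite and > 0"
            )


def apply_filters(
    counts: pd.DataFrame,
    replicates: Sequence[ReplicateInfo],
    cfg: Optional[FilterConfig] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pseudocount zeros and flag under-covered elements.

    An element is excluded iff in **some** replicate its raw count is
    below ``min_reads`` at T0 **and** at Tfinal (an element well covered
    at either timepoint of every replicate stays). The pseudocount is
    applied to zero counts only, after the coverage filter is evaluated
    on raw counts.

    Returns (pseudocounted counts, boolean Series ``excluded``).
    """
    cfg = cfg or FilterConfig()
    for rep in replicates:
        for s in (rep.t0_sample, rep.tfinal_sample):
            if s not in counts.columns:
                raise ValueError(f"sample {s!r} missing from count table")
    excluded = pd.Series(False, index=counts.index)
    for rep in replicates:
        low = (counts[rep.t0_sample] < cfg.min_reads) & (
            counts[rep.tfinal_sample] < cfg.min_reads
        )
        excluded |= low
    out = counts.where(counts > 0, cfg.pseudocount)
    return out, excluded


def gamma(
    counts: pd.DataFrame,
    replicate: ReplicateInfo,
    ntc_ids: Iterable[str],
    excluded: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-element gamma for one replicate.

    ``counts`` must already be pseudocounted; excluded elements get NaN.
    Depth normalization is reads-per-million over each sample column;
    any uniform rescaling of either sample cancels except through the
    NTC median, which is removed, so gamma is depth-invariant.
    """
    if excluded is None:
        excluded = pd.Series(False, index=counts.index)
    keep = ~excluded
    t0 = counts.loc[keep, replicate.t0_sample].astype(float)
    tf = counts.loc[keep, replicate.tfinal_sample].astype(float)
    rpm0 = t0 * 1e6 / counts[replicate.t0_sample].sum()
    rpmf = tf * 1e6 / counts[replicate.tfinal_sample].sum()
    log_ratio = np.log2(rpmf / rpm0)
    ntc = [i for i in ntc_ids if i in log_ratio.index]
    if not ntc:
        raise ValueError(
            f"replicate {replicate.replicate_id}: no unfiltered NTC element; "
            "cannot center phenotypes"
        )
    centered = (log_ratio - log_ratio.loc[ntc].median()) / replicate.doublings
    return centered.reindex(counts.index)


def aggregate_replicates(
    gammas: Mapping[str, pd.Series],
    gene_of: Optional[Mapping[str, str]] = None,
) -> tuple[pd.Series, Optional[pd.Series]]:
    """Mean gamma per element across replicates, and per gene.

    Elements filtered (NaN) in some replicates contribute their
    remaining replicates. Per-gene gamma is the mean over a gene's
    unfiltered elements (with a single element per gene they coincide).
    """
    df = pd.DataFrame(gammas)
    element_gamma = df.mean(axis=1, skipna=True)
    gene_gamma = None
    if gene_of is not None:
        genes = element_gamma.index.map(lambda e: gene_of.get(e))
        gene_gamma = element_gamma.groupby(genes).mean()
    return element_gamma, gene_gamma


def _auc_rank_sum(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney U rank-sum formulation with tie correction."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)  # midranks handle ties
    n1, n2 = len(pos_scores), len(neg_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def essential_recall_auc(
    gene_gammas: Mapping[str, float],
    positives: Iterable[str],
    negative_gammas: Iterable[float],
) -> float:
    """ROC AUC for recall of essential genes against NTC pairs.

    Positives are essential genes (by gene-level gamma); negatives are
    non-targeting control pairs (by element-level gamma). Items are
    ranked by depletion (score = -gamma).
    """
    gg = dict(gene_gammas)
    pos = np.array(
        [-gg[g] for g in positives if g in gg and np.isfinite(gg[g])], dtype=float
    )
    neg = np.array([-g for g in negative_gammas if np.isfinite(g)], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative classes must be non-empty")
    return _auc_rank_sum(pos, neg)


def compare_gene_sets(
    gammas_lib1: Mapping[str, float],
    gammas_lib2: Mapping[str, float],
    gene_set: Iterable[str],
) -> dict:
    """Compare two libraries' gamma over a shared gene set.

    Means over the intersection, a two-sided Mann–Whitney test (normal
    approximation with continuity and tie correction), and the percent
    change of library 2's mean relative to library 1's magnitude.
    """
    common = [
        g
        for g in gene_set
        if g in gammas_lib1
        and g in gammas_lib2
        and np.isfinite(gammas_lib1[g])
        and np.isfinite(gammas_lib2[g])
    ]
    if not common:
        raise ValueError("gene set has no genes measured in both libraries")
    x1 = np.array([gammas_lib1[g] for g in common])
    x2 = np.array([gammas_lib2[g] for g in common])
    res = stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    mean1, mean2 = float(x1.mean()), float(x2.mean())
    pct = 100.0 * (mean2 - mean1) / abs(mean1) if mean1 != 0 else np.nan
    return {
        "n": len(common),
        "mean1": mean1,
        "mean2": mean2,
        "mannwhitney_u": float(res.statistic),
        "mannwhitney_p": float(res.pvalue),
        "percent_change": pct,
    }


def competitive_growth_defect(
    ratio_timecourse: Sequence[tuple[float, float]], horizon_day: float
) -> dict:
    """Growth defect from a competitive flow-cytometry time course.

    ``ratio_timecourse`` holds (day, ratio of effector-expressing to
    reference cells). Each ratio is log2-normalized to day 0; the
    average percent growth defect per day is 100 × log2(ratio at the
    horizon / ratio at day 0) / horizon_day.
    """
    by_day = dict(ratio_timecourse)
    if 0 not in by_day and 0.0 not in by_day:
        raise ValueError("time course must include day 0")
    r0 = by_day.get(0, by_day.get(0.0))
    if not (r0 and r0 > 0):
        raise ValueError("day-0 ratio must be > 0")
    if horizon_day not in by_day:
        raise ValueError(f"horizon day {horizon_day} absent from time course")
    log2_norm = {d: float(np.log2(r / r0)) for d, r in by_day.items()}
    pct = 100.0 * log2_norm[horizon_day] / horizon_day
    return {"log2_normalized": log2_norm, "percent_per_day": pct}
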