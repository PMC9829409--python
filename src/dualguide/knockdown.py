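"""Knockdown quantification from single-cell and flow-cytometry readouts.

On-target knockdown of a CRISPRi element is measured as the fraction of
target mRNA remaining: mean depth-normalized target-gene expression in
cells bearing the element, divided by the same mean in cells bearing
non-targeting control (NTC) guides. Knockdown percent is
``100 * (1 - fraction_remaining)``. Only cells with a single, unambiguous
guide assignment should be supplied; assignment itself is upstream of
this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

try:  # AnnData input is convenient but optional
    from anndata import AnnData
except ImportError:  # pragma: no cover
    AnnData = None


@dataclass(frozen=True)
class KnockdownRecord:
    element_id: str
    gene: str
    fraction_remaining: float
    n_cells: int

    @property
    def knockdown_percent(self) -> float:
        return 100.0 * (1.0 - self.fraction_remaining)


def _as_frame(expr) -> pd.DataFrame:
    """Accept a cells × genes DataFrame or AnnData and return a DataFrame."""
    if isinstance(expr, pd.DataFrame):
        return expr
    if AnnData is not None and isinstance(expr, AnnData):
        x = expr.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return pd.DataFrame(np.asarray(x), index=expr.obs_names, columns=expr.var_names)
    raise TypeError("expr must be a pandas DataFrame or AnnData (cells × genes)")


def normalize_per_cell(expr: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Scale each cell to ``target_sum`` total counts (cells with 0 total kept as 0)."""
    totals = expr.sum(axis=1)
    scale = target_sum / totals.replace(0, np.nan)
    return expr.mul(scale, axis=0).fillna(0.0)


def perturbseq_knockdown(
    expr,
    assignments: Mapping[str, str],
    ntc_elements: Iterable[str],
    gene_of: Mapping[str, str],
    target_sum: float = 1e4,
) -> list[KnockdownRecord]:
    """Fraction of target mRNA remaining per element.

    Expression is normalized per cell to ``target_sum`` total counts
    before averaging (ratio of means, which is robust to zeros in
    sparse cells). NTC elements are evaluated too (their "target" is
    undefined, so they are skipped unless ``gene_of`` names a readout
    gene for them).

    Parameters
    ----------
    expr
        cells × genes counts (DataFrame or AnnData).
    assignments
        cell -> element, single-assignment cells only.
    gene_of
        element -> target gene symbol.
    """
    mat = _as_frame(expr)
    norm = normalize_per_cell(mat, target_sum)
    ntc = set(ntc_elements)

    cells_by_element: dict[str, list[str]] = {}
    for cell, elem in assignments.items():
        if cell in norm.index:
            cells_by_element.setdefault(elem, []).append(cell)

    ntc_cells = [c for e in ntc for c in cells_by_element.get(e, [])]
    if not ntc_cells:
        raise ValueError("no cells assigned to non-targeting control elements")
    ntc_mean = norm.loc[ntc_cells].mean(axis=0)

    records: list[KnockdownRecord] = []
    for elem, cells in sorted(cells_by_element.items()):
        if elem in ntc:
            continue
        gene = gene_of.get(elem)
        if gene is None or gene not in norm.columns:
            warnings.warn(
                f"element {elem}: target gene {gene!r} absent from matrix; skipped",
                stacklevel=2,
            )
            continue
        denom = float(ntc_mean[gene])
        if denom == 0:
            warnings.warn(
                f"element {elem}: zero NTC mean for gene {gene}; undefined",
                stacklevel=2,
            )
            records.append(KnockdownRecord(elem, gene, np.nan, len(cells)))
            continue
        frac = float(norm.loc[cells, gene].mean()) / denom
        records.append(KnockdownRecord(elem, gene, frac, len(cells)))
    return records


def records_to_frame(records: Sequence[KnockdownRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [r.element_id for r in records],
            "gene": [r.gene for r in records],
            "fraction_remaining": [r.fraction_remaining for r in records],
            "knockdown_percent": [r.knockdown_percent for r in records],
            "n_cells": [r.n_cells for r in records],
        }
    )


def summarize_per_gene(records: Sequence[KnockdownRecord]) -> dict:
    """Per-gene mean / best knockdown and the library-level medians.

    With three elements per gene this yields the "mean of 3" and
    "best of 3" summaries; genes with fewer elements use what they have.
    """
    df = records_to_frame(records).dropna(subset=["fraction_remaining"])
    per_gene = (
        df.groupby("gene")["knockdown_percent"]
        .agg(mean_knockdown="mean", best_knockdown="max", n_elements="size")
        .reset_index()
    )
    return {
        "per_gene": per_gene,
        "median_mean_knockdown": float(per_gene["mean_knockdown"].median()),
        "median_best_knockdown": float(per_gene["best_knockdown"].median()),
        "median_element_knockdown": float(df["knockdown_percent"].median()),
    }


def flow_knockdown(
    median_target: float, median_ntc: float, background: float = 0.0
) -> float:
    """Percent knockdown from flow-cytometry median intensities.

    ``100 * (1 - (median_target - background) / (median_ntc - background))``;
    negative values (up-regulation) are reported as-is.
    """
    if median_ntc <= background:
        raise ValueError("NTC median must exceed background signal")
    return 100.0 * (1.0 - (median_target - background) / (median_ntc - background))


def no_knockdown_fraction(
    intensities_target: Sequence[float],
    intensities_reference: Sequence[float],
    quantile_cut: float = 0.05,
) -> float:
    """Percent of cells without evidence of knockdown.

    The threshold is the ``quantile_cut`` quantile of the reference
    (NTC) intensity distribution; target cells at or above it are
    indistinguishable from unperturbed cells.
    """
    tgt = np.asarray(intensities_target, dtype=float)
    ref = np.asarray(intensities_reference, dtype=float)
    if tgt.size == 0 or ref.size == 0:
        raise ValueError("both distributions must be non-empty")
    thr = float(np.quantile(ref, quantile_cut))
    return 100.0 * float((tgt >= thr).mean())
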