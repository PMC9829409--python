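"""Readers and writers for the delimited-text formats used throughout.

All tabular interchange is TSV via pandas; FASTQ may be plain or
gzip-compressed.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .library_design import DualElement, GuideRecord

PathLike = Union[str, Path]


def open_fastq(path: Union[PathLike, _io.TextIOBase], mode: str = "rt"):
    """Open a FASTQ path, transparently handling .gz; passes through handles."""
    if hasattr(path, "read") or hasattr(path, "write"):
        return path
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_guides(path: PathLike) -> list[GuideRecord]:
    """Guide candidate table: guide_id, gene, protospacer, predicted_score[, transcript]."""
    df = pd.read_csv(path, sep="\t")
    has_tx = "transcript" in df.columns
    return [
        GuideRecord(
            guide_id=str(r.guide_id),
            gene=str(r.gene),
            protospacer=str(r.protospacer),
            predicted_score=float(r.predicted_score),
            transcript=str(r.transcript) if has_tx else None,
        )
        for r in df.itertuples()
    ]


def read_guide_stats(path: PathLike) -> pd.DataFrame:
    """Per-screen guide stats: screen_id, guide_id, phenotype, guide_fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"screen_id", "guide_id", "phenotype", "guide_fdr"}
    _require(df, required, path)
    return df


def read_gene_stats(path: PathLike) -> pd.DataFrame:
    """Per-screen gene stats: screen_id, gene, p_value, gene_fdr[, k562_gamma]."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"screen_id", "gene", "p_value", "gene_fdr"}, path)
    if (df["p_value"] <= 0).any():
        raise ValueError(f"{path}: p_value must be > 0")
    if "k562_gamma" not in df.columns:
        df["k562_gamma"] = float("nan")
    return df


def read_gene_list(path: PathLike) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_control_pairs(path: PathLike) -> list[tuple[str, str]]:
    """NTC pair pool: TSV with columns protospacer_a, protospacer_b."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"protospacer_a", "protospacer_b"}, path)
    return list(zip(df["protospacer_a"], df["protospacer_b"]))


def elements_to_frame(elements: Iterable[DualElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": e.element_id,
                "gene": e.gene,
                "rank_pair": e.rank_pair,
                "protospacer_a": e.protospacer_a,
                "protospacer_b": e.protospacer_b,
                "ibc": e.ibc or "",
            }
            for e in elements
        ]
    )


def write_elements(elements: Iterable[DualElement], path: PathLike) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False)


def read_elements(path: PathLike) -> list[DualElement]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require(
        df,
        {"element_id", "gene", "rank_pair", "protospacer_a", "protospacer_b"},
        path,
    )
    return [
        DualElement(
            element_id=str(r.element_id),
            gene=str(r.gene),
            protospacer_a=str(r.protospacer_a),
            protospacer_b=str(r.protospacer_b),
            rank_pair=str(r.rank_pair),
            ibc=str(r.ibc) if "ibc" in df.columns and str(r.ibc) else None,
        )
        for r in df.itertuples()
    ]


def read_sample_sheet(path: PathLike) -> dict[str, str]:
    """Sample sheet TSV with columns sample, index -> {index: sample}."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"sample", "index"}, path)
    return dict(zip(df["index"].str.upper(), df["sample"]))


def read_replicates(path: PathLike) -> pd.DataFrame:
    """Replicate sheet: replicate_id, t0_sample, tfinal_sample, doublings."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"replicate_id", "t0_sample", "tfinal_sample", "doublings"}, path)
    return df


def _require(df: pd.DataFrame, cols: set, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
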