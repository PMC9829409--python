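"""Recombination-aware counting of dual-sgRNA screen sequencing.

Screens of dual-sgRNA libraries are sequenced with a short paired-end
layout: Read 1 covers the first 19 nt of guide A, Read 2 the first 19 nt
of guide B (on the opposite strand of the cassette), with optional index
reads carrying the sample index and the integration barcode (IBC).

Lentiviral packaging co-encapsidates two genomes per virion, and the
reverse transcriptase can template-switch between them, producing an
integrated cassette whose two guides came from different library
elements. Reads whose two guides do not target the same gene are
classified as recombined and excluded from counts (kept in QC tallies);
non-targeting control pairs, which all share one gene label, are instead
compared at the element level. Matching is exact on the 19-nt keys — no
mismatches are tolerated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from ._seq import reverse_complement
from .io import open_fastq
from .library_design import CONTROL_LABEL, DualElement

KEY_LEN = 19

UNDETERMINED = "undetermined"


@dataclass
class LibraryReference:
    """Exact-match lookup tables for a dual-sgRNA library.

    Keys are the first 19 nt of each protospacer (the sequenced length).
    Every key maps to exactly one guide; colliding prefixes are rejected
    when the reference is built.
    """

    elements: list[DualElement]
    lookup_a: dict[str, str]  # 19-nt key -> element_id
    lookup_b: dict[str, str]
    gene_of: dict[str, str]  # element_id -> gene
    by_id: dict[str, DualElement]


def build_reference(elements: Sequence[DualElement]) -> LibraryReference:
    """Build exact-match lookups, rejecting ambiguous 19-nt prefixes."""
    lookup_a: dict[str, str] = {}
    lookup_b: dict[str, str] = {}
    by_id: dict[str, DualElement] = {}
    collisions: list[str] = []
    for e in elements:
        if e.element_id in by_id:
            raise ValueError(f"duplicate element_id {e.element_id!r}")
        by_id[e.element_id] = e
        for lookup, proto, side in (
            (lookup_a, e.protospacer_a, "A"),
            (lookup_b, e.protospacer_b, "B"),
        ):
            key = proto[:KEY_LEN]
            if key in lookup:
                collisions.append(
                    f"guide {side} key {key} shared by {lookup[key]} and {e.element_id}"
                )
            else:
                lookup[key] = e.element_id
    if collisions:
        raise ValueError(
            "ambiguous 19-nt guide prefixes:\n  " + "\n  ".join(collisions)
        )
    gene_of = {e.element_id: e.gene for e in elements}
    return LibraryReference(list(elements), lookup_a, lookup_b, gene_of, by_id)


@dataclass
class PairClassification:
    read_id: str
    category: str  # matched | recombined | unmapped
    element_a: Optional[str] = None
    element_b: Optional[str] = None
    ibc: Optional[str] = None
    sample: Optional[str] = None

    @property
    def element(self) -> Optional[str]:
        """Element a matched pair is attributed to (via guide A)."""
        return self.element_a if self.category == "matched" else None


def classify_pair(
    r1: str,
    r2: str,
    ref: LibraryReference,
    read2_revcomp: bool = True,
    read_id: str = "",
) -> PairClassification:
    """Classify one read pair as matched, recombined, or unmapped.

    Both guides found and targeting the same gene → matched (attributed
    to guide A's element). Both found but targeting different genes →
    recombined. Control pairs are compared at element level, since all
    controls share the control gene label. Any side missing from the
    reference (including reads containing N) → unmapped.
    """
    key1 = r1.upper()[:KEY_LEN]
    key2 = r2.upper()
    if read2_revcomp:
        key2 = reverse_complement(key2)
    key2 = key2[:KEY_LEN]

    ea = ref.lookup_a.get(key1) if "N" not in key1 else None
    eb = ref.lookup_b.get(key2) if "N" not in key2 else None
    if ea is None or eb is None:
        return PairClassification(read_id, "unmapped", ea, eb)
    gene_a, gene_b = ref.gene_of[ea], ref.gene_of[eb]
    if gene_a == CONTROL_LABEL or gene_b == CONTROL_LABEL:
        same = ea == eb
    else:
        same = gene_a == gene_b
    return PairClassification(read_id, "matched" if same else "recombined", ea, eb)


@dataclass
class CountTable:
    """Element × sample matched-read counts plus QC tallies."""

    counts: pd.DataFrame  # index element_id, columns samples, int
    totals: pd.DataFrame  # index sample, columns matched/recombined/unmapped
    recombined_with: pd.Series  # per element: recombined reads involving it
    recombined_pairs: pd.DataFrame  # element_a, element_b, sample, n
    element_matched: pd.Series  # per element: matched reads, all samples

    def sample_total(self, sample: str) -> int:
        return int(self.counts[sample].sum())


def _fastq_seqs(path) -> Iterator[tuple[str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_fastq(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split(None, 1)[0], seq


def _nearest_whitelist(seq: str, whitelist: Sequence[str], max_mm: int = 1) -> Optional[str]:
    if seq in whitelist:
        return seq
    best = None
    for w in whitelist:
        if len(w) == len(seq) and sum(a != b for a, b in zip(seq, w)) <= max_mm:
            if best is not None:
                return None  # ambiguous rescue
            best = w
    return best


def count_run(
    fastq_r1,
    fastq_r2,
    ref: LibraryReference,
    fastq_i1=None,
    fastq_i2=None,
    sample_sheet: Optional[Mapping[str, str]] = None,
    ibc_whitelist: Optional[Sequence[str]] = None,
    read2_revcomp: bool = True,
    default_sample: str = "sample1",
    index_max_mm: int = 1,
) -> CountTable:
    """Stream synchronized FASTQ files into an element × sample count table.

    Parameters
    ----------
    fastq_i1, sample_sheet
        Optional sample index read and ``index -> sample`` map; indices
        farther than ``index_max_mm`` mismatches from every sheet entry
        are assigned to the ``undetermined`` sample. Without an index
        read all pairs belong to ``default_sample``.
    fastq_i2, ibc_whitelist
        Optional IBC read; barcodes are matched exactly with a one-
        mismatch rescue against the whitelist (unique under a
        distance-4 code). IBC tallies are informational; counting is
        keyed on elements.
    """
    it1 = _fastq_seqs(fastq_r1)
    it2 = _fastq_seqs(fastq_r2)
    it_i1 = _fastq_seqs(fastq_i1) if fastq_i1 is not None else None
    it_i2 = _fastq_seqs(fastq_i2) if fastq_i2 is not None else None
    sheet = dict(sample_sheet) if sample_sheet else None

    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, dict[str, int]] = {}
    recombined_with: dict[str, int] = {}
    rec_pairs: dict[tuple[str, str, str], int] = {}
    element_matched: dict[str, int] = {}

    def bump_total(sample: str, cat: str) -> None:
        totals.setdefault(
            sample, {"matched": 0, "recombined": 0, "unmapped": 0}
        )[cat] += 1

    n = 0
    _sentinel = (None, None)
    for rec1, rec2 in zip_longest(it1, it2, fillvalue=_sentinel):
        if rec1 is _sentinel or rec2 is _sentinel:
            short, extra = ("R1", rec2) if rec1 is _sentinel else ("R2", rec1)
            raise ValueError(
                f"desynchronized FASTQ streams: {short} ended at read {extra[0]!r}"
            )
        (id1, s1), (id2, s2) = rec1, rec2
        if id1 != id2:
            raise ValueError(
                f"desynchronized FASTQ streams at read {id1!r} vs {id2!r}"
            )
        n += 1
        sample = default_sample
        if it_i1 is not None:
            try:
                idx_id, idx_seq = next(it_i1)
            except StopIteration:
                raise ValueError(f"index read stream truncated at {id1!r}") from None
            if idx_id != id1:
                raise ValueError(
                    f"desynchronized index stream at read {id1!r} vs {idx_id!r}"
                )
            sample = UNDETERMINED
            if sheet:
                hit = _nearest_whitelist(
                    idx_seq.upper(), list(sheet), max_mm=index_max_mm
                )
                if hit is not None:
                    sample = sheet[hit]
        ibc = None
        if it_i2 is not None:
            try:
                ibc_id, ibc_seq = next(it_i2)
            except StopIteration:
                raise ValueError(f"IBC read stream truncated at {id1!r}") from None
            if ibc_id != id1:
                raise ValueError(
                    f"desynchronized IBC stream at read {id1!r} vs {ibc_id!r}"
                )
            ibc = ibc_seq.upper()
            if ibc_whitelist is not None:
                ibc = _nearest_whitelist(ibc, ibc_whitelist)

        cls = classify_pair(s1, s2, ref, read2_revcomp=read2_revcomp, read_id=id1)
        bump_total(sample, cls.category)
        if cls.category == "matched":
            counts[(cls.element_a, sample)] = counts.get((cls.element_a, sample), 0) + 1
            element_matched[cls.element_a] = element_matched.get(cls.element_a, 0) + 1
            if cls.element_a != cls.element_b:
                # same gene, different elements (possible across sublibraries)
                element_matched[cls.element_b] = (
                    element_matched.get(cls.element_b, 0) + 1
                )
        elif cls.category == "recombined":
            for e in (cls.element_a, cls.element_b):
                recombined_with[e] = recombined_with.get(e, 0) + 1
            key = (cls.element_a, cls.element_b, sample)
            rec_pairs[key] = rec_pairs.get(key, 0) + 1

    element_ids = [e.element_id for e in ref.elements]
    samples = sorted(totals) if totals else [default_sample]
    cdf = pd.DataFrame(0, index=element_ids, columns=samples, dtype=int)
    for (eid, sample), c in counts.items():
        cdf.loc[eid, sample] = c
    tdf = pd.DataFrame(
        [
            {
                "sample": s,
                **totals.get(s, {"matched": 0, "recombined": 0, "unmapped": 0}),
            }
            for s in samples
        ]
    ).set_index("sample")
    rw = pd.Series(
        {e: recombined_with.get(e, 0) for e in element_ids}, dtype=int, name="recombined_with"
    )
    em = pd.Series(
        {e: element_matched.get(e, 0) for e in element_ids}, dtype=int, name="matched"
    )
    rp = pd.DataFrame(
        [(a, b, s, c) for (a, b, s), c in sorted(rec_pairs.items())],
        columns=["element_a", "element_b", "sample", "n"],
    )
    return CountTable(cdf, tdf, rw, rp, em)


def recombination_rate(table: CountTable, scope: str = "overall"):
    """Fraction of mapped read pairs whose guides target different genes.

    ``overall``: recombined / (matched + recombined), pooled over
    samples. ``per_element``: for each element, the fraction of mapped
    reads containing either of its guides that are recombined — the
    "apparent" per-element rate, which in a growth screen is inflated
    for strongly depleting elements (their intact copies drop out while
    chimeras persist).
    """
    if scope == "overall":
        matched = int(table.totals["matched"].sum())
        recombined = int(table.totals["recombined"].sum())
        mapped = matched + recombined
        if mapped == 0:
            warnings.warn("no mapped reads; recombination rate undefined", stacklevel=2)
            return None
        return recombined / mapped
    if scope == "per_element":
        out = {}
        for eid in table.recombined_with.index:
            rec = int(table.recombined_with[eid])
            mat = int(table.element_matched[eid])
            denom = rec + mat
            out[eid] = rec / denom if denom else None
        return out
    raise ValueError(f"unknown scope {scope!r}")
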