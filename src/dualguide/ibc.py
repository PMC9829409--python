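"""Integration-barcode (IBC) design.

IBCs are short barcodes embedded between the two sgRNA cassettes of a
dual-sgRNA lentiviral element. Each barcode marks a lineage of cells
descending from a single integration, which lets a screen distinguish
bottlenecking and amplification artifacts from true phenotypes. The set
is built as a minimum-Hamming-distance code (default distance >= 4 for
8-mers) with moderate GC content, so single sequencing errors can be
corrected unambiguously and synthesis/sequencing behave uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from ._seq import BSMBI_SITES, DNA_ALPHABET, gc_fraction, reverse_complement, validate_dna

# Homology arms of the single-stranded donor used to clone each barcode
# into the AscI-digested cassette; the barcode itself is carried as its
# reverse complement on the donor strand.
DONOR_ARM_5 = "CTCTTCCTGCCCGACCTTGGGG"
DONOR_ARM_3 = "CAGCGCCATAGCTGAGTGTAGATTCGAGC"

DEFAULT_GC_BOUNDS = (0.25, 0.75)


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _int_to_kmer(idx: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(DNA_ALPHABET[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


def generate_ibcs(
    length: int = 8,
    min_dist: int = 4,
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS,
    forbidden: Sequence[str] = BSMBI_SITES,
    max_n: Optional[int] = None,
) -> list[str]:
    """Greedy lexicographic barcode-set construction.

    Scans all ``4**length`` sequences in lexicographic order (A < C < G < T)
    and accepts a candidate iff its GC fraction lies within ``gc_bounds``
    (inclusive), it contains no forbidden substring, and its Hamming
    distance to every previously accepted barcode is at least ``min_dist``.
    The scan is deterministic, so two runs with the same parameters give
    byte-identical sets.

    Parameters
    ----------
    forbidden
        Substrings excluded from barcodes; defaults to the BsmBI
        recognition site and its reverse complement because barcodes are
        cloned via BsmBI Golden Gate.
    max_n
        Stop after accepting this many barcodes (None = exhaust the scan).
    """
    if min_dist > length:
        raise ValueError(f"min_dist {min_dist} exceeds barcode length {length}")
    if length < 1:
        raise ValueError("length must be >= 1")
    lo, hi = gc_bounds
    forbidden = [validate_dna(f, name="forbidden substring") for f in forbidden]

    n_total = 4**length
    # Encode candidates as base-4 digit matrices so the distance check
    # against the growing accepted set is a vectorized comparison.
    accepted_codes = np.empty((0, length), dtype=np.int8)
    accepted: list[str] = []
    digits = np.empty(length, dtype=np.int8)
    for idx in range(n_total):
        seq = _int_to_kmer(idx, length)
        gc = gc_fraction(seq)
        if gc < lo or gc > hi:
            continue
        if any(f in seq for f in forbidden):
            continue
        for j, base in enumerate(seq):
            digits[j] = DNA_ALPHABET.index(base)
        if accepted_codes.shape[0]:
            dists = (accepted_codes != digits).sum(axis=1)
            if int(dists.min()) < min_dist:
                continue
        accepted.append(seq)
        accepted_codes = np.vstack([accepted_codes, digits])
        if max_n is not None and len(accepted) >= max_n:
            break
    return accepted


@dataclass
class IBCReport:
    """Validation summary for a barcode set (report-only, never raises)."""

    n: int
    min_pairwise_distance: Optional[int]
    gc_min: Optional[float]
    gc_max: Optional[float]
    duplicates: list[str] = field(default_factory=list)
    forbidden_hits: list[tuple[str, str]] = field(default_factory=list)
    gc_violations: list[str] = field(default_factory=list)
    passed: bool = True


def validate_ibcs(
    barcodes: Sequence[str],
    min_dist: int = 4,
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS,
    forbidden: Sequence[str] = (),
) -> IBCReport:
    """Check a barcode set against distance/GC/substring constraints."""
    seqs = [validate_dna(b, name="barcode") for b in barcodes]
    lo, hi = gc_bounds
    seen: set[str] = set()
    dups = []
    for s in seqs:
        if s in seen:
            dups.append(s)
        seen.add(s)
    gcs = [gc_fraction(s) for s in seqs]
    gc_viol = [s for s, g in zip(seqs, gcs) if g < lo or g > hi]
    forb_hits = [(s, f) for s in seqs for f in forbidden if f.upper() in s]
    min_d: Optional[int] = None
    if len(seqs) >= 2:
        min_d = min(hamming(a, b) for a, b in combinations(seqs, 2))
    ok = (
        not dups
        and not gc_viol
        and not forb_hits
        and (min_d is None or min_d >= min_dist)
    )
    return IBCReport(
        n=len(seqs),
        min_pairwise_distance=min_d,
        gc_min=min(gcs) if gcs else None,
        gc_max=max(gcs) if gcs else None,
        duplicates=dups,
        forbidden_hits=forb_hits,
        gc_violations=gc_viol,
        passed=ok,
    )


def assemble_ibc_donor(ibc: str) -> str:
    """Single-stranded donor oligo carrying one barcode.

    The donor is the 5' homology arm, the reverse complement of the
    barcode, then the 3' homology arm (the cassette reads the barcode on
    the opposite strand). For an 8-mer the donor is 59 nt.
    """
    seq = validate_dna(ibc, name="IBC")
    return DONOR_ARM_5 + reverse_complement(seq) + DONOR_ARM_3


def parse_ibc_donor(donor: str) -> str:
    """Recover the barcode from a donor oligo (inverse of assembly)."""
    up = donor.upper()
    if not up.startswith(DONOR_ARM_5) or not up.endswith(DONOR_ARM_3):
        raise ValueError("donor oligo does not match the expected arm sequences")
    middle = up[len(DONOR_ARM_5) : len(up) - len(DONOR_ARM_3)]
    return reverse_complement(middle)
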