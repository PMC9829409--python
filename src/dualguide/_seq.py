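"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# BsmBI recognition site and its reverse complement; guides or barcodes
# containing either would be cut during Golden Gate cloning.
BSMBI_SITES = ("CGTCTC", "GAGACG")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def validate_dna(seq: str, *, name: str = "sequence", allow_n: bool = False) -> str:
    """Uppercase ``seq`` and verify it is a plain DNA string.

    Raises
    ------
    ValueError
        If the sequence contains characters outside {A, C, G, T}
        (plus N when ``allow_n``), naming the offending record.
    """
    up = seq.upper()
    allowed = set(DNA_ALPHABET + ("N" if allow_n else ""))
    bad = set(up) - allowed
    if bad:
        raise ValueError(
            f"{name}: non-ACGT character(s) {sorted(bad)} in sequence {seq!r}"
        )
    return up
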