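import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dualguide import CONTROL_LABEL, DualElement, build_reference


@pytest.fixture
def toy_elements():
    """Two targeting genes plus two NTC pairs, 20-nt guides, distinct prefixes."""
    seqs = []
    for i in range(8):
        base = ["A"] * 20
        base[0] = "ACGT"[i % 4]
        base[1] = "ACGT"[i // 4]
        base[2] = "C"
        seqs.append("".join(base))
    return [
        DualElement("GENE7_1_2", "GENE7", seqs[0], seqs[1], "1_2"),
        DualElement("GENE9_1_2", "GENE9", seqs[2], seqs[3], "1_2"),
        DualElement("NTC_0000", CONTROL_LABEL, seqs[4], seqs[5], "control"),
        DualElement("NTC_0001", CONTROL_LABEL, seqs[6], seqs[7], "control"),
    ]


@pytest.fixture
def toy_reference(toy_elements):
    return build_reference(toy_elements)


@pytest.fixture
def write_fastq(tmp_path):
    """Write a list of (read_id, seq) records as a plain FASTQ file."""

    def _write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    return _write


@pytest.fixture
def guide_stats_frame():
    def _make(rows):
        return pd.DataFrame(rows, columns=["screen_id", "guide_id", "phenotype", "guide_fdr"])

    return _make


@pytest.fixture
def gene_stats_frame():
    def _make(rows):
        return pd.DataFrame(
            rows, columns=["screen_id", "gene", "p_value", "gene_fdr", "k562_gamma"]
        )

    return _make
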