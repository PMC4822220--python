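import pytest

from paracopy import VariableSite, demo_paralogue_set, make_paralogue_set


@pytest.fixture
def demo_ps():
    """Six-copy, three-site demo gene model (5:1 ratio at every site)."""
    return demo_paralogue_set()


@pytest.fixture
def single_site_ps():
    """Seven copies, one A/G site with a 6:1 split, short reference."""
    gene_length = 300
    ref = ("ACGT" * 75)[:gene_length]
    site = VariableSite(150, "A", "G")
    ref = ref[:149] + "A" + ref[150:]
    return make_paralogue_set(
        ["A"] * 6 + ["G"], [site], gene_length, reference_sequence=ref
    )


def make_sam(path, reads, ref_name="gene", ref_len=50):
    """Write a minimal SAM file: reads = [(name, flag, pos1, mapq, cigar, seq, qual)]."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{ref_name}\tLN:{ref_len}",
    ]
    for name, flag, pos, mapq, cigar, seq, qual in reads:
        lines.append(
            f"{name}\t{flag}\t{ref_name}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def sam_writer():
    return make_sam
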