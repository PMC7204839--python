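import pytest

from strhap.panel import LocusDefinition, ParameterSet


@pytest.fixture
def locus_ac() -> LocusDefinition:
    """A simple dinucleotide (AC)n locus with short flanks."""
    return LocusDefinition(
        locus_id="locA",
        forward_primer="GATTACAGATTACAGATTACA",
        reverse_primer="TGCATGCATGCATGCATG",
        left_flank="TTGA",
        right_flank="CCTA",
        motif="AC",
        ref_repeat_count=10,
        target_len_range=(16, 40),
    )


@pytest.fixture
def ps1() -> ParameterSet:
    return ParameterSet("PS1", {-1: 50.0, +1: 10.0}, min_allele_reads=15,
                        min_locus_reads=20)


@pytest.fixture
def ps2() -> ParameterSet:
    return ParameterSet("PS2", {-1: 70.0, +1: 10.0}, min_allele_reads=10,
                        min_locus_reads=20)
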