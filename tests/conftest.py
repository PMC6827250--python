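import pytest

from alginseq import Mixture, NMRReadout, TruncationSeries

# Published product-table composition of the pentasaccharide fraction
UDP5_FRACTIONS = {"ΔGGMM": 0.467, "ΔMGMM": 0.133, "ΔGMMM": 0.311, "ΔMMMM": 0.089}


@pytest.fixture
def udp5_mixture():
    return Mixture.from_fractions(UDP5_FRACTIONS)


@pytest.fixture
def udp4_series():
    """DP4 series: parent ΔG:ΔM = 1:3.2 with pure-M reducing end; one cut shows ΔM only."""
    return TruncationSeries(4, {
        0: NMRReadout(1.0, 3.2, 0.0, 1.0),
        1: NMRReadout(0.0, 1.0, 0.0, 1.0),
    })


@pytest.fixture
def udp5_series():
    """DP5 series: parent 3.5:1 (RE pure M), one cut 1.5:1, two cuts ΔM only."""
    return TruncationSeries(5, {
        0: NMRReadout(3.5, 1.0, 0.0, 1.0),
        1: NMRReadout(1.5, 1.0, 0.0, 1.0),
        2: NMRReadout(0.0, 1.0, 0.0, 1.0),
    })
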