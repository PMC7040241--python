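import pytest

from thyrisk.diagnostics import ConfusionMatrix
from thyrisk.genomics import WeightTable, default_weight_table


@pytest.fixture
def weights() -> WeightTable:
    return default_weight_table()


@pytest.fixture
def trs_table() -> ConfusionMatrix:
    """Integer 2x2 table of the total risk score at its 0.7 cutoff."""
    return ConfusionMatrix(tp=22, fp=3, fn=4, tn=18)


@pytest.fixture
def xus_table() -> ConfusionMatrix:
    """Integer 2x2 table of the ultrasound score at its 0.9 cutoff."""
    return ConfusionMatrix(tp=9, fp=2, fn=17, tn=19)
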