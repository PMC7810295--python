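import numpy as np
import pandas as pd
import pytest

from rfacurve import ImpedanceCurve


@pytest.fixture
def simple_curve() -> ImpedanceCurve:
    """Five-point curve with obvious landmarks (min at mid-procedure)."""
    return ImpedanceCurve(
        sample_id="s1",
        t=np.array([0.0, 25.0, 50.0, 75.0, 100.0]),
        Z=np.array([100.0, 85.0, 80.0, 90.0, 150.0]),
    )


@pytest.fixture
def write_log(tmp_path):
    """Write a CSV equipment log from column arrays; returns the path."""

    def _write(name="log.csv", **columns):
        path = tmp_path / name
        pd.DataFrame(columns).to_csv(path, index=False)
        return path

    return _write
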