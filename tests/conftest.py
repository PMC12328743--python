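import numpy as np
import pytest

from porescribe import CurrentTrace, PeptideRecord


@pytest.fixture
def tmcin():
    return PeptideRecord.tmcin_g1905()


@pytest.fixture
def staircase_trace():
    """Noiseless 5-step staircase: 1 nS steps at 50 mV (50 pA plateaus)."""
    fs = 5000.0
    plateau = int(fs)  # 1 s per plateau
    levels = np.repeat(np.arange(6) * 50.0, plateau)
    return CurrentTrace(
        samples=levels, sampling_rate_hz=fs, holding_voltage_mV=50.0
    )
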