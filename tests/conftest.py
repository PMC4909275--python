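import numpy as np
import pytest

import pulsesst as ps
from pulsesst import protocols


@pytest.fixture(scope="session")
def tone_result():
    """Analysis of a clean 1.2 Hz unit tone (10 s at 100 Hz)."""
    t = np.arange(1000) / 100.0
    tone = ps.PulseSignal(np.cos(2 * np.pi * 1.2 * t), 100.0)
    return tone, ps.analyze_record(tone)


@pytest.fixture(scope="session")
def clean_fixture():
    """One clean study-condition record with its ground truth and analysis."""
    shape, params, signal = protocols.default_fixture(seed=5)
    return {"shape": shape, "params": params, "signal": signal,
            "analysis": ps.analyze_record(signal)}


@pytest.fixture(scope="session")
def battery():
    """20-fixture IF/AM/SPS recovery battery (clean + 0 dB noisy paths)."""
    return protocols.recovery_battery(n_fixtures=20, seed=123)


@pytest.fixture(scope="session")
def separable_report():
    """Full pipeline on a separable 20+20 cohort at 0 dB."""
    return protocols.separable_cohort(seed=42)


@pytest.fixture(scope="session")
def null_auc_report():
    """Held-out GPS AUC over replicate null cohorts."""
    return protocols.null_cohort_auc()
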