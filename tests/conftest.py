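import numpy as np
import pytest

from neuroignite import CohortSpec
from neuroignite.containers import ParcellatedBold


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """Small, strongly coupled cohort for fast structural tests."""
    return CohortSpec(
        n_control=4,
        n_meningioma=4,
        n_glioma=4,
        n_regions=42,
        n_timepoints=120,
        event_rate=1.5,
        coupling_within=0.5,
        coupling_between=0.2,
        seed=11,
    )


def make_bold(signal, tr_ms=2400.0, subject_id="test"):
    return ParcellatedBold(signal=np.asarray(signal, dtype=float), tr_ms=tr_ms, subject_id=subject_id)


@pytest.fixture
def sine_bold():
    """Two regions: a 0.04 Hz in-band sinusoid and a 0.2 Hz out-of-band one."""
    tr_s = 2.4
    t = np.arange(400) * tr_s
    sig = np.stack([np.sin(2 * np.pi * 0.04 * t), np.sin(2 * np.pi * 0.2 * t)])
    return make_bold(sig, tr_ms=2400.0)
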