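import pytest

import fearphys as fp


@pytest.fixture
def small_photometry_cfg():
    """Two-tone session small enough for fast end-to-end runs."""
    return fp.PhotometrySimConfig(n_tones=2, iti=60.0, first_onset=40.0, seed=7)


@pytest.fixture
def recording(small_photometry_cfg):
    rec, truth = fp.simulate_photometry(small_photometry_cfg)
    return rec, truth


@pytest.fixture
def spont_sweep():
    cfg = fp.EphysSimConfig(duration=30.0, event_rate=1.0, amp_mean=12.0, amp_sd=1.0,
                            noise_sd=1.0, seed=3)
    return fp.simulate_sepsc_trace(cfg)
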