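import numpy as np
import pytest

import wavescan as wsc


@pytest.fixture(scope="session")
def planar_noiseless():
    """5 planar waves (v0=15 mm/s, theta=0) on a 20x20 calcium-style grid."""
    gt = wsc.planar_wave_train(5, 4.0, 15.0, theta=0.0)
    rec, gt = wsc.make_wave_recording(20, 20, 0.05, 25.0, gt, noise_sd=0.0, seed=1)
    return rec, gt


@pytest.fixture(scope="session")
def planar_noiseless_processed(planar_noiseless):
    # mean-only detrending keeps the noise-free baseline flat, so the
    # onset of the first transient remains a (weak) local minimum
    rec, gt = planar_noiseless
    return wsc.zscore(wsc.detrend(rec, order=0)), gt


@pytest.fixture
def small_rec():
    """Tiny deterministic 4x4 recording for contract tests."""
    rng = np.random.default_rng(0)
    return wsc.GridRecording(
        signals=rng.normal(size=(16, 1000)),
        sampling_rate=25.0,
        spatial_scale=0.05,
        coords=wsc.full_grid_coords(4, 4),
        annotations={"anesthetic": "isoflurane", "dataset": "synthetic"},
    )
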