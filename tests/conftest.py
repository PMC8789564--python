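import numpy as np
import pytest

import hippostate as hs
from hippostate.synth import LfpParams


@pytest.fixture(scope="session")
def deep_session():
    """10 min of deep-anesthesia LFP with known burst/suppression truth."""
    lfp, emg, hyp, truth = hs.simulate_lfp_session([("deep", 600.0)], seed=1)
    return lfp, emg, hyp, truth


@pytest.fixture(scope="session")
def deep_session_with_transients():
    """Deep-anesthesia LFP with 50 injected 13-SD biphasic transients."""
    params = LfpParams(n_epileptiform=50, epi_amp_sd=13.0)
    return hs.simulate_lfp_session([("deep", 600.0)], params, seed=2)


@pytest.fixture(scope="session")
def sleep_wake_hypnogram():
    """Alternating active-wake / NREM hypnogram, 30 min per state in 4 blocks."""
    blocks = []
    t = 0.0
    for i in range(4):
        for state in ("active_wake", "NREM"):
            blocks.append((t, t + 450.0, state))
            t += 450.0
    return hs.IntervalSet(blocks)


@pytest.fixture(scope="session")
def wt_spike_session(sleep_wake_hypnogram):
    trains, truth = hs.simulate_spike_trains(
        200, (np.log(1.4), 1.0), sleep_wake_hypnogram, gain_preset="WT_like", seed=7
    )
    return trains, truth, sleep_wake_hypnogram


def make_motif_raster(seed, n_cells=100, n_frames=3000, n_motifs=8):
    """Motif-structured raster under the default study conditions."""
    rng = np.random.default_rng(1000 + seed)
    motifs = [rng.choice(n_cells, size=12, replace=False) for _ in range(n_motifs)]
    return hs.simulate_ca_raster(
        n_cells, n_frames, motifs=motifs, motif_rate=0.2, baseline_p=0.003, seed=seed
    )


@pytest.fixture(scope="session")
def motif_raster():
    return make_motif_raster(seed=0)
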