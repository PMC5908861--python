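import numpy as np
import pytest

from neuroburst.spikedata import BurstPauseGenConfig, SpikeTrainSet, generate_burst_pause


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def burst_pause_set():
    """Well-separated, supra-threshold synthetic burst-pause activity:
    deterministic bursts at fixed onsets so event bookkeeping is exact."""
    cfg = BurstPauseGenConfig(
        n_channels=60,
        duration=80.0,
        burst_rate=0.15,
        burst_len=0.3,
        within_burst_rate=50.0,
        background_rate=0.1,
        participation=0.8,
        jitter_sd=0.01,
        # this seed realizes 11 events, all >1.5 s apart and away from
        # the epoch edges, so every generated event is detectable
        seed=82,
    )
    sts = generate_burst_pause(cfg)
    return cfg, sts


def make_set(trains: dict, duration: float) -> SpikeTrainSet:
    return SpikeTrainSet(
        channels=list(trains),
        spikes={k: np.asarray(v, dtype=float) for k, v in trains.items()},
        duration=duration,
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """One short clustered-network simulation shared by the tests that
    only need *some* mechanistic output (not a specific regime)."""
    from neuroburst import gif

    top = gif.build_topology("fig6_baseline")
    res = gif.simulate(top, duration=8.0, dt=0.2, seed=11)
    cmap = gif.make_channel_map(res.n_neurons, seed=11)
    return res, gif.readout(res, cmap)
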