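"""Pairwise cross-correlation of MEA channels and channel clustering.

Compares synchronized burst-pause activity against desynchronized
(tonic Poisson) firing: the windowed, lag-maximized, window-averaged
cross-correlation separates the two regimes, and average-linkage
clustering orders channels for matrix display.
"""

import numpy as np

from neuroburst import (
    BurstPauseGenConfig,
    cross_correlation,
    generate_burst_pause,
    hierarchical_clustering,
)
from neuroburst.spikedata import SpikeTrainSet

sync = generate_burst_pause(
    BurstPauseGenConfig(n_channels=12, duration=60.0, burst_rate=0.3,
                        participation=1.0, background_rate=0.2, seed=3)
)
rng = np.random.default_rng(3)
tonic = SpikeTrainSet(
    channels=list(range(12)),
    spikes={c: np.sort(rng.uniform(0, 60.0, 120)) for c in range(12)},
    duration=60.0,
)

for label, sts in [("burst-pause", sync), ("tonic Poisson", tonic)]:
    mat = cross_correlation(sts)  # T=1000 ms windows, 1 ms bins, 100 ms kernel
    print(f"{label:>14}: mean pairwise correlation {np.nanmean(mat.offdiag()):.3f}")

Z, order, kept = hierarchical_clustering(cross_correlation(sync))
print(f"dendrogram leaf order: {order}")
print("# synchronized channels co-burst in most 1 s windows and score near 1;\n"
      "# independent tonic channels align only by chance and score lower.")
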