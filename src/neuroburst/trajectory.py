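"""Neural-trajectory analysis: low-dimensional projections of the
population activity.

Per-channel spike counts on a fine grid (20 ms bins) are smoothed with
a 50 ms Gaussian kernel and passed to PCA; the top K components
explaining 90% of the variance are retained. Plotting two of the K
latent coordinates against each other with consecutive time points
joined traces the network's "neural trajectory": burst-pause cycling
between UP (elevated firing) and DOWN (near-silent) states appears as
closed loops, whose count and radial amplitude quantify the phasic
synchronized activity of a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .spikedata import SpikeTrainSet

__all__ = ["TrajectoryResult", "neural_trajectory", "trajectory_loop_stats"]


@dataclass
class TrajectoryResult:
    """Latent trajectory of one epoch.

    ``latents`` is time x K (principal-component scores on the count
    grid), ``explained`` the per-component variance fractions over all
    channels (so ``explained[:K].sum() >= var_target``), ``times`` the
    grid centres in seconds.
    """

    latents: np.ndarray
    explained: np.ndarray
    K: int
    times: np.ndarray
    var_target: float
    metadata: dict = field(default_factory=dict)

    def plane(self, a: int = 0, b: int = 1) -> np.ndarray:
        """A 2-d projection: columns ``a`` and ``b`` of the latents."""
        if a >= self.K or b >= self.K:
            raise ValueError(f"plane ({a}, {b}) outside the K={self.K} kept components")
        return self.latents[:, [a, b]]


def neural_trajectory(
    sts: SpikeTrainSet,
    count_bin: float = 0.02,
    smooth_sd: float = 0.05,
    var_target: float = 0.90,
) -> TrajectoryResult:
    """Compute the PCA neural trajectory of an epoch.

    Per-channel spike counts on the ``count_bin`` grid (20 ms default)
    are smoothed with a Gaussian kernel of SD ``smooth_sd`` (50 ms
    default); PCA (centred, not variance-scaled per channel) is applied
    to the time x channel matrix and the smallest K with cumulative
    explained variance >= ``var_target`` is kept. Raises on
    constant (zero-variance) data, where no principal component exists.
    """
    if sts.n_channels < 2:
        raise ValueError("neural trajectory requires at least 2 channels")
    rate = 1.0 / count_bin
    n = int(np.ceil(sts.duration * rate))
    if n < 2:
        raise ValueError("epoch too short for the requested count_bin")
    X = np.zeros((n, sts.n_channels))
    for c, ch in enumerate(sts.channels):
        t = sts.spikes[ch]
        if t.size:
            idx = np.minimum((t * rate).astype(np.int64), n - 1)
            X[:, c] = np.bincount(idx, minlength=n)
    X = ndimage.gaussian_filter1d(X, sigma=smooth_sd / count_bin, axis=0, mode="constant")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("no principal components: data have zero variance")
    pca = PCA()
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    K = int(np.searchsorted(np.cumsum(explained), var_target) + 1)
    K = min(K, explained.size)
    times = (np.arange(n) + 0.5) * count_bin
    return TrajectoryResult(
        latents=scores[:, :K],
        explained=explained,
        K=K,
        times=times,
        var_target=var_target,
        metadata={"count_bin_s": count_bin, "smooth_sd_s": smooth_sd},
    )


def trajectory_loop_stats(
    result: TrajectoryResult, plane: tuple[int, int] = (0, 1)
) -> tuple[int, float]:
    """Count closed loops of the 2-d trajectory and their amplitude.

    The angular coordinate of the trajectory around its centroid is
    unwrapped over time; each completed 2*pi of angular range is one
    loop (a perfect circle traversed five times yields five). The
    amplitude is the mean radial distance from the centroid over the
    samples belonging to complete loops (the circle's radius for a
    circle). A degenerate zero-radius trajectory has zero loops. Loop
    counting is a summary statistic added by this package to quantify
    the "circle traces" of trajectory plots; it is not part of the
    classical trajectory method.
    """
    P = result.plane(*plane)
    c = P.mean(axis=0)
    d = P - c
    r = np.hypot(d[:, 0], d[:, 1])
    if np.max(r) <= 0:
        return 0, 0.0
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    span = float(theta.max() - theta.min())
    loops = int((span + 1e-9) // (2 * np.pi))  # epsilon guards exact turns
    if loops == 0:
        return 0, 0.0
    # samples inside the angular range covered by complete loops
    lo = theta.min()
    mask = theta <= lo + loops * 2 * np.pi
    amplitude = float(r[mask].mean()) if mask.any() else float(r.mean())
    return loops, amplitude
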