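"""Pairwise windowed cross-correlation of MEA channels and
hierarchical clustering of the resulting matrix.

For every channel the spike train is binned at 1 ms and smoothed with a
Gaussian kernel (SD 100 ms), giving a signal ``x_i``. The epoch is
tiled with non-overlapping windows of T = 1000 ms; within a window
starting at bin ``s`` the un-normalized cross-correlogram is

    C_ij(tau) = sum_{tau'=0..T} x_i[s + tau'] * x_j[s + tau' + tau]

normalized at each lag by ``sqrt(C_ii(0) * C_jj(tau))`` where
``C_jj(tau)`` is the energy of the lag-shifted j-segment
(``sum x_j[s + tau' + tau]^2``). At ``tau = 0`` this is the usual
``sqrt(C_ii(0) C_jj(0))`` normalizer; using the shifted energy at
``tau > 0`` is what Cauchy-Schwarz actually bounds against, so every
entry lies in [0, 1] with equality exactly for proportional segments.
The channel-pair entry takes the maximum of the normalized correlogram
over lags ``tau = 0..T`` within each window and, by default, averages
those per-window maxima across the windows of the epoch (an epoch-level
maximum is available as a variant). Negative lags are covered by taking
the larger of the two pair orderings, which also makes the matrix
symmetric. Pairs that co-burst in most windows score near 1; pairs
whose activity rarely aligns score visibly lower, which is what gives
the matrix its cluster structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .spikedata import SpikeTrainSet

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrMatrix",
    "cross_correlation",
    "hierarchical_clustering",
    "compare_matrices",
]


@dataclass
class CrossCorrMatrix:
    """Symmetric matrix of per-pair maximal normalized cross-correlation.

    Entries are NaN for pairs involving a channel with zero smoothed
    energy in every window ("missing"); the diagonal is 1 for channels
    with any activity.
    """

    values: np.ndarray
    channels: list
    window_ms: float
    bin_ms: float
    kernel_sd_ms: float
    n_windows: int
    metadata: dict = field(default_factory=dict)

    def valid_channels(self) -> list:
        ok = ~np.all(np.isnan(self.values), axis=1)
        return [c for c, o in zip(self.channels, ok) if o]

    def offdiag(self) -> np.ndarray:
        """Finite off-diagonal entries (upper triangle)."""
        iu = np.triu_indices(len(self.channels), k=1)
        v = self.values[iu]
        return v[np.isfinite(v)]


def _smoothed_bins(
    sts: SpikeTrainSet, bin_ms: float, kernel_sd_ms: float
) -> np.ndarray:
    rate = 1000.0 / bin_ms
    n = int(np.ceil(sts.duration * rate))
    out = np.zeros((sts.n_channels, n))
    for r, ch in enumerate(sts.channels):
        t = sts.spikes[ch]
        if t.size == 0:
            continue
        idx = np.minimum((t * rate).astype(np.int64), n - 1)
        counts = np.bincount(idx, minlength=n).astype(float)
        out[r] = ndimage.gaussian_filter1d(
            counts, sigma=kernel_sd_ms / bin_ms, mode="constant", truncate=6.0
        )
    return out


def cross_correlation(
    sts: SpikeTrainSet,
    T: float = 1000.0,
    bin: float = 1.0,
    kernel_sd: float = 100.0,
    summary: str = "mean",
) -> CrossCorrMatrix:
    """Windowed, normalized cross-correlation matrix of all channel
    pairs (see module docstring for the definition).

    ``T``, ``bin`` and ``kernel_sd`` are in milliseconds. ``summary``
    selects how per-window lag maxima are combined into the epoch
    entry: ``"mean"`` (default — the per-epoch average of per-window
    maxima) or ``"max"`` (the single best window; note that the best
    window of almost any active pair attains values near 1, so the
    maximum discards the synchrony contrast between pairs). Windows in
    which either channel has zero smoothed energy are skipped for that
    pair; a pair with no usable window is NaN.
    """
    if summary not in ("max", "mean"):
        raise ValueError("summary must be 'max' or 'mean'")
    x = _smoothed_bins(sts, bin, kernel_sd)
    n_ch, L = x.shape
    Tb = int(round(T / bin))
    # full windows need x_j out to s + 2T
    starts = [s for s in range(0, max(L - 2 * Tb, 0), Tb)]
    n_win = len(starts)
    if n_win == 0:
        raise ValueError(
            f"epoch too short for window T={T} ms (need > {2 * T} ms of data)"
        )
    nfft = int(2 ** np.ceil(np.log2(3 * Tb + 2)))
    acc = np.full((n_ch, n_ch), np.nan)
    cnt = np.zeros((n_ch, n_ch), dtype=int)
    for s in starts:
        seg_i = x[:, s : s + Tb + 1]               # tau' = 0..T
        seg_j = x[:, s : s + 2 * Tb + 1]           # tau' + tau up to 2T
        e0 = np.einsum("ij,ij->i", seg_i, seg_i)   # C_ii(0)
        ok = e0 > 0
        # shifted j-segment energies C_jj(tau), tau = 0..T, via cumsum
        sq = seg_j**2
        cs = np.concatenate(
            (np.zeros((n_ch, 1)), np.cumsum(sq, axis=1)), axis=1
        )
        Ej = cs[:, Tb + 1 : 2 * Tb + 2] - cs[:, : Tb + 1]  # (n_ch, Tb+1)
        ok_j = Ej > 0
        Fi = np.conj(np.fft.rfft(seg_i, nfft, axis=1))
        Fj = np.fft.rfft(seg_j, nfft, axis=1)
        sqrt_e0 = np.sqrt(e0)
        sqrt_Ej = np.sqrt(Ej)
        # chunk over rows to bound memory
        chunk = max(1, int(2e7 // (n_ch * nfft)))
        for a in range(0, n_ch, chunk):
            b = min(a + chunk, n_ch)
            corr = np.fft.irfft(Fi[a:b, None, :] * Fj[None, :, :], nfft, axis=2)
            corr = corr[:, :, : Tb + 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = corr / (sqrt_e0[a:b, None, None] * sqrt_Ej[None, :, :])
            ratio[np.broadcast_to(~ok_j[None, :, :], ratio.shape)] = 0.0
            m = ratio.max(axis=2)
            valid = np.outer(ok[a:b], ok)
            m[~valid] = np.nan
            blk = acc[a:b]
            new = np.isnan(blk) & ~np.isnan(m)
            blk[new] = m[new] if summary == "max" else 0.0
            both = ~np.isnan(blk) & ~np.isnan(m)
            if summary == "max":
                blk[both] = np.maximum(blk[both], m[both])
            else:
                blk[both] += m[both]
            cnt[a:b][valid] += 1
    if summary == "mean":
        with np.errstate(invalid="ignore"):
            acc = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    # symmetrize: larger of the two orderings covers negative lags
    vals = np.fmax(acc, acc.T)
    vals = np.clip(vals, 0.0, 1.0)  # guard FFT roundoff at the CS bound
    np.fill_diagonal(vals, np.where(np.isfinite(np.diag(vals)), 1.0, np.nan))
    return CrossCorrMatrix(
        values=vals,
        channels=list(sts.channels),
        window_ms=T,
        bin_ms=bin,
        kernel_sd_ms=kernel_sd,
        n_windows=n_win,
        metadata={"summary": summary},
    )


def hierarchical_clustering(mat: CrossCorrMatrix, method: str = "average"):
    """Agglomerative clustering of channels on distance
    ``d = 1 - correlation``.

    Channels whose entries are all missing are dropped first (logged).
    Returns ``(linkage, leaf_order, kept_channels)`` where ``linkage``
    is a SciPy linkage matrix and ``leaf_order`` lists kept channels in
    dendrogram order, for re-displaying the matrix grouped by cluster.
    """
    keep = [i for i, c in enumerate(mat.channels)
            if not np.all(np.isnan(np.delete(mat.values[i], i)))]
    dropped = [c for i, c in enumerate(mat.channels) if i not in keep]
    if dropped:
        logger.info("dropping silent channels from clustering: %s", dropped)
    if len(keep) < 2:
        raise ValueError("need at least 2 active channels to cluster")
    sub = mat.values[np.ix_(keep, keep)].copy()
    np.fill_diagonal(sub, 1.0)
    dist = 1.0 - sub
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = hierarchy.leaves_list(Z)
    kept_channels = [mat.channels[i] for i in keep]
    leaf_order = [kept_channels[i] for i in order]
    return Z, leaf_order, kept_channels


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a SciPy linkage tree as a Newick string (branch
    lengths from merge heights)."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return rec(tree, tree.dist) + ";"


def compare_matrices(baseline: CrossCorrMatrix, recovery: CrossCorrMatrix) -> dict:
    """Paired comparison of two epoch matrices over the same channels.

    Returns per-pair differences (recovery - baseline), the two epoch
    means, the mean difference, and a long-format table of paired
    entries ready for a two-way repeated-measures analysis (the test
    itself is left to standard statistics packages).
    """
    if list(baseline.channels) != list(recovery.channels):
        raise ValueError("matrices cover different channel sets")
    iu = np.triu_indices(len(baseline.channels), k=1)
    b = baseline.values[iu]
    r = recovery.values[iu]
    ok = np.isfinite(b) & np.isfinite(r)
    diff = r[ok] - b[ok]
    pairs = [
        (baseline.channels[i], baseline.channels[j])
        for i, j, o in zip(iu[0], iu[1], ok)
        if o
    ]
    return {
        "pairs": pairs,
        "baseline": b[ok],
        "recovery": r[ok],
        "difference": diff,
        "mean_baseline": float(np.mean(b[ok])) if ok.any() else np.nan,
        "mean_recovery": float(np.mean(r[ok])) if ok.any() else np.nan,
        "mean_difference": float(np.mean(diff)) if ok.any() else np.nan,
    }
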