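"""Clustered generalized-integrate-and-fire (GIF) network simulator.

The mechanistic synthetic-data generator of the package: a network of
current-based GIF neurons (leaky integrator with spike-triggered
adaptation current ``eta(t)``, moving threshold ``gamma(t)`` and
stochastic escape-noise spiking) connected by exponential
current-based synapses with a fixed 2 ms transmission delay, plus
independent Poisson background input per neuron.

Membrane dynamics of each neuron::

    C dV/dt = -g_L (V - E_L) - sum_spikes eta(t - t_hat) + I(t)

with stochastic spike emission at intensity::

    lambda(t) = lambda0 * exp((V - V_T(t)) / DeltaV),
    V_T(t)    = V_T* + sum_spikes gamma(t - t_hat)

After a spike the potential is reset to ``V_reset`` and clamped there
for the refractory period ``tau_ref``. ``eta`` and ``gamma`` are
single-exponential decaying kernels (the standard GIF parameterization
fitted to cortical neurons); synaptic input is
``I_i(t) = sum_j w_ij sum_f exp(-(t - t_f - Delta)/tau_syn)`` for
``t >= t_f + Delta``.

A *cluster* is a subgroup of excitatory neurons with elevated mutual
connection probability and weight embedded in an otherwise sparse
random (Erdos-Renyi) network. One or two such clusters, driven by the
Poisson noise and throttled by slow adaptation, ignite dish-wide
burst-pause oscillations at 0.1-0.5 Hz — the in vitro slow-oscillation
regime. Built-in presets pair a baseline topology with a recovery
topology in which the cluster structure has changed (a second cluster
added, or two clusters merged), which shifts burst duration and
inter-burst interval the way chemically stimulated cultures do.

All numerical parameter defaults here (neuron constants, kernel
amplitudes and time constants, connection probabilities and weights,
noise rates) are calibrated to place the baseline preset inside the
0.1-0.5 Hz burst-pause regime; they are plausible for cortical
cultures but are not measurements.

Simulation output is read out exactly like an MEA recording: 60 virtual
channels, each aggregating the spikes of 4 randomly chosen neurons,
yielding a :class:`~neuroburst.spikedata.SpikeTrainSet` that feeds
every analysis module unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .spikedata import SpikeTrainSet

__all__ = [
    "GIFParams",
    "SynapseSpec",
    "NetworkTopology",
    "ChannelMap",
    "SimResult",
    "DEFAULT_EXC_PARAMS",
    "DEFAULT_INH_PARAMS",
    "build_topology",
    "simulate",
    "make_channel_map",
    "readout",
    "poisson_input",
    "sample_clamped_spikes",
]


@dataclass(frozen=True)
class GIFParams:
    """Parameters of one GIF neuron population.

    Units: ``C`` pF, ``g_L`` nS, voltages mV, times ms, ``lambda0`` Hz,
    ``eta_amp`` pA (adaptation-current increment per spike),
    ``gamma_amp`` mV (threshold increment per spike). ``tau_eta`` and
    ``tau_gamma`` are the exponential decay constants of the
    spike-triggered kernels.
    """

    C: float = 200.0
    g_L: float = 10.0
    E_L: float = -65.0
    V_reset: float = -65.0
    tau_ref: float = 4.0
    lambda0: float = 10.0
    DeltaV: float = 2.0
    V_T_star: float = -50.0
    eta_amp: float = 12.0
    tau_eta: float = 1200.0
    gamma_amp: float = 4.0
    tau_gamma: float = 100.0

    def __post_init__(self) -> None:
        for name in ("C", "g_L", "DeltaV", "lambda0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.tau_eta <= 0 or self.tau_gamma <= 0:
            raise ValueError("kernel time constants must be positive")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L

    def intensity(self, V) -> np.ndarray:
        """Escape rate lambda(V) in Hz at threshold baseline (no
        accumulated gamma)."""
        return self.lambda0 * np.exp((np.asarray(V) - self.V_T_star) / self.DeltaV)


@dataclass(frozen=True)
class SynapseSpec:
    """Exponential current synapse: weight ``w`` (pA, sign carries
    excitation/inhibition), decay ``tau_syn`` (ms), transmission delay
    2 ms for every synapse."""

    w: float
    tau_syn: float
    delay: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


# Calibrated defaults (see module docstring): excitatory neurons carry
# strong slow adaptation that terminates bursts; inhibitory neurons are
# faster and only weakly adapting.
DEFAULT_EXC_PARAMS = GIFParams()
DEFAULT_INH_PARAMS = GIFParams(
    C=100.0,
    g_L=10.0,
    E_L=-65.0,
    V_reset=-65.0,
    tau_ref=2.0,
    lambda0=10.0,
    DeltaV=2.0,
    V_T_star=-50.0,
    eta_amp=2.0,
    tau_eta=500.0,
    gamma_amp=2.0,
    tau_gamma=50.0,
)


@dataclass
class NetworkTopology:
    """Description of the clustered network.

    ``cluster_sizes`` are disjoint contiguous blocks of excitatory
    neuron ids starting at 0 (ids are exchangeable in an Erdos-Renyi
    graph, so contiguous blocks lose no generality).
    ``p_intra``/``w_intra`` apply within each cluster;
    ``p_ee``/``w_ee`` apply to every other excitatory-excitatory pair
    (background-background, cluster-background and cluster-cluster).
    Inhibitory neurons share one background block per population pair.
    ``disconnected`` lists excitatory ids stripped of all synapses
    (in and out), used by the cluster-merge recovery preset.
    Noise: each neuron receives an independent Poisson spike train
    through the standard excitatory synapse at the given rate/weight.
    """

    n_exc: int = 3000
    n_inh: int = 900
    cluster_sizes: tuple = (95,)
    disconnected: tuple = ()
    p_intra: float = 0.5
    w_intra: float = 150.0
    p_ee: float = 0.05
    w_ee: float = 30.0
    p_ei: float = 0.05
    w_ei: float = 7.0
    p_ie: float = 0.05
    w_ie: float = -30.0
    p_ii: float = 0.05
    w_ii: float = -25.0
    tau_syn_e: float = 4.0
    tau_syn_i: float = 8.0
    delay: float = 2.0
    noise_rate_exc: float = 500.0
    noise_w_exc: float = 44.0
    noise_rate_inh: float = 500.0
    noise_w_inh: float = 36.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) > self.n_exc:
            raise ValueError("cluster sizes exceed the excitatory population")
        for p in (self.p_intra, self.p_ee, self.p_ei, self.p_ie, self.p_ii):
            if not 0 <= p <= 1:
                raise ValueError("connection probabilities must be in [0, 1]")
        if self.p_intra < self.p_ee:
            warnings.warn(
                "p_intra < p_ee: clusters are sparser than the background, "
                "which defeats their role as oscillation generators"
            )
        if any(i >= self.n_exc for i in self.disconnected):
            raise ValueError("disconnected ids must be excitatory neuron ids")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def clusters(self) -> list:
        """Cluster member id arrays (contiguous blocks)."""
        out, start = [], 0
        for size in self.cluster_sizes:
            out.append(np.arange(start, start + size))
            start += size
        return out


_PRESETS = {
    # one culture: a single 95-neuron cluster at baseline; stimulation
    # adds a second cluster of 90 during recovery
    "fig6_baseline": {"cluster_sizes": (95,)},
    "fig6_recovery": {"cluster_sizes": (95, 90)},
    # another culture: clusters of 65 and 40 at baseline merge into one
    # of 100 during recovery, and 5 formerly clustered neurons lose all
    # their connections
    "fig7_baseline": {"cluster_sizes": (65, 40)},
    "fig7_recovery": {"cluster_sizes": (100,), "disconnected": tuple(range(100, 105))},
}


def build_topology(preset: str | None = None, **overrides) -> NetworkTopology:
    """Build a :class:`NetworkTopology` from a named preset or from
    keyword overrides of the calibrated defaults.

    Presets: ``fig6_baseline`` (one 95-neuron cluster),
    ``fig6_recovery`` (clusters of 95 and 90), ``fig7_baseline``
    (clusters of 65 and 40), ``fig7_recovery`` (one merged cluster of
    100 with 5 former members fully disconnected). All use 3000
    excitatory and 900 inhibitory neurons.
    """
    kwargs: dict = {}
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        kwargs.update(_PRESETS[preset])
        kwargs["name"] = preset
    kwargs.update(overrides)
    return NetworkTopology(**kwargs)


@dataclass
class ChannelMap:
    """Virtual MEA readout: each channel aggregates the spikes of a
    fixed set of distinct neurons (4 per channel, 60 channels)."""

    members: np.ndarray  # (n_channels, per_channel) neuron ids
    seed: int | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        for row in self.members:
            if np.unique(row).size != row.size:
                raise ValueError("a neuron may not repeat within a channel")

    @property
    def n_channels(self) -> int:
        return self.members.shape[0]


def make_channel_map(
    n_neurons: int,
    n_channels: int = 60,
    per_channel: int = 4,
    seed: int | None = None,
) -> ChannelMap:
    """Randomly assign ``per_channel`` distinct neurons to each of
    ``n_channels`` virtual MEA channels."""
    rng = np.random.default_rng(seed)
    members = np.stack(
        [rng.choice(n_neurons, size=per_channel, replace=False) for _ in range(n_channels)]
    )
    return ChannelMap(members=members, seed=seed)


@dataclass
class SimResult:
    """Spike output of one network simulation: parallel arrays of spike
    times (s) and neuron ids, sorted by time."""

    spike_times: np.ndarray
    spike_ids: np.ndarray
    n_neurons: int
    n_exc: int
    duration: float
    dt: float
    topology_name: str = "custom"
    v_rec: np.ndarray | None = None
    v_rec_ids: np.ndarray | None = None

    def per_neuron(self) -> dict:
        """Spike times keyed by neuron id (only neurons that fired)."""
        order = np.argsort(self.spike_ids, kind="stable")
        ids = self.spike_ids[order]
        ts = self.spike_times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return {
            i: np.sort(ts[bounds[i] : bounds[i + 1]])
            for i in range(self.n_neurons)
            if bounds[i + 1] > bounds[i]
        }

    def spike_counts(self) -> np.ndarray:
        return np.bincount(self.spike_ids, minlength=self.n_neurons)

    def population_rate(self, exc_only: bool = False) -> float:
        """Mean firing rate per neuron in Hz."""
        n = self.n_exc if exc_only else self.n_neurons
        mask = self.spike_ids < n if exc_only else slice(None)
        return self.spike_ids[mask].size / (n * self.duration)


def readout(result: SimResult, channel_map: ChannelMap) -> SpikeTrainSet:
    """Aggregate simulated spikes onto virtual MEA channels: each
    channel's train is the merged, sorted union of its member neurons'
    spikes."""
    per = result.per_neuron()
    spikes = {}
    for ch in range(channel_map.n_channels):
        trains = [per[i] for i in channel_map.members[ch] if i in per]
        spikes[ch] = (
            np.sort(np.concatenate(trains)) if trains else np.empty(0)
        )
    return SpikeTrainSet(
        channels=list(range(channel_map.n_channels)),
        spikes=spikes,
        duration=result.duration,
    )


def poisson_input(
    rate: float, duration: float, seed: int | None = None
) -> np.ndarray:
    """A homogeneous Poisson spike train: sorted event times in seconds
    over ``[0, duration)``. This is the background-noise process each
    simulated neuron receives through the standard synapse."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def sample_clamped_spikes(
    params: GIFParams,
    V: float,
    duration: float,
    dt: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Spike times of a neuron whose membrane potential is clamped at
    ``V`` with adaptation and threshold movement disabled: a Poisson
    process at rate ``lambda0 * exp((V - V_T*)/DeltaV)``. Used to
    verify the escape-noise spiking mechanism; per-step emission
    probability is ``1 - exp(-lambda dt)`` exactly as in the network
    simulation."""
    rng = np.random.default_rng(seed)
    lam = float(params.intensity(V))  # Hz
    n_steps = int(round(duration * 1000.0 / dt))
    p = -np.expm1(-lam * dt * 1e-3)
    hits = rng.random(n_steps) < p
    return np.nonzero(hits)[0] * dt * 1e-3


# ---------------------------------------------------------------------------
# core integration kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _pop_step(
    lo, hi, k, slot, deliver_slot,
    V, Ie, Ii, eta, gam, ref,
    Be, Bi, dirty_e, dirty_i,
    # population scalars
    EL, inv_gL, decV, Vreset, ref_steps, lam0_dt, VT, inv_DV,
    eta_amp, gam_amp, dec_eta, dec_gam, dec_e, dec_i, exc_pop,
    i_ext,
    indptr, targets, weights,
    spk_step, spk_id, count,
):
    """Advance neurons [lo, hi) of one population by one step.
    Returns the updated spike count."""
    read_e = dirty_e[slot]
    read_i = dirty_i[slot]
    for i in range(lo, hi):
        Ie_i = Ie[i]
        Ii_i = Ii[i]
        if read_e:
            Ie_i += Be[slot, i]
            Be[slot, i] = 0.0
        if read_i:
            Ii_i += Bi[slot, i]
            Bi[slot, i] = 0.0
        if ref[i] > 0:
            ref[i] -= 1
            V[i] = Vreset
        else:
            I_tot = Ie_i + Ii_i - eta[i] + i_ext[i]
            Veq = EL + I_tot * inv_gL
            V[i] = Veq + (V[i] - Veq) * decV
            u = (V[i] - VT - gam[i]) * inv_DV
            # u < -12: escape probability below ~1e-8 per step; the
            # draw is skipped (bias far below one spike per epoch)
            if u > -12.0:
                if u > 30.0:
                    p = 1.0
                else:
                    lam = lam0_dt * np.exp(u)
                    p = lam if lam < 1e-3 else -np.expm1(-lam)
                if np.random.random() < p:
                    spk_step[count] = k
                    spk_id[count] = i
                    count += 1
                    V[i] = Vreset
                    ref[i] = ref_steps
                    eta[i] += eta_amp
                    gam[i] += gam_amp
                    if indptr[i + 1] > indptr[i]:
                        if exc_pop:
                            dirty_e[deliver_slot] = True
                            for a in range(indptr[i], indptr[i + 1]):
                                Be[deliver_slot, targets[a]] += weights[a]
                        else:
                            dirty_i[deliver_slot] = True
                            for a in range(indptr[i], indptr[i + 1]):
                                Bi[deliver_slot, targets[a]] += weights[a]
        # decay currents and kernels
        Ie[i] = Ie_i * dec_e
        Ii[i] = Ii_i * dec_i
        eta[i] *= dec_eta
        gam[i] *= dec_gam
    return count


@njit(cache=True, fastmath=True)
def _run_chunk(
    n_steps,
    rng_seed,
    # state (mutated in place)
    V, Ie, Ii, eta, gam, ref,
    # ring buffers (n_slots, n), dirty flags, current slot index
    Be, Bi, dirty_e, dirty_i, slot0, d_steps,
    # population scalar parameter tuples (exc, inh)
    n_exc,
    EL_e, inv_gL_e, decV_e, Vreset_e, ref_steps_e, lam0_dt_e, VT_e,
    inv_DV_e, eta_amp_e, gam_amp_e, dec_eta_e, dec_gam_e,
    EL_i, inv_gL_i, decV_i, Vreset_i, ref_steps_i, lam0_dt_i, VT_i,
    inv_DV_i, eta_amp_i, gam_amp_i, dec_eta_i, dec_gam_i,
    i_ext,
    # graph (CSR by presynaptic neuron)
    indptr, targets, weights,
    # synapse decay per step
    dec_e, dec_i,
    # noise events for this chunk, sorted by step
    noise_off, noise_id, noise_w,
    # spike output buffers
    spk_step, spk_id,
    # optional membrane-potential recording: v_rec[k, m] = V[v_ids[m]]
    v_ids, v_rec,
):
    np.random.seed(rng_seed)
    n = V.size
    n_slots = Be.shape[0]
    cap = spk_step.size
    count = 0
    slot = slot0
    for k in range(n_steps):
        if count + n > cap:
            # not enough room for a worst-case step: resume cleanly at k
            return k, count, slot
        # external Poisson noise (same exponential synapse, no delay)
        for e in range(noise_off[k], noise_off[k + 1]):
            j = noise_id[e]
            Ie[j] += noise_w[j]
        deliver_slot = (slot + d_steps) % n_slots
        count = _pop_step(
            0, n_exc, k, slot, deliver_slot,
            V, Ie, Ii, eta, gam, ref, Be, Bi, dirty_e, dirty_i,
            EL_e, inv_gL_e, decV_e, Vreset_e, ref_steps_e, lam0_dt_e,
            VT_e, inv_DV_e, eta_amp_e, gam_amp_e, dec_eta_e, dec_gam_e,
            dec_e, dec_i, True,
            i_ext, indptr, targets, weights, spk_step, spk_id, count,
        )
        count = _pop_step(
            n_exc, n, k, slot, deliver_slot,
            V, Ie, Ii, eta, gam, ref, Be, Bi, dirty_e, dirty_i,
            EL_i, inv_gL_i, decV_i, Vreset_i, ref_steps_i, lam0_dt_i,
            VT_i, inv_DV_i, eta_amp_i, gam_amp_i, dec_eta_i, dec_gam_i,
            dec_e, dec_i, False,
            i_ext, indptr, targets, weights, spk_step, spk_id, count,
        )
        dirty_e[slot] = False
        dirty_i[slot] = False
        for m in range(v_ids.size):
            v_rec[k, m] = V[v_ids[m]]
        slot = (slot + 1) % n_slots
    return n_steps, count, slot


def _build_graph(top: NetworkTopology, rng: np.random.Generator):
    """Realize the Erdos-Renyi block graph as a CSR adjacency by
    presynaptic neuron. Weight convention: ``weights`` holds w_ij for
    the connection presyn -> postsyn (sign included). No self-loops,
    no multi-edges."""
    n_e, n_i = top.n_exc, top.n_inh
    n = n_e + n_i
    W = np.zeros((n, n), dtype=np.float32)  # [pre, post]

    def fill(pre_lo, pre_hi, post_lo, post_hi, p, w):
        if p <= 0 or w == 0:
            return
        block = rng.random((pre_hi - pre_lo, post_hi - post_lo)) < p
        W[pre_lo:pre_hi, post_lo:post_hi][block] = w

    fill(0, n_e, 0, n_e, top.p_ee, top.w_ee)          # exc -> exc background
    for members in top.clusters:                       # intra-cluster overrides
        lo, hi = int(members[0]), int(members[-1]) + 1
        sub = rng.random((hi - lo, hi - lo)) < top.p_intra
        blk = W[lo:hi, lo:hi]
        blk[...] = 0.0
        blk[sub] = top.w_intra
    fill(0, n_e, n_e, n, top.p_ei, top.w_ei)           # exc -> inh
    fill(n_e, n, 0, n_e, top.p_ie, top.w_ie)           # inh -> exc
    fill(n_e, n, n_e, n, top.p_ii, top.w_ii)           # inh -> inh
    np.fill_diagonal(W, 0.0)
    for i in top.disconnected:
        W[i, :] = 0.0
        W[:, i] = 0.0

    indptr = np.zeros(n + 1, dtype=np.int64)
    targets_list = []
    weights_list = []
    for j in range(n):
        nz = np.nonzero(W[j])[0]
        targets_list.append(nz.astype(np.int64))
        weights_list.append(W[j, nz].astype(np.float32))
        indptr[j + 1] = indptr[j] + nz.size
    targets = np.concatenate(targets_list) if targets_list else np.empty(0, np.int64)
    weights = (
        np.concatenate(weights_list) if weights_list else np.empty(0, np.float32)
    )
    return indptr, targets, weights


def simulate(
    topology: NetworkTopology,
    duration: float,
    dt: float = 0.1,
    seed: int | None = None,
    exc_params: GIFParams = DEFAULT_EXC_PARAMS,
    inh_params: GIFParams = DEFAULT_INH_PARAMS,
    i_ext: np.ndarray | float = 0.0,
    record_v: list | None = None,
    chunk_steps: int = 20_000,
) -> SimResult:
    """Simulate the clustered GIF network.

    ``duration`` in seconds, ``dt`` in ms (must be <= 0.5 and no larger
    than the synaptic delay). ``seed`` drives four independent streams
    (graph realization, noise, spiking, channel selection elsewhere) so
    the topology can be held fixed across noise realizations by reusing
    the seed. ``i_ext`` is a constant injected current in pA (scalar
    or per-neuron), and ``record_v`` an optional list of neuron ids
    whose membrane potential is recorded every step
    (``SimResult.v_rec``, mV); both exist mainly for single-neuron
    validation.

    Integration: exponential-Euler for the leak (exact for piecewise
    constant input), forward accumulation of exponential synaptic and
    adaptation state variables, per-step spike emission with probability
    ``1 - exp(-lambda dt)``, reset and refractory clamp after each
    spike. Aborts with a diagnostic if the membrane potential leaves
    the finite range.
    """
    if dt <= 0 or dt > 0.5:
        raise ValueError("dt must be in (0, 0.5] ms")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if topology.delay < dt:
        raise ValueError("synaptic delay must be at least one time step")

    ss = np.random.SeedSequence(seed)
    graph_seed, noise_seed, spike_seed = ss.spawn(3)
    graph_rng = np.random.default_rng(graph_seed)
    noise_rng = np.random.default_rng(noise_seed)
    spike_seeds = spike_seed.generate_state(1 << 16) >> 1  # int31 per chunk

    n_e, n_i = topology.n_exc, topology.n_inh
    n = n_e + n_i
    indptr, targets, weights = _build_graph(topology, graph_rng)

    def per_neuron(attr_e, attr_i):
        out = np.empty(n)
        out[:n_e] = attr_e
        out[n_e:] = attr_i
        return out

    pe, pi = exc_params, inh_params

    def pop_scalars(p: GIFParams):
        return (
            float(p.E_L),
            float(1.0 / p.g_L),
            float(np.exp(-dt * p.g_L / p.C)),
            float(p.V_reset),
            int(round(p.tau_ref / dt)),
            float(p.lambda0 * dt * 1e-3),
            float(p.V_T_star),
            float(1.0 / p.DeltaV),
            float(p.eta_amp),
            float(p.gamma_amp),
            float(np.exp(-dt / p.tau_eta)),
            float(np.exp(-dt / p.tau_gamma)),
        )

    exc_scalars = pop_scalars(pe)
    inh_scalars = pop_scalars(pi)
    dec_e = float(np.exp(-dt / topology.tau_syn_e))
    dec_i = float(np.exp(-dt / topology.tau_syn_i))
    i_ext_arr = (
        np.broadcast_to(np.asarray(i_ext, dtype=np.float32), (n,)).copy()
    )

    d_steps = int(round(topology.delay / dt))
    n_slots = d_steps + 1
    Be = np.zeros((n_slots, n), dtype=np.float32)
    Bi = np.zeros((n_slots, n), dtype=np.float32)
    dirty_e = np.zeros(n_slots, dtype=np.bool_)
    dirty_i = np.zeros(n_slots, dtype=np.bool_)
    V = per_neuron(pe.E_L, pi.E_L).astype(np.float32)
    Ie = np.zeros(n, dtype=np.float32)
    Ii = np.zeros(n, dtype=np.float32)
    eta = np.zeros(n, dtype=np.float32)
    gam = np.zeros(n, dtype=np.float32)
    ref = np.zeros(n, dtype=np.int32)

    n_steps_total = int(round(duration * 1000.0 / dt))
    noise_lam_e = topology.noise_rate_exc * dt * 1e-3
    noise_lam_i = topology.noise_rate_inh * dt * 1e-3
    noise_w = per_neuron(topology.noise_w_exc, topology.noise_w_inh).astype(np.float32)

    v_ids = np.asarray(record_v if record_v is not None else [], dtype=np.int64)
    v_rec = np.empty((n_steps_total if v_ids.size else 0, v_ids.size), dtype=np.float32)

    cap = 2_000_000
    spk_step = np.empty(cap, dtype=np.int64)
    spk_id = np.empty(cap, dtype=np.int64)
    all_t: list[np.ndarray] = []
    all_id: list[np.ndarray] = []

    slot = 0
    step = 0
    chunk_idx = 0
    while step < n_steps_total:
        n_steps = min(chunk_steps, n_steps_total - step)
        # Poisson noise events for the chunk: totals are Poisson, event
        # placement uniform over (step, neuron) -- equivalent to
        # independent per-neuron Poisson trains.
        ke = noise_rng.poisson(noise_lam_e * n_steps * n_e)
        ki = noise_rng.poisson(noise_lam_i * n_steps * n_i)
        steps_ev = np.concatenate(
            (
                noise_rng.integers(0, n_steps, size=ke),
                noise_rng.integers(0, n_steps, size=ki),
            )
        )
        ids_ev = np.concatenate(
            (
                noise_rng.integers(0, n_e, size=ke),
                n_e + noise_rng.integers(0, n_i, size=ki),
            )
        )
        order = np.argsort(steps_ev, kind="stable")
        steps_ev = steps_ev[order]
        ids_ev = ids_ev[order].astype(np.int64)
        noise_off = np.zeros(n_steps + 1, dtype=np.int64)
        np.cumsum(np.bincount(steps_ev, minlength=n_steps), out=noise_off[1:])

        done = 0
        while done < n_steps:
            sub_steps = n_steps - done
            sub_off = (noise_off[done:] - noise_off[done]).copy()
            k_done, n_spk, slot = _run_chunk(
                sub_steps,
                int(spike_seeds[chunk_idx % spike_seeds.size]),
                V, Ie, Ii, eta, gam, ref,
                Be, Bi, dirty_e, dirty_i, slot, d_steps,
                n_e,
                *exc_scalars,
                *inh_scalars,
                i_ext_arr,
                indptr, targets, weights,
                dec_e, dec_i,
                sub_off, ids_ev[noise_off[done] :], noise_w,
                spk_step, spk_id,
                v_ids, v_rec[step + done : step + done + sub_steps],
            )
            chunk_idx += 1
            if n_spk:
                all_t.append((step + done + spk_step[:n_spk]) * dt * 1e-3)
                all_id.append(spk_id[:n_spk].copy())
            done += k_done
        step += n_steps
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(
                "membrane potential diverged; check parameter stability"
            )

    if all_t:
        t = np.concatenate(all_t)
        i = np.concatenate(all_id)
        order = np.argsort(t, kind="stable")
        t, i = t[order], i[order]
    else:
        t = np.empty(0)
        i = np.empty(0, dtype=np.int64)
    return SimResult(
        spike_times=t,
        spike_ids=i,
        n_neurons=n,
        n_exc=n_e,
        duration=duration,
        dt=dt,
        topology_name=topology.name,
        v_rec=v_rec if v_ids.size else None,
        v_rec_ids=v_ids if v_ids.size else None,
    )
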