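"""Spiking dynamics of a purely excitatory cultured network.

Leaky integrate-and-fire neurons (resting level 0, threshold ``v_th``,
reset to 0 with an absolute refractory period) are coupled through
current-based synapses with Tsodyks-Markram short-term depression: each
synapse partitions its neurotransmitter resources into effective (E),
recovered (R) and inactive (I = 1 - E - R) fractions.  A presynaptic spike
moves a fraction ``U * R`` from the recovered to the effective state; the
effective fraction decays to the inactive state with ``tau_inact`` and
resources recover with ``tau_rec``.  The recurrent current into neuron i is
``g_int * sum_j A[j, i] * E_j(t - delay)``.  Because synaptic parameters
are homogeneous, all synapses sharing a presynaptic neuron carry the same
state, which the integrator exploits.

Each neuron additionally receives an independent Poisson train ("minis",
the dominant noise source in cultures) through a static, non-depressing
coupling with exponential time course ``tau_syn``.

With depressing synapses this network switches irregularly between
near-synchronous network bursts and sparse inter-burst firing; the synaptic
weight is auto-tuned (:func:`tune_weight`) so bursts occur at a target rate
(default 0.1 Hz, i.e. about 360 bursts per simulated hour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.ndimage import maximum_filter1d

from ._seeds import derive_seed
from .errors import IntegrationError, TuningError
from .topology import DirectedNetwork

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "DriveParams",
    "SpikeRecord",
    "BurstList",
    "simulate",
    "detect_bursts",
    "burst_rate",
    "tune_weight",
]


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire constants.

    ``g_leak`` sets the current-to-voltage scale (pA per mV of steady-state
    depolarization); its absolute value is arbitrary and is absorbed by the
    synaptic-weight tuning.
    """

    tau_m: float = 20.0  # membrane time constant (ms)
    g_leak: float = 0.18  # leak conductance (pA/mV)
    v_th: float = 20.0  # firing threshold above rest (mV)
    t_ref: float = 2.0  # absolute refractory period (ms)
    delay: float = 2.0  # conduction delay (ms)
    dt: float = 0.1  # integration step (ms)

    def __post_init__(self):
        for name in ("tau_m", "g_leak", "v_th", "t_ref", "delay", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dt > self.delay:
            raise ValueError("dt must not exceed the conduction delay")


@dataclass(frozen=True)
class SynapseParams:
    """Recurrent coupling and Tsodyks-Markram depression constants."""

    g_int: float = 6.0  # recurrent synaptic weight (pA)
    U: float = 0.3  # release fraction per spike
    tau_inact: float = 3.0  # effective -> inactive decay (ms)
    tau_rec: float = 500.0  # inactive -> recovered recovery (ms)
    tau_syn: float = 2.0  # static (noise) synapse time constant (ms)

    def __post_init__(self):
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if not self.tau_rec > self.tau_inact > 0:
            raise ValueError("need tau_rec > tau_inact > 0")
        if self.g_int <= 0:
            raise ValueError("g_int must be positive")


@dataclass(frozen=True)
class DriveParams:
    """Independent Poisson 'mini' drive per neuron."""

    nu: float = 3200.0  # rate per neuron (Hz)
    g_noise: float = 0.4495  # drive weight (pA)

    def __post_init__(self):
        if self.nu < 0:
            raise ValueError("nu must be non-negative")


@dataclass
class SpikeRecord:
    """Per-neuron sorted spike times (s) over a known duration."""

    times: np.ndarray  # all spike times (s), globally sorted
    neurons: np.ndarray  # neuron index per spike
    n_neurons: int
    duration: float  # s
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def per_neuron(self) -> list[np.ndarray]:
        out = [np.empty(0)] * self.n_neurons
        order = np.argsort(self.neurons, kind="stable")
        srt_n = self.neurons[order]
        srt_t = self.times[order]
        bounds = np.searchsorted(srt_n, np.arange(self.n_neurons + 1))
        for i in range(self.n_neurons):
            out[i] = np.sort(srt_t[bounds[i]:bounds[i + 1]])
        return out

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def mean_rate(self) -> float:
        """Mean firing rate per neuron (Hz)."""
        return self.n_spikes / (self.n_neurons * self.duration)


@dataclass
class BurstList:
    """Network-burst onsets (s) and participating-neuron fractions."""

    onsets: np.ndarray
    fractions: np.ndarray

    @property
    def n_bursts(self) -> int:
        return self.onsets.size


@njit(cache=True, fastmath=True)
def _lif_tm_kernel(
    indptr,
    targets,
    nu,
    seed,
    n_steps,
    dt,
    tau_m,
    g_leak,
    v_th,
    ref_steps,
    delay_steps,
    g_int,
    U,
    tau_inact,
    tau_rec,
    tau_syn,
    g_noise,
    max_spikes,
    spike_t,
    spike_i,
):
    N = indptr.shape[0] - 1
    np.random.seed(seed)
    f_m = math.exp(-dt / tau_m)
    f_inact = math.exp(-dt / tau_inact)
    f_syn = math.exp(-dt / tau_syn)
    # exact one-step response of the membrane to an input current that
    # decays exponentially with tau over the step (piecewise-analytic
    # integration; no O(dt) bias from holding the current constant)
    k_inact = (tau_inact / (tau_inact - tau_m)) * (f_inact - f_m)
    k_syn = (tau_syn / (tau_syn - tau_m)) * (f_syn - f_m)
    c_syn = tau_syn / (tau_syn - tau_m)
    # (E, R) evolve freely between a neuron's own spikes, so the depression
    # state is advanced lazily with the exact propagator: E decays with
    # tau_inact and R relaxes to 1 - E(t) with tau_rec
    c_mix = tau_inact / (tau_rec - tau_inact)
    gi = g_int / g_leak
    gn = g_noise / g_leak

    V = np.zeros(N)
    dv = np.zeros(N)  # exact partial-step membrane charge from fresh events
    E = np.zeros(N)
    R = np.ones(N)
    last_up = np.zeros(N, np.int64)  # step of last E/R update per neuron
    s = np.zeros(N)  # summed delayed effective fraction seen by each target
    y = np.zeros(N)  # static Poisson-drive current state
    refr_until = np.zeros(N, np.int64)
    # ring buffer of scheduled release arrivals; one extra slot so writes at
    # (step + delay) never collide with the slot being consumed this step
    D = delay_steps + 1
    ring = np.zeros((D, N))
    # per-neuron Poisson next-event times in ms of continuous time, so the
    # drawn event stream does not depend on the integration step
    next_ev = np.empty(N)
    rate_per_ms = nu / 1000.0
    for i in range(N):
        if nu > 0:
            next_ev[i] = -math.log(np.random.random()) / rate_per_ms
        else:
            next_ev[i] = 1e18
    n_sp = 0
    for step in range(n_steps):
        slot = step % D
        arrive = (step + delay_steps) % D
        row = ring[slot]
        arow = ring[arrive]
        t_ms = step * dt
        for i in range(N):
            s[i] = s[i] * f_inact + row[i]
            row[i] = 0.0
            yi = y[i] * f_syn
            while next_ev[i] <= t_ms:
                # exact insertion of an event that fired inside the last
                # step: decayed drive amplitude plus the membrane charge
                # already accumulated since the event time, so neither the
                # drive nor V depends on the grid resolution
                age = t_ms - next_ev[i]
                a = math.exp(-age / tau_syn)
                yi += a
                dv[i] += gn * c_syn * (a - math.exp(-age / tau_m))
                next_ev[i] += -math.log(np.random.random()) / rate_per_ms
            y[i] = yi
        for i in range(N):
            if step < refr_until[i]:
                dv[i] = 0.0
                continue
            v = V[i] * f_m + gi * s[i] * k_inact + gn * y[i] * k_syn + dv[i]
            dv[i] = 0.0
            if v < v_th:
                V[i] = v
                continue
            if v > 1e6:
                return n_sp, -1  # numerical blow-up
            if n_sp >= max_spikes:
                return n_sp, -2  # spike budget exceeded
            spike_t[n_sp] = t_ms
            spike_i[n_sp] = i
            n_sp += 1
            V[i] = 0.0
            refr_until[i] = step + ref_steps
            # bring the depression state up to date, then release
            dt_el = (step - last_up[i]) * dt
            e0 = E[i]
            r0 = R[i]
            di = math.exp(-dt_el / tau_inact)
            dr = math.exp(-dt_el / tau_rec)
            e1 = e0 * di
            r1 = 1.0 + (r0 - 1.0 - c_mix * e0) * dr + c_mix * e0 * di
            rel = U * r1
            E[i] = e1 + rel
            R[i] = r1 - rel
            last_up[i] = step
            for kk in range(indptr[i], indptr[i + 1]):
                arow[targets[kk]] += rel
    return n_sp, 0


def simulate(
    net: DirectedNetwork,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    drive: DriveParams = DriveParams(),
    duration: float = 3600.0,
    seed: int = 0,
    max_mean_rate: float = 50.0,
) -> SpikeRecord:
    """Simulate ``duration`` seconds of network dynamics.

    Deterministic given ``seed``.  Raises :class:`IntegrationError` on
    numerical blow-up or if the spike count exceeds a sanity budget of
    ``max_mean_rate`` Hz per neuron on average (both indicate a runaway
    parameter set).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    N = net.n_nodes
    A = net.adjacency
    # CSR over outgoing links: spike of i is delivered to targets[indptr[i]:indptr[i+1]]
    indptr = np.zeros(N + 1, dtype=np.int64)
    indptr[1:] = A.sum(1).cumsum()
    targets = np.nonzero(A)[1].astype(np.int64)
    n_steps = int(round(duration * 1000.0 / neuron.dt))
    delay_steps = max(1, int(round(neuron.delay / neuron.dt)))
    ref_steps = int(round(neuron.t_ref / neuron.dt))
    max_spikes = int(max_mean_rate * N * duration)
    spike_t = np.empty(max_spikes)
    spike_i = np.empty(max_spikes, np.int64)
    n_sp, status = _lif_tm_kernel(
        indptr,
        targets,
        drive.nu,
        int(seed) & 0x7FFFFFFF,
        n_steps,
        neuron.dt,
        neuron.tau_m,
        neuron.g_leak,
        neuron.v_th,
        ref_steps,
        delay_steps,
        syn.g_int,
        syn.U,
        syn.tau_inact,
        syn.tau_rec,
        syn.tau_syn,
        drive.g_noise,
        max_spikes,
        spike_t,
        spike_i,
    )
    if status == -1:
        raise IntegrationError(
            f"membrane potential diverged (g_int={syn.g_int}, g_noise={drive.g_noise})"
        )
    if status == -2:
        raise IntegrationError(
            f"spike budget exceeded ({max_mean_rate} Hz/neuron mean): runaway "
            f"activity for g_int={syn.g_int}, g_noise={drive.g_noise}"
        )
    times = (spike_t[:n_sp] / 1000.0).copy()
    params = {
        "neuron": vars(neuron).copy() if not hasattr(neuron, "__dict__") else dict(neuron.__dict__),
        "synapse": dict(syn.__dict__),
        "drive": dict(drive.__dict__),
    }
    return SpikeRecord(
        times=times,
        neurons=spike_i[:n_sp].copy(),
        n_neurons=N,
        duration=float(duration),
        params=params,
        seed=int(seed),
    )


def detect_bursts(
    spikes: SpikeRecord,
    window: float = 50.0,
    fraction: float = 0.4,
    stride: float = 5.0,
) -> BurstList:
    """Detect network bursts: > ``fraction`` of neurons active in ``window`` ms.

    A sliding window (length ``window`` ms, advanced by ``stride`` ms) counts
    the fraction of neurons with at least one spike inside it.  A burst opens
    when the fraction exceeds the threshold and closes when it drops back
    below; events are non-overlapping and a burst must close before the next
    may start.  Onsets are the start times of the first supra-threshold
    window; each burst also reports the peak participating fraction.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if spikes.n_spikes == 0:
        return BurstList(np.empty(0), np.empty(0))
    stride_s = stride / 1000.0
    win_strides = max(1, int(round(window / stride)))
    n_strides = int(np.ceil(spikes.duration / stride_s)) + 1
    presence = np.zeros((spikes.n_neurons, n_strides), dtype=np.uint8)
    idx = np.minimum((spikes.times / stride_s).astype(np.int64), n_strides - 1)
    presence[spikes.neurons, idx] = 1
    # windowed "any spike" per neuron: window [t, t + win_strides)
    windowed = maximum_filter1d(presence, size=win_strides, axis=1, mode="constant",
                                origin=-(win_strides // 2))
    frac = windowed.mean(axis=0)
    above = frac > fraction
    onsets = []
    fractions = []
    in_burst = False
    peak = 0.0
    for t in range(frac.size):
        if above[t] and not in_burst:
            in_burst = True
            onsets.append(t * stride_s)
            peak = frac[t]
        elif above[t]:
            peak = max(peak, frac[t])
        elif in_burst:
            fractions.append(peak)
            in_burst = False
    if in_burst:
        fractions.append(peak)
    return BurstList(np.asarray(onsets), np.asarray(fractions))


def burst_rate(spikes: SpikeRecord, **kwargs) -> float:
    """Network burst rate (Hz) using :func:`detect_bursts` defaults."""
    return detect_bursts(spikes, **kwargs).n_bursts / spikes.duration


def tune_weight(
    net: DirectedNetwork,
    neuron: NeuronParams = NeuronParams(),
    syn_template: SynapseParams = SynapseParams(),
    drive: DriveParams = DriveParams(),
    target_rate: float = 0.1,
    tol: float = 0.01,
    probe_duration: float = 200.0,
    seed: int = 0,
    max_probes: int = 25,
    rate_fn: Callable[[float, int], float] | None = None,
) -> float:
    """Auto-tune the recurrent weight ``g_int`` to a target burst rate.

    Probes the burst rate on ``probe_duration``-second simulations.  If the
    first probe misses the target, the weight is moved by 10% (down when
    bursting too fast, up when too slow) and subsequent weights are obtained
    by linear (secant) extrapolation of the last two (weight, rate) pairs,
    until the measured rate is within ``tol`` Hz of the target.

    ``rate_fn(g, probe_index) -> rate`` may replace the simulator (used for
    testing the tuning logic in isolation).  Raises :class:`TuningError`
    with the probe trace if ``max_probes`` is exhausted; ``best`` on the
    exception holds the best weight found.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")

    def measure(g: float, k: int) -> float:
        if rate_fn is not None:
            return rate_fn(g, k)
        rec = simulate(
            net,
            neuron,
            replace(syn_template, g_int=g),
            drive,
            duration=probe_duration,
            seed=derive_seed(seed, f"tune-probe-{k}"),
        )
        return burst_rate(rec)

    trace: list[tuple[float, float]] = []
    g = syn_template.g_int
    r = measure(g, 0)
    trace.append((g, r))
    if abs(r - target_rate) < tol:
        return g
    g_next = g * (0.9 if r > target_rate else 1.1)
    for k in range(1, max_probes):
        r_next = measure(g_next, k)
        trace.append((g_next, r_next))
        if abs(r_next - target_rate) < tol:
            return g_next
        (g0, r0), (g1, r1) = trace[-2], trace[-1]
        if r1 == r0:
            # flat probe pair (e.g. both zero bursts): keep stepping
            g_new = g1 * (1.1 if r1 < target_rate else 0.9)
        else:
            g_new = g1 + (target_rate - r1) * (g1 - g0) / (r1 - r0)
        # keep the weight positive and the step bounded
        g_new = min(max(g_new, 0.2 * g1), 5.0 * g1)
        g_next = g_new
    best = min(trace, key=lambda t: abs(t[1] - target_rate))
    raise TuningError(
        f"burst-rate tuning did not converge within {max_probes} probes "
        f"(best |rate-target| = {abs(best[1] - target_rate):.3f} Hz at g={best[0]:.3f} pA)",
        best=best[0],
        trace=trace,
    )
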