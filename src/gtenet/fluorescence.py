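"""Calcium-fluorescence forward model.

Converts spike rasters into frame-sampled fluorescence the way a calcium
imaging experiment would see them: each action potential steps the bound
intra-cellular calcium concentration up by ``A_ca`` and the concentration
decays with ``tau_ca`` between frames; fluorescence is the calcium passed
through a saturating Hill-type non-linearity ``Ca / (Ca + K_sat)`` plus
i.i.d. Gaussian noise; finally, light scattered from surrounding cells adds
distance-weighted crosstalk between regions of interest (ROIs),

    F~_i = F_i + A_sc * sum_{j != i} exp(-d_ij^2 / r_sc^2) * F_j.

No deconvolution or spike inference is performed anywhere in the package:
the reconstruction method operates on these raw traces, and the residual
scattering artifact is part of the problem, not something to be removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import StructuralError
from .dynamics import SpikeRecord

__all__ = [
    "CalciumParams",
    "ScatterParams",
    "FluorescenceRecording",
    "spikes_to_calcium",
    "calcium_to_fluorescence",
    "apply_scattering",
    "synthesize",
]


@dataclass(frozen=True)
class CalciumParams:
    """Calcium indicator model constants."""

    a_ca: float = 50.0  # per-spike concentration step (a.u.)
    tau_ca: float = 1.0  # decay time (s)
    k_sat: float = 300.0  # half-saturation concentration (a.u.)
    noise_sd: float = 0.03  # Gaussian noise sd (fluorescence units)
    frame_interval: float = 0.02  # s between frames

    def __post_init__(self):
        for name in ("a_ca", "tau_ca", "k_sat", "noise_sd", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ScatterParams:
    """Light-scattering crosstalk: amplitude and Gaussian length scale."""

    a_sc: float = 0.15  # dimensionless amplitude
    r_sc: float = 0.03  # length scale (mm)

    def __post_init__(self):
        if self.a_sc < 0:
            raise ValueError("a_sc must be non-negative")
        if self.r_sc <= 0:
            raise ValueError("r_sc must be positive")


@dataclass
class FluorescenceRecording:
    """frames x N fluorescence matrix sampled at a fixed frame interval."""

    data: np.ndarray
    frame_interval: float  # s
    positions: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise StructuralError("fluorescence data must be frames x neurons")
        if not np.all(np.isfinite(self.data)):
            raise StructuralError("fluorescence data contains non-finite values")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[1], 2):
                raise StructuralError("positions must be (N, 2)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


def spikes_to_calcium(spikes: SpikeRecord, params: CalciumParams = CalciumParams()) -> np.ndarray:
    """Frame-resolved calcium concentration driven by the spike counts.

    Discrete update per frame: ``Ca_n = Ca_{n-1} (1 - dt/tau_ca) + a_ca * k_n``
    with ``k_n`` the number of action potentials the neuron fired inside
    frame ``n``.  Frame 0 already contains the spikes of the first interval.
    """
    dt = params.frame_interval
    n_frames = int(np.floor(spikes.duration / dt))
    counts = np.zeros((n_frames, spikes.n_neurons))
    frame_idx = np.minimum((spikes.times / dt).astype(np.int64), n_frames - 1)
    np.add.at(counts, (frame_idx, spikes.neurons.astype(np.int64)), 1.0)
    decay = 1.0 - dt / params.tau_ca
    # one-pole recursion Ca_n = decay * Ca_{n-1} + a_ca * counts_n
    ca = lfilter([params.a_ca], [1.0, -decay], counts, axis=0)
    return ca


def calcium_to_fluorescence(
    ca: np.ndarray,
    params: CalciumParams = CalciumParams(),
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> FluorescenceRecording:
    """Saturating non-linearity plus Gaussian noise: ``F = Ca/(Ca+K) + eta``."""
    rng = np.random.default_rng(seed)
    f = ca / (ca + params.k_sat)
    f = f + rng.normal(0.0, params.noise_sd, size=ca.shape)
    return FluorescenceRecording(
        f,
        params.frame_interval,
        positions=positions,
        provenance={"kind": "simulated", "noise_seed": int(seed), "scattered": False},
    )


def apply_scattering(
    rec: FluorescenceRecording,
    positions: np.ndarray | None = None,
    params: ScatterParams = ScatterParams(),
) -> FluorescenceRecording:
    """Add distance-weighted crosstalk from all other ROIs to each trace."""
    pos = positions if positions is not None else rec.positions
    if pos is None:
        raise StructuralError("scattering requires neuron positions")
    pos = np.asarray(pos, dtype=float)
    if params.a_sc == 0:
        return FluorescenceRecording(
            rec.data.copy(), rec.frame_interval, positions=pos,
            provenance={**rec.provenance, "scattered": False},
        )
    diff = pos[:, None, :] - pos[None, :, :]
    w = np.exp(-(diff**2).sum(-1) / params.r_sc**2)
    np.fill_diagonal(w, 0.0)
    data = rec.data + params.a_sc * (rec.data @ w)
    return FluorescenceRecording(
        data,
        rec.frame_interval,
        positions=pos,
        provenance={**rec.provenance, "scattered": True, "a_sc": params.a_sc, "r_sc": params.r_sc},
    )


def synthesize(
    spikes: SpikeRecord,
    calcium: CalciumParams = CalciumParams(),
    scatter: ScatterParams | None = ScatterParams(),
    positions: np.ndarray | None = None,
    seed: int = 0,
    settle: float = 10.0,
) -> FluorescenceRecording:
    """Full forward model: spikes -> calcium -> fluorescence (-> scattering).

    The first ``settle`` seconds of frames are discarded: the calcium
    model starts at zero concentration, and the ramp toward its
    activity-dependent baseline is an initialization artifact that a real
    recording (with the dye equilibrated) does not show.
    """
    ca = spikes_to_calcium(spikes, calcium)
    n_skip = int(round(settle / calcium.frame_interval))
    if n_skip >= ca.shape[0]:
        raise StructuralError("settle period longer than the recording")
    ca = ca[n_skip:]
    rec = calcium_to_fluorescence(ca, calcium, seed=seed, positions=positions)
    rec.provenance["settle_s"] = float(settle)
    if scatter is not None and scatter.a_sc > 0:
        if positions is None:
            raise StructuralError("scattering requires neuron positions")
        rec = apply_scattering(rec, positions, scatter)
    return rec
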