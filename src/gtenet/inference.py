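"""Directed functional-connectivity scores from fluorescence time series.

The centerpiece is a *generalized* Transfer Entropy (TE) estimator adapted
to slow, noisy calcium imaging:

* **Pre-processing** is a plain discrete differentiation of each trace,
  ``x_n = F_{n+1} - F_n``, which isolates candidate firing transients.
* **Same-bin interactions**: because the frame interval (tens of ms) is far
  longer than synaptic delays, causally related events routinely land in
  the same frame.  The source history window may therefore be shifted to
  include the current bin.
* **State conditioning**: cultured networks switch between synchronized
  bursts and quiet inter-burst periods, and only selected regimes carry
  information about monosynaptic structure.  Estimation is restricted to
  samples whose population-average fluorescence g(t) lies inside a
  conditioning interval; the upper level can be chosen automatically from
  the fluorescence histogram (two standard deviations above the mean of a
  Gaussian fitted to its left peak).

Probabilities are plug-in histogram estimates over ``bins`` discrete
levels per signal; scores are reported in bits (log base 2).  Competing
scores (cross-correlation, mutual information, Granger causality) are
computed under the identical pre-processing and conditioning so that
method comparisons are fair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .errors import ConvergenceError, StructuralError
from .fluorescence import FluorescenceRecording
from .topology import DirectedNetwork

__all__ = [
    "EstimatorSpec",
    "ScoreMatrix",
    "differentiate",
    "population_average",
    "conditioning_mask",
    "select_conditioning_level",
    "discretize",
    "gte_score",
    "mi_score",
    "xc_score",
    "gc_score",
    "score_matrix",
    "rank_and_threshold",
]


@dataclass(frozen=True)
class EstimatorSpec:
    """Parameterization of one score computation.

    ``order`` is the Markov order k (history length in frames).
    ``cond_low``/``cond_high`` bound the population-average fluorescence;
    a sample tuple is retained iff its most recent time index falls inside
    ``[cond_low, cond_high)``.  ``xc_lags`` is the half-width L of the
    cross-correlogram lag range (frames).
    """

    method: str = "te"  # te | mi | xc | gc
    order: int = 2
    same_bin: bool = True
    bins: int = 3
    cond_low: float = float("-inf")
    cond_high: float = float("inf")
    xc_lags: int = 2
    edge_sd: float | None = None

    def __post_init__(self):
        if self.method not in ("te", "mi", "xc", "gc"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.method in ("te", "mi") and self.bins < 2:
            raise ValueError("te/mi need at least 2 discretization levels")
        if self.edge_sd is not None and self.edge_sd <= 0:
            raise ValueError("edge_sd must be positive (or None for min/max edges)")
        if not self.cond_low < self.cond_high:
            raise ValueError("cond_low must be below cond_high")


@dataclass
class ScoreMatrix:
    """N x N directed pairwise scores; the diagonal is undefined (NaN)."""

    values: np.ndarray
    spec: EstimatorSpec
    n_samples: int  # retained sample tuples after conditioning
    warnings: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Flat vector of all N(N-1) off-diagonal scores (row-major)."""
        n = self.n_nodes
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]


# ---------------------------------------------------------------------------
# pre-processing and conditioning


def differentiate(rec: FluorescenceRecording | np.ndarray) -> np.ndarray:
    """Discrete differentiation ``x_n = F_{n+1} - F_n`` (length shrinks by 1)."""
    f = rec.data if isinstance(rec, FluorescenceRecording) else np.asarray(rec)
    return np.diff(f, axis=0)


def population_average(rec: FluorescenceRecording | np.ndarray) -> np.ndarray:
    """Average fluorescence g(t) over all neurons, per frame."""
    f = rec.data if isinstance(rec, FluorescenceRecording) else np.asarray(rec)
    return f.mean(axis=1)


def conditioning_mask(g: np.ndarray, g_low: float = float("-inf"), g_high: float = float("inf")) -> np.ndarray:
    """Boolean mask, true where ``g_low <= g < g_high``."""
    g = np.asarray(g)
    return (g >= g_low) & (g < g_high)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def select_conditioning_level(rec: FluorescenceRecording | np.ndarray, n_bins: int = 80) -> float:
    """Automatic conditioning level from the fluorescence histogram.

    Fits a Gaussian to the left (noise-dominated) peak of the histogram of
    the population-average fluorescence and returns ``mu + 2 sigma``.  The
    fit window runs from the left edge to where the histogram first drops
    below 10% of the peak, which isolates the Gaussian body from the
    high-fluorescence burst tail.
    """
    g = population_average(rec) if not (isinstance(rec, np.ndarray) and rec.ndim == 1) else rec
    counts, edges = np.histogram(g, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    if peak >= n_bins - 2:
        raise ConvergenceError(
            "fluorescence histogram has no left peak (monotone distribution); "
            "choose the conditioning level manually"
        )
    stop = peak
    while stop < n_bins and counts[stop] > 0.1 * counts[peak]:
        stop += 1
    lo = max(0, peak - (stop - peak) - 2)
    window = slice(lo, min(stop + 1, n_bins))
    xw, yw = centers[window], counts[window].astype(float)
    width0 = max((centers[min(stop, n_bins - 1)] - centers[peak]) / 2.0, edges[1] - edges[0])
    try:
        popt, _ = curve_fit(
            _gaussian,
            xw,
            yw,
            p0=(counts[peak], centers[peak], width0),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ConvergenceError(
            "Gaussian fit to the left fluorescence peak failed; choose the "
            "conditioning level manually"
        ) from exc
    amp, mu, sigma = popt
    sigma = abs(sigma)
    if not np.isfinite(mu) or not np.isfinite(sigma) or sigma == 0:
        raise ConvergenceError("degenerate Gaussian fit; choose the level manually")
    return float(mu + 2.0 * sigma)


def discretize(x: np.ndarray, bins: int, edges_from: np.ndarray | None = None) -> np.ndarray:
    """Quantize a signal into ``bins`` equal-width levels.

    Bin edges span the min..max of ``edges_from`` (defaults to ``x``
    itself, i.e. the conditioned samples the caller passes in); values
    outside are clipped into the boundary bins.  A zero-range signal maps
    to symbol 0 everywhere.
    """
    x = np.asarray(x, dtype=float)
    ref = x if edges_from is None else np.asarray(edges_from, dtype=float)
    lo = ref.min() if ref.size else 0.0
    hi = ref.max() if ref.size else 0.0
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.int64)
    sym = ((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(sym, 0, bins - 1)


# ---------------------------------------------------------------------------
# per-pair scores


def _history_code(sym: np.ndarray, k: int, b: int, include_same_bin: bool) -> np.ndarray:
    """Base-b code of a length-k history window per time index.

    With ``include_same_bin`` the window ends at the current bin t
    (covering t, t-1, ..., t-k+1); otherwise it covers t-1 ... t-k.
    Valid from index k onward in either case (kept uniform so that TE
    variants and competitors share the same sample set).
    """
    T = sym.shape[0]
    code = np.zeros(T, dtype=np.int64)
    offset = 0 if include_same_bin else 1
    for m in range(k):
        lag = m + offset
        if lag:
            code[lag:] += sym[: T - lag] * (b**m)
        else:
            code += sym * (b**m)
    return code


def _te_from_counts(joint: np.ndarray) -> float:
    """Plug-in TE (bits) from counts shaped (source, past, future)."""
    n = joint.sum()
    if n == 0:
        return 0.0
    c = joint / n
    c_sp = c.sum(axis=2, keepdims=True)  # p(source, past)
    c_pf = c.sum(axis=0, keepdims=True)  # p(past, future)
    c_p = c.sum(axis=(0, 2), keepdims=True)  # p(past)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * c_p) / (c_sp * c_pf)
        term = np.where(c > 0, c * np.log2(np.where(c > 0, ratio, 1.0)), 0.0)
    return float(term.sum())


def _edge_range(samples: np.ndarray, spec: EstimatorSpec) -> np.ndarray:
    """Reference range for bin edges, from the conditioned samples.

    With ``spec.edge_sd = c`` the bins span mean +/- c*sd (at the default
    c=3 and b=3 levels the bin width is twice the signal's standard
    deviation); samples outside are clipped into the boundary bins.  With
    ``edge_sd=None`` the raw min..max range is used instead.
    """
    if samples.size == 0:
        return samples
    if spec.edge_sd is None:
        return np.array([samples.min(), samples.max()])
    mu = samples.mean()
    sd = samples.std()
    return np.array([mu - spec.edge_sd * sd, mu + spec.edge_sd * sd])


@njit(cache=True)
def _te_pairs_kernel(tsel, ssel, b, k):
    """Plug-in generalized TE for every ordered pair.

    ``tsel``/``ssel`` are (N, M) arrays of per-neuron target codes
    (future + past) and source-history codes over the M retained samples.
    Returns values[source, target] in bits.
    """
    N, M = tsel.shape
    P = b**k  # number of past / source-history states
    C = b * P  # target-code states (future + past)
    nstates = C * P
    vals = np.full((N, N), np.nan)
    counts = np.zeros(nstates, np.int64)
    c_sp = np.zeros(P * P, np.int64)  # (source, past)
    c_pf = np.zeros(C, np.int64)  # (past, future)
    c_p = np.zeros(P, np.int64)
    if M == 0:
        for j in range(N):
            for i in range(N):
                if i != j:
                    vals[j, i] = 0.0
        return vals
    inv = 1.0 / (M * np.log(2.0))
    for j in range(N):
        for i in range(N):
            if i == j:
                continue
            for idx in range(nstates):
                counts[idx] = 0
            ti = tsel[i]
            sj = ssel[j]
            for t in range(M):
                counts[ti[t] + C * sj[t]] += 1
            # marginals
            for idx in range(P * P):
                c_sp[idx] = 0
            for idx in range(C):
                c_pf[idx] = 0
            for idx in range(P):
                c_p[idx] = 0
            for s in range(P):
                base = C * s
                for p in range(P):
                    for f in range(b):
                        c = counts[base + p * b + f]
                        if c:
                            c_sp[s * P + p] += c
                            c_pf[p * b + f] += c
                            c_p[p] += c
            te = 0.0
            for s in range(P):
                base = C * s
                for p in range(P):
                    for f in range(b):
                        c = counts[base + p * b + f]
                        if c:
                            ratio = (c * c_p[p]) / (c_sp[s * P + p] * c_pf[p * b + f])
                            te += c * np.log(ratio)
            vals[j, i] = te * inv
    return vals


def _pair_codes(x: np.ndarray, spec: EstimatorSpec, mask: np.ndarray | None):
    """Discretize one series on its conditioned samples and build codes."""
    T = x.shape[0]
    m = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    ref = x[m] if m.any() else x
    sym = discretize(x, spec.bins, edges_from=_edge_range(ref, spec))
    return sym, m


def gte_score(x_target: np.ndarray, x_source: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
              mask: np.ndarray | None = None) -> float:
    """Generalized TE (bits) from a source series to a target series.

    ``x_*`` are differentiated fluorescence traces.  ``mask`` marks time
    indices passing the conditioning criterion; a sample tuple is retained
    iff its most recent index (the future bin) is marked.  With
    ``spec.same_bin`` the source history window is shifted forward to
    include the future bin itself.
    """
    x_target = np.asarray(x_target, float)
    x_source = np.asarray(x_source, float)
    if x_target.shape != x_source.shape:
        raise StructuralError("series must have equal length")
    k, b = spec.order, spec.bins
    sym_t, m = _pair_codes(x_target, spec, mask)
    sym_s, _ = _pair_codes(x_source, spec, mask)
    tpast = _history_code(sym_t, k, b, include_same_bin=False)
    spast = _history_code(sym_s, k, b, include_same_bin=spec.same_bin)
    valid = np.zeros(sym_t.shape[0], dtype=bool)
    valid[k:] = True
    sel = valid & m
    combined = sym_t[sel] + b * tpast[sel] + (b ** (k + 1)) * spast[sel]
    joint = np.bincount(combined, minlength=b ** (2 * k + 1))
    # C-order reshape: axis order (source history, target past, future)
    return _te_from_counts(joint.reshape(b**k, b**k, b))


def mi_score(x_i: np.ndarray, x_j: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
             mask: np.ndarray | None = None) -> float:
    """Zero-lag mutual information (bits) of the discretized series.

    The first ``spec.order`` samples are excluded so MI is estimated on
    exactly the same retained sample set as TE under the same spec.
    """
    b = spec.bins
    sym_i, m = _pair_codes(np.asarray(x_i, float), spec, mask)
    sym_j, _ = _pair_codes(np.asarray(x_j, float), spec, mask)
    m = m.copy()
    m[: spec.order] = False
    joint = np.bincount(sym_i[m] + b * sym_j[m], minlength=b * b).reshape(b, b)
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    pi = p.sum(1, keepdims=True)
    pj = p.sum(0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p / (pi * pj)), 0.0)
    return float(term.sum())


def _masked_corr(a: np.ndarray, b_: np.ndarray) -> float:
    if a.size < 2:
        return 0.0
    sa, sb = a.std(), b_.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b_ - b_.mean())).mean() / (sa * sb))


def xc_score(x_i: np.ndarray, x_j: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
             mask: np.ndarray | None = None) -> float:
    """Largest Pearson cross-correlogram peak over lags -L..L."""
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    T = x_i.shape[0]
    m = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    L = spec.xc_lags
    best = -np.inf
    for lag in range(-L, L + 1):
        # pair (x_i[t], x_j[t - lag]); conditioning indexes t
        t0 = max(0, lag)
        t1 = T + min(0, lag)
        sel = m[t0:t1]
        c = _masked_corr(x_i[t0:t1][sel], x_j[t0 - lag:t1 - lag][sel])
        best = max(best, c)
    return best


def gc_score(x_target: np.ndarray, x_source: np.ndarray, spec: EstimatorSpec = EstimatorSpec(),
             mask: np.ndarray | None = None) -> float:
    """Granger causality: log ratio of AR residual variances.

    A univariate AR(k) fit of the target is compared with a bivariate fit
    whose source regressors start at the current bin when ``same_bin`` is
    on.  Fits are ordinary least squares on the conditioned samples.
    """
    x_t = np.asarray(x_target, float)
    x_s = np.asarray(x_source, float)
    T = x_t.shape[0]
    k = spec.order
    m = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    sel = np.zeros(T, dtype=bool)
    sel[k:] = True
    sel &= m
    idx = np.nonzero(sel)[0]
    y = x_t[idx]
    cols_uni = [np.ones(idx.size)] + [x_t[idx - mm] for mm in range(1, k + 1)]
    src_start = 0 if spec.same_bin else 1
    cols_src = [x_s[idx - mm] for mm in range(src_start, k + 1)]
    X_uni = np.column_stack(cols_uni)
    X_biv = np.column_stack(cols_uni + cols_src)
    res_uni = _ols_residual_var(X_uni, y)
    res_biv = _ols_residual_var(X_biv, y)
    if res_biv <= 0 or res_uni <= 0:
        return 0.0
    return float(np.log(res_uni / res_biv))


def _ols_residual_var(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float((r**2).mean())


# ---------------------------------------------------------------------------
# full matrices


def _prepare(rec: FluorescenceRecording, spec: EstimatorSpec):
    """Differentiate, align the conditioning mask, and report sample count."""
    x = differentiate(rec)
    g = population_average(rec)[1:]  # g at the later frame of each difference
    m = conditioning_mask(g, spec.cond_low, spec.cond_high)
    return x, m


def te_matrix(x: np.ndarray, mask: np.ndarray, spec: EstimatorSpec) -> ScoreMatrix:
    """Generalized-TE score matrix from differentiated traces and a mask.

    This is the computational core behind :func:`score_matrix` for the TE
    method; it is exposed separately so range analyses can score with an
    explicitly subsampled conditioning mask.
    """
    T, N = x.shape
    k, b = spec.order, spec.bins
    m = np.asarray(mask, dtype=bool)
    valid = np.zeros(T, dtype=bool)
    valid[k:] = True
    sel = valid & m
    warns: list[str] = []
    n_samples = int(sel.sum())
    if n_samples < 10 * b ** (2 * k + 1):
        warns.append(f"only {n_samples} retained tuples for {b ** (2 * k + 1)} joint states")
    sym = np.empty((T, N), dtype=np.int64)
    for i in range(N):
        ref = x[m, i] if m.any() else x[:, i]
        sym[:, i] = discretize(x[:, i], b, edges_from=_edge_range(ref, spec))
    tcode = np.empty((T, N), dtype=np.int64)
    scode = np.empty((T, N), dtype=np.int64)
    for i in range(N):
        past = _history_code(sym[:, i], k, b, include_same_bin=False)
        tcode[:, i] = sym[:, i] + b * past
        scode[:, i] = _history_code(sym[:, i], k, b, include_same_bin=spec.same_bin)
    tsel = np.ascontiguousarray(tcode[sel].T)
    ssel = np.ascontiguousarray(scode[sel].T)
    values = _te_pairs_kernel(tsel, ssel, b, k)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return ScoreMatrix(values=values, spec=spec, n_samples=n_samples, warnings=warns)


def score_matrix(rec: FluorescenceRecording, spec: EstimatorSpec = EstimatorSpec()) -> ScoreMatrix:
    """Score every ordered pair of neurons under one estimator spec.

    Deterministic given its inputs.  Records a warning when the number of
    retained tuples is below 10x the joint-state count of the TE histogram
    (under-sampled plug-in estimate).
    """
    x, m = _prepare(rec, spec)
    if spec.method == "te":
        return te_matrix(x, m, spec)
    T, N = x.shape
    k, b = spec.order, spec.bins
    warns: list[str] = []
    valid = np.zeros(T, dtype=bool)
    valid[k:] = True
    sel = valid & m
    n_samples = int(sel.sum())
    values = np.full((N, N), np.nan)

    if spec.method == "mi":
        # per-neuron edges from each neuron's own conditioned samples
        sym = np.empty((T, N), dtype=np.int64)
        for i in range(N):
            ref = x[m, i] if m.any() else x[:, i]
            sym[:, i] = discretize(x[:, i], b, edges_from=_edge_range(ref, spec))
        ssym = sym[sel]
        for i in range(N):
            for j in range(i + 1, N):
                jm = np.bincount(ssym[:, i] + b * ssym[:, j], minlength=b * b).reshape(b, b)
                n = jm.sum()
                p = jm / n if n else jm.astype(float)
                pi = p.sum(1, keepdims=True)
                pj = p.sum(0, keepdims=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(p > 0, p * np.log2(p / (pi * pj)), 0.0)
                values[i, j] = values[j, i] = float(term.sum())
    elif spec.method == "xc":
        L = spec.xc_lags
        best = np.full((N, N), -np.inf)
        for lag in range(-L, L + 1):
            t0 = max(0, lag)
            t1 = T + min(0, lag)
            msel = m[t0:t1]
            Xi = x[t0:t1][msel]
            Xj = x[t0 - lag:t1 - lag][msel]
            Xi = Xi - Xi.mean(0)
            Xj = Xj - Xj.mean(0)
            si = Xi.std(0)
            sj = Xj.std(0)
            si[si == 0] = np.inf
            sj[sj == 0] = np.inf
            corr = (Xi / si).T @ (Xj / sj) / Xi.shape[0]
            best = np.maximum(best, corr)
        values = best
        np.fill_diagonal(values, np.nan)
    elif spec.method == "gc":
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                values[j, i] = gc_score(x[:, i], x[:, j], spec, m)
        # values[source, target] orientation achieved by the index order above
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return ScoreMatrix(values=values, spec=spec, n_samples=n_samples, warnings=warns)


def rank_and_threshold(scores: ScoreMatrix, fraction: float = 0.10,
                       positions: np.ndarray | None = None) -> DirectedNetwork:
    """Retain the top ``fraction`` of ranked links as a reconstructed network.

    Scores are ranked ascending and rescaled to the unit range; exactly
    ``round(fraction * N(N-1))`` links are kept.  Ties are broken by
    (source, target) lexical order so the reconstruction is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    N = scores.n_nodes
    vals = scores.values
    src, dst = np.nonzero(~np.eye(N, dtype=bool))
    flat = vals[src, dst]
    n_keep = int(round(fraction * N * (N - 1)))
    # sort descending by score, ties by (source, target) ascending
    order = np.lexsort((dst, src, -flat))
    keep = order[:n_keep]
    A = np.zeros((N, N), dtype=bool)
    A[src[keep], dst[keep]] = True
    meta = {
        "ensemble": "reconstruction",
        "method": scores.spec.method,
        "fraction": float(fraction),
        "n_links": n_keep,
    }
    return DirectedNetwork(A, positions, meta)
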