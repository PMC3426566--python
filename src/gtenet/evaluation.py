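"""Reconstruction quality metrics and topology audits.

Against a known ground truth the primary quality measure is the ROC curve
over all score thresholds, summarized by the true-positive fraction at 10%
false positives (TP@0.1).  The positive precision curve (PPC) plots the
true-false ratio TFR = (#TP - #FP)/(#TP + #FP) against the number of
retained links (TFS); TFR = 0 means a retained link is equally likely to
be true or false.

For real recordings, where no ground truth exists, reconstructed
topologies are compared against full and partial randomizations
(:func:`topology_report`), and state-dependent functional hubs are
characterized by their neighborhood synchrony and burst timing
(:func:`hub_analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_curve as _sk_roc_curve

from .fluorescence import FluorescenceRecording
from .inference import (
    EstimatorSpec,
    ScoreMatrix,
    conditioning_mask,
    differentiate,
    population_average,
    rank_and_threshold,
    score_matrix,
)
from .topology import DirectedNetwork, connection_distances, full_clustering
from ._seeds import derive_rng

__all__ = [
    "ROCResult",
    "PPCResult",
    "HubReport",
    "roc",
    "performance",
    "ppc",
    "topology_report",
    "motif_audit",
    "hub_analysis",
    "state_range_analysis",
]


@dataclass
class ROCResult:
    """Monotone ROC curve plus the TP fraction at 10% FP."""

    fpr: np.ndarray
    tpr: np.ndarray
    tp_at_10fp: float


@dataclass
class PPCResult:
    """Positive precision curve: (TFS retained-link count, TFR ratio)."""

    tfs: np.ndarray
    tfr: np.ndarray
    n_tp: np.ndarray
    n_fp: np.ndarray


@dataclass
class HubRangeResult:
    """Hub statistics for one conditioning range."""

    hubs: np.ndarray  # node ids, strongest first
    within_sync: float  # mean pairwise peak XC inside hub neighborhoods
    across_sync: float  # mean peak XC between neighborhoods and the rest
    mw_pvalue: float  # Mann-Whitney test, within vs across
    peak_lag: float  # fitted correlogram lag of hub groups (frames; <0 leads)
    amplitude: float
    sigma: float
    fit_ok: bool


@dataclass
class HubReport:
    ranges: list = field(default_factory=list)  # (g_low, g_high) per range
    results: list = field(default_factory=list)  # HubRangeResult per range


def _truth_and_scores(scores: ScoreMatrix | np.ndarray, truth: DirectedNetwork):
    vals = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    n = vals.shape[0]
    if truth.adjacency.shape != (n, n):
        raise ValueError("score matrix and truth have different sizes")
    mask = ~np.eye(n, dtype=bool)
    return truth.adjacency[mask].astype(int), vals[mask]


def roc(scores: ScoreMatrix | np.ndarray, truth: DirectedNetwork) -> ROCResult:
    """ROC curve of the score matrix against the ground-truth adjacency.

    The threshold sweeps all distinct score values; the diagonal is
    excluded from both positive and negative counts.
    """
    y, s = _truth_and_scores(scores, truth)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    res = ROCResult(fpr=fpr, tpr=tpr, tp_at_10fp=float(np.interp(0.10, fpr, tpr)))
    return res


def performance(roc_result: ROCResult, fp: float = 0.10) -> float:
    """TP fraction at the given FP fraction, linearly interpolated."""
    return float(np.interp(fp, roc_result.fpr, roc_result.tpr))


def ppc(scores: ScoreMatrix | np.ndarray, truth: DirectedNetwork) -> PPCResult:
    """Positive precision curve over all retained-link counts.

    Links are added in descending score order (ties broken by row-major
    position, matching :func:`gtenet.inference.rank_and_threshold`); at
    each count TFS=k the curve reports TFR = (#TP - #FP) / k.
    """
    y, s = _truth_and_scores(scores, truth)
    order = np.argsort(-s, kind="stable")
    hits = y[order]
    tp = np.cumsum(hits)
    k = np.arange(1, hits.size + 1)
    fp = k - tp
    return PPCResult(tfs=k, tfr=(tp - fp) / k, n_tp=tp, n_fp=fp)


def topology_report(
    recon: DirectedNetwork,
    references: list[DirectedNetwork],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-network topology observables for a reconstruction and references.

    Returns a tidy frame with one row per (network, node) for clustering
    and in-degree and one row per link for distances, summarized by the
    caller as needed; the ``summary`` attribute (DataFrame.attrs) holds
    ensemble means and, when several references are present, the empirical
    two-sided percentile of the reconstruction's mean among them.
    """
    nets = [recon] + list(references)
    if labels is None:
        labels = ["reconstruction"] + [
            r.meta.get("ensemble", f"reference_{i}") for i, r in enumerate(references)
        ]
    rows = []
    means = []
    for label, net in zip(labels, nets):
        cc = full_clustering(net)
        indeg = net.adjacency.sum(0)
        dist = connection_distances(net) if net.positions is not None else np.empty(0)
        rows.append(
            pd.DataFrame(
                {
                    "network": label,
                    "node": np.arange(net.n_nodes),
                    "clustering": cc,
                    "in_degree": indeg,
                }
            )
        )
        means.append(
            {
                "network": label,
                "mean_clustering": float(cc.mean()),
                "mean_in_degree": float(indeg.mean()),
                "mean_distance": float(dist.mean()) if dist.size else np.nan,
                "n_links": net.n_links,
            }
        )
    frame = pd.concat(rows, ignore_index=True)
    summary = pd.DataFrame(means)
    # empirical percentile of the reconstruction among the references
    if len(references) >= 2:
        ref_cc = summary["mean_clustering"].to_numpy()[1:]
        obs = summary["mean_clustering"].iloc[0]
        summary.attrs["cc_percentile"] = float(100.0 * (ref_cc < obs).mean())
    frame.attrs["summary"] = summary
    return frame


def motif_audit(recon: DirectedNetwork, truth: DirectedNetwork) -> dict:
    """Motif-level audit of a thresholded reconstruction vs ground truth.

    Fractions reported:

    * ``bidir_recovered`` - ground-truth reciprocal pairs with both
      directions retained;
    * ``unidir_recovered`` - ground-truth unidirectional links present in
      the retained set;
    * ``unidir_reverse_spurious`` - retained ground-truth unidirectional
      links whose (false) reverse is also retained;
    * ``shared_source_spurious`` - shared-source triples (k->i, k->j, no
      true lateral link either way) where a lateral link was inferred;
    * ``chain_shortcut_spurious`` - chains i->j->k without a true direct
      i->k where the shortcut i->k was inferred.
    """
    A = truth.adjacency
    Rm = recon.adjacency
    if A.shape != Rm.shape:
        raise ValueError("shape mismatch")
    At = A.T
    bidir_pair = A & At
    iu = np.triu_indices_from(A, k=1)
    bp = bidir_pair[iu]
    n_bidir_pairs = int(bp.sum())
    both = (Rm & Rm.T)[iu][bp]
    bidir_recovered = float(both.mean()) if n_bidir_pairs else np.nan

    unidir = A & ~At
    n_unidir = int(unidir.sum())
    unidir_hit = Rm[unidir]
    unidir_recovered = float(unidir_hit.mean()) if n_unidir else np.nan

    retained_unidir = unidir & Rm
    if retained_unidir.sum():
        rev = Rm.T[retained_unidir]
        unidir_reverse = float(rev.mean())
    else:
        unidir_reverse = np.nan

    # shared-source motifs: k -> i and k -> j, no true lateral link; count
    # the fraction where the reconstruction adds i->j or j->i
    Af = A.astype(np.int64)
    shared_cnt = 0
    shared_bad = 0
    lateral_any = Rm | Rm.T
    no_true_lateral = ~(A | At)
    common = Af.T @ Af  # common[i, j] = number of shared sources of i and j
    for i, j in zip(*np.triu_indices_from(A, k=1)):
        if common[i, j] > 0 and no_true_lateral[i, j]:
            shared_cnt += 1
            if lateral_any[i, j]:
                shared_bad += 1
    shared_spurious = shared_bad / shared_cnt if shared_cnt else np.nan

    # embedded chains: i -> j -> k with no true i -> k (i != k)
    two_step = (Af @ Af) > 0
    np.fill_diagonal(two_step, False)
    chain = two_step & ~A
    n_chain = int(chain.sum())
    chain_bad = int((chain & Rm).sum())
    chain_spurious = chain_bad / n_chain if n_chain else np.nan

    return {
        "bidir_recovered": bidir_recovered,
        "unidir_recovered": unidir_recovered,
        "unidir_reverse_spurious": unidir_reverse,
        "shared_source_spurious": shared_spurious,
        "chain_shortcut_spurious": chain_spurious,
        "n_bidir_pairs": n_bidir_pairs,
        "n_unidir_links": n_unidir,
        "n_shared_source_pairs": shared_cnt,
        "n_chain_pairs": n_chain,
    }


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _peak_xc(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Largest Pearson correlation over integer lags -max_lag..max_lag."""
    best = -np.inf
    T = a.size
    for lag in range(-max_lag, max_lag + 1):
        t0, t1 = max(0, lag), T + min(0, lag)
        aa, bb = a[t0:t1], b[t0 - lag:t1 - lag]
        sa, sb = aa.std(), bb.std()
        if sa == 0 or sb == 0:
            continue
        c = float(((aa - aa.mean()) * (bb - bb.mean())).mean() / (sa * sb))
        best = max(best, c)
    return best


def hub_analysis(
    rec: FluorescenceRecording,
    scores_per_range: list[ScoreMatrix],
    ranges: list[tuple[float, float]],
    n_hubs: int = 20,
    top_fraction: float = 0.10,
    max_lag: int = 20,
    seed: int = 0,
    n_pair_sample: int = 300,
) -> HubReport:
    """State-dependent functional connectivity hubs and their dynamics.

    For each conditioning range: hubs are the ``n_hubs`` nodes with the
    largest summed incoming TE; a hub's neighborhood is the hub plus its
    first in-neighbors in the retained (top ``top_fraction``) functional
    graph of that range.  Within-neighborhood synchrony (mean pairwise
    peak cross-correlation of differentiated traces) is compared against
    across-group pairs with a Mann-Whitney test.  The timing of each
    range's hub communities is the peak lag of a Gaussian fitted to the
    cross-correlogram between the differentiated group-average and
    population-average fluorescence (negative lag = group leads).
    """
    x = differentiate(rec)
    xall = x.mean(axis=1)
    rng = derive_rng(seed, "hub-analysis")
    report = HubReport(ranges=list(ranges))
    for sm in scores_per_range:
        vals = sm.values.copy()
        np.fill_diagonal(vals, 0.0)
        incoming = np.nansum(vals, axis=0)
        hubs = np.argsort(-incoming)[: min(n_hubs, sm.n_nodes)]
        retained = rank_and_threshold(sm, top_fraction)
        members: set[int] = set()
        for h in hubs:
            members.add(int(h))
            members.update(np.nonzero(retained.adjacency[:, h])[0].tolist())
        members_arr = np.fromiter(members, dtype=int)
        outside = np.setdiff1d(np.arange(sm.n_nodes), members_arr)
        # sample pairs for the synchrony comparison
        def sample_pairs(pool_a, pool_b, n):
            out = []
            for _ in range(n):
                a = int(pool_a[rng.integers(pool_a.size)])
                b = int(pool_b[rng.integers(pool_b.size)])
                if a != b:
                    out.append((a, b))
            return out
        within_pairs = sample_pairs(members_arr, members_arr, n_pair_sample)
        across_pairs = (
            sample_pairs(members_arr, outside, n_pair_sample) if outside.size else []
        )
        within = [_peak_xc(x[:, a], x[:, b], max_lag) for a, b in within_pairs]
        across = [_peak_xc(x[:, a], x[:, b], max_lag) for a, b in across_pairs]
        if within and across:
            mw = mannwhitneyu(within, across, alternative="two-sided")
            pval = float(mw.pvalue)
        else:
            pval = np.nan
        # correlogram of group average vs population average
        xg = x[:, members_arr].mean(axis=1)
        lags = np.arange(-max_lag, max_lag + 1)
        cg = np.array(
            [
                _corr_at_lag(xg, xall, int(l))
                for l in lags
            ]
        )
        fit_ok = True
        try:
            p0 = (float(cg.max()), float(lags[int(np.argmax(cg))]), max_lag / 4.0)
            popt, _ = curve_fit(_gaussian, lags.astype(float), cg, p0=p0, maxfev=5000)
            amp, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        except RuntimeError:
            fit_ok = False
            amp, mu, sigma = np.nan, np.nan, np.nan
        report.results.append(
            HubRangeResult(
                hubs=hubs,
                within_sync=float(np.mean(within)) if within else np.nan,
                across_sync=float(np.mean(across)) if across else np.nan,
                mw_pvalue=pval,
                peak_lag=mu,
                amplitude=amp,
                sigma=sigma,
                fit_ok=fit_ok,
            )
        )
    return report


def _corr_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    T = a.size
    t0, t1 = max(0, lag), T + min(0, lag)
    aa, bb = a[t0:t1], b[t0 - lag:t1 - lag]
    sa, sb = aa.std(), bb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((aa - aa.mean()) * (bb - bb.mean())).mean() / (sa * sb))


def state_ranges(g: np.ndarray, n_ranges: int = 7) -> list[tuple[float, float]]:
    """Equal-width partition of the population-fluorescence span.

    The top range is closed above so every frame belongs to exactly one
    range.
    """
    lo, hi = float(g.min()), float(g.max())
    edges = np.linspace(lo, hi, n_ranges + 1)
    out = []
    for r in range(n_ranges):
        upper = float("inf") if r == n_ranges - 1 else edges[r + 1]
        out.append((edges[r], upper))
    return out


def state_range_analysis(
    rec: FluorescenceRecording,
    truth: DirectedNetwork | None,
    base_spec: EstimatorSpec = EstimatorSpec(),
    n_ranges: int = 7,
    equal_samples: bool = False,
    seed: int = 0,
) -> dict:
    """Reconstruction quality per population-fluorescence range.

    The distribution of the average fluorescence is split into
    ``n_ranges`` equal-width ranges; a separate score matrix (and, when a
    ground truth is given, ROC) is computed per range.  With
    ``equal_samples`` each range is subsampled (without replacement,
    seeded) to the smallest range's sample count, isolating genuine
    state dependence from sample-size effects.
    """
    g = population_average(rec)[1:]
    ranges = state_ranges(g, n_ranges)
    masks = [conditioning_mask(g, lo, hi) for lo, hi in ranges]
    counts = np.array([int(m.sum()) for m in masks])
    if equal_samples:
        n_min = counts.min()
        rng = derive_rng(seed, "equal-samples")
        sub_masks = []
        for m in masks:
            idx = np.nonzero(m)[0]
            keep = rng.choice(idx, size=n_min, replace=False)
            mm = np.zeros_like(m)
            mm[keep] = True
            sub_masks.append(mm)
        masks = sub_masks
    scores = []
    rocs = []
    for (lo, hi), m in zip(ranges, masks):
        spec = EstimatorSpec(
            method=base_spec.method,
            order=base_spec.order,
            same_bin=base_spec.same_bin,
            bins=base_spec.bins,
            cond_low=lo,
            cond_high=hi,
            xc_lags=base_spec.xc_lags,
            edge_sd=base_spec.edge_sd,
        )
        sm = _score_with_mask(rec, spec, m if equal_samples else None)
        scores.append(sm)
        if truth is not None:
            rocs.append(roc(sm, truth))
    return {
        "ranges": ranges,
        "counts": counts,
        "scores": scores,
        "rocs": rocs if truth is not None else None,
    }


def _score_with_mask(rec, spec, mask_override):
    if mask_override is None:
        return score_matrix(rec, spec)
    from .inference import differentiate as _diff, te_matrix

    # score with an explicitly subsampled conditioning mask
    x = _diff(rec)
    g = population_average(rec)[1:]
    base = conditioning_mask(g, spec.cond_low, spec.cond_high)
    return te_matrix(x, base & mask_override, spec)
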