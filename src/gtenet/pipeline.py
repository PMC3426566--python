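"""End-to-end pipelines: benchmark on simulated ground truth, and analysis
of real fluorescence recordings.

``pipeline_benchmark`` runs generate -> tune -> simulate -> fluorify
(-> scatter) -> reconstruct -> evaluate for one configuration; every stage
derives its random stream from the master seed plus a stable stage name,
so stages re-run in isolation reproduce the pipeline's results.

``pipeline_real`` starts from a fluorescence matrix (one column per ROI)
plus ROI positions, reconstructs the top-fraction functional network at
the automatically selected conditioning level, and reports its topology
against full and partial randomization baselines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as gio
from ._seeds import derive_seed
from .config import PipelineConfig
from .dynamics import SpikeRecord, SynapseParams, burst_rate, detect_bursts, simulate, tune_weight
from .errors import StructuralError, TuningError
from .evaluation import motif_audit, performance, ppc, roc, topology_report
from .fluorescence import FluorescenceRecording, synthesize
from .inference import (
    EstimatorSpec,
    population_average,
    rank_and_threshold,
    score_matrix,
    select_conditioning_level,
)
from .topology import (
    DirectedNetwork,
    full_clustering,
    generate_local,
    generate_nonlocal,
    randomize_full,
    randomize_partial,
)

__all__ = ["pipeline_benchmark", "pipeline_real", "trim_recording",
           "generate_network", "resolve_conditioning", "build_spec"]

log = logging.getLogger("gtenet")


def _stage(name, t0, **info):
    log.info("stage=%s wall=%.1fs %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def generate_network(cfg: PipelineConfig) -> DirectedNetwork:
    """Draw the ground-truth network the configuration describes."""
    t = cfg.topology
    seed = derive_seed(cfg.seed, "topology")
    if t.ensemble == "nonlocal":
        return generate_nonlocal(t.n_neurons, t.p, t.target_cc, seed, t.area_side)
    if t.ensemble == "local":
        return generate_local(t.n_neurons, t.p, t.lambda_mm, t.area_side, seed)
    raise ValueError(f"unknown ensemble {t.ensemble!r}")


def resolve_conditioning(rec: FluorescenceRecording, cfg: PipelineConfig) -> float:
    """Upper conditioning level according to the configured mode."""
    mode = cfg.estimator.cond_mode
    if mode == "none":
        return float("inf")
    if mode == "fixed":
        if cfg.estimator.cond_level is None:
            raise ValueError("cond_mode='fixed' needs cond_level")
        return float(cfg.estimator.cond_level)
    if mode == "gauss2sd":
        return select_conditioning_level(rec)
    if mode == "range2":
        g = population_average(rec)
        lo, hi = float(g.min()), float(g.max())
        return lo + 2.0 * (hi - lo) / cfg.evaluation.n_ranges
    raise ValueError(f"unknown cond_mode {mode!r}")


def build_spec(cfg: PipelineConfig, method: str, cond_high: float) -> EstimatorSpec:
    e = cfg.estimator
    return EstimatorSpec(
        method=method,
        order=e.order,
        same_bin=e.same_bin,
        bins=e.bins,
        cond_high=cond_high,
        xc_lags=e.xc_lags,
    )


def pipeline_benchmark(cfg: PipelineConfig) -> dict:
    """Full surrogate-data benchmark for one configuration.

    Returns a result bundle with the ground-truth network, tuned weight,
    spike record, fluorescence recording, per-method score matrices,
    reconstructions and evaluation summaries.  If ``cfg.outdir`` is set,
    every artifact is written there together with the serialized config.
    """
    t0 = time.time()
    out = Path(cfg.outdir) if cfg.outdir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    net = generate_network(cfg)
    _stage("generate", t0, links=net.n_links, cc=f"{full_clustering(net).mean():.3f}")

    if cfg.dynamics.tune:
        try:
            g_int = tune_weight(
                net,
                cfg.neuron,
                cfg.synapse,
                cfg.drive,
                target_rate=cfg.dynamics.target_burst_rate,
                tol=cfg.dynamics.tune_tol,
                probe_duration=cfg.dynamics.probe_duration,
                seed=derive_seed(cfg.seed, "tuning"),
            )
        except TuningError as err:
            log.warning("tuning did not converge (%s); using best probe", err)
            g_int = float(err.best)
    else:
        g_int = cfg.synapse.g_int
    syn = replace(cfg.synapse, g_int=g_int)
    _stage("tune", t0, g_int=f"{g_int:.3f}")

    spikes = simulate(
        net, cfg.neuron, syn, cfg.drive,
        duration=cfg.dynamics.duration,
        seed=derive_seed(cfg.seed, "simulate"),
    )
    bursts = detect_bursts(spikes)
    _stage("simulate", t0, spikes=spikes.n_spikes, bursts=bursts.n_bursts)

    rec = synthesize(
        spikes,
        cfg.calcium,
        cfg.scatter if cfg.apply_scatter else None,
        positions=net.positions,
        seed=derive_seed(cfg.seed, "fluorescence"),
    )
    _stage("fluorify", t0, frames=rec.n_frames)

    cond = resolve_conditioning(rec, cfg)
    results = {
        "config": cfg,
        "network": net,
        "g_int": g_int,
        "spikes": spikes,
        "bursts": bursts,
        "recording": rec,
        "cond_level": cond,
        "scores": {},
        "reconstructions": {},
        "rocs": {},
        "performance": {},
        "ppc": {},
        "motifs": {},
    }
    n_keep_frac = cfg.estimator.top_fraction
    for method in cfg.estimator.methods:
        spec = build_spec(cfg, method, cond)
        sm = score_matrix(rec, spec)
        recon = rank_and_threshold(sm, n_keep_frac, positions=net.positions)
        r = roc(sm, net)
        results["scores"][method] = sm
        results["reconstructions"][method] = recon
        results["rocs"][method] = r
        results["performance"][method] = performance(r, cfg.evaluation.fp_level)
        results["ppc"][method] = ppc(sm, net)
        results["motifs"][method] = motif_audit(recon, net)
        _stage(
            f"reconstruct[{method}]", t0,
            n_samples=sm.n_samples,
            tp_at_10fp=f"{results['performance'][method]:.3f}",
        )
        if out is not None:
            gio.write_scores(out / f"scores_{method}.tsv", sm)
            gio.write_adjacency(out / f"recon_{method}.tsv", recon)
    if out is not None:
        gio.write_adjacency(out / "truth.tsv", net)
        gio.write_positions(out / "positions.tsv", net)
        gio.write_spikes(out / "spikes.tsv", spikes)
        gio.write_fluorescence_h5(out / "fluorescence.h5", rec)
        summary = {
            "g_int": g_int,
            "n_bursts": int(bursts.n_bursts),
            "cond_level": cond,
            "performance": results["performance"],
            "motifs": {m: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                           for k, v in d.items()}
                       for m, d in results["motifs"].items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return results


def pipeline_real(
    rec: FluorescenceRecording,
    cfg: PipelineConfig | None = None,
    top_fraction: float = 0.05,
) -> dict:
    """Reconstruction of a real (or externally supplied) recording.

    Uses the automatic conditioning level (two sd above the left-peak
    Gaussian mean), retains the top ``top_fraction`` of TE-ranked links
    (default 5%, matching the denser biological cultures), and compares
    the reconstructed topology to full and partial randomizations.
    """
    cfg = cfg or PipelineConfig()
    if not np.all(np.isfinite(rec.data)):
        raise StructuralError("recording contains non-finite values")
    cond = select_conditioning_level(rec)
    spec = build_spec(cfg, cfg.estimator.methods[0], cond)
    sm = score_matrix(rec, spec)
    recon = rank_and_threshold(sm, top_fraction, positions=rec.positions)
    draws = cfg.evaluation.n_random_draws
    rand_full = [
        randomize_full(recon, derive_seed(cfg.seed, f"rand-full-{k}"))
        for k in range(draws)
    ]
    rand_part = [
        randomize_partial(recon, derive_seed(cfg.seed, f"rand-part-{k}"))
        for k in range(draws)
    ]
    report_full = topology_report(recon, rand_full)
    report_partial = topology_report(recon, rand_part)
    return {
        "cond_level": cond,
        "scores": sm,
        "reconstruction": recon,
        "randomized_full": rand_full,
        "randomized_partial": rand_part,
        "report_full": report_full,
        "report_partial": report_partial,
    }


def trim_recording(rec: FluorescenceRecording, divisor: int) -> FluorescenceRecording:
    """Keep the first 1/divisor of the frames (data-length sweeps)."""
    if divisor < 1 or int(divisor) != divisor:
        raise ValueError("divisor must be a positive integer")
    if divisor == 1:
        return rec
    n = rec.n_frames // int(divisor)
    return FluorescenceRecording(
        rec.data[:n].copy(),
        rec.frame_interval,
        positions=rec.positions,
        provenance={**rec.provenance, "trim_divisor": int(divisor)},
    )
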