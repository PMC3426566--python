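"""Reconstruction quality depends on the network's dynamical state.

Splits the population-fluorescence distribution into seven equal-width
ranges and reconstructs from each range separately.  Quiet and
burst-build-up ranges (low fluorescence) carry monosynaptic structure;
fully developed bursts (top ranges) reconstruct at chance because
collective synchrony swamps pairwise causation.
"""

from gtenet import (
    PipelineConfig,
    SynapseParams,
    generate_local,
    simulate,
    state_range_analysis,
    synthesize,
    tune_weight,
)

net = generate_local(N=80, p=0.12, lambda_mm=0.35, seed=2)
g = tune_weight(net, seed=5)
spikes = simulate(net, syn=SynapseParams(g_int=g), duration=1500.0, seed=6)
rec = synthesize(spikes, positions=net.positions, seed=7)

res = state_range_analysis(rec, net, n_ranges=7)
ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII"]
print("range  frames   TP@10%FP   (I = quiet/noise ... VII = burst peaks)")
for roman, n, r in zip(ROMAN, res["counts"], res["rocs"]):
    print(f"  {roman:>4} {n:8d}   {r.tp_at_10fp:.3f}")
print("expected pattern: low ranges well above 0.10, top ranges near 0.10")
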