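"""Simulate culture dynamics and auto-tune the synaptic weight.

Tunes the recurrent weight so the network bursts at 0.1 Hz (about 6
bursts per simulated minute of the probe), then simulates 10 minutes and
reports the burst statistics.  Expect a tuned weight near 5.3 pA for
this ensemble and roughly one burst every ten seconds.
"""

from gtenet import SynapseParams, detect_bursts, generate_nonlocal, simulate, tune_weight

net = generate_nonlocal(N=100, p=0.12, target_cc=0.5, seed=1)
g = tune_weight(net, target_rate=0.1, seed=7)
print(f"tuned recurrent weight: {g:.2f} pA")

spikes = simulate(net, syn=SynapseParams(g_int=g), duration=600.0, seed=42)
bursts = detect_bursts(spikes)  # >40% of neurons within 50 ms
print(f"10 min run: {spikes.n_spikes} spikes "
      f"({spikes.mean_rate():.2f} Hz/neuron), {bursts.n_bursts} bursts "
      f"({bursts.n_bursts / 600:.3f} Hz)")
print("peak participating fraction per burst:",
      ", ".join(f"{f:.2f}" for f in bursts.fractions[:8]), "...")
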