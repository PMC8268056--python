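"""Monte-Carlo recovery of the planted candidate under noise.

Repeats generate-study -> run-funnel over seeded replicates at two noise
levels and reports sensitivity (fraction of replicates recovering the
planted should-pass gene) and the false-positive rate (fraction of the
other proteases surviving the full funnel).
"""

from protfunnel import SimulationConfig, recovery_experiment

for sigma in (0.0, 0.5):
    sim = SimulationConfig(seed=1, noise_sigma=sigma)
    sens, fpr = recovery_experiment(sim, n_replicates=20)
    print(
        f"noise sigma {sigma:.1f} (log2 units): "
        f"sensitivity {sens:.2f}, false-positive rate {fpr:.4f}"
    )
# Sensitivity 1.0 at sigma 0 is the noiseless oracle guarantee; moderate
# multiplicative noise should leave recovery near-perfect.
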