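"""Cross-sectional two-device agreement: Bland-Altman + agreement index.

Simulates same-day paired thickness measurements of 500 eyes on two
scanners with a known inter-device bias per layer, then prints the
agreement table: mean difference with 95% CI, limits of agreement (the
band expected to contain 95% of individual-eye differences), and the mean
interscanner agreement index (1 = identical readings).
"""

from octlayers import bland_altman_table, simulate_paired_eyes

pairs = simulate_paired_eyes(n_eyes=500, seed=7)
table = bland_altman_table(pairs)

cols = ["layer", "mean_diff", "mean_diff_ci_low", "mean_diff_ci_high",
        "lower_loa", "upper_loa", "agreement_index_mean"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{v:7.3f}"))
print("\nA mean difference near the simulated device bias with LOA ~ "
      "bias +/- 1.96 SD shows the estimator recovers the generative "
      "parameters; indices near 1 indicate the devices agree to within "
      "a few percent of the layer thickness.")
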