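"""Longitudinal analysis: repeated-measures agreement and atrophy rates.

Simulates a two-visit cohort measured on both devices, compares the
between-visit changes across devices with the repeated-measures
Bland-Altman (two eyes per subject are not independent), and fits the
mixed-effects annual rate of GCIP change per device.
"""

from octlayers import (
    fit_rate_of_change,
    modified_bland_altman,
    simulate_longitudinal_cohort,
)

df = simulate_longitudinal_cohort(
    n_subjects=150, visit_years=(0.0, 1.4),
    devices=("cirrus", "spectralis"), layers=("GCIP",), seed=11,
)

# per-eye change between visits, per device
wide = df.pivot_table(index=["subject", "eye", "device"], columns="years",
                      values="GCIP").reset_index()
wide["change"] = wide[1.4] - wide[0.0]
ch = wide.pivot(index=["subject", "eye"], columns="device",
                values="change").reset_index()

ba = modified_bland_altman(ch["cirrus"], ch["spectralis"], ch["subject"])
print(f"mean difference of changes (spectralis - cirrus): "
      f"{ba.mean_diff:+.3f} um  (95% CI {ba.ci_mean[0]:+.3f} to "
      f"{ba.ci_mean[1]:+.3f})")
print(f"limits of agreement: {ba.loa_lower:+.2f} to {ba.loa_upper:+.2f} um "
      f"({ba.n_subjects} subjects, {ba.n} eyes)")
print("  -> a near-zero mean difference means the devices agree on the "
      "cohort's change; wide LOA warn against swapping devices for one "
      "patient.\n")

for device in ("cirrus", "spectralis"):
    r = fit_rate_of_change(df, device, "GCIP")
    print(f"GCIP rate of change on {device:10s}: {r.slope:+.3f} um/yr "
          f"(95% CI {r.ci[0]:+.3f}, {r.ci[1]:+.3f}; p = {r.p_value:.2g})")
print("  -> both fits should recover the simulated -0.59 um/yr atrophy "
      "within their confidence intervals.")
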