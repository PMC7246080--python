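"""Leave-one-patient-out cross-validation of the five architectures.

Simulates a training cohort, then for each architecture fits SI and AP
models on all-but-one patient (single best-correlated feature) and
predicts the held-out patient's shifts.  Prints the pooled mean absolute
residual per architecture.
"""

import ctvshift as cs

params = cs.GeneratorParams()
cohort = cs.simulate_cohort(params, n_patients=6, n_fractions_per_patient=15, seed=3)
features = cs.extract_cohort_features(cohort, params.click_noise_sd, seed=4,
                                      cop_click_noise_sd=params.cop_click_noise_sd)

print("pooled leave-one-patient-out residuals, one feature:")
for arch in cs.ARCHITECTURES:
    table = cs.run_lcv(features, arch, n_features=1, seed=0)
    s = cs.residual_summary(table)["pooled"]
    print(f"  {arch:8s} {s['mean']:.2f} +/- {s['sd']:.2f} mm (max {s['max']:.2f})")
print("\nResiduals are |reference - predicted| per direction, pooled over SI")
print("and AP; similar values across architectures mean the single wall")
print("feature carries most of the predictable signal.")
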