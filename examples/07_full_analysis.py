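"""The complete comparison design on a phantom, in one call.

Generates the dataset, calibrates alpha per correction variant, computes
maps, builds masks, and quantifies — via Bland-Altman against the
measured-field reference — what omitting the correction or substituting an
imperfect data-driven field costs in bias and error.
"""

from gratiomap.pipeline import AnalysisConfig, run_full_analysis

report = run_full_analysis(AnalysisConfig(seed=0))

print("per-variant calibration:")
print(report.calibration.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print(f"\nchosen SNR threshold: {report.threshold_search.chosen_threshold:.0f}")
print(f"high-SNR ROIs: {report.high_snr_ids}")

bm = report.between_method.query("roi_set == 'high_snr'")
print("\nagainst the measured-B1 reference (high-SNR ROI set):")
print(bm[["metric", "variant", "bias", "error", "relative_bias_pct",
          "relative_error_pct"]].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\ntest-retest of the reference variant:")
print(report.retest[["metric", "relative_bias_pct", "relative_error_pct"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nThe imperfect data-driven correction cuts both relative bias and error")
print("well below the uncorrected variant — the qualitative effect the full")
print("design exists to demonstrate; exact magnitudes depend on the field shape.")
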