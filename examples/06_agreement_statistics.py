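"""Bland-Altman agreement with dynamic-range normalization.

Recomputes the published summary arithmetic from the embedded 21-ROI
reference table: dynamic ranges, and the relative bias/error obtained by
dividing the published absolute Bland-Altman values by the dynamic range.
"""

from gratiomap import bland_altman, dynamic_range
from gratiomap import reference_tables as ref

print("metric  dynamic range (max - min of 21 ROI group means)")
for metric in ("g", "avf", "mvf"):
    print(f"{metric:>6}  {dynamic_range(ref.HIGH_SNR_ROI_TABLE[metric]):.3f}")
print(f"\nmean g across the 21 high-SNR ROIs: {ref.HIGH_SNR_ROI_TABLE['g'].mean():.3f}")

print("\nno-correction vs. reference, relative to the dynamic range:")
for (metric, variant), row in ref.BETWEEN_METHOD.iterrows():
    if variant != "none":
        continue
    dr = dynamic_range(ref.HIGH_SNR_ROI_TABLE[metric])
    print(f"  {metric:>3}: bias {100 * row['bias'] / dr:+7.2f}%   "
          f"error {100 * row['error'] / dr:6.2f}%")

# the machinery itself, on a toy pair of ROI-mean vectors
res = bland_altman([0.65, 0.66, 0.68], [0.66, 0.66, 0.67], dr=0.046)
print(f"\ntoy example: bias {res.bias:+.4f}, error {res.error:.4f}, "
      f"relative bias {res.relative_bias_pct:+.1f}% of dynamic range")
print("\nOmitting the correction costs ~89% of the g dynamic range in bias —")
print("larger than any plausible between-group effect in that metric.")
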