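"""Full pipeline on a static digital vial phantom.

A 10-vial T1/T1rho phantom is acquired with the variable-density Cartesian
trajectory (2x undersampling, 8 coils, complex Gaussian noise), then
reconstructed with iterative SENSE, water-fat separated, denoised,
polarity-restored and dictionary-matched. Recovered per-vial medians are
compared against the ground truth.
"""

from cardiomap.pipeline import vial_study

res = vial_study(seed=0)
print(f"image-domain SNR of the acquisition: {res.snr:.1f}")
print("per-vial recovery (median over a centred ROI):")
print(f"  {'true T1':>8} {'est T1':>8}   {'true T1rho':>10} {'est T1rho':>9}")
for _, r in res.per_vial.iterrows():
    print(f"  {r.t1_true:8.0f} {r.t1_est:8.1f}   {r.t1rho_true:10.0f} "
          f"{r.t1rho_est:9.1f}")
print(
    f"regression of recovered vs true values (vials with T1<=1300 ms, "
    f"T1rho<=150 ms):\n  slope {res.slope:.3f}, intercept "
    f"{res.intercept:.1f} ms, r^2 {res.r_squared:.4f}"
)
print("(slope near 1 and r^2 near 1: the pipeline recovers the phantom's "
      "relaxation times)")
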