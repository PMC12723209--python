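# cardiomap

Free-breathing 3D joint T1/T1ρ mapping for low-field cardiac MR, rebuilt as
a fully synthetic, desk-scale Python pipeline.

Quantifying myocardial T1 and T1ρ in one free-breathing scan promises
contrast-agent-free tissue characterisation (fibrosis, oedema, fat
infiltration) on emerging 0.55 T scanners, where lower SNR and weaker fat
suppression make the reconstruction chain as important as the sequence.
`cardiomap` implements that chain end to end for researchers who want to
study, stress or extend it without scanner data: every input is generated
by the package's own digital phantoms with known ground truth.

## What is implemented

* **Sequence simulation** — 1D longitudinal Bloch simulation of the
  interleaved 4-heartbeat block (IR prep TI = 245 ms / none / none /
  spin-lock TSL = 40 ms), with iNAV and imaging pulse trains, run to a
  fixed-point steady state.
* **Dictionary mapping** — subject-specific (T1, T1ρ) dictionary
  (291 × 122 = 35 502 atoms), Ps-IP-based polarity restoration, and
  maximum-inner-product matching; for unit-norm signals this minimises
  SSD = 2 − 2⟨s, d⟩.
* **Monte-Carlo precision analysis** — per-tissue noise trials with
  Bias(Y) = μ_Y − Y and CV(Y) = σ_Y/μ_Y over tissue grids and heart rates.
* **Acquisition & reconstruction** — variable-density Cartesian sampling
  with golden-angle spiral profile order, iNAV translation estimation,
  5-bin respiratory binning with intra-bin phase-ramp correction, and
  motion-corrected iterative SENSE solving
  `min_x ||Σ_b A_b(c) F S U_b x − k(c)||²` by conjugate gradients.
* **Water–fat separation & denoising** — two-point pseudo-in-phase /
  out-of-phase Dixon with exact fat phasors at TE = 2.60/6.50 ms
  (Δf ≈ 79.6 Hz at 0.55 T), and multi-contrast patch-tensor low-rank
  denoising (5³ patches, 20 similar patches, mode-wise singular-value
  truncation at λ = 0.07).
* **Reference fits & agreement** — IR-SE and T1ρ-SE reference fitting,
  per-vial ROI statistics, linear regression and Bland–Altman analysis
  with the T1 ≤ 1300 ms / T1ρ ≤ 150 ms myocardial-range filter.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

## Worked example

`examples/03_vial_phantom_pipeline.py` pushes a 10-vial digital phantom
through acquisition (2× undersampled, 8 coils, complex Gaussian noise),
iterative SENSE, Dixon separation, denoising, polarity restoration and
dictionary matching:

```
image-domain SNR of the acquisition: 33.6
per-vial recovery (median over a centred ROI):
   true T1   est T1   true T1rho est T1rho
       300    305.0           25      26.0
       450    440.0           35      34.0
       600    595.0           45      45.0
       750    745.0           55      55.0
       900    895.0           65      65.0
      1050   1050.0           75      75.0
      1200   1195.0           90      92.0
      1300   1295.0          110     112.0
      1600   1600.0          180     180.0
      2200   2200.0          280     300.0
regression of recovered vs true values (vials with T1<=1300 ms, T1rho<=150 ms):
  slope 0.995, intercept 0.4 ms, r^2 1.0000
```

Each row compares a vial's true relaxation times (ms) with the median of
the matched map inside a centred ROI: recovery is within a few percent and
grid resolution across the myocardial range, and the pooled regression of
recovered against true values is near the identity line. Off-range vials
(bottom two rows) are excluded from the regression by the myocardial-range
filter, mirroring how phantom agreement is analysed.

`examples/02_monte_carlo_precision.py` prints the precision story behind
the sequence — at (T1, T1ρ) = (700, 56) ms the CV grows from
4.8 %/11.0 % at HR 60 to 8.3 %/17.6 % at HR 120 (noise SD = M0/350 per
volume) — and `examples/04_motion_correction.py` shows motion-corrected
reconstruction cutting the T1 map NRMSE on a breathing cardiac phantom
from 2.17 to 0.78.

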