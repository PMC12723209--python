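# Methods

`cardiomap` implements a fully synthetic, desk-scale version of a
free-breathing 3D joint T1/T1ρ mapping framework for low-field (0.55 T)
cardiac MR: an interleaved 4-heartbeat acquisition with Dixon readout,
respiratory-motion-corrected iterative SENSE reconstruction, two-point
water–fat separation, multi-contrast patch-tensor denoising, and
Bloch-dictionary parameter mapping, validated end to end on digital
phantoms with known ground truth.

## Signal model and Bloch simulation

The sequence repeats a 4-heartbeat block: inversion recovery (TI = 245 ms)
on beat 1, no preparation on beats 2–3, spin-lock preparation
(TSL = 40 ms, SLA = 150 Hz) on beat 4. Each beat acquires one segment of a
3D RF-spoiled two-echo GRE volume (FA 8°, TR 9.71 ms, 16 segments per
beat, 155 ms acquisition window) preceded by a 14-pulse 2D image-navigator
train at FA 3°.

Because RF and gradient spoiling destroy transverse coherence, only Mz is
propagated: each pulse scales Mz by cos(FA), gaps relax mono-exponentially
toward M0 with time constant T1, inversion is an instantaneous sign flip
scaled by an efficiency parameter (default 1.0), and the spin lock is an
ideal exp(−TSL/T1ρ) attenuation of Mz occupying TSL of the timeline. B0/B1
effects on the preparation are out of scope. The SLA value is carried as
metadata only — with an ideal lock it does not enter the signal equation.

Timeline choices the protocol leaves open, fixed here once:

* TI is measured from the inversion pulse to the **first imaging pulse**
  (the k-space centre under centric reordering), with the iNAV train placed
  inside the TI interval immediately before imaging.
* The iNAV TR equals the imaging TR (unstated in the protocol); iNAV
  echoes do not affect Mz, only the 14 RF pulses do.
* The same prep-end→imaging layout is used on every beat, so the
  inversion-to-centre timing holds on the IR beat and the spin-lock beat's
  readout simply starts TSL later in the cycle.
* The trigger delay defaults to 0; only the RR interval and acquisition
  window influence the steady state, matching how subject HR and window
  are the simulation inputs.

The recorded per-volume signal is Mz just before the first imaging pulse
times sin(FA). Blocks repeat until the block-start Mz changes by less than
1e−6·M0 (cap 100 blocks, flagged if hit) — a deterministic, HR-independent
steady-state criterion. Consequently any two simulations of the same tissue
agree to ~1e−6·M0, which is the tolerance used whenever a test compares
independently converged runs. T2 decay at the echo times is ignored in the
dictionary signal; the dictionary is (T1, T1ρ) only.

One degeneracy worth noting: with TSL = 0 the spin-lock prep is an exact
identity, but volumes 2–4 do **not** coincide in steady state, because the
inversion on beat 1 leaves a residual that decays across the block. Only a
block with no preparations at all makes the four volumes identical.

## Dictionary and matching

The dictionary grid is T1 = [50:5:1400, 1400:50:1800, 1800:100:3000] ms ×
T1ρ = [5:5:20, 20:1:80, 80:4:300, 300:100:600] ms (shared endpoints
de-duplicated: 291 × 122 = 35 502 atoms), simulated at the subject's HR and
acquisition window in a single vectorised run and L2-normalised per atom.
Matching L2-normalises each voxel's signed 4-point signal and takes the
maximum inner product, equivalent to minimising SSD = 2 − 2⟨s, d⟩ for
unit-norm vectors; SSD is reported on the normalised signals. Ties resolve
to the smallest T1, then smallest T1ρ (atoms are stored in lexicographic
order and argmax returns the first maximum). Matching runs in voxel chunks
(default 1024 × 35 502 inner products) to bound memory.

Polarity restoration estimates the background phase by Gaussian low-pass
filtering the complex pseudo-in-phase echo (filtering the phasor rather
than the wrapped phase makes the estimate magnitude-weighted and
wrap-free; σ default 8 voxels, configurable) and re-signs the water
magnitude by sign(cos(residual phase)). The phase reference is
configurable: by default each volume uses its own Ps-IP echo, but the
pipeline uses a non-inverted contrast (volume 2) as the shared reference —
when an inverted region is larger than the filter kernel, the
same-contrast estimate is dominated by the locally inverted phase and
mis-signs it, whereas the background (coil/field) phase is common to all
four volumes.

## Monte-Carlo precision study

For each tissue on the study grid (defaults: T1 = [500:50:1400] ms ×
T1ρ = [40:4:80] ms, HR ∈ {60, 80, 100, 120} bpm, 10 000 trials) white
Gaussian noise of fixed SD per volume is added to the signed signal, the
noisy fingerprint is matched, and bias = mean − truth and CV = sample
SD/mean are reported. The published noise level is typeset as "1350M0",
read here as a lost fraction bar, SD = M0/350; the value is a config
parameter and every result row records it. Polarity is taken as known (no
phase images exist in this 1D study), and noise precedes normalisation.
The sample SD (n−1) convention is used for every SD/CV in the package.
The HR-sweep plots can fix T1 at either 700 ms or 1100 ms (both appear in
the source material); both are plain configuration values.

The acceptance script reduces the grid study to 2 000 trials per tissue
(209 tissues) to stay desk-scale; the HR sweep keeps 10 000 trials.

## Sampling, motion and reconstruction

**Trajectory.** Phase-encode points on the ky–kz plane follow spiral-like
arms (one per heartbeat, 16 points each) rotated by the golden angle
between heartbeats, with a power-law radius schedule (exponent 1.5,
half-turn twist) giving variable density; points snap to the Cartesian
grid, and collisions within a contrast move to the nearest free cell, so
the per-contrast sampled fraction is exactly n_points/grid. Arms are
re-sorted centre-out (centric). The published generator's density
constants are not public; the exponent and twist are documented generator
parameters. The readout axis is fully sampled and handled by the 3D FFT.

**Motion.** iNAV translations are estimated by normalised
cross-correlation template matching (template = central half of the
reference iNAV) with separable quadratic sub-pixel refinement.
Heartbeats are assigned to B = 5 equal-count bins by FH displacement
(partition rule unstated in the source; equal-count is the deterministic
choice), the reference bin is end-expiration (most superior median FH),
and intra-bin correction applies the linear k-space phase ramp moving each
heartbeat to its bin median (FH→z, RL→y; the unencoded readout axis
carries no correction, as with any 2D iNAV scheme).

**Encoding operator.** E(c) = Σ_b A_b(c) F S U_b with U_b a trilinear
pull-back warp whose adjoint is the exact interpolation transpose (not the
inverse warp) so the operator pair passes randomised adjoint tests at
1e−6–1e−5. Binned masks are disjoint by construction (a cell sampled in
two bins is attributed to the first) and reassemble the full per-contrast
mask. Images solve min ‖E(c)x − k(c)‖² by CG on the normal equations, zero
initialisation, 3 iterations for the motion-corrected solve. Three
iterations is deliberately early stopping: with fractional-voxel warps the
trilinear model attenuates high frequencies and CG semi-converges —
accuracy improves for a few iterations and then degrades as the
ill-conditioned modes amplify model mismatch. Binned (single-bin)
reconstructions that feed registration use up to 15 iterations with a
1e−6 residual tolerance, since no warp enters that system.

**Nonrigid registration** is a pluggable contract: any engine mapping
(fixed, moving) → displacement works, and ground-truth fields can be
injected. The default is SimpleITK's fast-symmetric-forces demons with a
two-level pyramid and field smoothing (SD 1.5 voxels). A diverged field
(non-finite values) falls back to identity with a warning. The end-to-end
motion experiment injects the known simulation fields so it measures the
correction machinery, not registration quality, which is tested
separately on synthetic warps.

## Water–fat separation

Single-peak fat model at Δf = γ·B0·3.4 ppm ≈ 79.6 Hz (0.55 T) with exact
phasors at TE = 2.60/6.50 ms — the first echo is only *pseudo* in-phase
(fat phase ≈ 75°), so the classic 0/π two-point assumption is replaced by
the exact complex exponents. With real non-negative amplitudes, the two
echo magnitudes give a linear 2×2 system in (W²+F², WF) and hence two
amplitude candidates per voxel (water- or fat-dominant), each implying a
B0 phasor over the echo spacing. The global seed is the intensity-weighted
mode of all candidate field angles with a 2:1 vote preference for the
water-dominant candidate (tissue is predominantly water and the shimmed
field is near zero — this also resolves the inherent two-point ambiguity of
uniform single-species objects toward water); per voxel the candidate
closer to the Gaussian-smoothed neighbourhood field (σ 4 voxels, 3
iterations) is kept. The final water/fat images are the exact least-squares
solve after field demodulation; a known field map can be injected, making
the separation exact to machine precision on noiseless two-species data.
Limitations: a single spectral fat peak, no T2* decay, and field offsets
beyond ±1/(2ΔTE) ≈ ±128 Hz alias into the constant image phase.

## Patch-tensor denoising

For each reference patch (5³ voxels, stride 2) the 20 most similar patches
in a 20³ search window (similarity = squared distance summed over all
contrasts; evaluated for all centres at once per displacement via box
filtering of shifted-difference volumes, with periodic wrap at the volume
edge) form a 3rd-order tensor (patch voxels × similar patches ×
contrasts). Each mode unfolding has singular values below λ × (that mode's
leading singular value) set to zero, sequentially over the three modes,
and overlapping patch estimates are averaged with uniform weights. λ
defaults to 0.07. Retained singular values are kept **unshrunk**
(truncation rather than soft shrinkage): subtracting λσ₁ from the leading
value itself would bias every patch by λ and cap noiseless structure
preservation near 23 dB, which contradicts the structure-preservation
behaviour this stage must have; the published method's exact shrinkage
variant is not public, and truncation is the scale-invariant choice that
is exactly the identity at λ = 0. Water and fat stacks are denoised
separately. Thin volumes clip the patch edge to the axis length.

## Digital phantoms and the forward simulator

Three vial phantoms (9-vial, 10-vial T1/T1ρ, 8-vial water–fat with fat
fractions 0–100 %) and a simple cardiac phantom (blood pool, myocardial
ring, epicardial fat rim, body) are generated as disjoint labelled
regions, 2 mm isotropic. The physical phantoms' relaxometry is not
tabulated anywhere, so the vial values are representative defaults
spanning T1 50–3000 ms / T1ρ 5–300 ms, config-overridable; phantom
regression targets are therefore properties (slope, r², recovery error),
not numeric reproductions. M0 is modulated by a smooth through-slab
profile (slab excitation/vial end caps) — without it the extruded 2D
geometry has no foot-head structure and coronal-projection iNAV matching
is degenerate. A configurable number of empty end slices (z-margin) keeps
FH motion from wrapping around the thin slab.

The forward simulator composes, per heartbeat: Bloch contrast weighting
per tissue (fat as a second species with T1 = 260 ms and a T2-like
rotating-frame constant of 60 ms — a documented simplification — plus the
Dixon phasor at each TE), an optional smooth background phase, the
respiratory state (translations applied exactly in k-space by the Fourier
shift theorem; nonrigid deformation applied in image space per quantised
motion state, 5 states along the FH trace), smooth synthetic coil
sensitivities (sum-of-squares ≈ 1), orthonormal FFT, sampling at that
heartbeat's trajectory points, and complex white Gaussian noise. iNAVs are
coronal projections of the moved M0 volume at the 3° excitation weighting.
Ground truth (maps, contrast images, sensitivities, translations, per-bin
fields including the inter-bin translation offsets) is returned alongside.

What the generator does *not* emulate — and what passing tests therefore do
not show about scanner data: realistic anatomy and partial-volume mixing,
cardiac contraction, B0/B1 inhomogeneity (including spin-lock offset-angle
artefacts), multi-peak fat, eddy-current or bipolar-readout phase errors,
and coil-array noise correlation.

## Reference fits and agreement analysis

The IR spin-echo reference uses S(TI) = M0(1 − 2e^(−TI/T1) + e^(−TR/T1))
with TIs = [50:300:2150] ms, TR = 8 s, fitted by Levenberg–Marquardt
(tolerances 1e−10; init T1 = TI_min|S|/ln 2, M0 = max|S|; signed input by
default with a magnitude-fit flag, since the handling of short-TI polarity
in 2D SE references is a protocol detail the source leaves open). The
T1ρ-prepared SE reference S(TSL) = M0·e^(−TSL/T1ρ) is fitted log-linearly
(TSLs = [2:12:86] ms), excluding non-positive samples. ROI agreement uses
per-vial mean/SD/CV, linear regression and Bland–Altman bias ±1.96 SD,
after excluding vials with reference T1 > 1300 ms or T1ρ > 150 ms (the
myocardial analysis range).

## Study problem sizes

The packaged studies run at desk scale: vial study on a 64×64×8 matrix at
2× undersampling with 8 coils, noise SD 8e−4 (image SNR ≈ 35, inside the
SNR ≥ 30 regime of the recovery claim) and 15 CG
iterations; motion experiment on 48×48×16 at 2× with 8 mm FH / 2 mm RL
sinusoidal breathing, 1.5-voxel peak nonrigid deformation, 5 bins and 3 CG
iterations; Monte-Carlo grid study at 2 000 trials per tissue and the HR
sweep at 10 000. These sizes were chosen so every study is a single-CPU,
minutes-scale computation while keeping each effect (undersampling,
motion, noise) clearly above its measurement floor.
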