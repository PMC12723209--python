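"""Digital vial and cardiac phantoms and the forward acquisition simulator.

The phantoms carry voxelwise ground-truth (T1, T1rho, M0, fat fraction).
The acquisition simulator composes the sequence Bloch signals with the
encoding physics: per heartbeat, the contrast-weighted complex image
(water + chemically shifted fat at each echo time, under a smooth background
phase) is moved to that heartbeat's respiratory state, weighted by smooth
synthetic coil sensitivities, Fourier transformed and sampled at the
heartbeat's trajectory points, with complex white Gaussian noise added.
Coronal-projection iNAVs are rendered from the same motion state.

Vial relaxation values are representative defaults spanning the clinically
relevant range (the physical phantoms' compositions are not tabulated);
they are config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import bloch
from .params import CardiacTiming, ConfigurationError, SequenceParams
from .recon import KSpaceDataset, fft3, translational_phase_ramp
from .trajectory import CaspirTrajectory

GYROMAGNETIC_MHZ_PER_T = 42.577

# Representative vial values (T1 ms, T1rho ms) spanning the mapping range.
T1MES_LIKE_VIALS = [
    (250, 35), (400, 45), (550, 50), (700, 56), (850, 62),
    (1000, 70), (1200, 80), (1800, 120), (2400, 200),
]
INHOUSE_T1T1RHO_VIALS = [
    (300, 25), (450, 35), (600, 45), (750, 55), (900, 65),
    (1050, 75), (1200, 90), (1300, 110), (1600, 180), (2200, 280),
]
WATERFAT_FRACTIONS = [0.0, 0.10, 0.20, 0.30, 0.50, 0.70, 0.90, 1.00]

# Single-peak fat species: short T1; the rotating-frame decay of fat is
# approximated by its T2-like constant.
FAT_T1_MS = 260.0
FAT_T1RHO_MS = 60.0


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "inhouse_t1t1rho"  # t1mes_like | inhouse_t1t1rho | waterfat | cardiac
    matrix: tuple[int, int, int] = (64, 64, 12)
    spacing_mm: float = 2.0
    vial_diameter_mm: float = 28.0
    vials: list | None = None  # (t1_ms, t1rho_ms) or fat fractions, overrides
    z_margin: int = 0  # empty slices at each z end (headroom for FH motion)

    def __post_init__(self) -> None:
        if self.kind not in {"t1mes_like", "inhouse_t1t1rho", "waterfat", "cardiac"}:
            raise ConfigurationError(f"unknown phantom kind: {self.kind}")


@dataclass
class Phantom:
    """Ground-truth parameter volumes plus disjoint region masks."""

    t1_ms: np.ndarray
    t1rho_ms: np.ndarray
    m0: np.ndarray
    fat_fraction: np.ndarray
    labels: np.ndarray            # 0 = background, 1..n = regions
    region_params: pd.DataFrame   # one row per region
    spacing_mm: float = 2.0

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


def _disk_centres(n: int, nx: int, ny: int, radius_vox: float):
    """Vial centres on one or two rings that fit the FOV."""
    margin = radius_vox + 2
    ring_r = min(nx, ny) / 2.0 - margin
    if ring_r <= radius_vox:
        raise ConfigurationError("vials do not fit the field of view")
    centres = []
    if n <= 1:
        return [(nx / 2, ny / 2)]
    n_outer = n if n <= 8 else n - 1
    for i in range(n_outer):
        a = 2 * np.pi * i / n_outer
        centres.append((nx / 2 + ring_r * np.cos(a), ny / 2 + ring_r * np.sin(a)))
    if n > 8:
        centres.append((nx / 2, ny / 2))
    return centres


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Deterministic region masks and tissue-parameter volumes."""
    nx, ny, nz = spec.matrix
    t1 = np.zeros(spec.matrix)
    t1rho = np.zeros(spec.matrix)
    m0 = np.zeros(spec.matrix)
    ff = np.zeros(spec.matrix)
    labels = np.zeros(spec.matrix, dtype=int)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    rows = []
    if 2 * spec.z_margin >= nz:
        raise ConfigurationError("z_margin leaves no slices")
    z_span = slice(spec.z_margin, nz - spec.z_margin)

    def paint(mask2d, label, t1v, t1rv, m0v, ffv, z=z_span):
        region = np.zeros(spec.matrix, dtype=bool)
        region[:, :, z] = mask2d[:, :, None]
        region &= labels == 0
        labels[region] = label
        t1[region] = t1v
        t1rho[region] = t1rv
        m0[region] = m0v
        ff[region] = ffv
        rows.append(
            {"label": label, "t1_ms": t1v, "t1rho_ms": t1rv, "m0": m0v,
             "fat_fraction": ffv}
        )

    if spec.kind in {"t1mes_like", "inhouse_t1t1rho", "waterfat"}:
        if spec.kind == "t1mes_like":
            vials = spec.vials or T1MES_LIKE_VIALS
        elif spec.kind == "inhouse_t1t1rho":
            vials = spec.vials or INHOUSE_T1T1RHO_VIALS
        else:
            vials = spec.vials or WATERFAT_FRACTIONS
        radius_vox = spec.vial_diameter_mm / 2.0 / spec.spacing_mm
        centres = _disk_centres(len(vials), nx, ny, radius_vox)
        for i, (centre, vial) in enumerate(zip(centres, vials), start=1):
            disk = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= radius_vox**2
            if spec.kind == "waterfat":
                frac = float(vial)
                paint(disk, i, 900.0, 60.0, 1.0, frac)
            else:
                t1v, t1rv = vial
                paint(disk, i, float(t1v), float(t1rv), 1.0, 0.0)
    elif spec.kind == "cardiac":
        cx, cy = nx * 0.5, ny * 0.45
        r_epi = min(nx, ny) * 0.22
        r_endo = r_epi * 0.6
        rr = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        body = ((xx - nx / 2) / (nx * 0.45)) ** 2 + (
            (yy - ny / 2) / (ny * 0.45)
        ) ** 2 <= 1
        myo = (rr <= r_epi) & (rr > r_endo)
        blood = rr <= r_endo
        fat_rim = (rr <= r_epi * 1.25) & (rr > r_epi)
        paint(blood, 1, 1700.0, 150.0, 1.0, 0.0)
        paint(myo, 2, 700.0, 56.0, 1.0, 0.0)
        paint(fat_rim, 3, FAT_T1_MS, FAT_T1RHO_MS, 0.9, 1.0)
        paint(body, 4, 400.0, 40.0, 0.8, 0.0)  # paint() skips already-labelled voxels
    # smooth through-slab M0 modulation (slab excitation profile / vial end
    # caps): gives the coronal projections genuine foot-head structure
    z0, z1 = z_span.start or 0, z_span.stop if z_span.stop is not None else nz
    if z1 > z0:
        zp = (np.arange(nz) - z0 + 0.5) / (z1 - z0)
        profile = np.clip(0.7 + 0.3 * np.sin(np.pi * np.clip(zp, 0, 1)), 0, None)
        m0 = m0 * profile[None, None, :]
    return Phantom(
        t1_ms=t1,
        t1rho_ms=t1rho,
        m0=m0,
        fat_fraction=ff,
        labels=labels,
        region_params=pd.DataFrame(rows),
        spacing_mm=spec.spacing_mm,
    )


@dataclass(frozen=True)
class MotionSpec:
    """Respiratory trace: sinusoidal (FH, RL) translation per heartbeat,
    optionally with a smooth nonrigid deformation scaled by the FH state."""

    fh_amplitude_mm: float = 8.0
    rl_amplitude_mm: float = 2.0
    period_s: float = 4.0
    nonrigid_scale: float = 0.0  # voxels of peak deformation per unit FH state

    def trace(self, timing: CardiacTiming, n_heartbeats: int) -> np.ndarray:
        """Per-heartbeat (FH, RL) displacement in mm (0 = end-expiration)."""
        t = np.cumsum([timing.rr(h) for h in range(n_heartbeats)])
        phase = 0.5 * (1 - np.cos(2 * np.pi * t / self.period_s))  # 0..1
        fh = -self.fh_amplitude_mm * phase  # inspiration moves toward feet
        rl = self.rl_amplitude_mm * np.sin(2 * np.pi * t / self.period_s)
        return np.column_stack([fh, rl])

    def base_deformation(self, vol_shape, seed: int = 0) -> np.ndarray:
        """Smooth random displacement field with unit peak magnitude."""
        rng = np.random.default_rng(seed)
        d = rng.normal(size=(3,) + tuple(vol_shape))
        for i in range(3):
            d[i] = gaussian_filter(d[i], sigma=[s / 4 for s in vol_shape])
        peak = np.abs(d).max()
        return d / peak if peak > 0 else d


def make_coil_sensitivities(
    vol_shape: tuple[int, int, int], n_coils: int, seed: int = 0
) -> np.ndarray:
    """Smooth complex coil profiles around the volume, sum-of-squares ~ 1."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = vol_shape
    grids = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    sens = np.zeros((n_coils,) + vol_shape, dtype=complex)
    for c in range(n_coils):
        a = 2 * np.pi * c / n_coils
        centre = np.array([1.3 * np.cos(a), 1.3 * np.sin(a), 0.0])
        r2 = sum((g - cc) ** 2 for g, cc in zip(grids, centre))
        width = 1.2 + 0.2 * rng.uniform()
        phase = (
            rng.uniform(-np.pi, np.pi)
            + 0.5 * grids[0] * rng.normal()
            + 0.5 * grids[1] * rng.normal()
        )
        sens[c] = np.exp(-r2 / width**2) * np.exp(1j * phase)
    sos = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
    return sens / np.where(sos > 0, sos, 1.0)


def contrast_images(
    phantom: Phantom,
    seq: SequenceParams,
    timing: CardiacTiming,
    field_strength_t: float = 0.55,
    fat_shift_ppm: float = 3.4,
    background_phase: np.ndarray | None = None,
) -> np.ndarray:
    """Noise- and motion-free complex images [4, n_echoes, nx, ny, nz].

    Water and fat compartments get their own Bloch signal; fat additionally
    carries the chemical-shift phasor exp(i 2 pi df TE) at each echo.
    """
    df_hz = GYROMAGNETIC_MHZ_PER_T * 1e6 * field_strength_t * fat_shift_ppm * 1e-6
    shape = phantom.t1_ms.shape
    out = np.zeros((4, 2) + shape, dtype=complex)
    regions = phantom.region_params
    water_sig = {}
    fat_sig = None
    for _, row in regions.iterrows():
        tissue = np.array([row.t1_ms / 1000.0]), np.array([row.t1rho_ms / 1000.0])
        s, _, _ = bloch.simulate_signals_grid(seq, timing, *tissue)
        water_sig[row.label] = s[0]
    fat_s, _, _ = bloch.simulate_signals_grid(
        seq, timing, np.array([FAT_T1_MS / 1000.0]), np.array([FAT_T1RHO_MS / 1000.0])
    )
    fat_sig = fat_s[0]
    if background_phase is None:
        background_phase = np.zeros(shape)
    phasor = np.exp(1j * background_phase)
    for _, row in regions.iterrows():
        mask = phantom.labels == row.label
        for e, te in enumerate((seq.te1, seq.te2)):
            fat_phasor = np.exp(2j * np.pi * df_hz * te)
            for v in range(4):
                w = (1 - row.fat_fraction) * row.m0 * water_sig[row.label][v]
                f = row.fat_fraction * row.m0 * fat_sig[v] * fat_phasor
                out[v, e][mask] = w + f
    return out * phasor[None, None]


def render_inavs(
    phantom: Phantom,
    translations_mm: np.ndarray,
    seq: SequenceParams,
) -> np.ndarray:
    """Coronal-projection iNAV per heartbeat at the iNAV excitation weighting.

    The projection integrates |M0 sin(FA_inav)| along the readout axis x of
    the moved phantom; axes are (FH, RL) = volume axes (z, y). Translation in
    (y, z) commutes with projection along x, so the static projection is
    Fourier-shifted per heartbeat.
    """
    from scipy.ndimage import fourier_shift

    base = (phantom.m0 * np.sin(np.radians(seq.fa_inav))).sum(axis=0)  # (y, z)
    base = base.T  # (z=FH, y=RL)
    out = np.zeros((len(translations_mm),) + base.shape)
    for i, (fh, rl) in enumerate(translations_mm):
        shift_vox = (fh / phantom.spacing_mm, rl / phantom.spacing_mm)
        out[i] = np.fft.ifftn(
            fourier_shift(np.fft.fftn(base), shift_vox)
        ).real
    return out


def simulate_acquisition(
    phantom: Phantom,
    seq: SequenceParams,
    timing: CardiacTiming,
    traj: CaspirTrajectory,
    motion: MotionSpec | None = None,
    n_coils: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    field_strength_t: float = 0.55,
    fat_shift_ppm: float = 3.4,
    background_phase: np.ndarray | None = None,
) -> tuple[KSpaceDataset, np.ndarray, dict]:
    """Forward-simulate the full multi-contrast acquisition.

    Returns (k-space dataset, iNAV series, ground-truth bundle). Motion is a
    per-heartbeat (FH, RL) translation from the MotionSpec trace, applied
    exactly in k-space via the Fourier shift theorem, plus an optional
    nonrigid deformation whose amplitude follows the FH state (applied in
    image space per quantised motion state).
    """
    rng = np.random.default_rng(seed)
    vol_shape = phantom.t1_ms.shape
    ny, nz = vol_shape[1], vol_shape[2]
    if traj.grid_shape != (ny, nz):
        raise ValueError("trajectory grid does not match the phantom geometry")
    sens = make_coil_sensitivities(vol_shape, n_coils, seed=seed)
    images = contrast_images(
        phantom, seq, timing, field_strength_t, fat_shift_ppm, background_phase
    )
    n_hb = traj.n_heartbeats
    translations = (
        motion.trace(timing, n_hb) if motion is not None else np.zeros((n_hb, 2))
    )

    # quantised nonrigid states (identity when nonrigid_scale == 0)
    n_states = 5 if motion is not None and motion.nonrigid_scale else 1
    fh = translations[:, 0]
    if n_states > 1:
        edges = np.quantile(fh, np.linspace(0, 1, n_states + 1))
        state_of_hb = np.clip(np.searchsorted(edges, fh, side="right") - 1, 0, n_states - 1)
        state_fh = np.array(
            [np.median(fh[state_of_hb == s]) if np.any(state_of_hb == s) else 0.0
             for s in range(n_states)]
        )
        base_def = motion.base_deformation(vol_shape, seed=seed)
    else:
        state_of_hb = np.zeros(n_hb, dtype=int)
        state_fh = np.zeros(1)
        base_def = None

    # k-space of S * image per (contrast, echo, coil, state)
    fh_ref = fh.max() if n_hb else 0.0
    k_states = {}
    state_fields = np.zeros((n_states, 3) + vol_shape)
    from .motion import warp

    for s in range(n_states):
        if base_def is not None:
            amp = motion.nonrigid_scale * (state_fh[s] - fh_ref) / max(
                np.abs(fh - fh_ref).max(), 1e-9
            )
            disp = amp * base_def
        else:
            disp = None
        state_fields[s] = disp if disp is not None else 0.0
        for c in range(4):
            for e in range(traj.n_echoes):
                img = images[c, e]
                if disp is not None:
                    img = warp(img.real, disp) + 1j * warp(img.imag, disp)
                k_states[(s, c, e)] = np.stack([fft3(sens[i] * img) for i in range(n_coils)])

    nx = vol_shape[0]
    samples = np.zeros(
        (n_hb, traj.n_segments, traj.n_echoes, n_coils, nx), dtype=complex
    )
    spacing = phantom.spacing_mm
    for hb in range(n_hb):
        c = traj.contrast_of(hb)
        s = state_of_hb[hb]
        d_fh, d_rl = translations[hb]
        ramp = translational_phase_ramp(
            (d_rl / spacing, d_fh / spacing), traj.ky[hb], traj.kz[hb], (ny, nz)
        )
        for e in range(traj.n_echoes):
            k = k_states[(s, c, e)]
            lines = k[:, :, traj.ky[hb], traj.kz[hb]]  # [coil, nx, n_seg]
            samples[hb, :, e] = (lines * ramp[None, None, :]).transpose(2, 0, 1)
    if noise_sd > 0:
        samples += noise_sd * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
    inavs = render_inavs(phantom, translations, seq)
    meta = pd.DataFrame(
        {
            "heartbeat": np.arange(n_hb),
            "contrast": [traj.contrast_of(h) for h in range(n_hb)],
            "fh_mm": translations[:, 0],
            "rl_mm": translations[:, 1],
        }
    )
    ds = KSpaceDataset(
        samples=samples,
        trajectory=traj,
        coil_sensitivities=sens,
        spacing_mm=(spacing,) * 3,
        hb_metadata=meta,
    )
    truth = {
        "t1_ms": phantom.t1_ms,
        "t1rho_ms": phantom.t1rho_ms,
        "m0": phantom.m0,
        "fat_fraction": phantom.fat_fraction,
        "labels": phantom.labels,
        "contrast_images": images,
        "sensitivities": sens,
        "translations_mm": translations,
        "state_of_hb": state_of_hb,
        "state_fields": state_fields,
        "noise_sd": noise_sd,
    }
    return ds, inavs, truth


def ground_truth_bin_fields(
    truth: dict, motion_fields, vol_shape, spacing_mm: float = 2.0
) -> np.ndarray:
    """Per-bin fields of the applied deformation sampled at bin medians.

    After intra-bin translational correction each bin sits at its median
    (FH, RL) position, so the bin-to-reference field is the nonrigid state
    deformation plus the constant inter-bin translation offset. Both use the
    pull-back convention bin_image(r) = reference_image(r + d(r)).
    """
    n_bins = motion_fields.n_bins
    fields = np.zeros((n_bins, 3) + tuple(vol_shape))
    state_fields = truth["state_fields"]
    state_of_hb = truth["state_of_hb"]
    ref = motion_fields.reference_bin
    for b in range(n_bins):
        hbs = np.flatnonzero(motion_fields.bin_of_hb == b)
        if len(hbs) == 0:
            continue
        states = state_of_hb[hbs]
        fields[b] = state_fields[int(np.median(states))]
        d_fh, d_rl = motion_fields.bin_medians_mm[b] - motion_fields.bin_medians_mm[ref]
        fields[b, 1] -= d_rl / spacing_mm  # content shift +s  <=>  d = -s
        fields[b, 2] -= d_fh / spacing_mm
    return fields


__all__ = [
    "PhantomSpec",
    "Phantom",
    "MotionSpec",
    "make_phantom",
    "make_coil_sensitivities",
    "contrast_images",
    "render_inavs",
    "simulate_acquisition",
    "ground_truth_bin_fields",
    "T1MES_LIKE_VIALS",
    "INHOUSE_T1T1RHO_VIALS",
    "WATERFAT_FRACTIONS",
    "FAT_T1_MS",
    "FAT_T1RHO_MS",
]
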