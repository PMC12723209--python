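"""Respiratory motion handling: iNAV translation estimation, respiratory
binning with intra-bin k-space phase-ramp correction, trilinear warping with
an exact adjoint, and a pluggable nonrigid registration engine.

Conventions: iNAVs are coronal 2D images with axis 0 = foot-head (FH,
positive toward the head) and axis 1 = right-left (RL). In the 3D volume,
FH maps to axis z and RL to axis y; the readout axis x is unencoded by the
trajectory and carries no per-heartbeat correction, matching a 2D
translational iNAV correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Trilinear warp and its exact adjoint


def _warp_weights(disp: np.ndarray, shape: tuple[int, ...]):
    """Corner indices and weights of the trilinear pull-back x(r + d(r))."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = [g + d for g, d in zip(grids, disp)]
    lo, frac = [], []
    for c, n in zip(coords, shape):
        c = np.clip(c, 0.0, n - 1.0)
        f = np.floor(c)
        f = np.minimum(f, n - 2) if n > 1 else np.zeros_like(f)
        lo.append(f.astype(int))
        frac.append(c - f)
    corners = []
    for bits in range(8):
        idx = []
        w = np.ones(shape)
        for ax in range(3):
            hi = (bits >> ax) & 1
            n = shape[ax]
            idx.append(np.minimum(lo[ax] + hi, n - 1))
            w = w * (frac[ax] if hi else 1.0 - frac[ax])
        corners.append((tuple(idx), w))
    return corners


def warp(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Pull-back warp (U x)(r) = x(r + d(r)) with trilinear interpolation.

    ``disp`` has shape (3, nx, ny, nz) in voxels, defined on the output grid.
    """
    img = np.asarray(img)
    out = np.zeros(img.shape, dtype=img.dtype)
    for idx, w in _warp_weights(disp, img.shape):
        out += w * img[idx]
    return out


def warp_adjoint(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`warp` (scatter with the same weights)."""
    img = np.asarray(img)
    out = np.zeros(img.shape, dtype=img.dtype)
    for idx, w in _warp_weights(disp, img.shape):
        np.add.at(out, idx, w * img)
    return out


# ---------------------------------------------------------------------------
# iNAV translation estimation


def estimate_translations(
    inav_reference: np.ndarray,
    inavs: np.ndarray,
    region: tuple[slice, slice] | None = None,
    pixel_size_mm: float = 2.0,
) -> np.ndarray:
    """Per-heartbeat (FH, RL) translations in mm by NCC template matching.

    A template cut from the reference (default: central half) is matched in
    each iNAV with normalised cross-correlation; the correlation peak is
    refined to subpixel precision by separable quadratic interpolation.
    """
    ref = np.asarray(inav_reference, dtype=float)
    series = np.atleast_3d(np.asarray(inavs, dtype=float))
    if series.ndim == 2:
        series = series[None]
    if ref.shape != series.shape[1:]:
        raise ValueError("iNAV geometry mismatch")
    if ref.std() == 0:
        raise EstimationError("flat reference iNAV")
    h, w = ref.shape
    if region is None:
        region = (slice(h // 4, h - h // 4), slice(w // 4, w - w // 4))
    template = ref[region]
    if template.std() == 0:
        raise EstimationError("flat template region")
    r0, c0 = region[0].start, region[1].start
    out = np.zeros((series.shape[0], 2))
    for i, img in enumerate(series):
        if img.std() == 0:
            raise EstimationError(f"flat iNAV at heartbeat {i}")
        cc = match_template(img, template, pad_input=False)
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        sub = []
        for ax, p in enumerate(peak):
            if 0 < p < cc.shape[ax] - 1:
                sel = list(peak)
                sel[ax] = slice(p - 1, p + 2)
                y0, y1, y2 = cc[tuple(sel)]
                denom = y0 - 2 * y1 + y2
                sub.append(p + (0.5 * (y0 - y2) / denom if denom != 0 else 0.0))
            else:
                sub.append(float(p))
        out[i, 0] = (sub[0] - r0) * pixel_size_mm
        out[i, 1] = (sub[1] - c0) * pixel_size_mm
    return out


# ---------------------------------------------------------------------------
# Respiratory binning


@dataclass
class MotionFields:
    """Binned respiratory motion model.

    translations_mm: per-heartbeat (FH, RL); bin_of_hb assigns each heartbeat
    to one of B equal-count bins ordered by FH displacement; fields holds the
    per-bin dense displacement (voxels, shape [B, 3, nx, ny, nz]) mapping the
    reference (end-expiration) position into each bin's position; the
    reference bin's field is identity (zero).
    """

    translations_mm: np.ndarray
    bin_of_hb: np.ndarray
    bin_medians_mm: np.ndarray      # [B, 2]
    reference_bin: int
    fields: np.ndarray | None = None
    masks: dict = field(default_factory=dict)  # (contrast, bin) -> ky/kz mask

    @property
    def n_bins(self) -> int:
        return len(self.bin_medians_mm)

    def identity_fields(self, vol_shape: tuple[int, int, int]) -> np.ndarray:
        return np.zeros((self.n_bins, 3) + tuple(vol_shape))


def assign_bins(translations_mm: np.ndarray, n_bins: int) -> MotionFields:
    """Equal-count binning by FH displacement.

    The reference bin is end-expiration: the bin whose median FH position is
    most superior (largest FH, positive-toward-head convention).
    """
    translations_mm = np.asarray(translations_mm, dtype=float)
    n_hb = translations_mm.shape[0]
    if n_hb < n_bins:
        raise ValueError("fewer heartbeats than bins")
    order = np.argsort(translations_mm[:, 0], kind="stable")
    bin_of_hb = np.empty(n_hb, dtype=int)
    for b, idx in enumerate(np.array_split(order, n_bins)):
        bin_of_hb[idx] = b
    medians = np.array(
        [np.median(translations_mm[bin_of_hb == b], axis=0) for b in range(n_bins)]
    )
    reference_bin = int(np.argmax(medians[:, 0]))
    return MotionFields(
        translations_mm=translations_mm,
        bin_of_hb=bin_of_hb,
        bin_medians_mm=medians,
        reference_bin=reference_bin,
    )


# ---------------------------------------------------------------------------
# Nonrigid registration (pluggable)


def _demons_engine(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Multi-resolution demons-style registration via SimpleITK.

    Returns the displacement (voxels, shape [3, nx, ny, nz]) such that
    moving(r + d(r)) ~= fixed(r).
    """
    import SimpleITK as sitk

    fixed_img = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float64))
    moving_img = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float64))
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(50)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(1.5)
    levels = [2, 1] if min(fixed.shape) >= 16 else [1]
    disp = None
    for shrink in levels:
        if shrink > 1:
            f = sitk.Shrink(fixed_img, [shrink] * 3)
            m = sitk.Shrink(moving_img, [shrink] * 3)
        else:
            f, m = fixed_img, moving_img
        if disp is None:
            disp = demons.Execute(f, m)
        else:
            disp = sitk.Resample(
                disp, f, sitk.Transform(), sitk.sitkLinear, 0.0, disp.GetPixelID()
            )
            disp = demons.Execute(f, m, disp)
    if disp.GetSize() != fixed_img.GetSize():
        disp = sitk.Resample(
            disp, fixed_img, sitk.Transform(), sitk.sitkLinear, 0.0, disp.GetPixelID()
        )
    arr = sitk.GetArrayFromImage(disp)
    # sitk arrays index (z, y, x) and vector components are (x, y, z):
    # reorder components to the numpy array axes
    return np.stack([arr[..., 2 - i] for i in range(3)])


def estimate_nonrigid_fields(
    bin_images: np.ndarray,
    reference_bin: int,
    engine=None,
) -> np.ndarray:
    """Dense per-bin displacement fields toward each bin from the reference.

    ``bin_images`` is [B, nx, ny, nz] (magnitudes are fine). Returns fields
    [B, 3, nx, ny, nz] with zero displacement at the reference bin such that
    reference_image(r + d_b(r)) ~= bin_image_b(r). Any engine with signature
    engine(fixed, moving) -> displacement may be supplied; divergence (field
    with non-finite values) falls back to the identity with a warning.
    """
    import warnings

    bin_images = np.abs(np.asarray(bin_images))
    n_bins = bin_images.shape[0]
    if n_bins < 2:
        raise ValueError("need at least two bins")
    engine = engine or _demons_engine
    shape = bin_images.shape[1:]
    fields = np.zeros((n_bins, 3) + shape)
    ref = bin_images[reference_bin]
    for b in range(n_bins):
        if b == reference_bin:
            continue
        d = engine(bin_images[b], ref)
        if not np.all(np.isfinite(d)):
            warnings.warn(f"registration diverged for bin {b}; identity used")
            d = np.zeros((3,) + shape)
        fields[b] = d
    return fields


__all__ = [
    "warp",
    "warp_adjoint",
    "estimate_translations",
    "assign_bins",
    "MotionFields",
    "estimate_nonrigid_fields",
    "EstimationError",
]
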