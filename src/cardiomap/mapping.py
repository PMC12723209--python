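"""Polarity restoration and dictionary matching of water contrast images.

The inversion-prepared volume can be negative at the imaging time, so the
magnitude images must be re-signed before matching. The background (coil +
field) phase is estimated from a low-pass-filtered pseudo-in-phase echo and
subtracted from the water-image phase; the sign of the cosine of the residual
phase restores the polarity. Matching then L2-normalises each voxel's 4-point
signal and selects the dictionary atom with maximum inner product, which for
unit-norm vectors is equivalent to minimising the sum of squared differences
SSD = 2 - 2 <s, d>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dictionary import Dictionary

SENTINEL = 0.0


@dataclass
class MatchResult:
    """Best-matching grid parameters for one voxel signal."""

    t1: float      # ms
    t1rho: float   # ms
    ssd: float
    polarity: np.ndarray  # sign applied to each of the 4 volume signals


@dataclass
class ParameterMaps:
    """Voxelwise T1/T1rho (ms) and SSD volumes with spacing metadata."""

    t1: np.ndarray
    t1rho: np.ndarray
    ssd: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    meta: dict = field(default_factory=dict)

    def save(self, prefix, affine: np.ndarray | None = None) -> None:
        import json
        from pathlib import Path

        import nibabel as nib

        prefix = Path(prefix)
        if affine is None:
            affine = np.diag(list(self.spacing) + [1.0])
        for name, vol in (("t1", self.t1), ("t1rho", self.t1rho), ("ssd", self.ssd)):
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                str(prefix) + f"_{name}.nii",
            )
        with open(str(prefix) + "_maps.json", "w") as fh:
            json.dump({"spacing_mm": list(self.spacing), **self.meta}, fh, indent=2)


def estimate_background_phase(
    psip: np.ndarray, sigma: float = 8.0
) -> np.ndarray:
    """Smooth background-phase phasor from a pseudo-in-phase complex image.

    The complex image (not the wrapped phase) is Gaussian-filtered so the
    estimate is implicitly magnitude-weighted and wrap-free.
    """
    sm = gaussian_filter(psip.real, sigma) + 1j * gaussian_filter(psip.imag, sigma)
    mag = np.abs(sm)
    return np.where(mag > 0, sm / np.where(mag > 0, mag, 1.0), 1.0 + 0.0j)


def restore_polarity(
    water_volumes: np.ndarray,
    psip_volumes: np.ndarray,
    sigma: float = 8.0,
    reference: int | None = None,
) -> np.ndarray:
    """Re-sign complex water volumes using Ps-IP background phase.

    Parameters
    ----------
    water_volumes, psip_volumes
        Arrays of shape (4, nx, ny, nz), complex.
    sigma
        Gaussian width (voxels) of the background-phase low-pass filter.
    reference
        Index of the Ps-IP volume used as the shared background-phase
        reference. ``None`` uses each volume's own Ps-IP echo; a non-inverted
        contrast (e.g. 1) is more robust when inverted regions are larger
        than the filter kernel.
    """
    water_volumes = np.asarray(water_volumes)
    psip_volumes = np.asarray(psip_volumes)
    if water_volumes.shape != psip_volumes.shape or water_volumes.shape[0] != 4:
        raise ValueError("expected matching (4, nx, ny, nz) volume stacks")
    signed = np.empty(water_volumes.shape, dtype=float)
    for v in range(4):
        ref = psip_volumes[reference if reference is not None else v]
        bg = estimate_background_phase(ref, sigma=sigma)
        residual = np.angle(water_volumes[v] * np.conj(bg))
        signed[v] = np.abs(water_volumes[v]) * np.sign(np.cos(residual))
    return signed


def match_signals(
    signals: np.ndarray, dictionary: Dictionary, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match rows of ``signals`` [n, 4] to the dictionary.

    Returns (t1_ms, t1rho_ms, ssd) arrays of length n. Rows are
    L2-normalised; all-zero rows get the sentinel parameters and SSD 0.
    Ties in the inner product resolve to the smallest T1 then smallest
    T1rho because atoms are stored in lexicographic (T1, T1rho) order.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != dictionary.atoms.shape[1]:
        raise ValueError("signals must be [n, 4]")
    n = signals.shape[0]
    t1 = np.full(n, SENTINEL)
    t1rho = np.full(n, SENTINEL)
    ssd = np.zeros(n)
    atoms_t = dictionary.atoms.T  # [4, n_atoms]
    for start in range(0, n, chunk):
        block = signals[start : start + chunk]
        norms = np.linalg.norm(block, axis=1)
        ok = norms > 0
        unit = block[ok] / norms[ok, None]
        if unit.size == 0:
            continue
        ip = unit @ atoms_t
        best = np.argmax(ip, axis=1)
        best_ip = np.take_along_axis(ip, best[:, None], axis=1)[:, 0]
        idx = np.flatnonzero(ok) + start
        t1[idx] = dictionary.atom_params[best, 0]
        t1rho[idx] = dictionary.atom_params[best, 1]
        ssd[idx] = np.maximum(2.0 - 2.0 * best_ip, 0.0)
    return t1, t1rho, ssd


def match_maps(
    signed_water: np.ndarray,
    dictionary: Dictionary,
    mask: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    chunk: int = 1024,
) -> ParameterMaps:
    """Voxelwise dictionary matching of a (4, nx, ny, nz) signed stack."""
    signed_water = np.asarray(signed_water, dtype=float)
    if signed_water.ndim != 4 or signed_water.shape[0] != 4:
        raise ValueError("expected a (4, nx, ny, nz) signed water stack")
    vol_shape = signed_water.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    if mask.shape != vol_shape:
        raise ValueError("mask geometry does not match the volumes")
    voxels = signed_water.reshape(4, -1).T[mask.ravel()]
    t1_v, t1rho_v, ssd_v = match_signals(voxels, dictionary, chunk=chunk)
    t1 = np.full(vol_shape, SENTINEL).ravel()
    t1rho = np.full(vol_shape, SENTINEL).ravel()
    ssd = np.full(vol_shape, SENTINEL).ravel()
    flat = mask.ravel()
    t1[flat] = t1_v
    t1rho[flat] = t1rho_v
    ssd[flat] = ssd_v
    return ParameterMaps(
        t1=t1.reshape(vol_shape),
        t1rho=t1rho.reshape(vol_shape),
        ssd=ssd.reshape(vol_shape),
        spacing=spacing,
        meta={
            "hr_bpm": dictionary.hr,
            "acq_window_s": dictionary.acq_window,
            "n_atoms": int(dictionary.n_atoms),
        },
    )


def match_voxel(signal: np.ndarray, dictionary: Dictionary) -> MatchResult:
    """Convenience single-voxel match (polarity recorded as the signal signs)."""
    t1, t1rho, ssd = match_signals(np.asarray(signal, dtype=float)[None, :], dictionary)
    return MatchResult(
        t1=float(t1[0]),
        t1rho=float(t1rho[0]),
        ssd=float(ssd[0]),
        polarity=np.sign(np.asarray(signal)),
    )


__all__ = [
    "MatchResult",
    "ParameterMaps",
    "estimate_background_phase",
    "restore_polarity",
    "match_signals",
    "match_maps",
    "match_voxel",
    "SENTINEL",
]
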