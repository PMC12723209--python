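"""Iterative SENSE reconstruction with respiratory-binned motion correction.

The encoding operator for contrast c is

    E(c) = sum_b  A_b(c) F S U_b ,

where U_b warps the reference-position image into bin b (trilinear, with the
exact interpolation transpose as adjoint), S multiplies by coil
sensitivities, F is the orthonormal 3D FFT and A_b(c) samples bin b's
phase-encode points. The images are the least-squares solutions of
||E(c) x - k(c)||_2^2, solved by conjugate gradients on the normal
equations from zero initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .motion import MotionFields, warp, warp_adjoint
from .trajectory import CaspirTrajectory


def fft3(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 3D FFT (image -> k-space)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def ifft3(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k), norm="ortho"))


@dataclass
class KSpaceDataset:
    """Multi-contrast, multi-echo, multi-coil sampled k-space.

    samples: complex [n_heartbeats, n_segments, n_echoes, n_coils, nx]
    (full readout lines, already in the kx domain). The trajectory gives each
    (heartbeat, segment) its (ky, kz) grid cell; heartbeat metadata records
    contrast assignment and respiratory displacement.
    """

    samples: np.ndarray
    trajectory: CaspirTrajectory
    coil_sensitivities: np.ndarray  # [n_coils, nx, ny, nz]
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hb_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n_hb, n_seg = self.trajectory.ky.shape
        if self.samples.shape[:2] != (n_hb, n_seg):
            raise ValueError("samples do not map onto the trajectory")
        if self.coil_sensitivities.shape[0] != self.samples.shape[3]:
            raise ValueError("coil count mismatch")
        ny, nz = self.trajectory.grid_shape
        if self.coil_sensitivities.shape[2:] != (ny, nz):
            raise ValueError("sensitivities do not share the trajectory grid")

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.coil_sensitivities.shape[1:]

    @property
    def n_coils(self) -> int:
        return self.coil_sensitivities.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.samples.shape[2]

    def grid_contrast(
        self, contrast: int, echo: int, heartbeats=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Accumulate sampled lines onto the full k-space grid.

        Returns (k [n_coils, nx, ny, nz], mask [ny, nz]). Cells sampled by
        several heartbeats are averaged.
        """
        traj = self.trajectory
        if heartbeats is None:
            heartbeats = traj.heartbeats_of(contrast)
        nx = self.samples.shape[4]
        ny, nz = traj.grid_shape
        k = np.zeros((self.n_coils, nx, ny, nz), dtype=complex)
        count = np.zeros((ny, nz))
        for hb in np.atleast_1d(heartbeats):
            for seg in range(traj.n_segments):
                y, z = traj.ky[hb, seg], traj.kz[hb, seg]
                k[:, :, y, z] += self.samples[hb, seg, echo].reshape(self.n_coils, nx)
                count[y, z] += 1
        mask = count > 0
        k[:, :, mask] /= count[mask]
        return k, mask

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.create_dataset("ky", data=self.trajectory.ky)
            f.create_dataset("kz", data=self.trajectory.kz)
            f.create_dataset("base_angles", data=self.trajectory.base_angles)
            f.create_dataset("coil_sensitivities", data=self.coil_sensitivities)
            f.attrs["grid_shape"] = self.trajectory.grid_shape
            f.attrs["n_contrasts"] = self.trajectory.n_contrasts
            f.attrs["acceleration"] = self.trajectory.acceleration
            f.attrs["spacing_mm"] = self.spacing_mm
            if self.hb_metadata is not None:
                for col in self.hb_metadata.columns:
                    f.create_dataset(f"hb_metadata/{col}", data=self.hb_metadata[col].to_numpy())

    @classmethod
    def load(cls, path) -> "KSpaceDataset":
        with h5py.File(path, "r") as f:
            traj = CaspirTrajectory(
                ky=f["ky"][:],
                kz=f["kz"][:],
                base_angles=f["base_angles"][:],
                grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
                n_contrasts=int(f.attrs["n_contrasts"]),
                acceleration=float(f.attrs["acceleration"]),
            )
            meta = None
            if "hb_metadata" in f:
                meta = pd.DataFrame(
                    {k: f[f"hb_metadata/{k}"][:] for k in f["hb_metadata"]}
                )
            return cls(
                samples=f["samples"][:],
                trajectory=traj,
                coil_sensitivities=f["coil_sensitivities"][:],
                spacing_mm=tuple(float(v) for v in f.attrs["spacing_mm"]),
                hb_metadata=meta,
            )


# ---------------------------------------------------------------------------
# Encoding operators


class MotionCorrectedOperator:
    """E = sum_b A_b F S U_b on complex 3D images.

    ``masks`` is [B, ny, nz] boolean (disjoint across bins); ``fields`` is
    [B, 3, nx, ny, nz] displacement in voxels (None = identity motion).
    The forward maps an image to [n_coils, nx, ny, nz] k-space with zeros
    at unsampled cells; the adjoint is the exact conjugate transpose.
    """

    def __init__(
        self,
        sensitivities: np.ndarray,
        masks: np.ndarray,
        fields: np.ndarray | None = None,
    ):
        self.S = np.asarray(sensitivities)
        self.masks = np.asarray(masks, dtype=bool)
        if self.masks.ndim == 2:
            self.masks = self.masks[None]
        self.fields = fields
        if fields is not None and len(fields) != len(self.masks):
            raise ValueError("one displacement field per bin required")
        self.vol_shape = self.S.shape[1:]

    def _warp(self, x: np.ndarray, b: int) -> np.ndarray:
        if self.fields is None:
            return x
        return warp(x, self.fields[b])

    def _warp_adj(self, x: np.ndarray, b: int) -> np.ndarray:
        if self.fields is None:
            return x
        return warp_adjoint(x, self.fields[b])

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros((self.S.shape[0],) + self.vol_shape, dtype=complex)
        for b, mask in enumerate(self.masks):
            xb = self._warp(x, b)
            for c in range(self.S.shape[0]):
                k = fft3(self.S[c] * xb)
                out[c, :, mask] += k[:, mask].T
        return out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.vol_shape, dtype=complex)
        for b, mask in enumerate(self.masks):
            acc = np.zeros(self.vol_shape, dtype=complex)
            for c in range(self.S.shape[0]):
                k = np.zeros(self.vol_shape, dtype=complex)
                k[:, mask] = y[c, :, mask].T
                acc += np.conj(self.S[c]) * ifft3(k)
            out += self._warp_adj(acc, b)
        return out

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(x))


def cg_normal(
    op: MotionCorrectedOperator,
    k_data: np.ndarray,
    n_iterations: int = 3,
    tol: float = 0.0,
) -> tuple[np.ndarray, list[float]]:
    """CG on the normal equations E^H E x = E^H k from zero initialisation.

    Returns the solution and the residual-norm history (normal-equation
    residual), which is non-increasing for a correct adjoint pair.
    """
    b = op.adjoint(k_data)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    history = [np.sqrt(rs)]
    b_norm = np.sqrt(rs)
    for _ in range(n_iterations):
        if b_norm > 0 and history[-1] / b_norm < tol:
            break
        ap = op.normal(p)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        history.append(np.sqrt(rs_new))
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, history


def translational_phase_ramp(
    shift_voxels: tuple[float, float],
    ky: np.ndarray,
    kz: np.ndarray,
    grid_shape: tuple[int, int],
) -> np.ndarray:
    """Linear phase shifting sampled (ky, kz) lines by (dy, dz) voxels.

    A positive shift moves image content toward positive axis indices.
    """
    ny, nz = grid_shape
    dy, dz = shift_voxels
    return np.exp(
        -2j * np.pi * ((ky - ny // 2) * dy / ny + (kz - nz // 2) * dz / nz)
    )


def bin_and_correct(
    kspace: KSpaceDataset, translations_mm: np.ndarray, n_bins: int = 5
) -> tuple[KSpaceDataset, MotionFields]:
    """Assign heartbeats to respiratory bins and align each bin internally.

    Every heartbeat's k-space lines receive the linear phase ramp that
    translates its data to the bin's median (FH, RL) position (FH -> volume
    axis z, RL -> axis y). Returns the corrected dataset and the motion model.
    """
    from .motion import assign_bins

    motion = assign_bins(translations_mm, n_bins)
    traj = kspace.trajectory
    sy, sz_ = kspace.spacing_mm[1], kspace.spacing_mm[2]
    corrected = kspace.samples.copy()
    for hb in range(traj.n_heartbeats):
        b = motion.bin_of_hb[hb]
        d_fh, d_rl = motion.bin_medians_mm[b] - motion.translations_mm[hb]
        ramp = translational_phase_ramp(
            (d_rl / sy, d_fh / sz_), traj.ky[hb], traj.kz[hb], traj.grid_shape
        )
        corrected[hb] *= ramp[:, None, None, None]
    out = KSpaceDataset(
        samples=corrected,
        trajectory=traj,
        coil_sensitivities=kspace.coil_sensitivities,
        spacing_mm=kspace.spacing_mm,
        hb_metadata=kspace.hb_metadata,
    )
    return out, motion


def binned_masks(
    kspace: KSpaceDataset, motion: MotionFields, contrast: int
) -> np.ndarray:
    """Per-bin sampling masks A_b(c); disjoint, reassembling the full mask."""
    traj = kspace.trajectory
    masks = np.zeros((motion.n_bins,) + traj.grid_shape, dtype=bool)
    for hb in traj.heartbeats_of(contrast):
        masks[motion.bin_of_hb[hb], traj.ky[hb], traj.kz[hb]] = True
    # a cell sampled in several bins is attributed to the first
    claimed = np.zeros(traj.grid_shape, dtype=bool)
    for b in range(motion.n_bins):
        masks[b] &= ~claimed
        claimed |= masks[b]
    return masks


def recon_binned(
    kspace: KSpaceDataset,
    heartbeats: np.ndarray,
    contrast: int = 0,
    echo: int = 0,
    n_iterations: int = 15,
    tol: float = 1e-6,
) -> np.ndarray:
    """Iterative SENSE on one respiratory bin (no motion in the operator)."""
    if len(np.atleast_1d(heartbeats)) == 0:
        raise ValueError("empty bin")
    if np.all(kspace.coil_sensitivities == 0):
        raise ValueError("zero coil sensitivities")
    k, mask = kspace.grid_contrast(contrast, echo, heartbeats=heartbeats)
    op = MotionCorrectedOperator(kspace.coil_sensitivities, mask[None])
    k = k * mask[None, None]
    x, _ = cg_normal(op, k, n_iterations=n_iterations, tol=tol)
    return x


def motion_corrected_recon(
    kspace: KSpaceDataset,
    motion: MotionFields,
    n_iterations: int = 3,
    contrasts=None,
    echoes=None,
) -> np.ndarray:
    """Nonrigid motion-corrected CG-SENSE for every (contrast, echo).

    Returns a complex array [n_contrasts, n_echoes, nx, ny, nz]. With
    ``motion.fields`` None (or all-zero) this reduces to plain iterative
    SENSE on the pooled, intra-bin-corrected data.
    """
    traj = kspace.trajectory
    contrasts = range(traj.n_contrasts) if contrasts is None else contrasts
    echoes = range(kspace.n_echoes) if echoes is None else echoes
    fields = motion.fields
    out = np.zeros(
        (traj.n_contrasts, kspace.n_echoes) + kspace.vol_shape, dtype=complex
    )
    for c in contrasts:
        masks = binned_masks(kspace, motion, c)
        op = MotionCorrectedOperator(kspace.coil_sensitivities, masks, fields)
        hbs_of_bin = [
            [hb for hb in traj.heartbeats_of(c) if motion.bin_of_hb[hb] == b]
            for b in range(motion.n_bins)
        ]
        for e in echoes:
            k_full = np.zeros(
                (kspace.n_coils,) + kspace.vol_shape, dtype=complex
            )
            for b in range(motion.n_bins):
                if not hbs_of_bin[b]:
                    continue
                kb, _ = kspace.grid_contrast(c, e, heartbeats=hbs_of_bin[b])
                k_full[:, :, masks[b]] = kb[:, :, masks[b]]
            out[c, e], _ = cg_normal(op, k_full, n_iterations=n_iterations)
    return out


__all__ = [
    "KSpaceDataset",
    "MotionCorrectedOperator",
    "cg_normal",
    "fft3",
    "ifft3",
    "bin_and_correct",
    "binned_masks",
    "recon_binned",
    "motion_corrected_recon",
    "translational_phase_ramp",
]
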