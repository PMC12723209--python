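"""Multi-contrast patch-tensor low-rank denoising (HD-PROST style).

For each reference patch on a stride grid, the most similar patches in a
local search window (similarity summed over all contrasts) are stacked into
a 3rd-order tensor [patch voxels x similar patches x contrasts]. Each mode
unfolding has its singular values thresholded at lambda times that mode's
leading singular value - a scale-invariant multilinear truncation - and the
overlapping denoised patches are aggregated by weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass(frozen=True)
class HdprostParams:
    lam: float = 0.07
    patch_size: int = 5
    search_window: int = 20
    n_similar: int = 20
    stride: int = 2

    def __post_init__(self) -> None:
        if self.patch_size > self.search_window:
            raise ValueError("patch must fit inside the search window")
        if self.n_similar < 1:
            raise ValueError("n_similar must be >= 1")


def _threshold_modes(tensor: np.ndarray, lam: float) -> np.ndarray:
    """Sequential mode-wise singular-value thresholding.

    Singular values below lambda times the mode's leading singular value are
    zeroed; values above survive unshrunk. Keeping the retained values intact
    (rather than subtracting the threshold) preserves noiseless low-rank
    structure exactly, which shrinkage of the leading value cannot.
    """
    out = tensor
    for mode in range(3):
        mat = np.moveaxis(out, mode, 0).reshape(out.shape[mode], -1)
        u, s, vh = np.linalg.svd(mat, full_matrices=False)
        if s.size and s[0] > 0:
            s = np.where(s >= lam * s[0], s, 0.0)
        mat = (u * s) @ vh
        out = np.moveaxis(
            mat.reshape((out.shape[mode],) + tuple(np.delete(out.shape, mode))),
            0,
            mode,
        )
    return out


def _search_offsets(params: HdprostParams, shape) -> list[tuple[int, int, int]]:
    half = params.search_window // 2
    offs = []
    for d in product(
        *[range(-min(half, n - 1), min(half, n - 1) + 1) for n in shape]
    ):
        offs.append(d)
    offs.sort(key=lambda d: (d != (0, 0, 0), np.hypot(np.hypot(d[0], d[1]), d[2])))
    return offs


def hdprost_denoise(
    volumes: np.ndarray, params: HdprostParams | None = None
) -> np.ndarray:
    """Denoise a stack of co-registered contrast volumes jointly.

    ``volumes`` is [n_contrast, nx, ny, nz], real or complex; the same patch
    selection is shared across contrasts. lambda = 0 returns the input.
    """
    params = params or HdprostParams()
    vols = np.asarray(volumes)
    if vols.ndim != 4:
        raise ValueError("expected a (n_contrast, nx, ny, nz) stack")
    if params.lam == 0:
        return vols.copy()
    n_c = vols.shape[0]
    shape = vols.shape[1:]
    # patch edge clipped to the volume along thin axes
    p_ax = tuple(min(params.patch_size, n) for n in shape)
    half_ax = tuple(p // 2 for p in p_ax)

    offsets = _search_offsets(params, shape)
    # patch-summed squared distance between the volume and its shifted copy,
    # evaluated for every patch centre at once per offset
    centres = [
        np.arange(h, n - (p - 1 - h), params.stride)
        for n, p, h in zip(shape, p_ax, half_ax)
    ]
    centres = [c if c.size else np.array([n // 2]) for c, n in zip(centres, shape)]
    grid = np.ix_(*centres)
    ssd = np.empty((len(offsets),) + tuple(len(c) for c in centres), dtype=np.float32)
    for i, d in enumerate(offsets):
        shifted = np.roll(vols, shift=d, axis=(1, 2, 3))
        diff = np.sum(np.abs(vols - shifted) ** 2, axis=0)
        ssd[i] = uniform_filter(diff, size=p_ax)[grid].astype(np.float32)

    k = min(params.n_similar, len(offsets))
    flat_ssd = ssd.reshape(len(offsets), -1)
    top = np.argpartition(flat_ssd, k - 1, axis=0)[:k]  # [k, n_centres]

    acc = np.zeros(vols.shape, dtype=vols.dtype)
    weight = np.zeros(shape)
    offsets_arr = np.array(offsets)
    n_centres = flat_ssd.shape[1]
    centre_coords = np.stack(
        np.meshgrid(*centres, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    n_patch_vox = int(np.prod(p_ax))
    for ci in range(n_centres):
        c0 = centre_coords[ci]
        sel = offsets_arr[top[:, ci]]
        patches = np.empty((n_patch_vox, k, n_c), dtype=vols.dtype)
        slices_list = []
        for j, d in enumerate(sel):
            pos = c0 + d
            sl = tuple(
                slice(int(np.clip(pos[a] - half_ax[a], 0, shape[a] - p_ax[a])),
                      int(np.clip(pos[a] - half_ax[a], 0, shape[a] - p_ax[a]))
                      + p_ax[a])
                for a in range(3)
            )
            slices_list.append(sl)
            patches[:, j, :] = vols[(slice(None),) + sl].reshape(n_c, -1).T
        den = _threshold_modes(patches, params.lam)
        for j, sl in enumerate(slices_list):
            acc[(slice(None),) + sl] += den[:, j, :].T.reshape((n_c,) + p_ax)
            weight[sl] += 1.0
    covered = weight > 0
    out = vols.copy()
    out[:, covered] = acc[:, covered] / weight[covered]
    return out


__all__ = ["HdprostParams", "hdprost_denoise"]
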