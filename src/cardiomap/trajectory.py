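"""Variable-density Cartesian sampling with spiral-like profile order.

Phase-encode points on the ky-kz plane are organised into spiral-like arms,
one arm per heartbeat, rotated by the golden angle between successive
heartbeats. Each arm acquires ``n_segments`` points ordered centre-out
(centric reordering), with radial density decreasing from the centre through
a power-law radius schedule. Points are snapped to the Cartesian grid and
collisions within a contrast are resolved to the nearest free cell, so the
sampled fraction per contrast is n_points / grid_size by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # rad


@dataclass
class CaspirTrajectory:
    """Per-heartbeat spiral-arm phase-encode coordinates on the ky-kz grid."""

    ky: np.ndarray            # [n_heartbeats, n_segments] int grid indices
    kz: np.ndarray
    base_angles: np.ndarray   # [n_heartbeats] arm rotation (rad)
    grid_shape: tuple[int, int]
    n_contrasts: int = 4
    n_echoes: int = 2
    acceleration: float = 1.0

    @property
    def n_heartbeats(self) -> int:
        return self.ky.shape[0]

    @property
    def n_segments(self) -> int:
        return self.ky.shape[1]

    def contrast_of(self, heartbeat: int) -> int:
        return heartbeat % self.n_contrasts

    def heartbeats_of(self, contrast: int) -> np.ndarray:
        return np.arange(contrast, self.n_heartbeats, self.n_contrasts)

    def mask(self, contrast: int, heartbeats=None) -> np.ndarray:
        """Boolean sampling mask on the ky-kz grid for one contrast."""
        if heartbeats is None:
            heartbeats = self.heartbeats_of(contrast)
        m = np.zeros(self.grid_shape, dtype=bool)
        for hb in np.atleast_1d(heartbeats):
            m[self.ky[hb], self.kz[hb]] = True
        return m

    def radii(self) -> np.ndarray:
        """Elliptical k-space radius (fraction of grid half-width) per point."""
        ny, nz = self.grid_shape
        ry = (self.ky - ny // 2) / max(ny / 2.0, 1.0)
        rz = (self.kz - nz // 2) / max(nz / 2.0, 1.0)
        return np.hypot(ry, rz)


def _nearest_free(taken: set, y: float, z: float, ny: int, nz: int):
    """Closest free grid cell to the continuous point (y, z)."""
    yc, zc = int(round(y)), int(round(z))
    for ring in range(max(ny, nz)):
        best = None
        best_d = np.inf
        for dy in range(-ring, ring + 1):
            for dz in range(-ring, ring + 1):
                if max(abs(dy), abs(dz)) != ring:
                    continue
                cy, cz = yc + dy, zc + dz
                if not (0 <= cy < ny and 0 <= cz < nz):
                    continue
                if (cy, cz) in taken:
                    continue
                d = (cy - y) ** 2 + (cz - z) ** 2
                if d < best_d:
                    best_d = d
                    best = (cy, cz)
        if best is not None:
            return best
    raise ConfigurationError("no free grid cells remain")


def generate_vdcaspr(
    matrix_ky: int,
    matrix_kz: int,
    acceleration: float,
    n_segments: int,
    n_heartbeats: int | None = None,
    seed: int = 0,
    n_contrasts: int = 4,
    density_exponent: float = 1.5,
    spiral_turns: float = 0.5,
) -> CaspirTrajectory:
    """Generate a VD-CASPR-style trajectory.

    ``n_heartbeats`` defaults to the count that gives each contrast
    ``matrix_ky * matrix_kz / acceleration`` phase-encode points. The radius
    schedule r ~ u**density_exponent concentrates samples near the centre;
    collision resolution pushes duplicates to adjacent free cells, which
    fills the central region completely at typical accelerations.
    """
    if acceleration < 1:
        raise ConfigurationError("acceleration must be >= 1")
    rng = np.random.default_rng(seed)
    n_grid = matrix_ky * matrix_kz
    if n_heartbeats is None:
        per_contrast = int(round(n_grid / acceleration))
        n_hb_per_contrast = max(1, int(round(per_contrast / n_segments)))
        n_heartbeats = n_hb_per_contrast * n_contrasts
    if (n_heartbeats / n_contrasts) * n_segments > n_grid:
        raise ConfigurationError("more points requested than grid slots")

    cy, cz = matrix_ky // 2, matrix_kz // 2
    max_ry = matrix_ky / 2.0 - 0.5
    max_rz = matrix_kz / 2.0 - 0.5
    ky = np.zeros((n_heartbeats, n_segments), dtype=int)
    kz = np.zeros((n_heartbeats, n_segments), dtype=int)
    base_angles = np.zeros(n_heartbeats)
    taken_per_contrast: list[set] = [set() for _ in range(n_contrasts)]
    for hb in range(n_heartbeats):
        contrast = hb % n_contrasts
        taken = taken_per_contrast[contrast]
        theta = (hb * GOLDEN_ANGLE) % (2 * np.pi)
        base_angles[hb] = theta
        # jitter the radial phase so arms do not all share identical radii
        u0 = rng.uniform(0, 1.0 / n_segments)
        pts = []
        for i in range(n_segments):
            u = min((i + u0) / n_segments, 1.0)
            f = u**density_exponent
            phi = theta + spiral_turns * 2 * np.pi * u
            y = cy + f * max_ry * np.cos(phi)
            z = cz + f * max_rz * np.sin(phi)
            cell = _nearest_free(taken, y, z, matrix_ky, matrix_kz)
            taken.add(cell)
            pts.append(cell)
        # centric reordering: centre-most point of the arm first
        pts = sorted(
            pts,
            key=lambda p: ((p[0] - cy) / max(cy, 1)) ** 2
            + ((p[1] - cz) / max(cz, 1)) ** 2,
        )
        ky[hb] = [p[0] for p in pts]
        kz[hb] = [p[1] for p in pts]
    return CaspirTrajectory(
        ky=ky,
        kz=kz,
        base_angles=base_angles,
        grid_shape=(matrix_ky, matrix_kz),
        n_contrasts=n_contrasts,
        acceleration=acceleration,
    )


__all__ = ["CaspirTrajectory", "generate_vdcaspr", "GOLDEN_ANGLE"]
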