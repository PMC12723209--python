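"""(T1, T1rho) signal dictionary: grid construction, atom simulation,
L2 normalisation and HDF5 persistence.

The default grid is the mapping grid of the sequence protocol,
T1 = [50:5:1400, 1400:50:1800, 1800:100:3000] ms and
T1rho = [5:5:20, 20:1:80, 80:4:300, 300:100:600] ms (shared endpoints
de-duplicated), giving 291 x 122 = 35,502 atoms of 4 samples each.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import bloch
from .params import CardiacTiming, ConfigurationError, SequenceParams


def _ranges_ms(segments: list[tuple[float, float, float]]) -> np.ndarray:
    """Concatenate [start:step:end] segments (inclusive ends), de-duplicated."""
    values: list[float] = []
    for start, step, end in segments:
        n = int(round((end - start) / step))
        values.extend(start + step * np.arange(n + 1))
    out = np.unique(np.round(np.asarray(values), 9))
    if np.any(out <= 0):
        raise ConfigurationError("grid values must be positive")
    return out


DEFAULT_T1_SEGMENTS_MS = [(50, 5, 1400), (1400, 50, 1800), (1800, 100, 3000)]
DEFAULT_T1RHO_SEGMENTS_MS = [(5, 5, 20), (20, 1, 80), (80, 4, 300), (300, 100, 600)]


@dataclass(frozen=True)
class DictionaryGrid:
    """Strictly increasing T1 and T1rho grid values in milliseconds."""

    t1_values: np.ndarray = field(
        default_factory=lambda: _ranges_ms(DEFAULT_T1_SEGMENTS_MS)
    )
    t1rho_values: np.ndarray = field(
        default_factory=lambda: _ranges_ms(DEFAULT_T1RHO_SEGMENTS_MS)
    )

    def __post_init__(self) -> None:
        for name in ("t1_values", "t1rho_values"):
            v = np.unique(np.asarray(getattr(self, name), dtype=float))
            if np.any(v <= 0):
                raise ConfigurationError(f"{name} must be positive")
            object.__setattr__(self, name, v)

    @property
    def n_atoms(self) -> int:
        return len(self.t1_values) * len(self.t1rho_values)


@dataclass
class Dictionary:
    """Unit-norm signal atoms plus the (T1, T1rho) parameters of each row."""

    grid: DictionaryGrid
    atoms: np.ndarray        # [n_atoms, 4], each row L2-normalised
    atom_params: np.ndarray  # [n_atoms, 2], (t1_ms, t1rho_ms)
    hr: float                # bpm used in the simulation
    acq_window: float        # s

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.atoms, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("dictionary atoms must be unit L2 norm")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def save(self, path, config: dict | None = None) -> None:
        config = config or {}
        blob = json.dumps(config, sort_keys=True).encode()
        with h5py.File(path, "w") as f:
            f.create_dataset("atoms", data=self.atoms)
            f.create_dataset("atom_params", data=self.atom_params)
            f.create_dataset("t1_values", data=self.grid.t1_values)
            f.create_dataset("t1rho_values", data=self.grid.t1rho_values)
            f.attrs["hr"] = self.hr
            f.attrs["acq_window"] = self.acq_window
            f.attrs["config_json"] = blob.decode()
            f.attrs["config_hash"] = hashlib.sha256(blob).hexdigest()

    @classmethod
    def load(cls, path) -> "Dictionary":
        with h5py.File(path, "r") as f:
            grid = DictionaryGrid(
                t1_values=f["t1_values"][:], t1rho_values=f["t1rho_values"][:]
            )
            return cls(
                grid=grid,
                atoms=f["atoms"][:],
                atom_params=f["atom_params"][:],
                hr=float(f.attrs["hr"]),
                acq_window=float(f.attrs["acq_window"]),
            )


def generate_dictionary(
    seq: SequenceParams,
    timing: CardiacTiming,
    grid: DictionaryGrid | None = None,
) -> Dictionary:
    """Simulate one atom per (T1, T1rho) pair and L2-normalise each.

    The full grid is simulated in a single vectorised Bloch run; atoms whose
    4-point signal is identically zero (possible only for degenerate flip
    angles) are left as zero rows and rejected by the Dictionary invariant.
    """
    grid = grid or DictionaryGrid()
    t1_ms, t1rho_ms = np.meshgrid(grid.t1_values, grid.t1rho_values, indexing="ij")
    t1_ms = t1_ms.ravel()
    t1rho_ms = t1rho_ms.ravel()
    signals, _, converged = bloch.simulate_signals_grid(
        seq, timing, t1_ms / 1000.0, t1rho_ms / 1000.0, m0=1.0
    )
    if not converged.all():
        import warnings

        warnings.warn("some atoms did not reach steady state", RuntimeWarning)
    norms = np.linalg.norm(signals, axis=1, keepdims=True)
    atoms = signals / np.where(norms > 0, norms, 1.0)
    hr = 60.0 / timing.rr(0)
    return Dictionary(
        grid=grid,
        atoms=atoms,
        atom_params=np.column_stack([t1_ms, t1rho_ms]),
        hr=hr,
        acq_window=seq.acq_window,
    )


__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "generate_dictionary",
    "DEFAULT_T1_SEGMENTS_MS",
    "DEFAULT_T1RHO_SEGMENTS_MS",
]
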