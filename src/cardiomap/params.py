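"""Sequence, timing and tissue parameter containers.

Units are SI (seconds, Hz) unless a field name says otherwise; relaxation
times in the public mapping API are milliseconds, matching how they are
quoted in cardiac MR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import yaml


class Prep(str, Enum):
    """Magnetisation preparation module played at the start of a heartbeat."""

    IR = "IR"
    NONE = "NONE"
    T1RHO = "T1RHO"


class ConfigurationError(ValueError):
    pass


class TimingError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceParams:
    """Interleaved 4-heartbeat joint T1/T1rho sequence settings.

    The default values are the protocol of the free-breathing 0.55 T
    acquisition: IR preparation (TI 245 ms) on beat 1, no preparation on
    beats 2-3, spin-lock preparation (TSL 40 ms, SLA 150 Hz) on beat 4,
    two-echo Dixon RF-spoiled GRE readout with centric reordering.
    """

    prep_pattern: tuple[Prep, ...] = (Prep.IR, Prep.NONE, Prep.NONE, Prep.T1RHO)
    ti: float = 0.245            # s, inversion to first imaging readout
    tsl: float = 0.040           # s, spin-lock duration
    sla: float = 150.0           # Hz, spin-lock amplitude (metadata only)
    fa_imaging: float = 8.0      # deg
    fa_inav: float = 3.0         # deg
    tr_imaging: float = 0.00971  # s
    te1: float = 0.00260         # s, pseudo-in-phase echo
    te2: float = 0.00650         # s, out-of-phase echo
    n_segments_per_hb: int = 16
    n_inav_pulses: int = 14
    acq_window: float = 0.155    # s
    inversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if len(self.prep_pattern) != 4:
            raise ConfigurationError("prep_pattern must cover exactly 4 heartbeats")
        for p in self.prep_pattern:
            if not isinstance(p, Prep):
                raise ConfigurationError(f"unknown prep module: {p!r}")
        for name in ("ti", "tsl", "tr_imaging", "te1", "te2", "acq_window"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 < self.inversion_efficiency <= 1.0):
            raise ConfigurationError("inversion_efficiency must lie in (0, 1]")
        if self.n_segments_per_hb * self.tr_imaging > self.acq_window + 1e-3:
            raise ConfigurationError(
                "imaging train exceeds the acquisition window by more than 1 ms"
            )
        if self.ti < self.inav_duration:
            raise ConfigurationError("TI shorter than the iNAV block it must contain")

    @property
    def inav_duration(self) -> float:
        return self.n_inav_pulses * self.tr_imaging

    @property
    def imaging_duration(self) -> float:
        return self.n_segments_per_hb * self.tr_imaging

    def prep_duration(self, prep: Prep) -> float:
        # IR modelled as instantaneous; the spin lock occupies TSL.
        return self.tsl if prep is Prep.T1RHO else 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        d = dict(d)
        if "prep_pattern" in d:
            d["prep_pattern"] = tuple(Prep(p) for p in d["prep_pattern"])
        return cls(**d)


@dataclass(frozen=True)
class CardiacTiming:
    """Heartbeat timing: fixed HR or an explicit RR series for variability runs."""

    rr_intervals: tuple[float, ...] = (1.0,)
    trigger_delay: float = 0.0

    def __post_init__(self) -> None:
        if len(self.rr_intervals) == 0:
            raise ConfigurationError("need at least one RR interval")
        if any(rr <= 0 for rr in self.rr_intervals):
            raise ConfigurationError("RR intervals must be positive")
        if self.trigger_delay < 0:
            raise ConfigurationError("trigger_delay must be non-negative")

    @classmethod
    def from_hr(cls, hr_bpm: float, trigger_delay: float = 0.0) -> "CardiacTiming":
        return cls(rr_intervals=(60.0 / hr_bpm,), trigger_delay=trigger_delay)

    def rr(self, heartbeat: int) -> float:
        return self.rr_intervals[heartbeat % len(self.rr_intervals)]

    def validate_against(self, seq: SequenceParams) -> None:
        """Every RR must fit trigger delay, prep, pre-imaging gap and window."""
        for prep in seq.prep_pattern:
            needed = (
                self.trigger_delay
                + seq.prep_duration(prep)
                + seq.ti
                + seq.imaging_duration
            )
            for rr in self.rr_intervals:
                if rr < needed - 1e-12:
                    raise TimingError(
                        f"RR={rr:.3f}s cannot accommodate prep {prep.value} "
                        f"({needed:.3f}s required)"
                    )


@dataclass(frozen=True)
class TissueParams:
    """Single-compartment tissue: T1/T1rho in seconds, equilibrium M0."""

    t1: float
    t1rho: float
    m0: float = 1.0
    fat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t1rho <= 0:
            raise ConfigurationError("t1 and t1rho must be positive")
        if self.m0 < 0:
            raise ConfigurationError("m0 must be non-negative")
        if not (0.0 <= self.fat_fraction <= 1.0):
            raise ConfigurationError("fat_fraction must lie in [0, 1]")


@dataclass
class SignalEvolution:
    """The 4-point signed signal evolution of one steady-state block."""

    signals: np.ndarray          # shape (4,), magnetisation units, signed
    sample_times: np.ndarray     # s from block start, first imaging pulse per HB
    converged: bool = True

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.signals.shape != (4,):
            raise ValueError("a signal evolution has exactly 4 volumes")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signal values")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "volume": np.arange(1, 5),
                "time_s": self.sample_times,
                "signal": self.signals,
            }
        ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Read a YAML/JSON config; keys mirror the dataclass field names."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def sequence_from_config(cfg: dict) -> tuple[SequenceParams, CardiacTiming]:
    seq = SequenceParams.from_dict(cfg.get("sequence", {}))
    tcfg = dict(cfg.get("timing", {}))
    if "hr_bpm" in tcfg:
        timing = CardiacTiming.from_hr(
            tcfg["hr_bpm"], trigger_delay=tcfg.get("trigger_delay", 0.0)
        )
    else:
        timing = CardiacTiming(
            rr_intervals=tuple(tcfg.get("rr_intervals", (1.0,))),
            trigger_delay=tcfg.get("trigger_delay", 0.0),
        )
    return seq, timing


__all__ = [
    "Prep",
    "SequenceParams",
    "CardiacTiming",
    "TissueParams",
    "SignalEvolution",
    "ConfigurationError",
    "TimingError",
    "load_config",
    "sequence_from_config",
    "replace",
]
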