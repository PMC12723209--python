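"""Reference spin-echo fitting and map agreement analysis.

The 2D IR-SE reference signal model is
S(TI) = M0 (1 - 2 exp(-TI/T1) + exp(-TR/T1)), fitted by Levenberg-Marquardt;
the T1rho-prepared SE reference S(TSL) = M0 exp(-TSL/T1rho) is fitted
linearly in log space. ROI agreement between two maps uses per-vial means,
linear regression and Bland-Altman statistics, after the myocardial-range
filter (T1 <= 1300 ms and T1rho <= 150 ms on the reference values).

The SD convention everywhere in this package is the sample SD (n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_IR_TIS_MS = (50, 350, 650, 950, 1250, 1550, 1850, 2150)
DEFAULT_T1RHO_TSLS_MS = (2, 14, 26, 38, 50, 62, 74, 86)


@dataclass(frozen=True)
class IrSeProtocol:
    tis_ms: tuple = DEFAULT_IR_TIS_MS
    tr_ms: float = 8000.0

    def __post_init__(self) -> None:
        tis = np.asarray(self.tis_ms, dtype=float)
        if np.any(np.diff(tis) <= 0):
            raise ValueError("TIs must be strictly increasing")
        if self.tr_ms <= tis[-1]:
            raise ValueError("TR must exceed the largest TI")


@dataclass(frozen=True)
class T1rhoSeProtocol:
    tsls_ms: tuple = DEFAULT_T1RHO_TSLS_MS
    sla_hz: float = 150.0

    def __post_init__(self) -> None:
        if np.any(np.diff(np.asarray(self.tsls_ms, dtype=float)) <= 0):
            raise ValueError("TSLs must be strictly increasing")


def ir_se_signal(ti_ms, t1_ms, m0, tr_ms):
    ti_ms = np.asarray(ti_ms, dtype=float)
    return m0 * (1 - 2 * np.exp(-ti_ms / t1_ms) + np.exp(-tr_ms / t1_ms))


@dataclass
class FitResult:
    t1: float       # ms (or t1rho for the SE fit)
    m0: float
    converged: bool = True


def fit_ir_se(
    signals,
    protocol: IrSeProtocol | None = None,
    init: tuple[float, float] | None = None,
    magnitude: bool = False,
) -> FitResult:
    """Two-parameter (T1, M0) Levenberg-Marquardt fit of signed IR-SE data.

    ``magnitude=True`` fits |S| for magnitude-reconstructed references.
    Default initialisation: T1 = TI at the minimum |signal| / ln 2 (the
    null-point identity) and M0 = max |signal|.
    """
    protocol = protocol or IrSeProtocol()
    signals = np.asarray(signals, dtype=float)
    tis = np.asarray(protocol.tis_ms, dtype=float)
    if signals.shape != tis.shape:
        raise ValueError("one signal per TI required")
    if len(tis) < 3:
        raise ValueError("need at least 3 TIs")
    if init is None:
        init = (tis[np.argmin(np.abs(signals))] / np.log(2), np.max(np.abs(signals)))

    def residuals(p):
        model = ir_se_signal(tis, max(p[0], 1e-6), p[1], protocol.tr_ms)
        if magnitude:
            model = np.abs(model)
        return model - signals

    sol = optimize.least_squares(
        residuals, x0=np.asarray(init, dtype=float), method="lm",
        xtol=1e-10, ftol=1e-10, gtol=1e-10,
    )
    if not sol.success:
        warnings.warn("IR-SE fit did not converge")
    return FitResult(t1=float(sol.x[0]), m0=float(sol.x[1]), converged=bool(sol.success))


def fit_t1rho_monoexp(
    signals, protocol: T1rhoSeProtocol | None = None
) -> FitResult:
    """Log-linear least-squares fit of S(TSL) = M0 exp(-TSL/T1rho).

    Non-positive samples are excluded from the log; fewer than two remaining
    points is an error.
    """
    protocol = protocol or T1rhoSeProtocol()
    signals = np.asarray(signals, dtype=float)
    tsls = np.asarray(protocol.tsls_ms, dtype=float)
    if signals.shape != tsls.shape:
        raise ValueError("one signal per TSL required")
    ok = signals > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive signals for the log fit")
    slope, intercept = np.polyfit(tsls[ok], np.log(signals[ok]), 1)
    if slope >= 0:
        warnings.warn("non-decaying T1rho signal")
        return FitResult(t1=np.inf, m0=float(np.exp(intercept)), converged=False)
    return FitResult(t1=float(-1.0 / slope), m0=float(np.exp(intercept)))


@dataclass
class AgreementReport:
    """Regression + Bland-Altman agreement between two sets of ROI means."""

    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    n_points: int
    table: pd.DataFrame = field(repr=False, default=None)
    filter_t1_ms: float = 1300.0
    filter_t1rho_ms: float = 150.0


def roi_stats(volume: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample SD and CV (%) of a map inside an ROI."""
    vals = np.asarray(volume)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return mean, sd, cv


def roi_compare(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    masks: list[np.ndarray],
    filter_t1_ms: float = 1300.0,
    filter_t1rho_ms: float | None = None,
    filter_values_b: np.ndarray | None = None,
) -> AgreementReport:
    """Per-ROI agreement of map A against reference map B.

    The vial filter is applied on the reference ROI means: vials above
    ``filter_t1_ms`` are excluded (pass ``filter_t1rho_ms`` with
    ``filter_values_b`` holding the reference T1rho ROI means to apply the
    joint T1/T1rho filter). Empty ROIs are excluded with a warning.
    """
    rows = []
    for i, mask in enumerate(masks):
        try:
            mean_a, sd_a, cv_a = roi_stats(maps_a, mask)
            mean_b, sd_b, cv_b = roi_stats(maps_b, mask)
        except ValueError:
            warnings.warn(f"ROI {i} is empty; excluded")
            continue
        rows.append(
            {
                "roi": i,
                "mean_a": mean_a, "sd_a": sd_a, "cv_a": cv_a,
                "mean_b": mean_b, "sd_b": sd_b, "cv_b": cv_b,
            }
        )
    table = pd.DataFrame(rows)
    keep = table["mean_b"] <= filter_t1_ms
    if filter_t1rho_ms is not None and filter_values_b is not None:
        keep &= np.asarray(filter_values_b)[table["roi"]] <= filter_t1rho_ms
    sel = table[keep]
    a = sel["mean_a"].to_numpy()
    b = sel["mean_b"].to_numpy()
    if len(sel) < 2:
        raise ValueError("fewer than 2 ROIs remain after filtering")
    if np.allclose(b, b[0]):
        slope, intercept, r2 = np.nan, np.nan, np.nan
    else:
        res = stats.linregress(b, a)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return AgreementReport(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_points=int(len(sel)),
        table=table,
        filter_t1_ms=filter_t1_ms,
        filter_t1rho_ms=filter_t1rho_ms if filter_t1rho_ms is not None else 150.0,
    )


__all__ = [
    "IrSeProtocol",
    "T1rhoSeProtocol",
    "ir_se_signal",
    "FitResult",
    "fit_ir_se",
    "fit_t1rho_monoexp",
    "AgreementReport",
    "roi_stats",
    "roi_compare",
    "DEFAULT_IR_TIS_MS",
    "DEFAULT_T1RHO_TSLS_MS",
]
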