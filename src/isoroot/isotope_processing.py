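"""Calibration of raw vapour-phase laser-spectrometer readings to liquid δ18O.

In-situ probes deliver water vapour in isotopic equilibrium with soil or
xylem water to a cavity ring-down analyser.  Turning the raw vapour δ18O
stream into liquid-equivalent values requires three corrections:

1. a water-vapour-concentration-dependent bias correction, derived once
   from a laboratory dilution series of water with known δ18O and fitted
   with a four-parameter logistic curve;
2. a two-point linear calibration against a pair of on-site standards of
   known isotopic composition, repeated every measurement cycle;
3. the temperature-dependent liquid–vapour equilibrium fractionation
   (Majoube coefficients), converting vapour δ to the liquid it
   equilibrated with.

Quality control annotates, never deletes: readings below a concentration
floor or with an elevated spectral residual (a symptom of organic
contamination) are flagged and excluded from daily means by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Flag, auto
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "QCFlag",
    "ProbeReading",
    "CorrectionCurve",
    "CycleCalibration",
    "fit_concentration_correction",
    "calibrate_cycle",
    "calibrate_series",
    "vapour_to_liquid",
    "liquid_to_vapour",
    "equilibrium_alpha",
    "qc_flags",
    "daily_summaries",
    "method_comparison",
]

#: Default concentration floor (ppm) below which precision degrades.
DEFAULT_PPM_FLOOR = 6000.0

#: Default known δ18O (‰ VSMOW) of the two on-site calibration standards.
DEFAULT_STANDARD_KNOWNS = (-4.4, -19.5)

#: Default reference water δ18O (‰) used for the lab dilution series.
DEFAULT_REFERENCE_DELTA = -8.2


class QCFlag(Flag):
    """Per-reading quality-control annotations."""

    NONE = 0
    LOW_PPM = auto()
    CONTAMINATED = auto()
    STANDARD = auto()
    INHERITED_CALIBRATION = auto()


@dataclass(frozen=True)
class ProbeReading:
    """One raw vapour-phase measurement."""

    probe_id: str
    timestamp: pd.Timestamp
    delta_vapour: float  # ‰ vs VSMOW
    h2o_ppm: float
    r_s: float  # spectral residual (dimensionless)
    temperature: float  # °C at the probe
    flags: QCFlag = QCFlag.NONE

    def __post_init__(self) -> None:
        if not self.h2o_ppm > 0:
            raise ValueError(f"h2o_ppm must be positive, got {self.h2o_ppm}")


def _logistic4(ppm: np.ndarray, lower: float, upper: float, inflection: float, slope: float) -> np.ndarray:
    """Four-parameter logistic: lower + (upper - lower) / (1 + (ppm/inflection)^slope)."""
    return lower + (upper - lower) / (1.0 + (ppm / inflection) ** slope)


@dataclass(frozen=True)
class CorrectionCurve:
    """Concentration-dependent bias model fitted to a lab dilution series.

    The fitted curve predicts the *measured* δ18O of reference water as a
    function of water-vapour concentration; the correction at a given ppm
    is ``reference_delta - fitted(ppm)`` and is *added* to raw readings.
    """

    lower: float
    upper: float
    inflection: float
    slope: float
    reference_delta: float = DEFAULT_REFERENCE_DELTA
    r_squared: float = float("nan")

    def fitted(self, ppm: np.ndarray | float) -> np.ndarray | float:
        return _logistic4(np.asarray(ppm, dtype=float), self.lower, self.upper, self.inflection, self.slope)

    def correction(self, ppm: np.ndarray | float) -> np.ndarray | float:
        """Additive correction (‰) at the given vapour concentration."""
        return self.reference_delta - self.fitted(ppm)

    def apply(self, delta_vapour: np.ndarray | float, ppm: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(delta_vapour, dtype=float) + self.correction(ppm)


def fit_concentration_correction(
    cal_readings: Sequence[tuple[float, float]],
    known_delta: float = DEFAULT_REFERENCE_DELTA,
    r2_warn: float = 0.99,
) -> CorrectionCurve:
    """Fit the 4-parameter logistic bias curve from (ppm, measured ‰) pairs.

    Parameters
    ----------
    cal_readings
        Laboratory calibration pairs spanning the instrument's working
        concentration range (at least six readings over a ≥ 3-fold span).
    known_delta
        True δ18O (‰) of the reference water used in the dilution series.
    r2_warn
        Emit a warning if the fit's R² falls below this value.
    """
    arr = np.asarray(cal_readings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 6:
        raise ValueError("need at least 6 (ppm, delta) calibration readings")
    ppm, measured = arr[:, 0], arr[:, 1]
    if ppm.min() <= 0:
        raise ValueError("ppm values must be positive")
    if ppm.max() / ppm.min() < 3.0:
        raise ValueError(
            f"degenerate ppm range [{ppm.min():.0f}, {ppm.max():.0f}]: "
            "calibration series must span at least a 3-fold concentration range"
        )

    # Initial guesses: asymptotes from the ppm extremes, inflection at the
    # geometric mid-range.
    order = np.argsort(ppm)
    p0 = (
        float(np.mean(measured[order[:3]])),
        float(np.mean(measured[order[-3:]])),
        float(np.sqrt(ppm.min() * ppm.max())),
        1.5,
    )
    try:
        popt, _ = optimize.curve_fit(
            _logistic4,
            ppm,
            measured,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-6, 1e-3], [np.inf, np.inf, 1e7, 50.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data pathology
        raise RuntimeError(f"concentration-correction logistic fit failed to converge: {exc}") from exc

    fitted = _logistic4(ppm, *popt)
    ss_res = float(np.sum((measured - fitted) ** 2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < r2_warn:
        warnings.warn(
            f"concentration-correction fit R²={r2:.4f} below {r2_warn}", stacklevel=2
        )
    return CorrectionCurve(*map(float, popt), reference_delta=known_delta, r_squared=r2)


@dataclass(frozen=True)
class CycleCalibration:
    """Two-point linear map from measured to known standard values for one cycle."""

    cycle: int
    known: tuple[float, float]
    measured: tuple[float, float]
    inherited: bool = False

    def __post_init__(self) -> None:
        if math.isclose(self.measured[0], self.measured[1]):
            raise ValueError(
                f"cycle {self.cycle}: identical measured standard values "
                f"({self.measured[0]}) give a degenerate calibration map"
            )

    @property
    def slope(self) -> float:
        return (self.known[0] - self.known[1]) / (self.measured[0] - self.measured[1])

    @property
    def intercept(self) -> float:
        return self.known[0] - self.slope * self.measured[0]

    def apply(self, delta: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(delta, dtype=float) + self.intercept


def calibrate_cycle(
    standard_readings: Sequence[tuple[float, float]],
    sample_readings: Sequence[float],
    cycle: int = 0,
) -> tuple[np.ndarray, CycleCalibration]:
    """Apply the two-point standard calibration of one measurement cycle.

    ``standard_readings`` is a pair of ``(known, measured)`` tuples (‰).
    Returns the calibrated sample values and the calibration used.
    """
    if len(standard_readings) != 2:
        raise ValueError("exactly two standard readings are required per cycle")
    (k1, m1), (k2, m2) = standard_readings
    if math.isclose(k1, k2):
        raise ValueError("the two standards must have distinct known values")
    cal = CycleCalibration(cycle=cycle, known=(k1, k2), measured=(m1, m2))
    return np.asarray(cal.apply(np.asarray(sample_readings, dtype=float))), cal


def calibrate_series(
    samples: pd.DataFrame,
    standards: pd.DataFrame,
    delta_col: str = "delta_vapour",
) -> pd.DataFrame:
    """Calibrate a season of readings cycle by cycle.

    Both frames need a ``cycle`` column; ``standards`` additionally needs
    ``known`` (‰).  Cycles without a complete standard pair inherit the
    nearest-in-time complete calibration and are flagged ``inherited``.
    """
    cals: dict[int, CycleCalibration] = {}
    for cyc, grp in standards.groupby("cycle"):
        if grp["known"].nunique() == 2:
            pair = grp.groupby("known")[delta_col].mean()
            knowns = tuple(pair.index)
            measured = tuple(pair.values)
            try:
                cals[int(cyc)] = CycleCalibration(int(cyc), knowns, measured)
            except ValueError:
                continue
    if not cals:
        raise ValueError("no cycle has a complete pair of standard readings")
    cal_cycles = np.array(sorted(cals))

    out = samples.copy()
    calibrated = np.empty(len(out), dtype=float)
    inherited = np.zeros(len(out), dtype=bool)
    for cyc, idx in out.groupby("cycle").indices.items():
        if int(cyc) in cals:
            cal = cals[int(cyc)]
            inh = False
        else:
            nearest = cal_cycles[np.argmin(np.abs(cal_cycles - int(cyc)))]
            cal, inh = cals[int(nearest)], True
        calibrated[idx] = cal.apply(out[delta_col].to_numpy()[idx])
        inherited[idx] = inh
    out["delta_calibrated"] = calibrated
    out["calibration_inherited"] = inherited
    return out


def equilibrium_alpha(temperature_c: np.ndarray | float) -> np.ndarray | float:
    """Liquid–vapour equilibrium fractionation factor α(T) for 18O/16O.

    Majoube (1971) liquid–vapour coefficients:
    1000·ln α = 1.137·(10⁶/T²) − 0.4156·(10³/T) − 2.0667, T in kelvin.
    """
    t = np.asarray(temperature_c, dtype=float) + 273.15
    ln_alpha = (1.137e6 / t**2 - 0.4156e3 / t - 2.0667) / 1000.0
    return np.exp(ln_alpha)


def _check_temperature(temperature_c: np.ndarray | float) -> None:
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t < -10.0) or np.any(t > 50.0):
        raise ValueError("temperature outside the valid range [-10, 50] °C")


def vapour_to_liquid(
    delta_vapour: np.ndarray | float,
    temperature_c: np.ndarray | float,
    alpha_override: float | None = None,
) -> np.ndarray | float:
    """Convert vapour δ18O to the equilibrated liquid value at temperature T.

    δ_l = (δ_v + 1000)·α(T) − 1000.  ``alpha_override`` bypasses the
    Majoube factor (test hook; ``alpha_override=1`` is the identity).
    """
    _check_temperature(temperature_c)
    alpha = alpha_override if alpha_override is not None else equilibrium_alpha(temperature_c)
    return (np.asarray(delta_vapour, dtype=float) + 1000.0) * alpha - 1000.0


def liquid_to_vapour(
    delta_liquid: np.ndarray | float,
    temperature_c: np.ndarray | float,
    alpha_override: float | None = None,
) -> np.ndarray | float:
    """Inverse of :func:`vapour_to_liquid`."""
    _check_temperature(temperature_c)
    alpha = alpha_override if alpha_override is not None else equilibrium_alpha(temperature_c)
    return (np.asarray(delta_liquid, dtype=float) + 1000.0) / alpha - 1000.0


def qc_flags(
    reading: ProbeReading,
    standards_rs_mean: float,
    standards_rs_sd: float,
    ppm_floor: float = DEFAULT_PPM_FLOOR,
) -> QCFlag:
    """Derive QC flags for one reading.

    LOW_PPM below the concentration floor; CONTAMINATED when the spectral
    residual exceeds the mean + 1 SD of the regularly measured standards.
    Flags annotate readings; they never remove them from the record.
    """
    if not (math.isfinite(standards_rs_mean) and math.isfinite(standards_rs_sd)):
        raise ValueError("spectral-residual thresholds must be finite")
    flags = reading.flags
    if reading.h2o_ppm < ppm_floor:
        flags |= QCFlag.LOW_PPM
    if reading.r_s > standards_rs_mean + standards_rs_sd:
        flags |= QCFlag.CONTAMINATED
    return flags


def daily_summaries(
    calibrated: pd.DataFrame,
    min_n: int = 3,
    exclude_flagged: bool = True,
    delta_col: str = "delta_liquid",
) -> pd.DataFrame:
    """Aggregate calibrated liquid δ18O per probe and calendar day.

    Expects columns ``probe_id``, ``timestamp``, ``delta_liquid`` and
    (optionally) boolean ``low_ppm`` / ``contaminated``.  Flagged readings
    are excluded from means when ``exclude_flagged``; days retaining fewer
    than ``min_n`` readings are marked ``low_n`` (a day whose readings are
    all flagged is kept with n = 0 rather than dropped).
    """
    cols = ["probe_id", "day", delta_col]
    if calibrated.empty:
        return pd.DataFrame(columns=["probe_id", "day", "mean", "sd", "n", "low_n"])
    df = calibrated.copy()
    df["day"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    ok = pd.Series(True, index=df.index)
    if exclude_flagged:
        for c in ("low_ppm", "contaminated"):
            if c in df.columns:
                ok &= ~df[c].astype(bool)
    kept = df[ok]
    grouped = kept.groupby(["probe_id", "day"])[delta_col]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    # reinstate fully-flagged probe-days with n = 0
    all_days = df[["probe_id", "day"]].drop_duplicates()
    summary = all_days.merge(summary, on=["probe_id", "day"], how="left")
    summary["n"] = summary["n"].fillna(0).astype(int)
    summary["low_n"] = summary["n"] < min_n
    return summary.sort_values(["probe_id", "day"]).reset_index(drop=True)


def method_comparison(paired: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Compare in-situ against reference (e.g. IRMS) measurements.

    Ordinary least squares of in-situ on reference values; reports the
    regression line, R², the mean bias (in-situ − reference) and the
    Euclidean distance of (slope, intercept) from the 1:1 line.
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("method comparison requires at least 3 paired measurements")
    in_situ, reference = arr[:, 0], arr[:, 1]
    res = stats.linregress(reference, in_situ)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "mean_bias": float(np.mean(in_situ - reference)),
        "distance_from_identity": float(math.hypot(res.slope - 1.0, res.intercept)),
        "n": float(arr.shape[0]),
    }
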