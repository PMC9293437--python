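"""Tree water status: VPD, tree water deficit, transpiration, drought windows.

Stem-radius traces from point dendrometers are separated into irreversible
growth (GRO, the running-maximum envelope) and reversible tree water
deficit (TWD, shrinkage below that envelope) under the zero-growth
assumption: no cell expansion occurs while the stem is shrunk below its
historical maximum.  Whole-tree transpiration is sap flux density times
sapwood area, normalised by crown projection area to mm per day.  A
drought period is segmented from the joint behaviour of TWD, topsoil
water content and precipitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TreeDay",
    "DroughtSegmentation",
    "MAGNUS_COEFFICIENTS",
    "saturation_vapour_pressure",
    "compute_vpd",
    "compute_twd",
    "sapwood_area_from_dbh",
    "daily_transpiration",
    "classify_drought_period",
]

#: Magnus-type constants (kPa, –, °C) for saturation vapour pressure.
MAGNUS_COEFFICIENTS = (0.6108, 17.27, 237.3)


@dataclass(frozen=True)
class TreeDay:
    """Daily per-tree state."""

    tree_id: str
    date: pd.Timestamp
    transpiration: float  # mm d⁻¹, ground-area based
    twd: float  # µm, daily mean
    xylem_delta: float  # ‰
    xylem_delta_sd: float  # ‰
    dbh: float = float("nan")  # cm
    sapwood_area: float = float("nan")  # cm²
    crown_area: float = float("nan")  # m²

    def __post_init__(self) -> None:
        if self.transpiration < 0:
            raise ValueError("transpiration must be non-negative")
        if self.twd < 0:
            raise ValueError("TWD must be non-negative")


@dataclass(frozen=True)
class DroughtSegmentation:
    """Detected drought window and the thresholds that produced it."""

    start: pd.Timestamp | None
    end: pd.Timestamp | None
    twd_threshold: float  # µm
    vwc_threshold: float  # m³ m⁻³
    rain_threshold: float  # mm per 24 h
    end_is_season_end: bool = False

    @property
    def detected(self) -> bool:
        return self.start is not None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and not self.start < self.end:
            raise ValueError("drought start must precede end")


def saturation_vapour_pressure(t_air: np.ndarray | float) -> np.ndarray | float:
    """Magnus-type saturation vapour pressure e_s(T) in kPa."""
    a, b, c = MAGNUS_COEFFICIENTS
    t = np.asarray(t_air, dtype=float)
    return a * np.exp(b * t / (t + c))


def compute_vpd(t_air: np.ndarray | float, rh: np.ndarray | float) -> np.ndarray | float:
    """Vapour pressure deficit (kPa) from air temperature (°C) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return saturation_vapour_pressure(t_air) * (1.0 - rh_arr / 100.0)


def compute_twd(stem_radius: pd.Series) -> pd.DataFrame:
    """Split a stem-radius series (µm) into TWD and GRO (zero-growth concept).

    TWD_t = running-max(SR)_t − SR_t; GRO_t = running-max(SR)_t − SR_0.
    The running maximum carries across gaps; SR itself is not interpolated.

    Returns a DataFrame indexed like the input with columns ``twd`` and
    ``gro``.
    """
    if len(stem_radius) == 0:
        raise ValueError("stem-radius series is empty")
    sr = stem_radius.astype(float)
    if not sr.index.is_monotonic_increasing:
        raise ValueError("stem-radius series must be time-sorted")
    running_max = np.maximum.accumulate(sr.to_numpy())
    twd = running_max - sr.to_numpy()
    gro = running_max - sr.to_numpy()[0]
    return pd.DataFrame({"twd": twd, "gro": gro}, index=sr.index)


def daily_mean_twd(stem_radius: pd.Series) -> pd.Series:
    """Daily mean TWD (µm) from a sub-daily stem-radius series."""
    twd = compute_twd(stem_radius)["twd"]
    return twd.groupby(twd.index.normalize()).mean()


def sapwood_area_from_dbh(dbh: float, a: float, b: float) -> float:
    """Sapwood area (cm²) from diameter at breast height via SA = a·dbh^b.

    The allometry coefficients are site-specific and must be supplied;
    there is no universal default.
    """
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    if a <= 0 or b <= 0:
        raise ValueError("allometry coefficients must be positive")
    return a * dbh**b


def daily_transpiration(
    fd: pd.Series,
    sapwood_area: float,
    crown_area: float,
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Ground-area transpiration E (mm d⁻¹) from sap flux density.

    ``fd`` is sap flux density (l cm⁻² s⁻¹) on a regular sub-daily index.
    Whole-tree sap flow T_t = FD × SA (l s⁻¹) is integrated over each
    calendar day and divided by the crown projection area (1 l m⁻² = 1 mm).
    Days missing more than ``max_missing_fraction`` of their expected
    steps are flagged, not dropped.
    """
    if sapwood_area <= 0 or crown_area <= 0:
        raise ValueError("sapwood and crown areas must be positive")
    vals = fd.astype(float)
    if np.any(vals.to_numpy() < 0):
        raise ValueError("sap flux density must be non-negative")
    if len(vals) < 2:
        raise ValueError("need at least two FD samples to infer the timestep")
    step_s = (vals.index[1] - vals.index[0]).total_seconds()
    expected_per_day = round(86400.0 / step_s)
    day = vals.index.normalize()
    litres = vals * sapwood_area * step_s  # l per step
    daily = litres.groupby(day).sum() / crown_area
    n = vals.groupby(day).count()
    flagged = n < (1.0 - max_missing_fraction) * expected_per_day
    return pd.DataFrame({"e_mm": daily, "n_steps": n, "incomplete": flagged})


def classify_drought_period(
    daily_twd: pd.DataFrame,
    daily_topsoil_vwc: pd.Series,
    daily_precip: pd.Series,
    twd_threshold: float = 100.0,
    vwc_threshold: float = 0.12,
    rain_threshold: float = 20.0,
    require_vwc: bool = True,
) -> DroughtSegmentation:
    """Segment the drought period from daily series.

    Start: first day on which *any* tree's daily mean TWD (columns of
    ``daily_twd``, µm) exceeds ``twd_threshold`` while the topsoil VWC is
    below ``vwc_threshold`` (the VWC conjunct can be disabled).  End: the
    first subsequent day with 24-h precipitation ≥ ``rain_threshold`` mm;
    if none occurs, the season end is used and a warning issued.
    """
    idx = daily_twd.index.intersection(daily_topsoil_vwc.index).intersection(daily_precip.index)
    if len(idx) == 0:
        raise ValueError("daily series share no common dates")
    twd = daily_twd.loc[idx]
    vwc = daily_topsoil_vwc.loc[idx]
    rain = daily_precip.loc[idx]

    exceed = (twd > twd_threshold).any(axis=1)
    if require_vwc:
        exceed &= vwc < vwc_threshold
    if not exceed.any():
        return DroughtSegmentation(None, None, twd_threshold, vwc_threshold, rain_threshold)
    start = exceed.idxmax()

    after = rain.loc[rain.index > start]
    heavy = after[after >= rain_threshold]
    if len(heavy) == 0:
        warnings.warn(
            f"no 24-h precipitation ≥ {rain_threshold} mm after drought onset; "
            "using season end as drought end",
            stacklevel=2,
        )
        return DroughtSegmentation(start, idx[-1], twd_threshold, vwc_threshold, rain_threshold, True)
    return DroughtSegmentation(start, heavy.index[0], twd_threshold, vwc_threshold, rain_threshold)
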