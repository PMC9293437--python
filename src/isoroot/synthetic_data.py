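"""Synthetic drought–recovery season with known ground truth.

Everything the field campaign measured is emulated here so that each
downstream stage — calibration, water-status extraction, mixing-model
inference, uptake partitioning — can be tested against a known answer:

* meteorological forcing (diurnal air temperature and humidity, stochastic
  precipitation with per-event δ18O, a rain-free drought window broken by
  one large drought-ending event);
* a layered soil-bucket model (infiltration, downward displacement
  drainage, root uptake, topsoil evaporation with linear evaporative
  δ18O enrichment) whose water balance closes to numerical precision;
* tree states: daily transpiration responding to evaporative demand and
  topsoil moisture, tree water deficit, and xylem δ18O formed as the
  concentration-weighted mixture of the soil sources under a prescribed
  daily uptake-proportion trajectory;
* raw instrument streams produced by inverting the calibration chain:
  vapour-phase probe readings on the 13-probe × 10-min cycle schedule
  (with per-cycle calibration drift, a concentration-dependent bias curve
  and Gaussian measurement noise), dendrometer stem-radius traces, and
  sap-flux-density series.

The prescribed uptake trajectory mimics the observed regime: roughly half
of the water from the topsoil before the drought, declining to ~0.16 at
the drought end, recovering over about three weeks after rewetting.

All randomness flows from one root seed through named child streams, so
regenerating with the same configuration is byte-identical and adding a
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isotope_processing import liquid_to_vapour
from .mixing_model import concentration_adjust
from .tree_water_status import compute_vpd

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_root_profile",
    "default_proportion_nodes",
    "simulate_forcing",
    "simulate_soil",
    "SoilColumn",
    "generate_season",
    "emit_observations",
]

#: Fine-root biomass fractions per 5-cm bin, 0–50 cm (percent / 100).
#: 41 % of fine roots in 0–10 cm, 58 % in 0–15 cm, 12 % below 35 cm.
_DEFAULT_ROOT_PROFILE = (0.22, 0.19, 0.17, 0.10, 0.08, 0.07, 0.05, 0.05, 0.04, 0.03)


def default_root_profile() -> np.ndarray:
    """Default monotone fine-root biomass profile per 5-cm bin, 0–50 cm."""
    return np.asarray(_DEFAULT_ROOT_PROFILE, dtype=float)


#: Weekly-mean uptake proportions anchoring the prescribed trajectory:
#: pre-drought / end-of-drought / three-weeks-after-rewetting.
_P_PRE = (0.54, 0.23, 0.15, 0.08)
_P_DROUGHT_END = (0.16, 0.32, 0.29, 0.23)
_P_RECOVERED = (0.34, 0.35, 0.20, 0.11)


def default_proportion_nodes(
    season_start: date, season_end: date, drought_window: tuple[date, date]
) -> tuple[tuple[date, tuple[float, ...]], ...]:
    """Piecewise-linear node set for the true daily uptake proportions."""
    d0, d1 = drought_window
    decline_start = min(d0 + timedelta(days=25), d1 - timedelta(days=1))
    recovered = min(d1 + timedelta(days=21), season_end)
    nodes = [
        (season_start, _P_PRE),
        (decline_start, _P_PRE),
        (d1, _P_DROUGHT_END),
        (recovered, _P_RECOVERED),
        (season_end, _P_RECOVERED),
    ]
    # drop duplicate / out-of-order dates that degenerate windows can create
    out: list[tuple[date, tuple[float, ...]]] = []
    for d, p in nodes:
        if not out or d > out[-1][0]:
            out.append((d, p))
    return tuple(out)


@dataclass(frozen=True)
class InstrumentBias:
    """Parameters of the inverse calibration chain applied by the emitter.

    ``reported = slope_c · δ_v + offset_c + bias(ppm) + N(0, noise)`` with
    per-cycle slope/offset drift and a four-parameter-logistic
    concentration bias that vanishes at high vapour concentration.
    """

    cycle_offset_sd: float = 0.08  # ‰
    cycle_slope_sd: float = 0.004
    bias_amplitude: float = 2.5  # ‰ at the low-ppm asymptote
    bias_inflection_ppm: float = 4000.0
    bias_slope: float = 2.0

    def bias(self, ppm: np.ndarray | float) -> np.ndarray | float:
        ppm = np.asarray(ppm, dtype=float)
        return self.bias_amplitude / (1.0 + (ppm / self.bias_inflection_ppm) ** self.bias_slope)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic season."""

    season_start: date = date(2018, 5, 10)
    season_end: date = date(2018, 9, 16)
    timestep_min: int = 10
    n_trees: int = 3
    depths_cm: tuple[float, ...] = (5.0, 15.0, 30.0, 45.0)
    layer_boundaries_cm: tuple[float, ...] = (0.0, 10.0, 22.5, 37.5, 50.0)
    root_profile: tuple[float, ...] = _DEFAULT_ROOT_PROFILE
    drought_window: tuple[date, date] = (date(2018, 6, 29), date(2018, 8, 23))
    proportion_nodes: tuple[tuple[date, tuple[float, ...]], ...] | None = None
    noise_delta: float = 0.3  # ‰, instrument measurement noise
    instrument_bias: InstrumentBias = field(default_factory=InstrumentBias)
    # forcing
    rain_prob_per_day: float = 0.35
    rain_mean_mm: float = 7.0
    drought_event_mm: float = 39.0
    drought_event_delta: float = -7.9
    precip_delta_range: tuple[float, float] = (-8.7, -1.4)
    # soil
    porosity: float = 0.45
    field_capacity: float = 0.33
    residual_vwc: float = 0.05
    initial_vwc: tuple[float, ...] = (0.30, 0.31, 0.32, 0.32)
    initial_delta: tuple[float, ...] = (-9.0, -9.8, -10.4, -11.0)
    evap_coefficient: float = 0.6  # mm d⁻¹ kPa⁻¹ at full topsoil wetness
    enrichment_per_mm: float = 0.4  # ‰ of topsoil δ18O per mm evaporated
    # trees
    e_max: float = 5.4  # mm d⁻¹ asymptotic transpiration
    e_vpd_scale: float = 0.6  # kPa
    soil_limitation_floor: float = 0.25
    twd_vpd_um_per_kpa: float = 57.0  # µm of stem shrinkage per kPa demand
    twd_dryness_um: float = 13.0  # µm added at full topsoil dryness
    tree_delta_sd: float = 0.15  # ‰ day-to-day per-tree xylem deviation
    sapwood_areas_cm2: tuple[float, ...] = (350.0, 430.0, 510.0)
    crown_areas_m2: tuple[float, ...] = (41.4, 45.0, 49.4)
    dbh_cm: tuple[float, ...] = (31.5, 39.0, 47.2)
    seed: int = 0

    def __post_init__(self) -> None:
        profile = np.asarray(self.root_profile, dtype=float)
        if abs(profile.sum() - 1.0) > 1e-9:
            raise ValueError("root_profile must sum to 1")
        if np.any(np.diff(profile) > 1e-12):
            raise ValueError("root_profile must be non-increasing with depth")
        bounds = np.asarray(self.layer_boundaries_cm, dtype=float)
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("layer_boundaries_cm must be strictly increasing")
        d0, d1 = self.drought_window
        if not (self.season_start <= d0 < d1 <= self.season_end):
            raise ValueError("drought_window must lie within the season")
        for _, p in self.nodes:
            arr = np.asarray(p, dtype=float)
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("every proportion node must lie on the simplex")
            if len(arr) != self.n_layers:
                raise ValueError("proportion nodes must have one entry per soil layer")

    @property
    def n_layers(self) -> int:
        return len(self.layer_boundaries_cm) - 1

    @property
    def layer_thickness_cm(self) -> np.ndarray:
        return np.diff(np.asarray(self.layer_boundaries_cm, dtype=float))

    @property
    def nodes(self) -> tuple[tuple[date, tuple[float, ...]], ...]:
        if self.proportion_nodes is not None:
            return self.proportion_nodes
        return default_proportion_nodes(self.season_start, self.season_end, self.drought_window)

    @property
    def n_days(self) -> int:
        return (self.season_end - self.season_start).days + 1

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.season_start, self.season_end, freq="D")

    @property
    def steps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            pd.Timestamp(self.season_start),
            pd.Timestamp(self.season_end) + pd.Timedelta(days=1) - pd.Timedelta(minutes=self.timestep_min),
            freq=f"{self.timestep_min}min",
        )

    def child_rng(self, tag: str) -> np.random.Generator:
        """Deterministic per-component random stream."""
        tag_int = int.from_bytes(tag.encode(), "little") % (2**31)
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence([self.seed, tag_int])))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one generated season."""

    config: SimConfig
    dates: pd.DatetimeIndex
    steps: pd.DatetimeIndex
    p_true: np.ndarray  # (n_days, K) prescribed uptake proportions
    vwc_daily: np.ndarray  # (n_days, K)
    delta_daily: np.ndarray  # (n_days, K) soil liquid δ18O
    vwc_steps: np.ndarray  # (n_steps, K)
    delta_steps: np.ndarray  # (n_steps, K)
    soil_temp_steps: np.ndarray  # (n_steps, K) °C
    stem_temp_steps: np.ndarray  # (n_steps,) °C
    transpiration: np.ndarray  # (n_days, n_trees) mm d⁻¹ ground-area
    twd: np.ndarray  # (n_days, n_trees) µm daily mean
    xylem_delta: np.ndarray  # (n_days, n_trees) ‰ liquid
    events: pd.DataFrame  # precipitation events: date, mm, delta
    forcing: pd.DataFrame  # per-step t_air, rh, precip_mm, vpd
    water_balance: Mapping[str, float]
    seed: int


def _interp_proportions(config: SimConfig) -> np.ndarray:
    """Daily true proportions by piecewise-linear interpolation of the nodes."""
    nodes = config.nodes
    node_days = np.array([(d - config.season_start).days for d, _ in nodes], dtype=float)
    node_p = np.array([p for _, p in nodes], dtype=float)
    days = np.arange(config.n_days, dtype=float)
    out = np.empty((config.n_days, config.n_layers))
    for k in range(config.n_layers):
        out[:, k] = np.interp(days, node_days, node_p[:, k])
    return out / out.sum(axis=1, keepdims=True)


def _soil_temperature(config: SimConfig, t_air: np.ndarray, steps: pd.DatetimeIndex) -> np.ndarray:
    """Depth-damped, lagged soil temperature per probe depth."""
    frac = (steps.hour * 60 + steps.minute).to_numpy() / 1440.0
    day_idx = (steps.normalize() - steps[0].normalize()).days.to_numpy()
    seasonal = pd.Series(t_air).groupby(day_idx).transform("mean").to_numpy()
    out = np.empty((len(steps), len(config.depths_cm)))
    for j, depth in enumerate(config.depths_cm):
        damp = np.exp(-depth / 15.0)
        diurnal = 4.0 * damp * np.sin(2 * np.pi * (frac - 0.625 - depth / 200.0))
        out[:, j] = 0.75 * seasonal + 0.25 * 14.0 + diurnal
    return out


def simulate_forcing(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Meteorological forcing at the model timestep plus the event table.

    Air temperature follows a seasonal course (warm plateau inside the
    drought window) with a diurnal sinusoid; relative humidity moves in
    anti-phase.  Precipitation events are drawn daily outside the drought
    window and suppressed inside it, except the single drought-ending
    event placed on the window's last day.  Event δ18O is uniform on the
    configured range.
    """
    rng = config.child_rng("forcing")
    steps = config.steps
    n = len(steps)
    day_idx = (steps.normalize() - steps[0].normalize()).days.to_numpy()
    frac = (steps.hour * 60 + steps.minute).to_numpy() / 1440.0

    d0 = (config.drought_window[0] - config.season_start).days
    d1 = (config.drought_window[1] - config.season_start).days
    n_days = config.n_days

    seasonal = np.full(n_days, 17.0)
    ramp = np.clip((np.arange(n_days) - (d0 - 14)) / 14.0, 0.0, 1.0)
    seasonal += 5.0 * ramp
    post = np.clip((np.arange(n_days) - d1) / 5.0, 0.0, 1.0)
    seasonal -= 6.0 * post
    seasonal += rng.normal(0.0, 1.2, size=n_days)

    t_air = seasonal[day_idx] + 6.0 * np.sin(2 * np.pi * (frac - 0.375))
    # drier air during the drought window (ramped in and out with temperature)
    rh_base = 78.0 - 16.0 * ramp + 14.0 * post
    rh = np.clip(
        rh_base[day_idx] - 28.0 * np.sin(2 * np.pi * (frac - 0.375)) + rng.normal(0, 3, n),
        20.0,
        100.0,
    )

    # precipitation events, one optional per day
    lo, hi = config.precip_delta_range
    events = []
    precip = np.zeros(n)
    steps_per_day = 1440 // config.timestep_min
    for d in range(n_days):
        in_drought = d0 <= d < d1
        is_ending = d == d1
        if is_ending:
            mm, delta = config.drought_event_mm, config.drought_event_delta
        elif in_drought or rng.uniform() > config.rain_prob_per_day:
            continue
        else:
            mm = float(np.clip(rng.gamma(1.5, config.rain_mean_mm / 1.5), 0.4, 60.0))
            delta = float(rng.uniform(lo, hi))
        start_frac = rng.uniform(0.0, 0.7)
        dur = max(1, int(steps_per_day * (0.25 if is_ending else 0.1)))
        s0 = d * steps_per_day + int(start_frac * steps_per_day)
        s1 = min(s0 + dur, n)
        precip[s0:s1] += mm / (s1 - s0)
        events.append({"date": pd.Timestamp(config.season_start) + pd.Timedelta(days=d), "mm": mm, "delta": delta})

    rh = np.where(precip > 0, np.clip(rh + 15.0, None, 100.0), rh)
    vpd = compute_vpd(t_air, rh)
    forcing = pd.DataFrame(
        {"t_air": t_air, "rh": rh, "precip_mm": precip, "vpd": vpd}, index=steps
    )
    event_df = pd.DataFrame(events, columns=["date", "mm", "delta"])
    return forcing, event_df


class SoilColumn:
    """Layered bucket model with isotope mass balance.

    State per layer: stored water V (mm) and liquid δ18O (‰).  Per step:
    infiltration mixes rain into the top layer (volume-weighted), excess
    above field capacity drains downward displacing water and its δ,
    root uptake removes water without fractionation, and evaporation
    (top layer only) removes water while enriching the remaining pool by
    a fixed ‰ per mm evaporated.  Stored water never drops below the
    residual moisture.  A running audit closes the water balance.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        thick_mm = config.layer_thickness_cm * 10.0  # cm soil → mm water per unit VWC
        self.thick_mm = thick_mm
        self.v = np.asarray(config.initial_vwc, dtype=float) * thick_mm
        self.delta = np.asarray(config.initial_delta, dtype=float).copy()
        self.v_res = config.residual_vwc * thick_mm
        self.v_fc = config.field_capacity * thick_mm
        self.v_sat = config.porosity * thick_mm
        self._initial_storage = float(self.v.sum())
        self.totals = {"precip": 0.0, "drainage": 0.0, "uptake": 0.0, "evaporation": 0.0}

    @property
    def vwc(self) -> np.ndarray:
        return self.v / self.thick_mm

    def step(self, precip_mm: float, precip_delta: float, uptake_mm: np.ndarray, evap_mm: float) -> np.ndarray:
        """Advance one timestep; returns the realised per-layer uptake (mm)."""
        uptake_mm = np.asarray(uptake_mm, dtype=float)
        if np.any(uptake_mm < 0):
            raise ValueError("uptake demand must be non-negative")
        k = len(self.v)
        # infiltration into the top layer, volume-weighted isotope mixing
        if precip_mm > 0:
            self.delta[0] = (self.v[0] * self.delta[0] + precip_mm * precip_delta) / (self.v[0] + precip_mm)
            self.v[0] += precip_mm
            self.totals["precip"] += precip_mm
        # drainage cascade: excess above field capacity displaces downward
        for j in range(k):
            excess = self.v[j] - self.v_fc[j]
            if excess > 0:
                self.v[j] -= excess
                if j + 1 < k:
                    self.delta[j + 1] = (self.v[j + 1] * self.delta[j + 1] + excess * self.delta[j]) / (
                        self.v[j + 1] + excess
                    )
                    self.v[j + 1] += excess
                else:
                    self.totals["drainage"] += excess
        # root uptake, non-fractionating, floored at residual moisture
        avail = np.maximum(self.v - self.v_res, 0.0)
        taken = np.minimum(uptake_mm, avail)
        self.v -= taken
        self.totals["uptake"] += float(taken.sum())
        # topsoil evaporation with linear enrichment
        evap = min(evap_mm, max(self.v[0] - self.v_res[0], 0.0))
        if evap > 0:
            self.v[0] -= evap
            self.delta[0] += self.config.enrichment_per_mm * evap
            self.totals["evaporation"] += evap
        return taken

    def balance(self) -> dict[str, float]:
        storage_change = float(self.v.sum()) - self._initial_storage
        residual = (
            self.totals["precip"]
            - self.totals["drainage"]
            - self.totals["uptake"]
            - self.totals["evaporation"]
            - storage_change
        )
        return dict(self.totals, storage_change=storage_change, residual=residual)


def simulate_soil(
    config: SimConfig,
    forcing: pd.DataFrame,
    events: pd.DataFrame,
    uptake_demand: np.ndarray,
    evap_demand: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Run the soil column over the season for a fixed uptake-demand path.

    ``uptake_demand`` has shape (n_steps, K) in mm per step.  Returns the
    per-step VWC and δ18O arrays plus the closing water balance.
    """
    demand = np.asarray(uptake_demand, dtype=float)
    steps = forcing.index
    if demand.shape != (len(steps), config.n_layers):
        raise ValueError("uptake_demand must have shape (n_steps, n_layers)")
    delta_by_day = {pd.Timestamp(r.date).normalize(): r.delta for r in events.itertuples()}
    col = SoilColumn(config)
    vwc = np.empty((len(steps), config.n_layers))
    delta = np.empty_like(vwc)
    precip = forcing["precip_mm"].to_numpy()
    evap = np.zeros(len(steps)) if evap_demand is None else np.asarray(evap_demand, dtype=float)
    days = steps.normalize()
    for i in range(len(steps)):
        p_delta = delta_by_day.get(days[i], -6.0)
        col.step(float(precip[i]), float(p_delta), demand[i], float(evap[i]))
        vwc[i] = col.vwc
        delta[i] = col.delta
    return vwc, delta, col.balance()


def generate_season(config: SimConfig = SimConfig()) -> SimTruth:
    """Generate the full coupled season (forcing → soil → trees).

    The soil, transpiration and tree-water-deficit states are advanced day
    by day so that transpiration can respond to the simulated topsoil
    moisture: E = E_max · (1 − exp(−VPD/s)) · f(topsoil wetness), split
    across layers by the prescribed proportions p*.
    """
    cfg = config
    forcing, events = simulate_forcing(cfg)
    rng = cfg.child_rng("trees")
    steps = cfg.steps
    steps_per_day = 1440 // cfg.timestep_min
    n_days, k, n_trees = cfg.n_days, cfg.n_layers, cfg.n_trees

    p_true = _interp_proportions(cfg)
    delta_by_day = {pd.Timestamp(r.date).normalize(): r.delta for r in events.itertuples()}

    col = SoilColumn(cfg)
    vwc_steps = np.empty((len(steps), k))
    delta_steps = np.empty_like(vwc_steps)
    e_daily = np.empty((n_days, n_trees))
    twd_daily = np.empty((n_days, n_trees))
    xylem = np.empty((n_days, n_trees))
    vwc_daily = np.empty((n_days, k))
    delta_daily = np.empty((n_days, k))

    precip = forcing["precip_mm"].to_numpy()
    vpd = forcing["vpd"].to_numpy()
    day_dates = cfg.dates
    tree_scale = 1.0 + 0.1 * (np.arange(n_trees) - (n_trees - 1) / 2.0)

    wet_range = cfg.field_capacity - cfg.residual_vwc
    for d in range(n_days):
        s0, s1 = d * steps_per_day, (d + 1) * steps_per_day
        vpd_day = float(np.mean(vpd[s0:s1]))
        wetness = float(np.clip((col.vwc[0] - cfg.residual_vwc) / wet_range, 0.0, 1.0))
        limitation = cfg.soil_limitation_floor + (1.0 - cfg.soil_limitation_floor) * wetness

        e_mean = cfg.e_max * (1.0 - np.exp(-vpd_day / cfg.e_vpd_scale)) * limitation
        e_trees = np.clip(e_mean * tree_scale * (1.0 + rng.normal(0, 0.08, n_trees)), 0.0, None)
        e_daily[d] = e_trees
        e_stand = float(np.mean(e_trees))

        # tree water deficit: demand term plus soil-moisture term (µm)
        twd_base = cfg.twd_vpd_um_per_kpa * vpd_day + cfg.twd_dryness_um * (1.0 - wetness)
        twd_daily[d] = np.clip(twd_base * tree_scale * (1.0 + rng.normal(0, 0.05, n_trees)), 0.0, None)

        evap_day = cfg.evap_coefficient * vpd_day * wetness
        demand_day = p_true[d] * e_stand  # mm d⁻¹ per layer
        p_delta = delta_by_day.get(day_dates[d], -6.0)
        for i in range(s0, s1):
            col.step(
                float(precip[i]),
                float(p_delta),
                demand_day / steps_per_day,
                evap_day / steps_per_day,
            )
            vwc_steps[i] = col.vwc
            delta_steps[i] = col.delta
        vwc_daily[d] = vwc_steps[s0:s1].mean(axis=0)
        delta_daily[d] = delta_steps[s0:s1].mean(axis=0)

        p_adj = concentration_adjust(p_true[d], vwc_daily[d])
        mix = float(p_adj @ delta_daily[d])
        xylem[d] = mix + rng.normal(0.0, cfg.tree_delta_sd, n_trees)

    t_air = forcing["t_air"].to_numpy()
    soil_temp = _soil_temperature(cfg, t_air, steps)
    day_idx = (steps.normalize() - steps[0].normalize()).days.to_numpy()
    stem_temp = 0.8 * pd.Series(t_air).groupby(day_idx).transform("mean").to_numpy() + 0.2 * 14.0

    return SimTruth(
        config=cfg,
        dates=day_dates,
        steps=steps,
        p_true=p_true,
        vwc_daily=vwc_daily,
        delta_daily=delta_daily,
        vwc_steps=vwc_steps,
        delta_steps=delta_steps,
        soil_temp_steps=soil_temp,
        stem_temp_steps=stem_temp,
        transpiration=e_daily,
        twd=twd_daily,
        xylem_delta=xylem,
        events=events,
        forcing=forcing,
        water_balance=col.balance(),
        seed=cfg.seed,
    )


#: Standard knowns used by the emitter (‰, liquid).
STANDARD_KNOWNS = (-4.4, -19.5)


def cycle_probe_schedule(config: SimConfig) -> list[tuple[str, str]]:
    """Probe order within one measurement cycle: (probe_id, kind).

    Trees first, then the soil probes of both profiles, then the two
    standards; each slot lasts one 10-min sampling interval.
    """
    schedule: list[tuple[str, str]] = []
    for t in range(config.n_trees):
        schedule.append((f"tree_{t + 1}", "xylem"))
    for profile in ("A", "B"):
        for depth in config.depths_cm:
            schedule.append((f"soil_{profile}_{depth:g}cm", "soil"))
    schedule.append(("standard_heavy", "standard"))
    schedule.append(("standard_light", "standard"))
    return schedule


def cycle_duration_minutes(config: SimConfig, slot_minutes: float = 10.0) -> float:
    """Duration of one full measurement cycle."""
    return slot_minutes * len(cycle_probe_schedule(config))


def lab_concentration_series(
    config: SimConfig,
    reference_delta: float = -8.2,
    n_points: int = 40,
) -> pd.DataFrame:
    """Pre-season laboratory dilution series of reference water.

    Vapour of known δ18O is generated across the 1000–30000 ppm working
    range and read through the instrument's concentration-bias curve plus
    measurement noise — the raw material for the logistic correction fit.
    """
    rng = config.child_rng("labcal")
    ppm = np.geomspace(1000.0, 30000.0, n_points)
    measured = reference_delta + config.instrument_bias.bias(ppm)
    measured = measured + rng.normal(0.0, 0.05, n_points)
    return pd.DataFrame({"ppm": ppm, "measured": measured, "known": reference_delta})


def emit_observations(
    truth: SimTruth,
    alpha_override: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Produce the raw instrument streams from the ground truth.

    Returns a dict with:

    ``probe_readings``
        Long-format raw vapour readings on the cycle schedule with
        columns probe_id, kind, timestamp, cycle, delta_vapour, h2o_ppm,
        r_s, temperature, known (standards only).
    ``stem_radius``
        Per-tree 10-min stem radius (µm relative to season start).
    ``sap_flux``
        Per-tree 10-min sap flux density FD (l cm⁻² s⁻¹).
    ``lab_calibration``
        The laboratory concentration-dependence series.

    ``alpha_override`` forces the liquid–vapour equilibrium factor (the
    value 1 short-circuits fractionation; with zero noise and zero bias
    the emitted vapour δ then equals the truth liquid δ).
    """
    cfg = truth.config
    rng = cfg.child_rng("obs")
    bias = cfg.instrument_bias
    schedule = cycle_probe_schedule(cfg)
    slot = pd.Timedelta(minutes=10)
    cycle_len = slot * len(schedule)
    season_start = pd.Timestamp(cfg.season_start)
    season_end = pd.Timestamp(cfg.season_end) + pd.Timedelta(days=1)
    n_cycles = int((season_end - season_start) / cycle_len)

    step_min = cfg.timestep_min
    n_steps = len(truth.steps)
    depths = list(cfg.depths_cm)

    rows: list[dict] = []
    for c in range(n_cycles):
        cyc_start = season_start + c * cycle_len
        offset_c = rng.normal(0.0, bias.cycle_offset_sd)
        slope_c = 1.0 + rng.normal(0.0, bias.cycle_slope_sd)
        for s, (probe_id, kind) in enumerate(schedule):
            ts = cyc_start + s * slot
            step_i = min(int((ts - season_start).total_seconds() // (step_min * 60)), n_steps - 1)
            day_i = min((ts - season_start).days, cfg.n_days - 1)
            if kind == "xylem":
                tree_i = int(probe_id.split("_")[1]) - 1
                liquid = truth.xylem_delta[day_i, tree_i]
                temp = truth.stem_temp_steps[step_i]
                known = np.nan
                r_s = rng.normal(0.58, 0.05)
            elif kind == "soil":
                depth = float(probe_id.rsplit("_", 1)[1][:-2])
                j = depths.index(depth)
                liquid = truth.delta_steps[step_i, j]
                temp = truth.soil_temp_steps[step_i, j]
                known = np.nan
                r_s = rng.normal(0.58, 0.05)
            else:
                known = STANDARD_KNOWNS[0] if probe_id == "standard_heavy" else STANDARD_KNOWNS[1]
                liquid = known
                temp = truth.stem_temp_steps[step_i]
                r_s = rng.normal(0.60, 0.07)
            ppm = float(np.clip(9000.0 + 550.0 * temp + rng.normal(0.0, 600.0), 6500.0, 32000.0))
            vapour = liquid_to_vapour(liquid, temp, alpha_override=alpha_override)
            reported = (
                slope_c * vapour
                + offset_c
                + bias.bias(ppm)
                + (rng.normal(0.0, cfg.noise_delta) if cfg.noise_delta > 0 else 0.0)
            )
            rows.append(
                {
                    "probe_id": probe_id,
                    "kind": kind,
                    "timestamp": ts,
                    "cycle": c,
                    "delta_vapour": reported,
                    "h2o_ppm": ppm,
                    "r_s": r_s,
                    "temperature": temp,
                    "known": known,
                }
            )
    probe_readings = pd.DataFrame(rows)

    # dendrometer: growth envelope frozen while the soil-moisture TWD term
    # keeps the stem below its historical maximum (zero-growth concept)
    frac = (truth.steps.hour * 60 + truth.steps.minute).to_numpy() / 1440.0
    shape = 0.5 * (1.0 - np.cos(2 * np.pi * (frac - 0.25)))  # 0 at 06:00, 1 at 18:00
    shape_mean = float(shape[: 1440 // step_min].mean())
    steps_per_day = 1440 // step_min
    sr_frames = {}
    for t in range(cfg.n_trees):
        twd = truth.twd[:, t]
        growth_rate = np.where(twd < 50.0, 2.5, 0.0)  # µm d⁻¹ while unstressed
        envelope_daily = np.concatenate([[0.0], np.cumsum(growth_rate)[:-1]])
        env = np.repeat(envelope_daily, steps_per_day)
        dip = np.repeat(twd, steps_per_day) * shape / shape_mean
        sr_frames[f"tree_{t + 1}"] = env - dip
    stem_radius = pd.DataFrame(sr_frames, index=truth.steps)

    # sap flux density scaled so the daily integral reproduces truth E
    day_shape = np.clip(np.sin(np.pi * (frac - 0.25) / 0.58), 0.0, None)  # daylight half-sine
    fd_frames = {}
    for t in range(cfg.n_trees):
        sa = cfg.sapwood_areas_cm2[t % len(cfg.sapwood_areas_cm2)]
        crown = cfg.crown_areas_m2[t % len(cfg.crown_areas_m2)]
        integral = float(day_shape[:steps_per_day].sum() * step_min * 60.0)  # s-weighted shape
        fd = np.repeat(truth.transpiration[:, t], steps_per_day) * crown / (sa * integral) * day_shape
        fd_frames[f"tree_{t + 1}"] = fd
    sap_flux = pd.DataFrame(fd_frames, index=truth.steps)

    # soil-moisture sensors read the true VWC with small sensor noise
    vwc_cols = {
        f"vwc_{d:g}cm": truth.vwc_steps[:, j] + rng.normal(0.0, 0.003, n_steps)
        for j, d in enumerate(cfg.depths_cm)
    }
    soil_moisture = pd.DataFrame(vwc_cols, index=truth.steps)

    return {
        "probe_readings": probe_readings,
        "stem_radius": stem_radius,
        "sap_flux": sap_flux,
        "soil_moisture": soil_moisture,
        "lab_calibration": lab_concentration_series(cfg),
    }
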