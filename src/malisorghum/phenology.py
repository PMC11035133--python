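"""Thermal-time phenology with the triple broken-linear photoperiod response.

Sorghum development is driven by thermal time (degree-days above a base
temperature, with a broken-linear decline between the optimum and maximum
temperatures).  West-African photoperiod-sensitive cultivars additionally
delay panicle initiation under long days: the thermal duration of the phase
from end of the juvenile stage to panicle initiation rises linearly with the
mean photoperiod of that phase between two critical day lengths (Ppcrit1,
Ppcrit2) at a cultivar-specific rate (Ppslope, degCd per hour of day length),
and is flat outside them.  Because panicle initiation caps the main-stem leaf
number, this response couples day length to canopy size — the mechanistic
loop the rest of the package builds on.

The module also provides the rainfall-triggered sowing rule used in the
simulation protocol and least-squares calibration of Ppslope from trial data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources

import numpy as np
import yaml

from .soil import SoilWaterState, step_water_balance

__all__ = [
    "Stage",
    "CultivarParams",
    "PhenologyState",
    "CULTIVAR_PRESETS",
    "cultivar_preset",
    "daily_thermal_time",
    "endjuv_to_init_duration",
    "total_leaf_number",
    "sowing_date",
    "new_phenology",
    "advance_phenology",
    "fit_ppslope",
    "PhotoperiodSlopeRegression",
]

DOY_JUN1 = 152
DOY_JUL15 = 196


class Stage(IntEnum):
    PRESOWING = 0
    SOWING = 1
    EMERGENCE = 2
    END_JUVENILE = 3
    PANICLE_INITIATION = 4
    FLAG_LEAF = 5
    FLOWERING = 6
    START_GRAIN_FILL = 7
    MATURITY = 8
    RIPE = 9


@dataclass(frozen=True)
class CultivarParams:
    """Genotype coefficients: photoperiod response, phase durations (degCd),
    grain-filling and leaf-profile parameters, plus growth parameters the
    source trials do not constrain (cardinal temperatures, plastochron,
    phyllochron, embryo leaf count), all configurable."""

    name: str
    Ppcrit1: float  # h, minimum photoperiod
    Ppcrit2: float  # h, maximum photoperiod
    Ppslope: float  # degCd h^-1
    tt_endjuv_to_init_base: float  # degCd at/below Ppcrit1
    tt_flag_to_flower: float
    tt_flower_to_start_grain: float
    tt_flower_to_maturity: float
    tt_maturity_to_ripe: float
    dm_per_seed: float  # g per seed (grain-number determination)
    maxGFRate: float  # mg grain^-1 degCd^-1, potential grain-filling rate
    largest_leaf_multiplier: float
    aMaxSlope: float  # cm2 per leaf
    aMaxIntercept: float  # cm2
    plastochron: float = 34.0  # degCd per initiated leaf
    phyllochron: float = 40.0  # degCd per emerged leaf
    embryo_leaves: int = 4
    # emergence + basic vegetative (juvenile) phase, lumped.  Not reported in
    # the source trials; set so that June-sown crops flower in the observed
    # September window and carry realistic main-stem leaf numbers (~23 for
    # CSM63E, ~27 for CSM335 at 12.5 degN).
    tt_sow_to_endjuv: float = 450.0
    tt_sow_to_emergence: float = 60.0
    base_temp: float = 11.0
    opt_temp: float = 30.0
    max_temp: float = 42.0

    def __post_init__(self) -> None:
        if not self.Ppcrit1 < self.Ppcrit2:
            raise ValueError("require Ppcrit1 < Ppcrit2")
        if self.Ppslope < 0:
            raise ValueError("Ppslope must be >= 0")
        for a in ("tt_endjuv_to_init_base", "tt_flag_to_flower",
                  "tt_flower_to_start_grain", "tt_flower_to_maturity",
                  "tt_maturity_to_ripe", "tt_sow_to_endjuv"):
            if getattr(self, a) < 0:
                raise ValueError(f"{a} must be >= 0")
        if not self.base_temp < self.opt_temp < self.max_temp:
            raise ValueError("require base < optimum < maximum temperature")
        if self.tt_flower_to_start_grain > self.tt_flower_to_maturity:
            raise ValueError("start of grain fill must precede maturity")


def _load_presets() -> dict[str, CultivarParams]:
    text = resources.files("malisorghum.data").joinpath("cultivars.yml").read_text()
    raw = yaml.safe_load(text)
    return {k: CultivarParams(name=k, **v) for k, v in raw.items()}


CULTIVAR_PRESETS: dict[str, CultivarParams] = _load_presets()


def cultivar_preset(name: str) -> CultivarParams:
    try:
        return CULTIVAR_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cultivar {name!r}; expected one of {sorted(CULTIVAR_PRESETS)}"
        ) from None


def daily_thermal_time(tmax: float, tmin: float, cultivar: CultivarParams) -> float:
    """Thermal time accrued in one day, degCd, from the daily mean temperature.

    Broken-linear response: zero at or below the base temperature, rising
    linearly to (opt - base) at the optimum, then declining linearly to zero
    at the maximum temperature.
    """
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    tm = 0.5 * (tmax + tmin)
    b, o, x = cultivar.base_temp, cultivar.opt_temp, cultivar.max_temp
    if tm <= b or tm >= x:
        return 0.0
    if tm <= o:
        return tm - b
    return (o - b) * (x - tm) / (x - o)


def endjuv_to_init_duration(photoperiod: float, cultivar: CultivarParams) -> float:
    """Thermal duration (degCd) of the end-juvenile -> panicle-initiation phase.

    Triple broken-linear in photoperiod: the base duration below Ppcrit1, a
    linear rise of Ppslope degCd per hour between the critical photoperiods,
    and a plateau above Ppcrit2.
    """
    if not 0.0 < photoperiod < 24.0:
        raise ValueError("photoperiod must be in (0, 24) h")
    pp = min(max(photoperiod, cultivar.Ppcrit1), cultivar.Ppcrit2)
    return cultivar.tt_endjuv_to_init_base + cultivar.Ppslope * (pp - cultivar.Ppcrit1)


def total_leaf_number(tt_emergence_to_panicle_init: float,
                      cultivar: CultivarParams) -> int:
    """Final main-stem leaf number.

    Leaves are initiated every plastochron degCd from emergence until panicle
    initiation, on top of the leaves preformed in the embryo; longer juvenile
    phases (longer days) therefore mean more leaves.  Rounded to the nearest
    integer, ties up.
    """
    if tt_emergence_to_panicle_init < 0:
        raise ValueError("thermal time must be >= 0")
    raw = cultivar.embryo_leaves + tt_emergence_to_panicle_init / cultivar.plastochron
    return int(math.floor(raw + 0.5))


# ---------------------------------------------------------------------------
# Sowing rule
# ---------------------------------------------------------------------------

def sowing_date(weather, soil_state: SoilWaterState,
                window_start: int = DOY_JUN1, window_end: int = DOY_JUL15,
                min_rain_7d: float = 20.0, min_asw: float = 10.0,
                return_state: bool = False):
    """First sowable day of year in the window, or its last day as fallback.

    A day qualifies when the trailing 7-day rainfall sum reaches
    ``min_rain_7d`` (20 mm) and the bare-soil plant-available water is at
    least ``min_asw`` (10 mm).  ``soil_state`` is the state at the start of
    the sowing window — the simulation protocol resets it there to 20%
    fractional available water at the beginning of each growing season — and
    is stepped daily through the window (rain in, bare-soil evaporation out).
    If no day qualifies, sowing is forced on the last day of the window.
    """
    from .canopy import equilibrium_evaporation  # local import to avoid a cycle

    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    if window_end > len(weather.rain):
        raise ValueError("weather series does not cover the sowing window")
    rain = weather.rain
    state = soil_state
    sow_doy = None
    for doy in range(window_start, window_end + 1):
        i = doy - 1
        pot_evap = equilibrium_evaporation(
            weather.radiation[i], weather.tmax[i], weather.tmin[i])
        state = step_water_balance(state, float(rain[i]), pot_evap, 0.0)
        if sow_doy is None and doy >= window_start:
            rain7 = float(rain[max(0, doy - 7):doy].sum())
            if rain7 >= min_rain_7d and state.total_available_water >= min_asw:
                sow_doy = doy
                break
    if sow_doy is None:
        sow_doy = window_end
    return (sow_doy, state) if return_state else sow_doy


# ---------------------------------------------------------------------------
# Stage machine
# ---------------------------------------------------------------------------

@dataclass
class PhenologyState:
    """Stage machine state.  Thermal time in excess of a stage target carries
    into the next stage, so the degCd attributed to each phase equals its
    target exactly; ``transitions`` records (day of year, cumulative degCd at
    the transition) per stage reached."""

    cultivar: CultivarParams
    stage: Stage = Stage.SOWING
    tt_in_stage: float = 0.0
    cum_tt: float = 0.0
    transitions: dict = field(default_factory=dict)
    pp_sum: float = 0.0
    pp_days: int = 0
    max_leaf_no: int | None = None
    leaves_at_init: float | None = None
    tt_init_to_flag: float | None = None

    @property
    def mean_photoperiod(self) -> float | None:
        return self.pp_sum / self.pp_days if self.pp_days else None

    def transition_tt(self, stage: Stage) -> float:
        return self.transitions[stage][1]

    def transition_doy(self, stage: Stage) -> int:
        return self.transitions[stage][0]


def new_phenology(cultivar: CultivarParams, sow_doy: int = 0) -> PhenologyState:
    state = PhenologyState(cultivar=cultivar)
    state.transitions[Stage.SOWING] = (sow_doy, 0.0)
    return state


def _stage_target(state: PhenologyState) -> float:
    cv = state.cultivar
    s = state.stage
    if s == Stage.SOWING:
        return cv.tt_sow_to_emergence
    if s == Stage.EMERGENCE:
        return cv.tt_sow_to_endjuv - cv.tt_sow_to_emergence
    if s == Stage.END_JUVENILE:
        pp = state.mean_photoperiod
        if pp is None:  # no photoperiod seen yet this phase
            return cv.tt_endjuv_to_init_base
        return endjuv_to_init_duration(pp, cv)
    if s == Stage.PANICLE_INITIATION:
        return state.tt_init_to_flag if state.tt_init_to_flag is not None else 0.0
    if s == Stage.FLAG_LEAF:
        return cv.tt_flag_to_flower
    if s == Stage.FLOWERING:
        return cv.tt_flower_to_start_grain
    if s == Stage.START_GRAIN_FILL:
        return cv.tt_flower_to_maturity - cv.tt_flower_to_start_grain
    if s == Stage.MATURITY:
        return cv.tt_maturity_to_ripe
    return math.inf  # RIPE: terminal


def _on_transition(state: PhenologyState, doy: int) -> None:
    """Bookkeeping at the moment a stage boundary is crossed."""
    cv = state.cultivar
    if state.stage == Stage.PANICLE_INITIATION:
        tt_emerg_to_init = (state.transition_tt(Stage.PANICLE_INITIATION)
                            - state.transition_tt(Stage.EMERGENCE))
        state.max_leaf_no = total_leaf_number(tt_emerg_to_init, cv)
        # leaves *emerge* one per phyllochron from emergence (leaf 1 visible
        # at emergence); initiation runs faster, one per plastochron
        state.leaves_at_init = min(
            float(state.max_leaf_no),
            1.0 + tt_emerg_to_init / cv.phyllochron,
        )
        state.tt_init_to_flag = max(
            (state.max_leaf_no - state.leaves_at_init) * cv.phyllochron, 0.0
        )


def advance_phenology(state: PhenologyState, daily_tt: float,
                      photoperiod: float, doy: int = 0) -> PhenologyState:
    """Advance the stage machine by one day of ``daily_tt`` degCd.

    The photoperiod driving the juvenile extension is the running mean over
    the end-juvenile -> panicle-initiation phase, re-evaluated daily, so the
    phase target shifts as the day length drifts.  Stages never skip or
    reorder; several boundaries may be crossed in one hot day.
    """
    if daily_tt < 0:
        raise ValueError("daily_tt must be >= 0")
    st = replace(state, transitions=dict(state.transitions))
    consumed = 0.0
    remaining = daily_tt
    if st.stage == Stage.END_JUVENILE:
        st.pp_sum += photoperiod
        st.pp_days += 1
    while st.stage < Stage.RIPE:
        target = _stage_target(st)
        need = target - st.tt_in_stage
        if remaining < need or not math.isfinite(need):
            st.tt_in_stage += remaining
            consumed += remaining
            remaining = 0.0
            break
        consumed += need
        remaining -= need
        st.stage = Stage(st.stage + 1)
        st.tt_in_stage = 0.0
        st.transitions[st.stage] = (doy, st.cum_tt + consumed)
        _on_transition(st, doy)
        if st.stage == Stage.END_JUVENILE:
            # the entry day counts toward the phase-mean photoperiod
            st.pp_sum += photoperiod
            st.pp_days += 1
    st.cum_tt += daily_tt
    return st


# ---------------------------------------------------------------------------
# Ppslope calibration
# ---------------------------------------------------------------------------

class UnidentifiableSlopeError(ValueError):
    """The photoperiod design cannot identify the slope."""


class PhotoperiodSlopeRegression:
    """Least-squares calibration of the photoperiod slope from trial data.

    An sklearn-style estimator: ``fit`` takes mean photoperiods (h) and the
    observed thermal durations of the end-juvenile -> panicle-initiation phase
    (degCd), keeps only observations strictly inside the photoperiod-sensitive
    range ``(ppcrit1, ppcrit2)``, and fits the linear segment by ordinary
    least squares.  Fitted attributes: ``slope_`` (degCd h^-1) and ``base_``
    (the duration at Ppcrit1, degCd).

    Parameters
    ----------
    ppcrit1, ppcrit2 : float
        Critical photoperiods bounding the sensitive range, hours.
    """

    def __init__(self, ppcrit1: float = 11.5, ppcrit2: float = 13.5):
        self.ppcrit1 = ppcrit1
        self.ppcrit2 = ppcrit2

    def get_params(self, deep: bool = True) -> dict:
        return {"ppcrit1": self.ppcrit1, "ppcrit2": self.ppcrit2}

    def set_params(self, **params) -> "PhotoperiodSlopeRegression":
        for k, v in params.items():
            if k not in ("ppcrit1", "ppcrit2"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "PhotoperiodSlopeRegression":
        pp = np.asarray(X, dtype=float).reshape(-1)
        tt = np.asarray(y, dtype=float).reshape(-1)
        if pp.shape != tt.shape:
            raise ValueError("X and y must have the same length")
        inside = (pp > self.ppcrit1) & (pp < self.ppcrit2)
        pp, tt = pp[inside], tt[inside]
        if pp.size < 2 or np.ptp(pp) == 0.0:
            raise UnidentifiableSlopeError(
                "slope unidentifiable: need >= 2 distinct photoperiods strictly "
                f"inside ({self.ppcrit1}, {self.ppcrit2}) h"
            )
        slope, intercept = np.polyfit(pp, tt, 1)
        self.slope_ = float(slope)
        self.base_ = float(intercept + slope * self.ppcrit1)
        self.n_obs_ = int(pp.size)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "slope_"):
            raise RuntimeError("estimator is not fitted")
        pp = np.clip(np.asarray(X, dtype=float).reshape(-1),
                     self.ppcrit1, self.ppcrit2)
        return self.base_ + self.slope_ * (pp - self.ppcrit1)


def fit_ppslope(observations, ppcrit1: float = 11.5,
                ppcrit2: float = 13.5) -> tuple[float, float]:
    """OLS fit of (slope, base) from ``(photoperiod h, duration degCd)`` pairs.

    Thin wrapper over :class:`PhotoperiodSlopeRegression`.
    """
    obs = np.asarray(observations, dtype=float)
    est = PhotoperiodSlopeRegression(ppcrit1=ppcrit1, ppcrit2=ppcrit2)
    est.fit(obs[:, 0], obs[:, 1])
    return est.slope_, est.base_
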