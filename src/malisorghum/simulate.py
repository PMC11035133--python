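"""Daily-timestep season simulation: weather + soil + phenology + canopy.

One call simulates one cropping season for a (weather year, soil, cultivar,
management) combination, following the study protocol: soil water reset to
20% fractional available water at the start of the season, sowing triggered
by 20 mm of rain in 7 days with at least 10 mm of stored available water
inside a 1 June - 15 July window (forced on the window's last day
otherwise), fixed plant density, and water-limited growth through grain
filling.  The daily record of the supply/demand ratio and thermal time is
what the envirotyping stage clusters into drought scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import canopy as cp
from . import phenology as ph
from . import soil as sl
from .weather import DailyWeatherSeries

__all__ = ["SeasonResult", "simulate_season"]


@dataclass
class SeasonResult:
    """Outcome of one simulated season."""

    site: str
    year: int
    soil: str
    cultivar: str
    sow_doy: int
    phenology: ph.PhenologyState
    crop: cp.CropState
    water: sl.SoilWaterState
    doy: np.ndarray  # one entry per simulated crop day (from sowing)
    daily_tt: np.ndarray
    cum_tt: np.ndarray  # cumulative degCd at the end of each day
    daily_sd: np.ndarray
    daily_supply: np.ndarray
    daily_demand: np.ndarray
    daily_lai: np.ndarray
    daily_biomass: np.ndarray
    daily_stage: np.ndarray
    completed: bool = True

    @property
    def flowering_tt(self) -> float | None:
        tr = self.phenology.transitions
        return tr[ph.Stage.FLOWERING][1] if ph.Stage.FLOWERING in tr else None

    @property
    def flowering_doy(self) -> int | None:
        tr = self.phenology.transitions
        return tr[ph.Stage.FLOWERING][0] if ph.Stage.FLOWERING in tr else None

    @property
    def maturity_doy(self) -> int | None:
        tr = self.phenology.transitions
        return tr[ph.Stage.MATURITY][0] if ph.Stage.MATURITY in tr else None

    @property
    def max_leaf_no(self) -> int | None:
        return self.phenology.max_leaf_no

    @property
    def peak_lai(self) -> float:
        return float(self.daily_lai.max()) if self.daily_lai.size else 0.0

    def preflowering_demand(self) -> float:
        """Cumulative transpiration demand (mm) before the flowering day."""
        if self.flowering_doy is None:
            return float(self.daily_demand.sum())
        mask = self.doy < self.flowering_doy
        return float(self.daily_demand[mask].sum())

    def daily_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doy": self.doy,
                "stage": self.daily_stage,
                "tt": self.daily_tt,
                "cum_tt": self.cum_tt,
                "lai": self.daily_lai,
                "biomass_kg_ha": self.daily_biomass * 10.0,
                "supply_mm": self.daily_supply,
                "demand_mm": self.daily_demand,
                "sd_ratio": self.daily_sd,
            }
        )

    def summary(self) -> dict:
        return {
            "site": self.site,
            "year": self.year,
            "soil": self.soil,
            "cultivar": self.cultivar,
            "sow_doy": self.sow_doy,
            "flowering_doy": self.flowering_doy,
            "maturity_doy": self.maturity_doy,
            "max_leaf_no": self.max_leaf_no,
            "peak_lai": round(self.peak_lai, 3),
            "grain_yield_kg_ha": round(self.crop.grain_yield_kg_ha, 1),
            "biomass_kg_ha": round(self.crop.biomass_kg_ha, 1),
            "completed": self.completed,
        }


def _projected_leaf_number(phen: ph.PhenologyState, photoperiod: float,
                           cultivar: ph.CultivarParams) -> int:
    """Best current estimate of the final leaf number before initiation.

    Until panicle initiation fixes the leaf number, the canopy profile is
    built from the projected duration of the juvenile extension at the
    best-available photoperiod (the phase running mean once in the phase,
    today's day length before it)."""
    if phen.max_leaf_no is not None:
        return phen.max_leaf_no
    pp = phen.mean_photoperiod if phen.mean_photoperiod is not None else photoperiod
    cv = cultivar
    tt_emerg_to_endjuv = cv.tt_sow_to_endjuv - cv.tt_sow_to_emergence
    projected = tt_emerg_to_endjuv + ph.endjuv_to_init_duration(pp, cv)
    return ph.total_leaf_number(projected, cv)


def simulate_season(
    weather: DailyWeatherSeries,
    soil_profile: sl.SoilProfile,
    cultivar: ph.CultivarParams,
    management: cp.ManagementSpec | None = None,
) -> SeasonResult:
    """Simulate one season; returns daily records and final state.

    The loop runs from the day after sowing until the crop is ripe or the
    calendar year ends (an unfinished crop is flagged ``completed=False``).
    """
    mgmt = management or cp.ManagementSpec()
    init = sl.reset_fractional_asw(soil_profile, mgmt.initial_fasw)
    sow_doy, water = ph.sowing_date(
        weather, init, *mgmt.sowing_window, return_state=True)

    phen = ph.new_phenology(cultivar, sow_doy)
    crop = cp.CropState()
    profile_cache: dict[int, cp.LeafProfileParams] = {}

    rows: list[tuple] = []
    gain_history: list[tuple[float, float]] = []  # (cum_tt at end of day, gain)
    root_depth = 0.0
    prev_sd = 1.0

    for doy in range(sow_doy + 1, len(weather.rain) + 1):
        i = doy - 1
        tt = ph.daily_thermal_time(weather.tmax[i], weather.tmin[i], cultivar)
        pp = float(weather.photoperiod[i])
        phen = ph.advance_phenology(phen, tt, pp, doy)
        stage = phen.stage
        flowered = ph.Stage.FLOWERING in phen.transitions

        # --- root front: grows from sowing, stops at flowering
        if not flowered or doy <= phen.transition_doy(ph.Stage.FLOWERING):
            root_depth = min(cp.ROOT_FRONT_VELOCITY * (doy - sow_doy),
                             soil_profile.total_depth)

        # --- canopy
        if stage >= ph.Stage.EMERGENCE:
            maxl = _projected_leaf_number(phen, pp, cultivar)
            profile = profile_cache.get(maxl)
            if profile is None:
                profile = cp.build_canopy_profile(maxl, cultivar)
                profile_cache[maxl] = profile
            tt_since_emerg = phen.cum_tt - phen.transition_tt(ph.Stage.EMERGENCE)
            leaves = min(float(maxl), 1.0 + tt_since_emerg / cultivar.phyllochron)
            crop = cp.update_lai(
                crop, leaves, profile, mgmt.plant_density,
                senescence_tt=tt if flowered else 0.0,
                stressed=prev_sd < 0.3,
                expansion_factor=prev_sd,
            )

        # --- water demand, supply, stress
        pot_gain = cp.potential_biomass_gain(weather.radiation[i], crop.lai)
        vpd = max(cp.daytime_vpd(weather.tmax[i], weather.tmin[i]), 0.05)
        demand = cp.transpiration_demand(pot_gain, vpd)
        supply_layers = sl.water_supply_layers(water, root_depth)
        supply = float(supply_layers.sum())
        sd = cp.sd_ratio(supply, demand)

        # --- growth
        gain = pot_gain * sd
        crop = cp.daily_growth(crop, weather.radiation[i], crop.lai, sd)
        gain_history.append((phen.cum_tt, gain))

        # --- grain number and grain filling
        if flowered and crop.grain_number is None:
            f_tt = phen.transition_tt(ph.Stage.FLOWERING)
            if phen.cum_tt >= f_tt + cp.GRAIN_NUMBER_WINDOW_TT:
                window = sum(
                    g for (ctt, g) in gain_history
                    if f_tt - cp.GRAIN_NUMBER_WINDOW_TT
                    <= ctt <= f_tt + cp.GRAIN_NUMBER_WINDOW_TT
                )
                crop.anthesis_window_biomass = window
                crop = cp.set_grain_number(crop, cultivar.dm_per_seed)
        if (crop.grain_number is not None
                and ph.Stage.MATURITY not in phen.transitions):
            crop = cp.grain_fill(crop, tt, cultivar, assimilate=gain)

        # --- soil update
        pot_soil_evap = (cp.equilibrium_evaporation(
            weather.radiation[i], weather.tmax[i], weather.tmin[i])
            * float(np.exp(-cp.EXTINCTION_K * crop.lai)))
        uptake_total = min(demand * sd, supply)
        uptake = (supply_layers * (uptake_total / supply)
                  if supply > 0 else np.zeros(soil_profile.n_layers))
        water = sl.step_water_balance(
            water, float(weather.rain[i]), pot_soil_evap, uptake)

        crop.supply_today, crop.demand_today, crop.sd_ratio_today = supply, demand, sd
        prev_sd = sd
        rows.append((doy, tt, phen.cum_tt, sd, supply, demand,
                     crop.lai, crop.biomass, int(stage)))
        if stage >= ph.Stage.RIPE:
            break

    arr = np.array(rows, dtype=float) if rows else np.empty((0, 9))
    return SeasonResult(
        site=weather.site,
        year=weather.year,
        soil=soil_profile.name,
        cultivar=cultivar.name,
        sow_doy=sow_doy,
        phenology=phen,
        crop=crop,
        water=water,
        doy=arr[:, 0].astype(int),
        daily_tt=arr[:, 1],
        cum_tt=arr[:, 2],
        daily_sd=arr[:, 3],
        daily_supply=arr[:, 4],
        daily_demand=arr[:, 5],
        daily_lai=arr[:, 6],
        daily_biomass=arr[:, 7],
        daily_stage=arr[:, 8].astype(int),
        completed=phen.stage >= ph.Stage.MATURITY,
    )
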