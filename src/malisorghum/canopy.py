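"""Individual-leaf-area canopy, biomass accumulation, and grain filling.

Canopy size is built bottom-up from the sizes of individual main-stem leaves:
leaf area varies with rank as a bell-shaped curve

    Y = Y0 * exp(a * (X - X0)^2 + b * (X - X0)^3)

where X0 is the rank of the largest leaf and Y0 its area, itself a linear
function of the total leaf number (Y0 = MaxLNo * aMaxSlope + aMaxIntercept).
Because the total leaf number is set by photoperiod-dependent phenology, this
couples day length to leaf area index, and through it to radiation capture
and transpiration demand.

Biomass accrues from intercepted radiation at a fixed radiation-use
efficiency, scaled by the daily water supply/demand (S/D) ratio — the
package's drought-stress index, capped at 1.  Grain yield comes from a
sink/source grain-filling model: grain number is set by biomass growth in a
+-100 degCd window around flowering, then grains fill at a
temperature-driven potential rate limited by current assimilation plus a
capped stem reserve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phenology import CultivarParams

__all__ = [
    "LeafProfileParams",
    "CropState",
    "ManagementSpec",
    "individual_leaf_area",
    "largest_leaf_area",
    "build_canopy_profile",
    "update_lai",
    "transpiration_demand",
    "sd_ratio",
    "daily_growth",
    "grain_fill",
    "saturation_vapour_pressure",
    "daytime_vpd",
    "equilibrium_evaporation",
]

# APSIM-conventional physiology constants, all overridable per call
RUE = 1.25  # g biomass per MJ intercepted radiation
EXTINCTION_K = 0.4
TE_COEFF_PA = 9.0  # transpiration-efficiency coefficient, Pa
VPD_FRACTION = 0.75  # daytime VPD as a fraction of the (Tmax, Tmin) SVP span
ALBEDO = 0.15
SENESCENCE_RATE = 0.0005  # fraction of LAI lost per degCd after flowering
SENESCENCE_STRESS_FACTOR = 3.0  # applied when S/D < 0.3
GRAIN_NUMBER_WINDOW_TT = 100.0  # degCd either side of flowering
STEM_RETRANS_FRACTION = 0.2  # of stem biomass, available to grain
STEM_BIOMASS_FRACTION = 0.5  # stem share of vegetative biomass (organ proxy)
ROOT_FRONT_VELOCITY = 25.0  # mm d^-1 from sowing until flowering


@dataclass(frozen=True)
class ManagementSpec:
    """Agronomic settings held constant across the simulation protocol."""

    plant_density: float = 5.7  # plants m^-2
    row_spacing_cm: float = 86.0
    sowing_window: tuple[int, int] = (152, 196)  # doy, Jun 1 - Jul 15
    initial_fasw: float = 0.20

    def __post_init__(self) -> None:
        if self.plant_density <= 0:
            raise ValueError("plant_density must be > 0")


@dataclass(frozen=True)
class LeafProfileParams:
    """Bell-curve parameters for the main-stem leaf-size profile."""

    max_leaf_no: int
    x0: float  # rank of the largest leaf
    y0: float  # area of the largest leaf, cm2
    a: float  # breadth (< 0)
    b: float  # skewness

    def __post_init__(self) -> None:
        if not 1 <= self.x0 <= self.max_leaf_no:
            raise ValueError("require 1 <= X0 <= MaxLNo")
        if self.y0 <= 0:
            raise ValueError("Y0 must be > 0")
        if self.a >= 0:
            raise ValueError("breadth constant a must be < 0")

    def leaf_areas(self) -> np.ndarray:
        """Area of every leaf rank 1..MaxLNo, cm2."""
        ranks = np.arange(1, self.max_leaf_no + 1, dtype=float)
        return individual_leaf_area(ranks, self)


def individual_leaf_area(X, params: LeafProfileParams):
    """Area (cm2) of the leaf at rank ``X`` from the bell-shaped profile."""
    x = np.asarray(X, dtype=float)
    d = x - params.x0
    area = params.y0 * np.exp(params.a * d**2 + params.b * d**3)
    return float(area) if np.ndim(X) == 0 else area


def largest_leaf_area(max_leaf_no: int, cultivar: CultivarParams) -> float:
    """Area of the largest main-culm leaf (cm2), linear in total leaf number."""
    y0 = max_leaf_no * cultivar.aMaxSlope + cultivar.aMaxIntercept
    if y0 <= 0:
        raise ValueError(
            f"leaf number {max_leaf_no} gives non-positive largest-leaf area "
            f"({y0:.1f} cm2): outside the regression's domain"
        )
    return float(y0)


def build_canopy_profile(max_leaf_no: int, cultivar: CultivarParams,
                         x0_fraction: float = 0.66,
                         a_coeffs: tuple[float, float] = (-0.009, -0.2),
                         b_const: float = 0.0006) -> LeafProfileParams:
    """Leaf-size profile for a plant with ``max_leaf_no`` main-stem leaves.

    The largest leaf sits at rank ``x0_fraction * MaxLNo`` and its area is the
    cultivar regression scaled by the largest-leaf multiplier (converting the
    main-culm regression to effective per-plant area).  The breadth constant
    defaults to ``a = -0.009 - 0.2 / MaxLNo`` and the skewness to a small
    positive constant — the source regressions for a and b as functions of
    leaf number are not published, so these are package defaults chosen to
    give realistic unimodal profiles, and are configurable.
    """
    y0 = largest_leaf_area(max_leaf_no, cultivar) * cultivar.largest_leaf_multiplier
    x0 = max(1.0, x0_fraction * max_leaf_no)
    a = a_coeffs[0] + a_coeffs[1] / max_leaf_no
    return LeafProfileParams(max_leaf_no=max_leaf_no, x0=x0, y0=y0,
                             a=a, b=b_const)


@dataclass
class CropState:
    """Daily crop status: canopy, biomass pools (g m^-2 internally), and the
    day's water supply/demand terms (mm).  Yields are exposed in kg ha^-1
    via properties (1 g m^-2 = 10 kg ha^-1)."""

    lai: float = 0.0
    lai_potential: float = 0.0  # unstressed LAI ceiling reached so far
    leaves_emerged: float = 0.0
    biomass: float = 0.0  # above-ground, g m^-2
    grain: float = 0.0  # g m^-2
    grain_number: float | None = None  # grains m^-2, set near flowering
    anthesis_window_biomass: float = 0.0
    retrans_pool: float = 0.0  # g m^-2 stem reserve still available to grain
    supply_today: float = 0.0  # mm d^-1
    demand_today: float = 0.0  # mm d^-1
    sd_ratio_today: float = 1.0

    @property
    def biomass_kg_ha(self) -> float:
        return self.biomass * 10.0

    @property
    def grain_yield_kg_ha(self) -> float:
        return self.grain * 10.0


# ---------------------------------------------------------------------------
# Atmosphere helpers
# ---------------------------------------------------------------------------

def saturation_vapour_pressure(temp_c: float) -> float:
    """Tetens saturation vapour pressure, kPa."""
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def daytime_vpd(tmax: float, tmin: float, fraction: float = VPD_FRACTION) -> float:
    """Daytime vapour pressure deficit, kPa, estimated from the diurnal range."""
    return fraction * (saturation_vapour_pressure(tmax)
                       - saturation_vapour_pressure(tmin))


def equilibrium_evaporation(radiation: float, tmax: float, tmin: float,
                            albedo: float = ALBEDO) -> float:
    """Priestley-Taylor-style equilibrium evaporation, mm d^-1.

    Standard radiation-driven estimate used as the atmospheric demand for
    bare-soil evaporation.
    """
    td = 0.6 * tmax + 0.4 * tmin
    return max(radiation * (4.88e-3 - 4.37e-3 * albedo) * (td + 29.0), 0.0)


# ---------------------------------------------------------------------------
# Daily canopy / growth / grain operations
# ---------------------------------------------------------------------------

def update_lai(state: CropState, leaves_emerged: float,
               profile: LeafProfileParams, plant_density: float,
               senescence_tt: float = 0.0,
               stressed: bool = False,
               expansion_factor: float = 1.0) -> CropState:
    """Advance LAI from the emerged part of the leaf profile.

    The unstressed ceiling is the summed area of fully emerged leaves (plus
    the expanding fraction of the currently emerging leaf) converted from cm2
    per plant to m2 m^-2 at ``plant_density``.  The day's *increment* of that
    ceiling is realised scaled by ``expansion_factor`` (the previous day's
    supply/demand ratio): leaf expansion is water-limited, and expansion lost
    to drought is not recovered — which is what makes early-season stress
    costly.  After flowering, ``senescence_tt`` degCd of ageing removes a
    constant fraction of LAI per degCd, accelerated under severe stress.
    """
    leaves_emerged = min(leaves_emerged, float(profile.max_leaf_no))
    areas = profile.leaf_areas()
    whole = int(leaves_emerged)
    area = float(areas[:whole].sum())
    if whole < profile.max_leaf_no:
        area += (leaves_emerged - whole) * float(areas[whole])
    ceiling = area * 1e-4 * plant_density
    new = replace(state, leaves_emerged=leaves_emerged)
    if senescence_tt > 0.0:
        rate = SENESCENCE_RATE * (SENESCENCE_STRESS_FACTOR if stressed else 1.0)
        # senesce the *current* canopy; expansion has stopped by then
        new.lai = max(state.lai * (1.0 - rate * senescence_tt), 0.0)
    else:
        growth = max(ceiling - state.lai_potential, 0.0)
        new.lai = state.lai + growth * float(np.clip(expansion_factor, 0.0, 1.0))
    new.lai_potential = max(ceiling, state.lai_potential)
    return new


def transpiration_demand(potential_biomass_gain: float, vpd: float,
                         te_coeff_pa: float = TE_COEFF_PA) -> float:
    """Water demand (mm d^-1) to realise a potential biomass gain (g m^-2).

    Transpiration efficiency is ``te_coeff / vpd`` (g biomass per g water),
    so the water needed is ``gain * vpd / te_coeff``; 1 mm = 1000 g m^-2.
    """
    if vpd <= 0:
        raise ValueError("vpd must be > 0")
    if potential_biomass_gain <= 0:
        return 0.0
    water_g = potential_biomass_gain * (vpd * 1000.0) / te_coeff_pa
    return water_g / 1000.0


def sd_ratio(supply: float, demand: float) -> float:
    """Crop water supply/demand ratio, min(1, S/D); 1 when there is no demand."""
    if supply < 0 or demand < 0:
        raise ValueError("supply and demand must be >= 0")
    if demand == 0.0:
        return 1.0
    return min(1.0, supply / demand)


def daily_growth(state: CropState, radiation: float, lai: float, sd: float,
                 rue: float = RUE, k: float = EXTINCTION_K) -> CropState:
    """Accrue one day of biomass.

    Intercepted radiation is ``radiation * (1 - exp(-k * LAI))``; the
    radiation-limited gain ``RUE * interception`` is scaled by the day's S/D
    ratio so water stress curtails growth proportionally.
    """
    interception = radiation * (1.0 - np.exp(-k * lai))
    gain = rue * interception * sd
    return replace(state, biomass=state.biomass + gain)


def potential_biomass_gain(radiation: float, lai: float,
                           rue: float = RUE, k: float = EXTINCTION_K) -> float:
    """Radiation-limited (unstressed) biomass gain, g m^-2 d^-1."""
    return rue * radiation * (1.0 - np.exp(-k * lai))


def set_grain_number(state: CropState, dm_per_seed: float) -> CropState:
    """Fix grain number from biomass accumulated around anthesis.

    grains m^-2 = (biomass gained within +-100 degCd of flowering) / (g seed^-1).
    Also banks the retranslocatable stem reserve available during grain fill.
    """
    number = state.anthesis_window_biomass / dm_per_seed
    reserve = (STEM_RETRANS_FRACTION * STEM_BIOMASS_FRACTION * state.biomass)
    return replace(state, grain_number=number, retrans_pool=reserve)


def grain_fill(state: CropState, daily_tt: float, cultivar: CultivarParams,
               assimilate: float | None = None) -> CropState:
    """Advance grain filling by one day.

    The sink demand is ``maxGFRate (mg/grain/degCd) * grain_number *
    daily_tt``; the source is the day's assimilation plus whatever remains of
    the stem reserve (20% of stem biomass at the start of fill).
    ``assimilate`` defaults to the biomass gained today being entirely
    available.  Grain mass never exceeds total biomass.
    """
    if state.grain_number is None:
        return state
    sink = cultivar.maxGFRate * 1e-3 * state.grain_number * daily_tt
    if assimilate is None:
        assimilate = sink  # unlimited-source convention for unit tests
    growth = min(sink, assimilate + state.retrans_pool)
    from_reserve = max(growth - assimilate, 0.0)
    new_grain = min(state.grain + growth, state.biomass)
    return replace(state, grain=new_grain,
                   retrans_pool=state.retrans_pool - from_reserve)
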