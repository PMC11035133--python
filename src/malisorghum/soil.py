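"""Layered bucket soil-water balance.

A minimal APSIM-style soil: the profile is split into layers, each holding
water between a lower limit (LL, the driest a crop can pump it) and a drained
upper limit (DUL); water above DUL drains downward at a fixed daily fraction,
and roots extract water from each rooted layer at a rate proportional to its
plant-available content (the ``kl`` coefficient).  Two presets reproduce the
soils sorghum is mostly grown on in Mali: a shallow Plinthaquic Kandiustalf
(62 mm plant-available water over 101 cm) and a deeper Alfisol (156 mm over
120 cm).

All storage terms are mm of water; the balance closes to machine precision
(rain in = drainage + evaporation + transpiration + change in storage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SoilProfile",
    "SoilWaterState",
    "SOIL_PRESETS",
    "soil_preset",
    "reset_fractional_asw",
    "step_water_balance",
    "water_supply",
]

DEFAULT_KL = 0.07  # per-layer daily extractable fraction, typical for sorghum
DEFAULT_DRAINAGE_COEFF = 0.5

# Two-stage soil evaporation constants
STAGE1_LIMIT_MM = 6.0  # energy-limited cumulative evaporation after wetting
STAGE2_COEFF = 3.5  # mm d^-0.5, falling-rate stage
REWET_THRESHOLD_MM = 4.0  # rain that resets evaporation to stage 1


@dataclass(frozen=True)
class SoilProfile:
    """Static description of a layered soil.

    ``lower_limit``/``drained_upper_limit``/``saturation`` are volumetric
    fractions per layer; ``layer_thickness`` is mm.  ``swhc`` (soil water
    holding capacity, the profile total of (DUL - LL) x thickness) is the
    maximum plant-available water in mm.
    """

    name: str
    layer_thickness: np.ndarray
    lower_limit: np.ndarray
    drained_upper_limit: np.ndarray
    saturation: np.ndarray
    kl: np.ndarray
    organic_carbon: float = 0.2
    drainage_coeff: float = DEFAULT_DRAINAGE_COEFF

    def __post_init__(self) -> None:
        for name in ("layer_thickness", "lower_limit", "drained_upper_limit",
                     "saturation", "kl"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.layer_thickness)
        if not all(len(getattr(self, a)) == n for a in
                   ("lower_limit", "drained_upper_limit", "saturation", "kl")):
            raise ValueError("per-layer arrays have unequal lengths")
        if not np.all(self.lower_limit < self.drained_upper_limit):
            raise ValueError("require LL < DUL in every layer")
        if not np.all(self.drained_upper_limit < self.saturation):
            raise ValueError("require DUL < SAT in every layer")

    @property
    def n_layers(self) -> int:
        return len(self.layer_thickness)

    @property
    def total_depth(self) -> float:
        return float(self.layer_thickness.sum())

    @property
    def ll_mm(self) -> np.ndarray:
        return self.lower_limit * self.layer_thickness

    @property
    def dul_mm(self) -> np.ndarray:
        return self.drained_upper_limit * self.layer_thickness

    @property
    def sat_mm(self) -> np.ndarray:
        return self.saturation * self.layer_thickness

    @property
    def swhc(self) -> float:
        return float((self.dul_mm - self.ll_mm).sum())

    def layer_depths(self) -> np.ndarray:
        """Depth of the bottom of each layer, mm."""
        return np.cumsum(self.layer_thickness)


def _uniform_profile(name: str, swhc: float, depth_mm: float, n_layers: int,
                     organic_carbon: float) -> SoilProfile:
    thickness = np.full(n_layers, depth_mm / n_layers)
    ll = np.full(n_layers, 0.15)
    paw_frac = swhc / depth_mm  # uniform (DUL - LL) by volume
    dul = ll + paw_frac
    sat = dul + 0.08
    return SoilProfile(
        name=name,
        layer_thickness=thickness,
        lower_limit=ll,
        drained_upper_limit=dul,
        saturation=sat,
        kl=np.full(n_layers, DEFAULT_KL),
        organic_carbon=organic_carbon,
    )


#: The two soils of the study region: keys are used in config files.
SOIL_PRESETS: dict[str, SoilProfile] = {
    "low_swhc": _uniform_profile("low_swhc", swhc=62.0, depth_mm=1010.0,
                                 n_layers=6, organic_carbon=0.2),
    "high_swhc": _uniform_profile("high_swhc", swhc=156.0, depth_mm=1200.0,
                                  n_layers=7, organic_carbon=0.37),
}


def soil_preset(key: str) -> SoilProfile:
    try:
        return SOIL_PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown soil preset {key!r}; expected one of {sorted(SOIL_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SoilWaterState:
    """Mutable-by-replacement water state: per-layer storage plus cumulative
    season fluxes for mass-balance accounting (all mm)."""

    profile: SoilProfile
    stored_water: np.ndarray  # mm per layer, LL*thickness <= s <= SAT*thickness
    rain_in: float = 0.0
    drainage: float = 0.0
    soil_evap: float = 0.0
    transpiration: float = 0.0
    evap_since_wetting: float = 0.0
    days_since_wetting: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stored_water",
                           np.asarray(self.stored_water, dtype=float))

    @property
    def available_water(self) -> np.ndarray:
        """Plant-available water per layer (above LL), mm."""
        return np.maximum(self.stored_water - self.profile.ll_mm, 0.0)

    @property
    def total_available_water(self) -> float:
        return float(self.available_water.sum())

    @property
    def fractional_asw(self) -> float:
        return self.total_available_water / self.profile.swhc

    def mass_balance_error(self, initial_storage: float) -> float:
        """rain - (drainage + evap + transpiration) - Δstorage, mm."""
        delta = float(self.stored_water.sum()) - initial_storage
        return self.rain_in - self.drainage - self.soil_evap - self.transpiration - delta


def reset_fractional_asw(profile: SoilProfile, fraction: float) -> SoilWaterState:
    """Initial-season state holding ``fraction`` of the profile's SWHC.

    The study protocol resets the soil to 20% fractional available soil water
    at the start of every season.  Water is filled top-down: surface layers
    are brought to DUL first, consistent with early-season rains wetting the
    profile from above.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    paw = profile.dul_mm - profile.ll_mm
    remaining = fraction * profile.swhc
    fill = np.zeros(profile.n_layers)
    for i in range(profile.n_layers):
        fill[i] = min(paw[i], remaining)
        remaining -= fill[i]
    return SoilWaterState(profile=profile, stored_water=profile.ll_mm + fill)


def step_water_balance(
    state: SoilWaterState,
    rain: float,
    potential_soil_evap: float,
    transpiration_uptake: float | np.ndarray,
    root_depth: float | None = None,
) -> SoilWaterState:
    """Advance the soil one day.

    Order of operations: rain infiltrates the top layer and cascades (water
    above saturation spills immediately; water above DUL drains at the
    profile's drainage coefficient per day); soil evaporation is taken from
    the top layer only, limited by its water above LL and by the two-stage
    (energy-limited, then falling-rate) drying model; transpiration uptake is
    removed from rooted layers in proportion to each layer's extractable
    supply.  ``transpiration_uptake`` may be a scalar (requires
    ``root_depth``) or a per-layer array.  Uptake in excess of the available
    supply raises ``ValueError`` — callers must respect :func:`water_supply`.
    """
    if rain < 0 or potential_soil_evap < 0:
        raise ValueError("fluxes must be non-negative")
    profile = state.profile
    stored = state.stored_water.copy()
    sat = profile.sat_mm
    dul = profile.dul_mm
    ll = profile.ll_mm

    # Resolve scalar uptake against the *morning* supply (the quantity
    # water_supply reported to the caller), before infiltration/drainage.
    if np.ndim(transpiration_uptake) == 0:
        total_uptake = float(transpiration_uptake)
        if total_uptake < 0:
            raise ValueError("fluxes must be non-negative")
        if total_uptake > 0:
            if root_depth is None:
                raise ValueError("scalar uptake requires root_depth")
            per_layer_supply = _layer_supply(stored, profile, root_depth)
            supply_sum = float(per_layer_supply.sum())
            if total_uptake > supply_sum + 1e-9:
                raise ValueError(
                    f"requested uptake {total_uptake:.3f} mm exceeds supply "
                    f"{supply_sum:.3f} mm"
                )
            uptake = (per_layer_supply * (min(total_uptake, supply_sum) / supply_sum)
                      if supply_sum > 0 else np.zeros(profile.n_layers))
        else:
            uptake = np.zeros(profile.n_layers)
    else:
        uptake = np.asarray(transpiration_uptake, dtype=float)
        if np.any(uptake < 0):
            raise ValueError("fluxes must be non-negative")

    # --- infiltration and drainage cascade (top-down, single pass)
    flux_in = float(rain)
    drained_below = 0.0
    for i in range(profile.n_layers):
        stored[i] += flux_in
        overflow = max(stored[i] - sat[i], 0.0)
        stored[i] -= overflow
        drain = profile.drainage_coeff * max(stored[i] - dul[i], 0.0)
        stored[i] -= drain
        flux_in = overflow + drain
    drained_below = flux_in

    # --- transpiration uptake (after infiltration, which only adds water,
    #     so morning-supply-sized uptake never pushes a layer below LL)
    if np.any(uptake > np.maximum(stored - ll, 0.0) + 1e-9):
        raise ValueError("per-layer uptake exceeds available water")
    uptake = np.minimum(uptake, np.maximum(stored - ll, 0.0))
    stored -= uptake

    # --- two-stage soil evaporation from the top layer
    if rain >= REWET_THRESHOLD_MM:
        evap_since_wetting, days_since_wetting = 0.0, 0
    else:
        evap_since_wetting = state.evap_since_wetting
        days_since_wetting = state.days_since_wetting
    if evap_since_wetting < STAGE1_LIMIT_MM:
        evap_cap = min(potential_soil_evap, STAGE1_LIMIT_MM - evap_since_wetting)
    else:
        t = days_since_wetting + 1
        evap_cap = min(potential_soil_evap,
                       STAGE2_COEFF * (np.sqrt(t) - np.sqrt(t - 1)))
    actual_evap = min(evap_cap, max(stored[0] - ll[0], 0.0))
    stored[0] -= actual_evap

    return replace(
        state,
        stored_water=np.maximum(stored, ll),
        rain_in=state.rain_in + rain,
        drainage=state.drainage + drained_below,
        soil_evap=state.soil_evap + actual_evap,
        transpiration=state.transpiration + float(np.sum(uptake)),
        evap_since_wetting=evap_since_wetting + actual_evap,
        days_since_wetting=days_since_wetting + 1,
    )


def _layer_supply(stored: np.ndarray, profile: SoilProfile,
                  root_depth: float) -> np.ndarray:
    """kl-limited extractable water per layer for roots of ``root_depth`` mm.

    The deepest rooted layer contributes in proportion to root penetration.
    """
    depths = profile.layer_depths()
    tops = depths - profile.layer_thickness
    frac = np.clip((root_depth - tops) / profile.layer_thickness, 0.0, 1.0)
    avail = np.maximum(stored - profile.ll_mm, 0.0)
    return profile.kl * avail * frac


def water_supply_layers(state: SoilWaterState, root_depth: float) -> np.ndarray:
    """Per-layer potential daily root water supply (mm d^-1).

    Useful for apportioning a total uptake over layers: the kl-limited
    per-layer amounts remain extractable after same-day infiltration and
    drainage, so uptake sized from the morning supply never overdraws.
    """
    if root_depth < 0:
        raise ValueError("root_depth must be >= 0")
    return _layer_supply(state.stored_water, state.profile, root_depth)


def water_supply(state: SoilWaterState, profile: SoilProfile | None = None,
                 root_depth: float = 0.0) -> float:
    """Potential daily root water supply (mm d^-1).

    Sum over rooted layers of ``kl x (stored - LL)``, the supply side of the
    crop water supply/demand ratio.  Zero for an empty root zone.
    """
    profile = profile or state.profile
    if root_depth < 0:
        raise ValueError("root_depth must be >= 0")
    return float(_layer_supply(state.stored_water, profile, root_depth).sum())
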