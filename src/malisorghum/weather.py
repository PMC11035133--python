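"""Synthetic Sahelian/Sudanian daily weather and solar geometry.

Mali's sorghum belt has a strongly monsoonal climate: a single rainy season
from roughly June to October whose duration lengthens from north to south,
embedded in an otherwise dry year.  Because long-term station records for the
region are not freely redistributable, this module generates daily weather
series that emulate that climate zone by zone — a WGEN-style stochastic
generator (first-order two-state Markov chain for wet/dry days, gamma wet-day
amounts) calibrated so the expected annual total matches a site's isohyet
target, plus sinusoidal temperature and radiation cycles.

It also provides the astronomical day length (photoperiod) including the
civil-twilight extension used by photoperiod-sensitive phenology, and
read/write support for APSIM ``.met``-style and CSV weather files.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ISOHYET_ZONES",
    "SiteSpec",
    "DailyWeatherSeries",
    "WeatherValidationError",
    "daylength",
    "generate_season",
    "read_weather",
    "write_weather",
]

DAYS_PER_YEAR = 365  # fixed-length calendar; no leap handling

#: Recognised isohyet (mean-annual-rainfall) zones, north to south, and the
#: wet-window climatology used for each: mean onset / cessation day-of-year.
#: Onset is later and more variable in the drier north; cessation varies
#: little everywhere (mid-October, earlier northward).
ISOHYET_ZONES: dict[str, dict[str, float]] = {
    "400-600": {"onset_doy": 178.0, "cessation_doy": 253.0, "tmax_mean": 35.5, "tmin_mean": 21.5},
    "600-800": {"onset_doy": 170.0, "cessation_doy": 268.0, "tmax_mean": 34.5, "tmin_mean": 21.0},
    "800-1000": {"onset_doy": 163.0, "cessation_doy": 281.0, "tmax_mean": 33.5, "tmin_mean": 20.5},
    ">1000": {"onset_doy": 156.0, "cessation_doy": 291.0, "tmax_mean": 32.5, "tmin_mean": 20.0},
}

ONSET_SD_DAYS = 12.0
CESSATION_SD_DAYS = 5.0

# Markov-chain transition probabilities inside the wet window:
# P(wet | yesterday dry) and P(wet | yesterday wet).
P_WET_AFTER_DRY = 0.33
P_WET_AFTER_WET = 0.70
GAMMA_SHAPE = 0.9  # daily rainfall amounts are strongly right-skewed
OFF_SEASON_P_WET = 0.01  # rare out-of-season showers ("mango rains")
OFF_SEASON_MEAN_MM = 4.0


class WeatherValidationError(ValueError):
    """A weather series or file violates the daily-weather contract."""


@dataclass(frozen=True)
class SiteSpec:
    """A simulation site: where it is and what climate it should receive.

    Parameters
    ----------
    name : str
        Site label (e.g. ``"Samanko"``).
    latitude : float
        Degrees north, within [5, 20] (the Malian sorghum belt).
    isohyet_zone : str
        One of ``"400-600"``, ``"600-800"``, ``"800-1000"``, ``">1000"`` (mm).
    target_annual_rainfall : float
        Long-term mean annual rainfall the generator is calibrated to, mm.
    n_seasons : int
        Number of season-years available/generated for this site.
    """

    name: str
    latitude: float
    isohyet_zone: str
    target_annual_rainfall: float
    n_seasons: int = 1

    def __post_init__(self) -> None:
        if self.isohyet_zone not in ISOHYET_ZONES:
            raise WeatherValidationError(
                f"unknown isohyet zone {self.isohyet_zone!r}; "
                f"expected one of {sorted(ISOHYET_ZONES)}"
            )
        if not 5.0 <= self.latitude <= 20.0:
            raise WeatherValidationError(
                f"latitude {self.latitude} outside the supported [5, 20] degN band"
            )
        if self.target_annual_rainfall < 0:
            raise WeatherValidationError("target_annual_rainfall must be >= 0")
        if self.n_seasons < 1:
            raise WeatherValidationError("n_seasons must be >= 1")


@dataclass
class DailyWeatherSeries:
    """One calendar year of daily weather for a site.

    Arrays all have length 365 and are indexed by day of year - 1.
    ``photoperiod`` is derived (day length including civil twilight) and is
    recomputed from ``latitude`` rather than stored in files.
    """

    site: str
    latitude: float
    year: int
    rain: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    radiation: np.ndarray
    photoperiod: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("rain", "tmax", "tmin", "radiation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        self.validate()
        if self.photoperiod is None:
            self.photoperiod = daylength(
                self.latitude, self.day_of_year, twilight_angle=2.2
            )

    @property
    def day_of_year(self) -> np.ndarray:
        return np.arange(1, len(self.rain) + 1)

    def validate(self) -> None:
        n = len(self.rain)
        if not (len(self.tmax) == len(self.tmin) == len(self.radiation) == n):
            raise WeatherValidationError("weather columns have unequal lengths")
        if n != DAYS_PER_YEAR:
            raise WeatherValidationError(
                f"expected {DAYS_PER_YEAR} days, got {n}"
            )
        if not np.all(np.isfinite(self.rain)):
            raise WeatherValidationError("rain contains non-finite values")
        bad = np.flatnonzero(self.rain < 0)
        if bad.size:
            raise WeatherValidationError(
                f"negative rain on day of year {bad[0] + 1}"
            )
        bad = np.flatnonzero(self.tmax < self.tmin)
        if bad.size:
            raise WeatherValidationError(
                f"tmax < tmin on day of year {bad[0] + 1}"
            )
        if np.any(self.radiation < 0):
            raise WeatherValidationError("negative radiation")

    def annual_rainfall(self) -> float:
        return float(self.rain.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "day": self.day_of_year,
                "radn": self.radiation,
                "maxt": self.tmax,
                "mint": self.tmin,
                "rain": self.rain,
            }
        )


def daylength(latitude, day_of_year, twilight_angle: float = 0.0):
    """Day length in hours, optionally extended to a twilight sun angle.

    Uses the standard solar declination / hour-angle geometry with the
    horizon depressed by ``twilight_angle`` degrees, so day "starts" and
    "ends" when the sun centre is that far below the geometric horizon.
    Photoperiod-sensitive phenology conventionally uses 2.2 degrees.

    Parameters
    ----------
    latitude : float
        Degrees north (negative south); must satisfy ``|latitude| <= 60``.
    day_of_year : int or array
        1..366.
    twilight_angle : float
        Degrees below the horizon, >= 0 for a twilight extension.

    Returns
    -------
    float or ndarray
        Hours, strictly inside (0, 24).
    """
    lat = float(latitude)
    if abs(lat) > 60.0:
        raise ValueError(
            f"latitude {lat} not supported: polar day/night possible beyond +-60"
        )
    doy = np.asarray(day_of_year, dtype=float)
    decl = -23.45 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)
    phi = np.deg2rad(lat)
    delta = np.deg2rad(decl)
    alpha = np.deg2rad(-float(twilight_angle))  # sun elevation at day bounds
    cos_h = (np.sin(alpha) - np.sin(phi) * np.sin(delta)) / (
        np.cos(phi) * np.cos(delta)
    )
    if np.any(np.abs(cos_h) > 1.0):
        raise ValueError("sun never rises/sets for this latitude and day")
    hours = 2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0
    if np.ndim(day_of_year) == 0:
        return float(hours)
    return hours


def _site_rng(site: SiteSpec, seed: int, year: int) -> np.random.Generator:
    # crc32 gives a stable site hash across processes (builtin hash() is salted)
    tag = zlib.crc32(f"{site.name}|{year}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


def generate_season(site: SiteSpec, seed: int, year: int = 2000) -> DailyWeatherSeries:
    """Generate one synthetic season-year of daily weather for ``site``.

    The rainfall process is a first-order two-state Markov chain for wet/dry
    days inside a stochastically drawn wet window (onset ~ mid-June, sd 12 d,
    earlier southward; cessation ~ mid-October, sd 5 d), with gamma-distributed
    wet-day amounts whose scale follows a mid-season hump and is calibrated so
    the *expected* annual total equals ``site.target_annual_rainfall``.  About
    2% of the expected total is allotted to rare out-of-season showers, so at
    least ~95-98% of rain falls inside the wet window.  Temperatures and solar
    radiation follow sinusoidal annual cycles with Gaussian noise; wet days
    are slightly cooler and receive 20% less radiation.

    Deterministic: identical ``(site, seed, year)`` gives an identical series.
    """
    rng = _site_rng(site, seed, year)
    zone = ISOHYET_ZONES[site.isohyet_zone]
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)

    onset = zone["onset_doy"] + ONSET_SD_DAYS * rng.standard_normal()
    cessation = zone["cessation_doy"] + CESSATION_SD_DAYS * rng.standard_normal()
    onset = float(np.clip(onset, 130, 210))
    cessation = float(np.clip(cessation, max(onset + 30, 240), 330))
    in_window = (doy >= onset) & (doy <= cessation)

    # Wet/dry day occurrence (Markov inside the window, rare showers outside)
    wet = np.zeros(DAYS_PER_YEAR, dtype=bool)
    u = rng.random(DAYS_PER_YEAR)
    prev_wet = False
    for i in range(DAYS_PER_YEAR):
        if in_window[i]:
            p = P_WET_AFTER_WET if prev_wet else P_WET_AFTER_DRY
        else:
            p = OFF_SEASON_P_WET
        wet[i] = u[i] < p
        prev_wet = wet[i]

    # Seasonal intensity hump: heavier storms mid-season (Aug) than at edges
    mid = 0.5 * (onset + cessation)
    half = 0.5 * (cessation - onset)
    hump = np.where(
        in_window, 0.5 + 0.5 * np.cos(0.5 * np.pi * (doy - mid) / half) ** 2, 0.0
    )

    # Calibrate the in-window gamma mean so E[annual total] hits the target.
    pi_wet = P_WET_AFTER_DRY / (1.0 + P_WET_AFTER_DRY - P_WET_AFTER_WET)
    expected_offseason = (
        OFF_SEASON_P_WET * OFF_SEASON_MEAN_MM * float((~in_window).sum())
    )
    in_target = max(site.target_annual_rainfall - expected_offseason, 0.0)
    denom = pi_wet * float(hump[in_window].sum())
    base_mean = in_target / denom if denom > 0 else 0.0

    rain = np.zeros(DAYS_PER_YEAR)
    n_wet = int(wet.sum())
    if n_wet:
        mean_mm = np.where(in_window, base_mean * hump, OFF_SEASON_MEAN_MM)[wet]
        rain[wet] = rng.gamma(GAMMA_SHAPE, mean_mm / GAMMA_SHAPE)
    if site.target_annual_rainfall == 0:
        rain[:] = 0.0

    # Temperatures: hottest just before the monsoon (May), coolest around Jan;
    # wet days knock ~2 degC off the maximum.
    phase = 2.0 * np.pi * (doy - 135.0) / 365.0
    tmax = zone["tmax_mean"] + 3.5 * np.cos(phase) + 0.8 * rng.standard_normal(DAYS_PER_YEAR)
    tmin = zone["tmin_mean"] + 3.0 * np.cos(phase - 0.5) + 0.8 * rng.standard_normal(DAYS_PER_YEAR)
    tmax = tmax - 2.0 * wet
    tmax = np.maximum(tmax, tmin + 1.0)

    radn = 21.0 + 2.5 * np.cos(2.0 * np.pi * (doy - 120.0) / 365.0)
    radn = radn + 0.8 * rng.standard_normal(DAYS_PER_YEAR)
    radn = np.where(wet, 0.8 * radn, radn)
    radn = np.clip(radn, 4.0, None)

    return DailyWeatherSeries(
        site=site.name,
        latitude=site.latitude,
        year=year,
        rain=rain,
        tmax=tmax,
        tmin=tmin,
        radiation=radn,
    )


def wet_window(site: SiteSpec) -> tuple[float, float]:
    """Climatological (mean) wet-window bounds for a site's zone, as doy.

    Returned with a margin of three onset/cessation standard deviations so the
    window contains essentially all in-season rain realisations.
    """
    zone = ISOHYET_ZONES[site.isohyet_zone]
    return (
        zone["onset_doy"] - 3.0 * ONSET_SD_DAYS,
        zone["cessation_doy"] + 3.0 * CESSATION_SD_DAYS,
    )


# ---------------------------------------------------------------------------
# File I/O: APSIM ".met"-style and CSV dialects
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["year", "day", "radn", "maxt", "mint", "rain"]


def write_weather(series: DailyWeatherSeries, path, dialect: str = "met") -> None:
    """Write a series to ``path`` in the ``met`` or ``csv`` dialect.

    The ``met`` dialect is whitespace-separated with the APSIM column header
    (``year day radn maxt mint rain``) preceded by ``[weather.met.weather]``
    section lines carrying the site name and latitude; the ``csv`` dialect is
    a plain CSV with the same columns plus the same metadata as ``#`` comments.
    """
    frame = series.to_frame()
    if dialect == "met":
        with open(path, "w") as fh:
            fh.write("[weather.met.weather]\n")
            fh.write(f"site = {series.site}\n")
            fh.write(f"latitude = {series.latitude:.4f} (DECIMAL DEGREES)\n")
            fh.write(" ".join(_MET_COLUMNS) + "\n")
            fh.write("() () (MJ/m^2/day) (oC) (oC) (mm)\n")
            frame.to_string(fh, header=False, index=False)
            fh.write("\n")
    elif dialect == "csv":
        with open(path, "w") as fh:
            fh.write(f"# site = {series.site}\n")
            fh.write(f"# latitude = {series.latitude:.4f}\n")
            frame.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_weather(path, latitude: float | None = None) -> DailyWeatherSeries:
    """Read a ``met`` or ``csv`` weather file written by :func:`write_weather`.

    Also accepts generic files with the same column header.  Validates the
    series (no missing day, ``tmax >= tmin``, non-negative rain) and raises
    :class:`WeatherValidationError` naming the first offending day of year.
    """
    site = "unknown"
    lat = latitude
    header_idx = None
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        s = line.strip()
        low = s.lower().lstrip("# ")
        if low.startswith("site"):
            site = s.split("=", 1)[1].strip() if "=" in s else site
        elif low.startswith("latitude"):
            tok = s.split("=", 1)[1].strip().split()[0] if "=" in s else ""
            try:
                lat = float(tok)
            except ValueError:
                pass
        cols = s.replace(",", " ").split()
        if [c.lower() for c in cols[: len(_MET_COLUMNS)]] == _MET_COLUMNS:
            header_idx = i
            break
    if header_idx is None:
        raise WeatherValidationError(
            f"{path}: no '{' '.join(_MET_COLUMNS)}' header found"
        )
    body = lines[header_idx:]
    # drop the APSIM units line if present
    if len(body) > 1 and body[1].lstrip().startswith("("):
        body = [body[0]] + body[2:]
    frame = pd.read_csv(
        io.StringIO("".join(body)), sep=r"[,\s]+", engine="python", comment="#"
    )
    frame.columns = [c.lower() for c in frame.columns]
    missing = set(_MET_COLUMNS) - set(frame.columns)
    if missing:
        raise WeatherValidationError(f"{path}: missing columns {sorted(missing)}")

    days = frame["day"].to_numpy(dtype=int)
    expected = np.arange(days[0], days[0] + len(days))
    gaps = np.flatnonzero(days != expected)
    if gaps.size:
        raise WeatherValidationError(
            f"{path}: missing or out-of-order day at doy {int(expected[gaps[0]])}"
        )
    if lat is None:
        raise WeatherValidationError(
            f"{path}: latitude not found in file and not supplied"
        )
    return DailyWeatherSeries(
        site=site,
        latitude=float(lat),
        year=int(frame["year"].iloc[0]),
        rain=frame["rain"].to_numpy(dtype=float),
        tmax=frame["maxt"].to_numpy(dtype=float),
        tmin=frame["mint"].to_numpy(dtype=float),
        radiation=frame["radn"].to_numpy(dtype=float),
    )
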