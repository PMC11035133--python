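"""Goodness-of-fit statistics, divergence-line coverage, and run manifests."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitReport",
    "RunManifest",
    "fit_statistics",
    "divergence_coverage",
    "build_manifest",
]


@dataclass(frozen=True)
class FitReport:
    """Standard observed-vs-predicted agreement statistics.

    ``r_squared`` is the squared Pearson correlation (the regression-line
    reading); ``r_squared_1to1`` is 1 - SSE/SST about the 1:1 line, which can
    be negative for a fit worse than the observed mean — both are reported to
    avoid ambiguity.  NRMSE and MAPE are percentages.
    """

    n: int
    r_squared: float
    r_squared_1to1: float
    mse: float
    rmse: float
    nrmse: float
    mae: float
    mape: float
    cv_observed: float


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).reshape(-1)
    pred = np.asarray(predicted, dtype=float).reshape(-1)
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: {obs.size} observed vs {pred.size} predicted")
    if obs.size < 2:
        raise ValueError("need at least 2 paired values")
    return obs, pred


def fit_statistics(observed, predicted) -> FitReport:
    """Compute R2, MSE, RMSE, NRMSE (% of observed mean), MAE and MAPE (%)."""
    obs, pred = _check_pair(observed, predicted)
    err = pred - obs
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(err)))
    mean_obs = float(np.mean(obs))
    if mean_obs == 0.0:
        raise ValueError("NRMSE undefined: observed mean is zero")
    if np.any(obs == 0.0):
        raise ValueError("MAPE undefined: zero observed value(s)")
    nrmse = rmse / abs(mean_obs) * 100.0
    mape = float(np.mean(np.abs(err / obs))) * 100.0
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        r2 = 0.0  # correlation undefined for a constant series
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    sst = float(np.sum((obs - mean_obs) ** 2))
    r2_11 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("-inf")
    cv = float(np.std(obs, ddof=1) / abs(mean_obs)) * 100.0
    return FitReport(n=obs.size, r_squared=r2, r_squared_1to1=r2_11, mse=mse,
                     rmse=rmse, nrmse=nrmse, mae=mae, mape=mape, cv_observed=cv)


def divergence_coverage(observed, predicted,
                        threshold: float = 0.80) -> tuple[float, bool]:
    """Fraction of predictions within the divergence lines, and a pass flag.

    The divergence lines bracket the 1:1 line by the coefficient of variation
    of the observations: a point is inside when
    ``|pred - obs| <= CV * obs``.  A well-set-up model is expected to place
    about 80% of its predictions inside this space.
    """
    obs, pred = _check_pair(observed, predicted)
    mean_obs = float(np.mean(obs))
    if mean_obs == 0.0:
        raise ValueError("CV undefined: observed mean is zero")
    cv = float(np.std(obs, ddof=1) / abs(mean_obs))
    inside = np.abs(pred - obs) <= cv * np.abs(obs)
    coverage = float(np.mean(inside))
    return coverage, coverage >= threshold


@dataclass(frozen=True)
class RunManifest:
    """Enumeration of every site-year x soil x cultivar run in a study."""

    runs: tuple  # of (site, year_index, soil, cultivar)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.runs)


def build_manifest(sites, seasons_per_site, soils, cultivars,
                   seed: int = 0) -> RunManifest:
    """Enumerate all runs: sum over sites of seasons x |soils| x |cultivars|.

    ``seasons_per_site`` may be a single count or a per-site sequence; the
    459 site-year x 2 soil x 2 cultivar study design enumerates 1836 runs.
    """
    sites = list(sites)
    if np.ndim(seasons_per_site) == 0:
        seasons = [int(seasons_per_site)] * len(sites)
    else:
        seasons = [int(s) for s in seasons_per_site]
        if len(seasons) != len(sites):
            raise ValueError("seasons_per_site must match sites")
    if min(seasons, default=0) < 1 or not soils or not cultivars:
        raise ValueError("all counts must be >= 1")
    runs = tuple(
        (site, year, soil, cultivar)
        for site, n in zip(sites, seasons)
        for year, soil, cultivar in itertools.product(
            range(n), soils, cultivars)
    )
    return RunManifest(runs=runs, seed=seed)
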