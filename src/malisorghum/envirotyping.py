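"""Drought-scenario envirotyping from supply/demand trajectories.

Every simulated run is reduced to eight numbers: the mean crop water
supply/demand (S/D) ratio over the 100-degCd intervals spanning 400 degCd
before to 400 degCd after flowering.  Clustering these trajectories across
all runs (k-means or PAM on raw Euclidean distances — the values already
share the (0, 1] scale) partitions the seasons into recurring drought-stress
scenarios; with k = 3 these resolve into "no stress", "flowering stress"
(onset at flowering) and "early pre-flowering stress" (onset before
flowering, unrelieved to maturity).  Because weather-record depth differs
between rainfall zones, seasons are weighted so every isohyet zone carries
equal total weight before scenario frequencies and yield distributions are
summarised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "SCENARIO_LABELS",
    "SDTrajectory",
    "ScenarioAssignment",
    "WeightingSpec",
    "TrajectoryExclusionError",
    "extract_trajectory",
    "DroughtScenarioClassifier",
    "cluster_scenarios",
    "label_scenarios",
    "season_weight",
    "frequency_table",
    "yield_cpf",
]

#: Interval anchors (degCd relative to flowering): [-400,-300) ... (300,400];
#: the flowering day itself falls in the first post-flowering interval.
INTERVAL_EDGES = np.arange(-400, 500, 100)
N_INTERVALS = 8

NO_STRESS = "no_stress"
FLOWERING_STRESS = "flowering_stress"
EARLY_PREFLOWER_STRESS = "early_preflowering_stress"
SCENARIO_LABELS = (NO_STRESS, FLOWERING_STRESS, EARLY_PREFLOWER_STRESS)

NO_STRESS_CENTROID_MEAN = 0.95  # centroid mean above which a cluster is unstressed
ONSET_THRESHOLD = 0.9  # S/D below this marks stress onset in a centroid


class TrajectoryExclusionError(ValueError):
    """The run cannot supply the full +-400 degCd window around flowering."""


@dataclass(frozen=True)
class SDTrajectory:
    """Interval-averaged S/D trajectory for one run, plus its outcomes."""

    run_id: tuple  # (site, year, soil, cultivar)
    values: np.ndarray  # 8 interval means, each in (0, 1]
    flowering_doy: int
    grain_yield: float = float("nan")  # kg ha^-1
    biomass_yield: float = float("nan")
    isohyet: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (N_INTERVALS,):
            raise ValueError(f"expected {N_INTERVALS} interval means")
        if np.any(vals <= 0) or np.any(vals > 1.0 + 1e-12):
            raise ValueError("S/D interval means must lie in (0, 1]")


def _interval_index(p: float) -> int | None:
    """Index 0..7 of the interval containing thermal position ``p``
    (degCd relative to flowering); None outside +-400 degCd."""
    if p < -400.0 or p > 400.0:
        return None
    if p < 0.0:
        return min(int(np.floor((p + 400.0) / 100.0)), 3)
    if p == 0.0:
        return 4
    return 4 + min(int(np.ceil(p / 100.0)) - 1, 3)


def extract_trajectory(daily_sd, daily_tt, flowering_index: int,
                       run_id: tuple = ("", 0, "", ""),
                       **outcomes) -> SDTrajectory:
    """Average daily S/D into the 8 thermal-time intervals around flowering.

    ``flowering_index`` is the position (in the daily arrays) of the day on
    which the flowering transition occurred; a day's thermal position is its
    cumulative degCd distance from that day.  Raises
    :class:`TrajectoryExclusionError` if fewer than 400 degCd accumulated
    before or after flowering — such runs (crop failure, truncated season)
    are excluded from clustering and reported.
    """
    sd = np.asarray(daily_sd, dtype=float)
    tt = np.asarray(daily_tt, dtype=float)
    if sd.shape != tt.shape:
        raise ValueError("daily_sd and daily_tt must have the same length")
    cum = np.cumsum(tt)
    anchor = cum[flowering_index]
    pos = cum - anchor
    if -pos[0] + tt[0] < 400.0 - 1e-9:
        raise TrajectoryExclusionError(
            f"only {anchor - cum[0] + tt[0]:.0f} degCd accumulated before "
            "flowering; need 400")
    if pos[-1] < 400.0 - 1e-9:
        raise TrajectoryExclusionError(
            f"only {pos[-1]:.0f} degCd accumulated after flowering; need 400")
    sums = np.zeros(N_INTERVALS)
    counts = np.zeros(N_INTERVALS, dtype=int)
    for p, s in zip(pos, sd):
        idx = _interval_index(float(p))
        if idx is not None:
            sums[idx] += s
            counts[idx] += 1
    if np.any(counts == 0):
        raise TrajectoryExclusionError(
            f"empty thermal interval(s) {np.flatnonzero(counts == 0).tolist()}")
    return SDTrajectory(run_id=run_id, values=sums / counts,
                        flowering_doy=0, **outcomes)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pam(X: np.ndarray, k: int, rng: np.random.Generator,
         n_restarts: int = 1, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids (BUILD + SWAP) on Euclidean dissimilarities.

    Returns (medoid indices, labels).  Deterministic given ``rng``; ties
    broken by lowest objective then lexicographic medoid order.
    """
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)

    def total_cost(meds: np.ndarray) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best_meds, best_cost = None, np.inf
    for _ in range(n_restarts):
        # BUILD: greedy; first medoid minimises total distance
        meds = [int(np.argmin(d.sum(axis=0)))]
        while len(meds) < k:
            current = d[:, meds].min(axis=1)
            gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
            gains[meds] = -np.inf
            meds.append(int(np.argmax(gains)))
        meds = np.array(sorted(meds))
        cost = total_cost(meds)
        # SWAP: steepest-descent exchanges until no improvement
        for _ in range(max_iter):
            improved = False
            non_meds = np.setdiff1d(np.arange(n), meds)
            best_swap, best_swap_cost = None, cost
            for mi, m in enumerate(meds):
                for h in non_meds:
                    cand = meds.copy()
                    cand[mi] = h
                    c = total_cost(cand)
                    if c < best_swap_cost - 1e-12:
                        best_swap, best_swap_cost = cand, c
            if best_swap is not None:
                meds, cost = np.sort(best_swap), best_swap_cost
                improved = True
            if not improved:
                break
        if cost < best_cost - 1e-12:
            best_meds, best_cost = meds, cost
    labels = np.argmin(d[:, best_meds], axis=1)
    return best_meds, labels


class DroughtScenarioClassifier:
    """Cluster S/D trajectories into drought-stress scenarios.

    An sklearn-style estimator.  ``fit`` partitions the 8-interval
    trajectories with k-means (via :class:`sklearn.cluster.KMeans`,
    k-means++ initialisation, best of ``n_restarts``) or PAM (k-medoids,
    BUILD+SWAP on Euclidean dissimilarities); with ``n_clusters=3`` the
    clusters are mapped to agronomic labels by :func:`label_scenarios`.

    Fitted attributes: ``cluster_centers_`` (k x 8), ``labels_`` (cluster
    index per trajectory), ``scenario_names_`` (label per cluster index,
    when k = 3), ``inertia_`` (within-cluster sum of squares or total
    dissimilarity).
    """

    def __init__(self, n_clusters: int = 3, method: str = "kmeans",
                 n_restarts: int = 25, random_state: int = 0):
        self.n_clusters = n_clusters
        self.method = method
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "method": self.method,
                "n_restarts": self.n_restarts, "random_state": self.random_state}

    def set_params(self, **params) -> "DroughtScenarioClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_matrix(trajectories) -> np.ndarray:
        if isinstance(trajectories, np.ndarray):
            X = np.asarray(trajectories, dtype=float)
        else:
            X = np.array([t.values for t in trajectories], dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D trajectory matrix")
        return X

    def fit(self, trajectories, y=None) -> "DroughtScenarioClassifier":
        X = self._as_matrix(trajectories)
        k = self.n_clusters
        if len(np.unique(X, axis=0)) < k:
            raise ValueError(
                f"need at least {k} distinct trajectories, got "
                f"{len(np.unique(X, axis=0))}")
        if self.method == "kmeans":
            km = KMeans(n_clusters=k, n_init=self.n_restarts,
                        random_state=self.random_state).fit(X)
            centers, labels = km.cluster_centers_, km.labels_
            self.inertia_ = float(km.inertia_)
        elif self.method == "pam":
            rng = np.random.default_rng(self.random_state)
            meds, labels = _pam(X, k, rng, n_restarts=1)
            centers = X[meds]
            self.medoid_indices_ = meds
            self.inertia_ = float(
                np.linalg.norm(X - centers[labels], axis=1).sum())
        else:
            raise ValueError(f"unknown method {self.method!r}")
        # canonical cluster order: by descending centroid mean (least stressed
        # first) then lexicographic, so numbering is permutation-stable
        order = np.lexsort((*centers.T[::-1], -centers.mean(axis=1)))
        centers = centers[order]
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(k)
        labels = relabel[labels]
        self.cluster_centers_ = centers
        self.labels_ = labels
        self.scenario_names_ = (label_scenarios(centers)
                                if k == len(SCENARIO_LABELS) else None)
        return self

    def predict(self, trajectories) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("estimator is not fitted")
        X = self._as_matrix(trajectories)
        d = np.linalg.norm(X[:, None, :] - self.cluster_centers_[None], axis=2)
        return np.argmin(d, axis=1)

    def fit_predict(self, trajectories, y=None) -> np.ndarray:
        return self.fit(trajectories).labels_


@dataclass
class ScenarioAssignment:
    """Joint clustering result over a set of runs."""

    trajectories: list
    cluster_index: np.ndarray  # per run
    centroids: np.ndarray  # k x 8
    scenario_names: tuple  # per cluster index
    method: str

    @property
    def scenarios(self) -> list[str]:
        return [self.scenario_names[i] for i in self.cluster_index]


def cluster_scenarios(trajectories, k: int = 3, method: str = "kmeans",
                      seed: int = 0, n_restarts: int = 25) -> ScenarioAssignment:
    """Cluster runs into ``k`` scenarios; labels attached when k = 3."""
    est = DroughtScenarioClassifier(n_clusters=k, method=method,
                                    n_restarts=n_restarts, random_state=seed)
    est.fit(trajectories)
    names = est.scenario_names_ or tuple(f"cluster_{i}" for i in range(k))
    return ScenarioAssignment(
        trajectories=list(trajectories), cluster_index=est.labels_,
        centroids=est.cluster_centers_, scenario_names=names, method=method)


class ScenarioLabelingError(ValueError):
    """Cluster centroids cannot be mapped unambiguously to scenario names."""


def label_scenarios(centroids) -> tuple:
    """Map 3 cluster centroids to agronomic scenario names.

    The centroid whose mean S/D is at least 0.95 over all 8 intervals is
    "no stress" (exactly one must qualify).  Of the remaining two, the one
    whose S/D first drops below 0.9 in a pre-flowering interval is the
    "early pre-flowering stress"; the other (onset at or after flowering) is
    the "flowering stress".  Order-invariant in the input.
    """
    C = np.asarray(centroids, dtype=float)
    if C.shape != (3, N_INTERVALS):
        raise ValueError("expected exactly 3 centroids of 8 intervals")
    unstressed = np.flatnonzero(C.mean(axis=1) >= NO_STRESS_CENTROID_MEAN)
    if len(unstressed) != 1:
        raise ScenarioLabelingError(
            f"{len(unstressed)} centroids have mean S/D >= "
            f"{NO_STRESS_CENTROID_MEAN}; cannot identify a unique no-stress "
            "scenario (consider a different k)")
    names = [None, None, None]
    names[unstressed[0]] = NO_STRESS
    rest = [i for i in range(3) if i != unstressed[0]]

    def onset(row: np.ndarray) -> int:
        below = np.flatnonzero(row < ONSET_THRESHOLD)
        return int(below[0]) if below.size else N_INTERVALS

    onsets = [onset(C[i]) for i in rest]
    if onsets[0] == onsets[1]:
        # tie: the centroid with the lower pre-flowering mean started earlier
        early = rest[int(np.argmin([C[i, :4].mean() for i in rest]))]
    else:
        early = rest[int(np.argmin(onsets))]
    late = rest[0] if rest[1] == early else rest[1]
    names[early] = EARLY_PREFLOWER_STRESS
    names[late] = FLOWERING_STRESS
    return tuple(names)


# ---------------------------------------------------------------------------
# Weighting and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightingSpec:
    """Season counts used for the equal-isohyet weighting."""

    seasons_in_isohyet: dict  # isohyet -> count

    def __post_init__(self) -> None:
        if not self.seasons_in_isohyet:
            raise ValueError("need at least one isohyet")
        if any(c < 1 for c in self.seasons_in_isohyet.values()):
            raise ValueError("every isohyet needs at least one season")

    @property
    def max_seasons(self) -> int:
        return max(self.seasons_in_isohyet.values())

    @property
    def total_seasons(self) -> int:
        return sum(self.seasons_in_isohyet.values())


def season_weight(spec: WeightingSpec, isohyet: str) -> float:
    """Weight of one season in ``isohyet``:

        max seasons over isohyets / (total seasons x seasons in this isohyet)

    so each isohyet's seasons carry equal total weight regardless of how
    deep its weather record is.
    """
    try:
        n = spec.seasons_in_isohyet[isohyet]
    except KeyError:
        raise KeyError(f"unknown isohyet {isohyet!r}") from None
    return spec.max_seasons / (spec.total_seasons * n)


def frequency_table(assignment: ScenarioAssignment, spec: WeightingSpec,
                    group_by: tuple = ("isohyet", "soil", "cultivar")) -> pd.DataFrame:
    """Weighted scenario frequencies (%) per group; rows sum to 100.

    ``group_by`` may name any of ``isohyet``, ``soil``, ``cultivar``.
    """
    records = []
    for traj, scen in zip(assignment.trajectories, assignment.scenarios):
        site, year, soil, cultivar = traj.run_id
        records.append({
            "isohyet": traj.isohyet, "soil": soil, "cultivar": cultivar,
            "scenario": scen,
            "weight": season_weight(spec, traj.isohyet),
        })
    frame = pd.DataFrame.from_records(records)
    keys = list(group_by)
    grouped = (frame.groupby(keys + ["scenario"], sort=True)["weight"]
               .sum().unstack("scenario", fill_value=0.0))
    for name in SCENARIO_LABELS:
        if name not in grouped.columns:
            grouped[name] = 0.0
    grouped = grouped[list(SCENARIO_LABELS)]
    pct = grouped.div(grouped.sum(axis=1), axis=0) * 100.0
    return pct


def yield_cpf(yields, weights=None) -> pd.DataFrame:
    """Weighted empirical cumulative probability curve of yields.

    Returns a frame with sorted unique ``yield`` values and the cumulative
    probability ``cpf`` (0..1] attained at each; non-decreasing by
    construction.
    """
    y = np.asarray(yields, dtype=float)
    if y.size == 0:
        raise ValueError("need at least one yield")
    w = (np.ones_like(y) if weights is None
         else np.asarray(weights, dtype=float))
    if w.shape != y.shape:
        raise ValueError("weights must match yields")
    order = np.argsort(y, kind="stable")
    y, w = y[order], w[order]
    cum = np.cumsum(w) / w.sum()
    # collapse duplicate yield values to their last (highest) cumulative prob
    frame = pd.DataFrame({"yield": y, "cpf": cum}).groupby("yield", sort=True).max()
    return frame.reset_index()
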