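"""Expression-trend analysis: z-scores, fuzzy c-means, paralogue pattern calls.

Per-gene profiles over a developmental series are standardized to z-scores
(mean 0, sample SD 1) and soft-clustered with fuzzy c-means into k clusters
(default 6).  Within gene families, paralogues are classified as expressed
in a *similar* (concerted) or *different* (contrasting) manner from the
pairwise Pearson correlation of their raw RPKM profiles: Pearson r is
location/scale invariant, so paralogues transcribed at very different
absolute levels but with matching fluctuation trends still score r ~ 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError
from .io import GeneFamilyMap

DEFAULT_K = 6
DEFAULT_FUZZIFIER = 2.0
DEFAULT_R_THRESHOLD = 0.5
DEFAULT_EXPRESSION_FLOOR = 1.0


@dataclass
class PatternParams:
    """Fuzzy c-means settings.

    ``m`` is the fuzzifier (> 1; 2.0 is the conventional default, m -> 1
    approaches hard k-means).  ``n_starts`` random initializations are run
    and the solution with the lowest final objective wins (ties broken by
    the lowest start index).
    """

    k: int = DEFAULT_K
    m: float = DEFAULT_FUZZIFIER
    max_iter: int = 300
    tol: float = 1e-9
    n_starts: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.m <= 1:
            raise ConfigurationError(f"fuzzifier m must be > 1, got {self.m}")
        if self.tol <= 0:
            raise ConfigurationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.n_starts < 1:
            raise ConfigurationError(f"n_starts must be >= 1, got {self.n_starts}")


@dataclass
class FuzzyClustering:
    """Soft clustering result: memberships, centers and the objective trace."""

    membership: pd.DataFrame  # genes x k, rows sum to 1
    centers: pd.DataFrame  # k x series positions
    objective: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def hard_labels(self) -> pd.Series:
        labels = self.membership.to_numpy().argmax(axis=1)
        return pd.Series(labels, index=self.membership.index, name="cluster")


def zscore(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize each row to mean 0 and sample SD (ddof=1) 1.

    Constant rows cannot be standardized; they come back as all-zero rows
    with their flag set in the returned boolean Series.
    """
    if profiles.shape[1] < 2:
        raise ConfigurationError("need >= 2 columns to standardize profiles")
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (arr - mean) / sd
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=profiles.index, columns=profiles.columns),
        pd.Series(constant, index=profiles.index, name="constant"),
    )


def fuzzy_cmeans(data: pd.DataFrame, params: PatternParams) -> FuzzyClustering:
    """Fuzzy c-means by alternating minimization of the weighted objective

        J = sum_i sum_j u_ij^m ||x_i - c_j||^2

    Memberships update as u_ij proportional to d_ij^(-2/(m-1)); centers are
    the u^m-weighted means.  A profile exactly coincident with a center gets
    full membership in that center (the standard singularity rule).  Each of
    the ``n_starts`` seeded starts initializes the centers at k distinct
    randomly drawn profiles (a symmetric membership initialization collapses
    every center onto the global mean, a degenerate fixed point); the best
    final objective wins and identical seeds reproduce identical results.
    """
    params.validate()
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    if n < params.k:
        raise ConfigurationError(f"{n} profiles cannot support k={params.k} clusters")

    children = np.random.SeedSequence(params.seed).spawn(params.n_starts)
    best: tuple[float, int, np.ndarray, np.ndarray, list[float]] | None = None
    for start, child in enumerate(children):
        rng = np.random.default_rng(child)
        centers0 = X[rng.choice(n, size=params.k, replace=False)]
        U, centers, objective, trace = _fcm_iterate(X, centers0, params)
        if best is None or objective < best[0] - 1e-12:
            best = (objective, start, U, centers, trace)
    assert best is not None
    objective, _, U, centers, trace = best
    return FuzzyClustering(
        membership=pd.DataFrame(
            U, index=data.index, columns=[f"cluster_{j}" for j in range(params.k)]
        ),
        centers=pd.DataFrame(
            centers, index=[f"cluster_{j}" for j in range(params.k)], columns=data.columns
        ),
        objective=float(objective),
        objective_trace=trace,
    )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij from squared distances, with the coincident-point singularity rule."""
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
    rows = zero.any(axis=1)
    if rows.any():
        U[rows] = 0.0
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def _fcm_iterate(
    X: np.ndarray, centers: np.ndarray, params: PatternParams
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    m = params.m
    trace: list[float] = []
    prev = np.inf
    U = np.empty((X.shape[0], params.k))
    for _ in range(params.max_iter):
        U = _memberships(cdist(X, centers, metric="sqeuclidean"), m)
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        # objective after both half-steps: non-increasing across iterations
        objective = float((Um * cdist(X, centers, metric="sqeuclidean")).sum())
        trace.append(objective)
        if abs(prev - objective) < params.tol:
            break
        prev = objective
    return U, centers, trace[-1], trace


def classify_family_patterns(
    expr: pd.DataFrame,
    fam_map: GeneFamilyMap,
    series: dict[str, list[str]],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    min_series_length: int = 5,
) -> pd.DataFrame:
    """Label each family's paralogue trends as similar/different per family.

    Within each developmental series, a member counts as *expressed* when
    its maximum RPKM over the series reaches ``expression_floor``.  Pairwise
    Pearson r is computed among expressed members on raw RPKM profiles; a
    family is ``similar`` iff every pairwise r reaches ``r_threshold`` in
    every evaluated series with >= 2 expressed members, ``different``
    otherwise, and ``insufficient_data`` when no series qualifies.  Series
    shorter than ``min_series_length`` sample groups are not evaluated: a
    correlation over 3 points carries essentially no trend information.
    Members constant across a series contribute r = 0 (no trend evidence).

    Returns one row per family: ``label``, ``min_pairwise_r``,
    ``n_series_evaluated``, ``n_members``.
    """
    for name, codes in series.items():
        unknown = [c for c in codes if c not in expr.columns]
        if unknown:
            raise ConfigurationError(f"series {name!r}: unknown sample codes {unknown}")

    records = []
    for fam in fam_map.families:
        members = [g for g in fam_map.members(fam) if g in expr.index]
        min_rs: list[float] = []
        n_eval = 0
        for name, codes in series.items():
            if len(codes) < min_series_length:
                continue  # too short for a meaningful trend correlation
            sub = expr.loc[members, codes]
            expressed = sub.max(axis=1) >= expression_floor
            genes = list(sub.index[expressed])
            if len(genes) < 2:
                continue
            n_eval += 1
            prof = sub.loc[genes].to_numpy(dtype=float)
            rs = []
            for a, b in itertools.combinations(range(len(genes)), 2):
                r = _pearson(prof[a], prof[b])
                rs.append(r)
            min_rs.append(min(rs))
        if n_eval == 0:
            label, min_r = "insufficient_data", np.nan
        else:
            min_r = float(min(min_rs))
            label = "similar" if min_r >= r_threshold else "different"
        records.append((fam, label, min_r, n_eval, len(members)))
    return pd.DataFrame(
        records,
        columns=["family_id", "label", "min_pairwise_r", "n_series_evaluated", "n_members"],
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 when either profile is constant (no trend information)."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
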