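"""Sample-based species accumulation and total-species (T-S) extrapolation.

The T-S procedure estimates the richness of a much larger area than was
sampled by exploiting heterogeneity between sub-areas: accumulation curves
are computed for every combination of k sub-areas (k = 1..K) and their mean
terminal richness T_k is regressed on the logarithm of sampling effort; the
fitted line is read off at the target effort (e.g. 10^6 root systems of 24
clones each).  Because T_k grows with the between-sub-area turnover actually
observed, the extrapolation corrects the downward bias of reading richness
off a single accumulation curve.  Uncertainty is judged by bootstrap
resampling of sub-areas with replacement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator


def _as_bool_matrix(incidence) -> np.ndarray:
    X = np.asarray(incidence)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("incidence must be a non-empty 2-D sample x OTU matrix")
    return X > 0


@dataclass
class AccumulationCurve:
    """Expected richness as a function of number of pooled samples."""

    x: np.ndarray  # 1..N samples
    mean: np.ndarray
    sd: np.ndarray | None
    mode: str
    n_permutations: int | None = None
    per_permutation: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_samples": self.x, "mean_richness": self.mean,
             "sd_richness": self.sd if self.sd is not None else np.nan}
        )


def exact_accumulation(incidence) -> AccumulationCurve:
    """Closed-form expected accumulation curve.

    E[S_k] = sum_j [1 - C(N - n_j, k) / C(N, k)] where n_j is the number of
    samples containing OTU j -- the sample-based rarefaction expectation
    under random sample orderings.
    """
    X = _as_bool_matrix(incidence)
    N = X.shape[0]
    n_j = X.sum(axis=0).astype(float)
    k = np.arange(1, N + 1)

    def log_comb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    means = np.empty(N)
    for i, kk in enumerate(k):
        with np.errstate(invalid="ignore"):
            frac = np.where(
                N - n_j >= kk,
                np.exp(log_comb(N - n_j, kk) - log_comb(N, kk)),
                0.0,
            )
        means[i] = float(np.sum(1.0 - frac))
    return AccumulationCurve(k, means, None, "exact")


def permutation_accumulation(
    incidence, n_permutations: int = 1000, seed=None, keep_permutations: bool = False
) -> AccumulationCurve:
    """Monte-Carlo accumulation curve over random sample orderings."""
    X = _as_bool_matrix(incidence)
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    richness = np.empty((n_permutations, N))
    chunk = max(1, int(2e7 // max(1, X.size)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        orders = np.argsort(rng.random((b, N)), axis=1)
        cum = np.logical_or.accumulate(X[orders], axis=1)
        richness[done : done + b] = cum.sum(axis=2)
        done += b
    curve = AccumulationCurve(
        np.arange(1, N + 1),
        richness.mean(axis=0),
        richness.std(axis=0, ddof=1),
        "permutation",
        n_permutations,
        richness if keep_permutations else None,
    )
    return curve


def accumulation_curve(
    incidence, n_permutations: int = 1000, seed=None, mode: str = "permutation"
) -> AccumulationCurve:
    """Sample-based species-accumulation curve (permutation or exact)."""
    if mode == "exact":
        return exact_accumulation(incidence)
    if mode == "permutation":
        return permutation_accumulation(incidence, n_permutations, seed)
    raise ValueError(f"unknown mode {mode!r}")


def _subarea_matrices(incidence, groups) -> tuple[np.ndarray, np.ndarray]:
    """Pooled incidence (K x S) and sample counts per sub-area."""
    X = _as_bool_matrix(incidence)
    groups = np.asarray(groups)
    if len(groups) != X.shape[0]:
        raise ValueError("groups must label every sample row")
    labels = pd.unique(groups)
    pooled = np.stack([X[groups == g].any(axis=0) for g in labels])
    sizes = np.array([(groups == g).sum() for g in labels])
    if (sizes == 0).any():
        raise ValueError("empty sub-area")
    return pooled, sizes


def combination_terminal_points(
    incidence,
    groups,
    max_combinations: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Mean pooled richness over combinations of k sub-areas, k = 1..K.

    All C(K, k) combinations are enumerated when their number does not
    exceed ``max_combinations``; otherwise a seeded random subset of that
    size is drawn.  Returns columns k, n_samples (mean sampling effort of
    the combinations) and t_mean (the T_k terminal richness).
    """
    pooled, sizes = _subarea_matrices(incidence, groups)
    K = pooled.shape[0]
    if K < 2:
        raise ValueError("need at least two sub-areas")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, K + 1):
        n_comb = math.comb(K, k)
        if n_comb <= max_combinations:
            combos = itertools.combinations(range(K), k)
        else:
            combos = (
                rng.choice(K, size=k, replace=False) for _ in range(max_combinations)
            )
        rich, effort = [], []
        for combo in combos:
            idx = np.fromiter(combo, dtype=int)
            rich.append(pooled[idx].any(axis=0).sum())
            effort.append(sizes[idx].sum())
        rows.append(
            {"k": k, "n_samples": float(np.mean(effort)), "t_mean": float(np.mean(rich))}
        )
    return pd.DataFrame(rows)


@dataclass
class TSEstimate:
    """Terminal points, log-linear fit and extrapolated total richness."""

    terminal_points: pd.DataFrame
    intercept: float
    slope: float
    target_subareas: float
    samples_per_subarea: float
    estimate: float
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    n_bootstrap: int | None = None


def ts_extrapolate(
    terminal_points: pd.DataFrame,
    target_subareas: float = 1e6,
    window: int | None = None,
) -> TSEstimate:
    """Least-squares fit of T_k on ln(sampling effort), extrapolated.

    ``window`` restricts the fit to the last m terminal points (default: all
    points).  The estimate is the fitted value at an effort of
    ``target_subareas`` sub-areas of the observed mean size.
    """
    tp = terminal_points.reset_index(drop=True)
    if window is not None:
        tp = tp.tail(window).reset_index(drop=True)
    if len(tp) < 2:
        raise ValueError("need at least two terminal points to extrapolate")
    x = np.log(tp["n_samples"].to_numpy(dtype=float))
    y = tp["t_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log effort; cannot fit")
    fit = stats.linregress(x, y)
    m = tp["n_samples"].iloc[-1] / tp["k"].iloc[-1]
    target_effort = target_subareas * m
    estimate = fit.intercept + fit.slope * np.log(target_effort)
    return TSEstimate(
        terminal_points=terminal_points,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        target_subareas=float(target_subareas),
        samples_per_subarea=float(m),
        estimate=float(estimate),
    )


def _replicate_estimate(
    pooled: np.ndarray,
    sizes: np.ndarray,
    choice: np.ndarray,
    max_combinations: int,
    rng,
    target_subareas: float,
    window: int | None,
) -> float:
    # terminal points only need the pooled sub-area rows, so resampled
    # sub-areas are rebuilt directly without expanding to pseudo-samples
    rep_pooled = pooled[choice]
    K = len(choice)
    rows = []
    for k in range(1, K + 1):
        n_comb = math.comb(K, k)
        if n_comb <= max_combinations:
            combos = itertools.combinations(range(K), k)
        else:
            combos = (
                rng.choice(K, size=k, replace=False) for _ in range(max_combinations)
            )
        rich, effort = [], []
        for combo in combos:
            idx = np.fromiter(combo, dtype=int)
            rich.append(rep_pooled[idx].any(axis=0).sum())
            effort.append(sizes[choice][idx].sum())
        rows.append({"k": k, "n_samples": np.mean(effort), "t_mean": np.mean(rich)})
    tp = pd.DataFrame(rows)
    return ts_extrapolate(tp, target_subareas, window).estimate


def bootstrap_ts(
    incidence,
    groups,
    n_bootstrap: int = 100,
    seed=None,
    target_subareas: float = 1e6,
    max_combinations: int = 200,
    window: int | None = None,
    method: str = "sample",
) -> tuple[float, float, np.ndarray]:
    """Bootstrap the T-S estimate by resampling sub-areas with replacement.

    Returns (mean, sd, replicate estimates) over ``n_bootstrap`` replicates.
    A degenerate replicate in which every drawn sub-area is the same one is
    redrawn (up to 100 attempts).  ``method="exhaustive"`` enumerates the
    full K^K resample space instead (feasible only for tiny K; used as an
    oracle surface).
    """
    pooled, sizes = _subarea_matrices(incidence, groups)
    K = pooled.shape[0]
    rng = np.random.default_rng(seed)
    estimates = []
    if method == "exhaustive":
        for choice in itertools.product(range(K), repeat=K):
            estimates.append(
                _replicate_estimate(
                    pooled, sizes, np.array(choice), max_combinations, rng,
                    target_subareas, window,
                )
            )
    elif method == "sample":
        for _ in range(n_bootstrap):
            for _attempt in range(100):
                choice = rng.integers(0, K, size=K)
                if len(np.unique(choice)) > 1:
                    break
            estimates.append(
                _replicate_estimate(
                    pooled, sizes, choice, max_combinations, rng,
                    target_subareas, window,
                )
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    est = np.array(estimates)
    return float(est.mean()), float(est.std(ddof=1)), est


class TotalSpeciesEstimator(BaseEstimator):
    """Total-species richness estimator over heterogeneous sub-areas.

    Scikit-learn style: ``fit(X, groups=...)`` takes a sample x OTU
    incidence matrix and a sub-area label per sample, computes combination
    terminal points, the log-linear fit, the extrapolated richness and its
    bootstrap spread.

    Attributes (after fit): ``terminal_points_``, ``intercept_``, ``slope_``,
    ``estimate_``, ``observed_richness_``, ``bootstrap_mean_``,
    ``bootstrap_sd_``.
    """

    def __init__(
        self,
        target_subareas: float = 1e6,
        max_combinations: int = 200,
        n_bootstrap: int = 100,
        window: int | None = None,
        random_state: int | None = None,
    ):
        self.target_subareas = target_subareas
        self.max_combinations = max_combinations
        self.n_bootstrap = n_bootstrap
        self.window = window
        self.random_state = random_state

    def fit(self, X, y=None, groups=None):
        if groups is None:
            raise ValueError("groups (sub-area label per sample) is required")
        ss = np.random.SeedSequence(self.random_state)
        s_tp, s_boot = ss.spawn(2)
        tp = combination_terminal_points(
            X, groups, self.max_combinations, seed=s_tp
        )
        est = ts_extrapolate(tp, self.target_subareas, self.window)
        self.terminal_points_ = tp
        self.intercept_ = est.intercept
        self.slope_ = est.slope
        self.samples_per_subarea_ = est.samples_per_subarea
        self.estimate_ = est.estimate
        self.observed_richness_ = int(_as_bool_matrix(X).any(axis=0).sum())
        if self.n_bootstrap and self.n_bootstrap > 0:
            mean, sd, reps = bootstrap_ts(
                X,
                groups,
                n_bootstrap=self.n_bootstrap,
                seed=s_boot,
                target_subareas=self.target_subareas,
                max_combinations=self.max_combinations,
                window=self.window,
            )
            self.bootstrap_mean_, self.bootstrap_sd_ = mean, sd
            self.bootstrap_estimates_ = reps
        else:
            self.bootstrap_mean_ = self.bootstrap_sd_ = None
            self.bootstrap_estimates_ = None
        return self

    def result_(self) -> TSEstimate:
        return TSEstimate(
            self.terminal_points_,
            self.intercept_,
            self.slope_,
            self.target_subareas,
            self.samples_per_subarea_,
            self.estimate_,
            self.bootstrap_mean_,
            self.bootstrap_sd_,
            self.n_bootstrap,
        )
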