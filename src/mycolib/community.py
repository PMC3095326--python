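"""Hierarchical sharing statistics, dissimilarity and ordination.

Community structure is summarised at three spatial levels (root systems
within sub-localities, sub-localities within main localities, and between
main localities), and the main compositional gradients are extracted by two
ordination methods run in parallel -- correspondence analysis with optional
detrending (CA/DCA) and global non-metric multidimensional scaling (NMDS) on
Sørensen dissimilarities.  Concordant orderings from the two methods
(checked with Kendall's rank correlation) indicate that the gradients are a
property of the data rather than of either algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof


# ---------------------------------------------------------------------------
# sharing statistics


def shared_otu_stats(incidence: pd.DataFrame, hierarchy: pd.DataFrame) -> pd.DataFrame:
    """Mean number of OTUs shared by root-system pairs, per spatial stratum.

    ``incidence`` is OTU x root-system 0/1; ``hierarchy`` maps root_system to
    sub_locality and main_locality.  Pairs are stratified as within
    sub-locality, between sub-localities of the same main locality, and
    between main localities.
    """
    h = hierarchy.set_index("root_system")
    rs = list(incidence.columns)
    missing = [r for r in rs if r not in h.index]
    if missing:
        raise ValueError(f"root systems missing from hierarchy: {missing}")
    X = (incidence.to_numpy() > 0).astype(int)
    shared = X.T @ X
    strata: dict[str, list[int]] = {
        "within_sublocality": [],
        "between_sublocalities": [],
        "between_main_localities": [],
    }
    for i in range(len(rs)):
        for j in range(i + 1, len(rs)):
            a, b = h.loc[rs[i]], h.loc[rs[j]]
            if a["sub_locality"] == b["sub_locality"]:
                key = "within_sublocality"
            elif a["main_locality"] == b["main_locality"]:
                key = "between_sublocalities"
            else:
                key = "between_main_localities"
            strata[key].append(shared[i, j])
    rows = [
        {
            "stratum": k,
            "mean_shared": float(np.mean(v)) if v else np.nan,
            "n_pairs": len(v),
        }
        for k, v in strata.items()
    ]
    return pd.DataFrame(rows)


def venn_counts(sets: list[set]) -> pd.Series:
    """Counts of the 7 regions of a three-set Venn diagram.

    Region keys are membership patterns over (A, B, C), e.g. '110' = in A
    and B but not C.  Counts sum to the size of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly three sets")
    a, b, c = (set(s) for s in sets)
    out = {}
    for pattern in ("100", "010", "001", "110", "101", "011", "111"):
        inc = [s for s, bit in zip((a, b, c), pattern) if bit == "1"]
        exc = [s for s, bit in zip((a, b, c), pattern) if bit == "0"]
        region = set.intersection(*inc) - set().union(*exc)
        out[pattern] = len(region)
    return pd.Series(out, name="count")


def sorensen_dissimilarity(incidence) -> np.ndarray:
    """Pairwise Sørensen dissimilarity 1 - 2|A∩B| / (|A|+|B|) between rows.

    The qualitative (presence/absence) reduction of percentage (Bray-Curtis)
    dissimilarity.  A pair of empty rows is defined to have distance 0.
    """
    X = (np.asarray(incidence) > 0).astype(float)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(denom > 0, 2.0 * inter / np.where(denom == 0, 1, denom), 1.0)
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ordination

@dataclass
class OrdinationResult:
    """Two-axis site ordination from CA/DCA or NMDS."""

    scores: np.ndarray  # sites x axes
    method: str
    eigenvalues: np.ndarray | None = None
    gradient_lengths: np.ndarray | None = None  # DCA only, approximate
    gradient_lengths_approximate: bool = True
    stress: float | None = None  # NMDS only
    n_converged_starts: int | None = None
    accepted: bool | None = None
    site_labels: list | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.site_labels or range(len(self.scores))
        df = pd.DataFrame(
            self.scores[:, :2], index=idx, columns=["axis1", "axis2"]
        )
        df["method"] = self.method
        return df


class CorrespondenceAnalysis(BaseEstimator):
    """Correspondence analysis of a site x species abundance/incidence matrix.

    Eigen-decomposition of the chi-square standardised matrix; site scores
    are returned in principal coordinates, so eigenvalues lie in [0, 1).
    All-zero rows or columns are dropped with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or min(X.shape) < 3:
            raise ValueError("need a matrix with at least 3 sites and 3 species")
        row_ok = X.sum(axis=1) > 0
        col_ok = X.sum(axis=0) > 0
        if not row_ok.all() or not col_ok.all():
            warnings.warn("dropping all-zero rows/columns before CA")
        self.row_kept_ = np.nonzero(row_ok)[0]
        self.col_kept_ = np.nonzero(col_ok)[0]
        X = X[np.ix_(self.row_kept_, self.col_kept_)]

        P = X / X.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S, full_matrices=False)
        # drop the trivial/null dimensions
        keep = s > 1e-10
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        n_axes = min(self.n_components, len(s))
        if n_axes < self.n_components:
            warnings.warn(
                f"rank-deficient matrix: only {n_axes} ordination axes available"
            )
        self.eigenvalues_ = s[:n_axes] ** 2
        self.row_scores_ = (U[:, :n_axes] * s[:n_axes]) / np.sqrt(r)[:, None]
        self.col_scores_ = Vt[:n_axes].T / np.sqrt(c)[:, None]
        self.row_weights_ = r
        return self.row_scores_

    def result(self, site_labels=None) -> OrdinationResult:
        return OrdinationResult(
            scores=self.row_scores_,
            method="CA",
            eigenvalues=self.eigenvalues_,
            site_labels=site_labels,
        )


def _detrend_by_segments(axis1: np.ndarray, z: np.ndarray, n_segments: int) -> np.ndarray:
    """Subtract the within-segment mean of z over equal-width segments of axis1."""
    edges = np.linspace(axis1.min(), axis1.max(), n_segments + 1)
    seg = np.clip(np.searchsorted(edges, axis1, side="right") - 1, 0, n_segments - 1)
    out = z.astype(float).copy()
    for s in np.unique(seg):
        mask = seg == s
        out[mask] -= out[mask].mean()
    return out


class DetrendedCorrespondenceAnalysis(BaseEstimator):
    """CA with axis 2+ detrended against axis 1 by segments.

    Removes the arch effect: higher-axis scores have their within-segment
    means (over ``n_segments`` equal-width segments of axis 1) subtracted,
    iterating with re-orthogonalisation against axis 1 under the row-mass
    inner product.  Hill's non-linear rescaling is *not* performed; the
    reported gradient lengths are a labelled approximation (score range
    divided by the mean within-site weighted standard deviation of species
    scores) and carry an ``approximate`` flag.
    """

    def __init__(self, n_components: int = 2, n_segments: int = 26, n_iter: int = 10):
        self.n_components = n_components
        self.n_segments = n_segments
        self.n_iter = n_iter

    def fit_transform(self, X, y=None) -> np.ndarray:
        ca = CorrespondenceAnalysis(n_components=max(self.n_components, 2))
        scores = ca.fit_transform(X)
        self.ca_ = ca
        r = ca.row_weights_
        axis1 = scores[:, 0]
        out = [axis1]
        for a in range(1, scores.shape[1]):
            z = scores[:, a].copy()
            for _ in range(self.n_iter):
                # re-orthogonalise against axis 1 (row-mass inner product)
                z = z - (np.sum(r * z * axis1) / np.sum(r * axis1**2)) * axis1
                z = _detrend_by_segments(axis1, z, self.n_segments)
            norm = np.sqrt(np.sum(r * z**2))
            if norm > 0:
                z = z * (np.sqrt(ca.eigenvalues_[a]) / norm) * np.sqrt(np.sum(r * axis1**2) / ca.eigenvalues_[0])
            out.append(z)
        self.scores_ = np.column_stack(out)[:, : self.n_components]
        self.eigenvalues_ = ca.eigenvalues_[: self.n_components]
        self.gradient_lengths_ = self._gradient_lengths(np.asarray(X, dtype=float))
        return self.scores_

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def _gradient_lengths(self, X) -> np.ndarray:
        """Approximate axis lengths in SD units of species turnover."""
        X = X[np.ix_(self.ca_.row_kept_, self.ca_.col_kept_)]
        lengths = []
        for a in range(self.scores_.shape[1]):
            site = self.scores_[:, a]
            col_tot = X.sum(axis=0)
            species = (X.T @ site) / col_tot
            # weighted sd of species scores within each site
            sds = []
            for i in range(X.shape[0]):
                w = X[i]
                if w.sum() == 0:
                    continue
                mu = np.average(species, weights=w)
                sds.append(np.sqrt(np.average((species - mu) ** 2, weights=w)))
            beta = float(np.mean(sds)) if sds else 1.0
            lengths.append(np.ptp(site) / beta if beta > 0 else np.nan)
        return np.array(lengths)

    def result(self, site_labels=None) -> OrdinationResult:
        return OrdinationResult(
            scores=self.scores_,
            method="DCA",
            eigenvalues=self.eigenvalues_,
            gradient_lengths=self.gradient_lengths_,
            gradient_lengths_approximate=True,
            site_labels=site_labels,
        )


def ca_ordination(incidence, n_components: int = 2, site_labels=None) -> OrdinationResult:
    """Correspondence analysis of a site x species matrix."""
    ca = CorrespondenceAnalysis(n_components)
    ca.fit_transform(incidence)
    return ca.result(site_labels)


def dca_ordination(
    incidence, n_components: int = 2, n_segments: int = 26, site_labels=None
) -> OrdinationResult:
    """Detrended correspondence analysis (detrending by segments)."""
    dca = DetrendedCorrespondenceAnalysis(n_components, n_segments)
    dca.fit_transform(incidence)
    return dca.result(site_labels)


class GlobalNMDS(BaseEstimator):
    """Global non-metric MDS with multi-start concordance acceptance.

    Kruskal stress-1 is minimised (SMACOF with isotonic regression) from
    ``n_starts`` random configurations; the best solution is accepted only
    when at least one other start converges to a configuration matching it
    within a symmetric Procrustes RMSE of ``procrustes_tol`` of the
    configuration scale.  The returned configuration is centred and rotated
    to its principal axes.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_starts: int = 100,
        max_iter: int = 1000,
        stress_ratio_stop: float = 0.99999,
        procrustes_tol: float = 0.01,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.stress_ratio_stop = stress_ratio_stop
        self.procrustes_tol = procrustes_tol
        self.random_state = random_state

    def fit(self, D, y=None):
        self.fit_transform(D)
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square dissimilarity matrix")
        if not np.allclose(D, D.T) or (np.diag(D) != 0).any():
            raise ValueError("D must be symmetric with a zero diagonal")
        # sklearn's SMACOF stops on an absolute stress decrement, not the
        # relative stress-reduction ratio quoted in the stopping rule; map
        # the ratio conservatively so same-basin starts converge to
        # configurations that agree within the Procrustes tolerance
        eps = max(1e-12, (1.0 - self.stress_ratio_stop) * 1e-4)
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_starts)
        configs, stresses = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in seeds:
                conf, stress = smacof(
                    D,
                    metric=False,
                    n_components=self.n_components,
                    init=None,
                    n_init=1,
                    max_iter=self.max_iter,
                    eps=eps,
                    random_state=np.random.default_rng(s).integers(2**31),
                    normalized_stress=True,
                )
                configs.append(conf)
                stresses.append(stress)
        stresses = np.array(stresses)
        best = int(np.argmin(stresses))
        n_same = 0
        for i, conf in enumerate(configs):
            if i == best:
                continue
            try:
                _, _, disparity = procrustes(configs[best], conf)
            except ValueError:
                continue
            rmse = np.sqrt(disparity / len(conf))
            if rmse < self.procrustes_tol:
                n_same += 1
        conf = configs[best] - configs[best].mean(axis=0)
        # rotate to principal axes
        _, _, Vt = np.linalg.svd(conf, full_matrices=False)
        self.embedding_ = conf @ Vt.T
        self.stress_ = float(stresses[best])
        self.n_converged_starts_ = n_same + 1
        self.accepted_ = n_same >= 1
        return self.embedding_

    def result(self, site_labels=None) -> OrdinationResult:
        return OrdinationResult(
            scores=self.embedding_,
            method="NMDS",
            stress=self.stress_,
            n_converged_starts=self.n_converged_starts_,
            accepted=self.accepted_,
            site_labels=site_labels,
        )


def nmds(
    dissimilarity,
    n_components: int = 2,
    n_starts: int = 100,
    max_iter: int = 1000,
    stress_ratio_stop: float = 0.99999,
    seed: int | None = None,
    site_labels=None,
) -> OrdinationResult:
    """Global NMDS of a dissimilarity matrix (see :class:`GlobalNMDS`)."""
    est = GlobalNMDS(
        n_components=n_components,
        n_starts=n_starts,
        max_iter=max_iter,
        stress_ratio_stop=stress_ratio_stop,
        random_state=seed,
    )
    est.fit_transform(dissimilarity)
    return est.result(site_labels)


# ---------------------------------------------------------------------------
# concordance and ANOVA


def kendall_concordance(scores_a: np.ndarray, scores_b: np.ndarray) -> pd.DataFrame:
    """Kendall tau-b between every pair of axes of two score matrices.

    Reflection of an ordination axis is arbitrary, so the comparison is
    sign-invariant: ``abs_tau`` is the magnitude of tau.  A constant score
    vector leaves tau undefined (NaN).
    """
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    B = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if A.shape[0] == 1:
        A = A.T
    if B.shape[0] == 1:
        B = B.T
    if A.shape[0] != B.shape[0]:
        raise ValueError("score matrices must have equal numbers of sites")
    rows = []
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            if np.ptp(A[:, i]) == 0 or np.ptp(B[:, j]) == 0:
                tau = np.nan
            else:
                tau = stats.kendalltau(A[:, i], B[:, j]).statistic
            rows.append(
                {"axis_a": i + 1, "axis_b": j + 1, "tau": tau, "abs_tau": abs(tau)}
            )
    return pd.DataFrame(rows)


def anova_richness(counts, groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-root-system OTU counts by locality."""
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    samples = [counts[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two observations per group")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere; F undefined")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def pool_sublocalities(incidence: pd.DataFrame, hierarchy: pd.DataFrame) -> pd.DataFrame:
    """OTU x sub-locality incidence: union over member root systems."""
    mapping = hierarchy.set_index("root_system")["sub_locality"]
    return incidence.T.groupby(mapping).max().T
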