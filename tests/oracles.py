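"""Independent brute-force oracles used only by the tests.

Everything here is written for transparency, not speed, and deliberately
avoids the code paths of the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dp_align_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Optimal global alignment score with free end gaps, plain DP."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    best = max(max(H[n]), max(H[i][m] for i in range(n + 1)))
    return best


def dp_align_identity(
    a: str, b: str, match=1, mismatch=-1, gap=-2, min_overlap=0.5
) -> float:
    """Identity (matches / columns, terminal gaps excluded) of one optimal
    alignment, traced back with diagonal preference; alignments spanning
    fewer columns than ``min_overlap`` of the shorter sequence score 0."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    # best end on last row/column (trailing gaps free)
    ends = [(H[i][m], i, m) for i in range(n + 1)] + [
        (H[n][j], n, j) for j in range(m + 1)
    ]
    _, i, j = max(ends, key=lambda t: (t[0], t[1] + t[2]))
    matches = columns = 0
    while i > 0 and j > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i][j - 1] + gap:
            columns += 1
            j -= 1
        else:
            columns += 1
            i -= 1
    if columns < min_overlap * min(len(a), len(b)):
        return 0.0
    return matches / columns if columns else 0.0


def single_linkage_components(identity: np.ndarray, threshold: float) -> list[set[int]]:
    """Connected components of the >= threshold identity graph, by BFS."""
    n = identity.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            u = queue.pop()
            for v in range(n):
                if v not in comp and identity[u, v] >= threshold:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def accumulation_by_enumeration(X: np.ndarray) -> np.ndarray:
    """Mean richness over *all* sample orderings (tiny N only)."""
    X = np.asarray(X) > 0
    N = X.shape[0]
    sums = np.zeros(N)
    count = 0
    for perm in itertools.permutations(range(N)):
        cum = np.logical_or.accumulate(X[list(perm)], axis=0)
        sums += cum.sum(axis=1)
        count += 1
    return sums / count


def terminal_points_by_enumeration(pooled: np.ndarray) -> list[float]:
    """T_k over all combinations of k sub-areas (pooled: K x S bool)."""
    K = pooled.shape[0]
    out = []
    for k in range(1, K + 1):
        vals = [
            pooled[list(c)].any(axis=0).sum()
            for c in itertools.combinations(range(K), k)
        ]
        out.append(float(np.mean(vals)))
    return out


def ts_fit(t_k: list[float], n_samples: list[float], target_effort: float):
    """Least squares of T on ln(effort) by the normal equations."""
    x = np.log(np.asarray(n_samples, dtype=float))
    y = np.asarray(t_k, dtype=float)
    b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    a = y.mean() - b * x.mean()
    return a + b * math.log(target_effort)


def bootstrap_space_estimates(pooled: np.ndarray, sizes: np.ndarray, target_subareas: float):
    """T-S estimate for every point of the K^K resample space."""
    K = pooled.shape[0]
    estimates = []
    for choice in itertools.product(range(K), repeat=K):
        sub = pooled[list(choice)]
        sz = sizes[list(choice)]
        t_k, eff = [], []
        for k in range(1, K + 1):
            vals, efforts = [], []
            for c in itertools.combinations(range(K), k):
                vals.append(sub[list(c)].any(axis=0).sum())
                efforts.append(sz[list(c)].sum())
            t_k.append(np.mean(vals))
            eff.append(np.mean(efforts))
        m = eff[-1] / K
        estimates.append(ts_fit(t_k, eff, target_subareas * m))
    return np.array(estimates)


def kendall_tau_by_pairs(x, y) -> float:
    """Tau-b by explicit concordant/discordant pair counting."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


def anova_by_hand(groups: list[np.ndarray]) -> float:
    """One-way F = MSB / MSW from the definitional sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def nmds_smacof_oracle(D: np.ndarray, n_components=2, n_iter=2000, seed=0):
    """Tiny independent non-metric SMACOF: isotonic regression on ranks plus
    Guttman updates, run long from several starts; returns the best stress."""
    from scipy.optimize import isotonic_regression

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    d_flat = D[iu]
    order = np.argsort(d_flat, kind="stable")
    rng = np.random.default_rng(seed)
    best_stress = np.inf
    for _ in range(8):
        X = rng.normal(size=(n, n_components))
        for _ in range(n_iter):
            dist = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
            dd = dist[iu]
            disp = np.empty_like(dd)
            disp[order] = isotonic_regression(dd[order]).x
            # scale disparities to the distances (Kruskal stress-1 form)
            disp *= np.sqrt((dd**2).sum() / (disp**2).sum())
            stress = np.sqrt(((dd - disp) ** 2).sum() / (dd**2).sum())
            # Guttman transform
            W = np.zeros((n, n))
            W[iu] = disp
            W += W.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, W / dist, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        best_stress = min(best_stress, stress)
    return best_stress
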