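"""Sharing statistics, Venn counts, Sørensen, ordination and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycolib.community import (
    CorrespondenceAnalysis,
    anova_richness,
    ca_ordination,
    dca_ordination,
    kendall_concordance,
    nmds,
    pool_sublocalities,
    shared_otu_stats,
    sorensen_dissimilarity,
    venn_counts,
)
from mycolib.simulate import gradient_incidence
from oracles import anova_by_hand, kendall_tau_by_pairs, nmds_smacof_oracle


def toy_hierarchy():
    rows = []
    for m in (1, 2):
        for s_ in (1, 2):  # 2 mains x 2 subs (partial design is fine)
            rows.append(
                {
                    "root_system": f"M{m}S{s_}R1",
                    "sub_locality": f"M{m}S{s_}",
                    "main_locality": f"M{m}",
                }
            )
    # add a second root system in M1S1 so the within-sub stratum exists
    rows.append(
        {"root_system": "M1S1R2", "sub_locality": "M1S1", "main_locality": "M1"}
    )
    rows.append(
        {"root_system": "M2S2R2", "sub_locality": "M2S2", "main_locality": "M2"}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sharing


def test_identical_root_systems_share_their_full_richness():
    hier = toy_hierarchy()
    inc = pd.DataFrame(1, index=[f"otu{i}" for i in range(4)], columns=hier["root_system"])
    out = shared_otu_stats(inc, hier).set_index("stratum")
    assert (out["mean_shared"] == 4).all()


def test_disjoint_root_systems_share_nothing():
    hier = toy_hierarchy()
    inc = pd.DataFrame(
        np.eye(6, dtype=int), index=[f"otu{i}" for i in range(6)],
        columns=hier["root_system"],
    )
    out = shared_otu_stats(inc, hier)
    assert (out["mean_shared"] == 0).all()


def test_sharing_means_match_hand_enumeration():
    """6 root systems, hand-enumerated pairwise intersections per stratum."""
    hier = toy_hierarchy()
    rs = list(hier["root_system"])
    otu_sets = {
        "M1S1R1": {1, 2, 3},
        "M1S2R1": {2, 3},
        "M2S1R1": {3},
        "M2S2R1": {1, 4},
        "M1S1R2": {2, 5},
        "M2S2R2": {4},
    }
    otus = sorted(set().union(*otu_sets.values()))
    inc = pd.DataFrame(
        [[int(o in otu_sets[r]) for r in rs] for o in otus], index=otus, columns=rs
    )
    out = shared_otu_stats(inc, hier).set_index("stratum")
    # within sub-locality: (M1S1R1, M1S1R2) share {2}; (M2S2R1, M2S2R2) share {4}
    assert out.loc["within_sublocality", "mean_shared"] == pytest.approx(1.0)
    assert out.loc["within_sublocality", "n_pairs"] == 2
    # between subs within mains: M1 pairs (R1-S2:2), (R2-S2:1); M2: (S1-S2R1: 0), (S1-S2R2: 0)
    assert out.loc["between_sublocalities", "mean_shared"] == pytest.approx(
        (2 + 1 + 0 + 0) / 4
    )
    # between mains: 3 x 3 = 9 pairs; non-empty intersections are
    # {3}, {1}, {3} for M1S1R1/M1S2R1 against the M2 root systems
    assert out.loc["between_main_localities", "n_pairs"] == 9
    assert out.loc["between_main_localities", "mean_shared"] == pytest.approx(3 / 9)


# ---------------------------------------------------------------------------
# venn


def test_venn_identical_sets():
    counts = venn_counts([{1, 2, 3}] * 3)
    assert counts["111"] == 3 and counts.drop("111").sum() == 0


def test_venn_disjoint_sets():
    counts = venn_counts([{1}, {2, 3}, {4}])
    assert counts[["100", "010", "001"]].tolist() == [1, 2, 1]
    assert counts[["110", "101", "011", "111"]].sum() == 0


def test_venn_mixed_sets_against_membership_tabulation():
    sets = [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}]
    counts = venn_counts(sets)
    expected = {}
    for x in set().union(*sets):
        pattern = "".join("1" if x in s else "0" for s in sets)
        expected[pattern] = expected.get(pattern, 0) + 1
    for pattern, n in expected.items():
        assert counts[pattern] == n
    assert counts.sum() == len(set().union(*sets))


# ---------------------------------------------------------------------------
# Sørensen


def test_sorensen_formula_and_properties():
    inc = np.array([[1, 1, 1, 0], [0, 1, 1, 1], [0, 0, 0, 0]])
    D = sorensen_dissimilarity(inc)
    assert D[0, 1] == pytest.approx(1 / 3)  # {a,b,c} vs {b,c,d}
    assert D[0, 0] == 0
    assert D[2, 2] == 0  # both-empty convention
    assert D[0, 2] == 1.0  # disjoint
    assert np.allclose(D, D.T)
    assert (D >= 0).all() and (D <= 1).all()


# ---------------------------------------------------------------------------
# ordination


def test_ca_eigenvalues_bounded(rng):
    X = (rng.random((10, 15)) < 0.4).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    ca = CorrespondenceAnalysis().fit(X)
    assert np.all(ca.eigenvalues_ >= 0) and np.all(ca.eigenvalues_ < 1)


def test_ca_separates_block_diagonal_communities():
    X = np.zeros((6, 6))
    X[:3, :3] = 1
    X[3:, 3:] = 1
    ca = CorrespondenceAnalysis().fit(X)
    s = np.sign(ca.row_scores_[:, 0])
    assert len(set(s[:3])) == 1 and len(set(s[3:])) == 1 and s[0] != s[-1]
    # axis-1 scores match a direct eigen-decomposition of the CA operator
    P = X / X.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    w = np.linalg.eigvalsh(S @ S.T)
    assert ca.eigenvalues_[0] == pytest.approx(sorted(w)[-1])


def test_dca_within_segment_means_are_zero():
    G = gradient_incidence(n_sites=20, n_species=40, niche_width=10, seed=2)
    from mycolib.community import DetrendedCorrespondenceAnalysis, _detrend_by_segments

    dca = DetrendedCorrespondenceAnalysis(n_segments=5)
    scores = dca.fit_transform(G)
    axis1, axis2 = scores[:, 0], scores[:, 1]
    edges = np.linspace(axis1.min(), axis1.max(), 6)
    seg = np.clip(np.searchsorted(edges, axis1, side="right") - 1, 0, 4)
    for s_ in np.unique(seg):
        assert abs(axis2[seg == s_].mean()) < 1e-9


def test_dca_gradient_lengths_are_flagged_approximate():
    G = gradient_incidence(seed=0)
    res = dca_ordination(G)
    assert res.gradient_lengths_approximate
    assert res.gradient_lengths is not None and (res.gradient_lengths > 0).all()


def test_nmds_recovers_euclidean_configuration(rng):
    pts = rng.normal(size=(9, 2))
    D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    res = nmds(D, n_starts=12, seed=4)
    assert res.stress < 1e-3
    assert res.accepted


def test_nmds_deterministic_for_fixed_seed(rng):
    X = (rng.random((8, 25)) < 0.35).astype(int)
    D = sorensen_dissimilarity(X)
    r1 = nmds(D, n_starts=8, seed=9)
    r2 = nmds(D, n_starts=8, seed=9)
    assert np.allclose(r1.scores, r2.scores)
    assert r1.stress == r2.stress


def test_nmds_stress_close_to_independent_smacof_oracle(rng):
    X = (rng.random((6, 18)) < 0.4).astype(int)
    X[X.sum(axis=1) == 0, 0] = 1
    D = sorensen_dissimilarity(X)
    res = nmds(D, n_starts=20, max_iter=2000, seed=3)
    oracle = nmds_smacof_oracle(D, n_iter=500, seed=1)
    assert res.stress <= oracle + 0.02


def test_nmds_rejects_invalid_matrix():
    with pytest.raises(ValueError):
        nmds(np.array([[0.0, 1.0], [0.5, 0.0]]))


# ---------------------------------------------------------------------------
# concordance and ANOVA


def test_kendall_identical_and_reversed_rankings(rng):
    x = rng.normal(size=10)
    out = kendall_concordance(x, x)
    assert out["tau"].iloc[0] == pytest.approx(1.0)
    out = kendall_concordance(x, -x)
    assert out["tau"].iloc[0] == pytest.approx(-1.0)
    assert out["abs_tau"].iloc[0] == pytest.approx(1.0)


def test_kendall_matches_pair_counting_oracle(rng):
    x, y = rng.normal(size=8), rng.normal(size=8)
    out = kendall_concordance(x, y)
    assert out["tau"].iloc[0] == pytest.approx(kendall_tau_by_pairs(x, y))


def test_kendall_constant_vector_is_nan(rng):
    out = kendall_concordance(np.ones(6), rng.normal(size=6))
    assert np.isnan(out["tau"].iloc[0])


def test_anova_matches_hand_computation():
    g1 = np.array([4.0, 6.0, 5.0])
    g2 = np.array([8.0, 9.0, 10.0])
    f, p = anova_richness(np.concatenate([g1, g2]), ["a"] * 3 + ["b"] * 3)
    assert f == pytest.approx(anova_by_hand([g1, g2]))
    assert 0 < p < 1


def test_anova_location_invariance(rng):
    x = rng.normal(size=12)
    groups = ["a"] * 6 + ["b"] * 6
    f1, _ = anova_richness(x, groups)
    f2, _ = anova_richness(x + 100.0, groups)
    assert f1 == pytest.approx(f2)


def test_anova_type_one_error_is_calibrated(rng):
    """Under the null (equal means), p-values are roughly uniform."""
    n_sim, alpha = 400, 0.05
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(size=18)
        _, p = anova_richness(x, ["a", "b", "c"] * 6)
        hits += p < alpha
    se = np.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(hits / n_sim - alpha) < 4 * se + 0.01


def test_anova_rejects_degenerate_input():
    with pytest.raises(ValueError):
        anova_richness([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


def test_pool_sublocalities_is_union():
    hier = toy_hierarchy()
    inc = pd.DataFrame(
        np.eye(6, dtype=int),
        index=[f"otu{i}" for i in range(6)],
        columns=hier["root_system"],
    )
    pooled = pool_sublocalities(inc, hier)
    assert pooled["M1S1"].sum() == 2  # union of the two M1S1 root systems
    assert (pooled.to_numpy() <= 1).all()
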