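import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pugmark import (
    AlgorithmConfig,
    PopulationSpec,
    build_rcv,
    canonical_variates,
    centroid_ellipse,
    compare_trails,
    ellipses_overlap,
    generate_population,
    pairwise_matrix,
    split_trail,
    stepwise_select,
)
from pugmark.pairwise import Ellipse, variable_columns


# --- oracles ---------------------------------------------------------------

def overlap_oracle(e1, e2, n=4096):
    """Dense boundary sampling + centre containment."""
    if e1.contains(e2.center) or e2.contains(e1.center):
        return True
    for a, b in ((e1, e2), (e2, e1)):
        pts = a.boundary(n)
        d = pts - b.center
        m = np.einsum("ij,ij->i", d, np.linalg.solve(b.shape, d.T).T)
        if np.any(m <= b.scale):
            return True
    return False


def random_ellipse(rng):
    q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
    eigs = rng.uniform(0.1, 2.0, size=2)
    shape = q @ np.diag(eigs) @ q.T
    return Ellipse(
        center=rng.uniform(-3, 3, size=2),
        shape=0.5 * (shape + shape.T),
        scale=rng.uniform(0.5, 4.0),
    )


def cva_oracle(X, groups):
    """Brute-force generalized eigenpairs via explicit matrix inversion."""
    X = np.asarray(X, float)
    labels = np.unique(groups)
    n, p = X.shape
    g = len(labels)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    grand = X.mean(axis=0)
    # standardize by pooled within-group s.d. as the implementation does
    for lab in labels:
        sub = X[np.asarray(groups) == lab]
        W += (sub - sub.mean(0)).T @ (sub - sub.mean(0))
    sd = np.sqrt(np.diag(W) / (n - g))
    Z = (X - grand) / sd
    Wz = np.zeros((p, p))
    Bz = np.zeros((p, p))
    zgrand = Z.mean(axis=0)
    for lab in labels:
        sub = Z[np.asarray(groups) == lab]
        Wz += (sub - sub.mean(0)).T @ (sub - sub.mean(0))
        Bz += len(sub) * np.outer(sub.mean(0) - zgrand, sub.mean(0) - zgrand)
    evals, evecs = np.linalg.eig(np.linalg.inv(Wz) @ Bz)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order], Z, Wz


# --- build_rcv -------------------------------------------------------------

def _toy_table(n_animals=5, trails_per=2, prints=3, n_vars=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for t in range(trails_per):
            for f in range(prints):
                row = {
                    "footprint_id": f"A{a}-T{t}-F{f}",
                    "trail_id": f"A{a}-T{t}",
                    "animal_id": f"A{a}",
                }
                for j in range(n_vars):
                    row[f"V{j + 1}"] = rng.normal(a, 1.0)
                rows.append(row)
    return pd.DataFrame(rows)


class TestBuildRCV:
    def test_all_other_animals(self):
        table = _toy_table(n_animals=35, trails_per=1)
        rcv = build_rcv(table, "A0-T0", "A1-T0", "all-other-animals")
        assert set(rcv["animal_id"]) == {f"A{i}" for i in range(2, 35)}

    def test_whole_table_duplicate_row_count(self):
        table = _toy_table(n_animals=5)
        rcv = build_rcv(table, "A0-T0", "A1-T0", "whole-table-duplicate")
        assert len(rcv) == len(table)

    def test_two_animal_library_errors(self):
        table = _toy_table(n_animals=2)
        with pytest.raises(ValueError, match="library too small"):
            build_rcv(table, "A0-T0", "A1-T0", "all-other-animals")


class TestStepwiseSelect:
    def test_perfect_separator_selected_first(self):
        rng = np.random.default_rng(0)
        n_per = 10
        groups = np.repeat(["a", "b", "c"], n_per)
        X = rng.normal(size=(3 * n_per, 6))
        X[:, 3] = np.repeat([0.0, 5.0, 10.0], n_per) + rng.normal(
            scale=1e-3, size=3 * n_per
        )
        sel = stepwise_select(X, groups, 3, names=[f"V{i}" for i in range(6)])
        assert sel[0][0] == "V3"

    def test_smaller_within_variance_wins(self):
        rng = np.random.default_rng(1)
        groups = np.repeat(["a", "b", "c"], 20)
        centers = np.repeat([0.0, 1.0, 2.0], 20)
        X = np.column_stack(
            [centers + rng.normal(scale=1.0, size=60),
             centers + rng.normal(scale=0.1, size=60)]
        )
        sel = stepwise_select(X, groups, 1, names=["wide", "tight"])
        assert len(sel) == 1
        assert sel[0][0] == "tight"

    def test_first_pick_matches_anova_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            groups = np.repeat(["a", "b", "c"], 8)
            X = rng.normal(size=(24, 6)) + rng.normal(size=(1, 6)) * np.repeat(
                [0, 1, 2], 8
            )[:, None] * rng.uniform(0, 1, size=(1, 6))
            sel = stepwise_select(X, groups, 1, names=[f"V{i}" for i in range(6)])
            fs = [
                stats.f_oneway(X[:8, j], X[8:16, j], X[16:, j]).statistic
                for j in range(6)
            ]
            assert sel[0][0] == f"V{int(np.argmax(fs))}"
            assert sel[0][1] == pytest.approx(max(fs), rel=1e-9)

    def test_constant_variable_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(["a", "b"], 10)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            sel = stepwise_select(X, groups, 3, names=["V0", "V1", "V2"])
        assert "V1" not in [v for v, _ in sel]

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(["a", "b", "c"], 10)
        X = rng.normal(size=(30, 8))
        s1 = stepwise_select(X, groups, 4)
        s2 = stepwise_select(X, groups, 4)
        assert s1 == s2

    def test_max_vars_cap(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(["a", "b"], 4)
        X = rng.normal(size=(8, 20))
        with pytest.warns(UserWarning, match="truncated"):
            sel = stepwise_select(X, groups, 20)
        assert len(sel) <= 8 - 2 - 1


class TestCanonicalVariates:
    def test_identical_groups_zero_eigenvalues(self):
        rng = np.random.default_rng(6)
        block = rng.normal(size=(12, 4))
        X = np.vstack([block, block, block])
        groups = np.repeat(["a", "b", "c"], 12)
        res = canonical_variates(X, groups)
        assert np.all(res.eigenvalues <= 1e-10)

    def test_single_discriminating_variable(self):
        rng = np.random.default_rng(7)
        groups = np.repeat(["a", "b", "c"], 30)
        X = rng.normal(size=(90, 4))
        X[:, 2] += np.repeat([0.0, 8.0, 16.0], 30)
        res = canonical_variates(X, groups)
        lead = np.abs(res.loadings[:, 0])
        assert lead[2] > 5 * lead[[0, 1, 3]].max()

    def test_matches_dense_generalized_eigen_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(8):
            groups = np.repeat(["a", "b", "c"], 10)
            X = rng.normal(size=(30, 5)) + np.repeat(
                rng.normal(scale=2.0, size=(3, 5)), 10, axis=0
            )
            res = canonical_variates(X, groups)
            evals, evecs, Z, Wz = cva_oracle(X, groups)
            np.testing.assert_allclose(res.eigenvalues, evals[:2], atol=1e-8)
            for j in range(2):
                v_impl = res.loadings[:, j]
                v_orc = evecs[:, j]
                cos = abs(v_impl @ v_orc) / (
                    np.linalg.norm(v_impl) * np.linalg.norm(v_orc)
                )
                assert cos == pytest.approx(1.0, abs=1e-8)

    def test_score_normalization_unit_pooled_within_variance(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(["a", "b", "c"], 15)
        X = rng.normal(size=(45, 4)) + np.repeat(
            rng.normal(scale=3.0, size=(3, 4)), 15, axis=0
        )
        res = canonical_variates(X, groups)
        n, g = 45, 3
        resid = res.scores.copy()
        for lab in np.unique(groups):
            m = np.asarray(groups) == lab
            resid[m] -= res.scores[m].mean(axis=0)
        pooled_var = (resid**2).sum(axis=0) / (n - g)
        np.testing.assert_allclose(pooled_var, 1.0, atol=1e-8)

    def test_eigenvalues_sorted_nonnegative(self):
        rng = np.random.default_rng(10)
        groups = np.repeat(["a", "b", "c"], 10)
        X = rng.normal(size=(30, 6))
        res = canonical_variates(X, groups)
        assert res.eigenvalues[0] >= res.eigenvalues[1] >= 0.0

    def test_singular_scatter_ridge_warns(self):
        rng = np.random.default_rng(11)
        groups = np.repeat(["a", "b", "c"], 4)
        base = rng.normal(size=(12, 2))
        X = np.column_stack([base, base[:, 0] + base[:, 1]])  # exact collinearity
        with pytest.warns(UserWarning, match="ridge"):
            res = canonical_variates(X, groups)
        assert np.all(np.isfinite(res.scores))


class TestCentroidEllipse:
    def test_frozen_f_quantile_example(self):
        # n=5, sample covariance I, p=0.95:
        # shape = I/5, c = (8/3) * F^-1(0.95; 2, 3) = 25.472251989...
        rng = np.random.default_rng(12)
        raw = rng.normal(size=(5, 2))
        raw = (raw - raw.mean(0)) @ np.linalg.inv(
            np.linalg.cholesky(np.cov(raw.T, ddof=1))
        ).T  # whiten: sample covariance exactly I
        e = centroid_ellipse(raw, 0.95)
        np.testing.assert_allclose(e.shape, np.eye(2) / 5, atol=1e-12)
        assert e.scale == pytest.approx(25.47225198912307, rel=1e-12)
        # boundary radius^2 = c/5
        r2 = np.sum((e.boundary(16) - e.center) ** 2, axis=1)
        np.testing.assert_allclose(r2, e.scale / 5, rtol=1e-9)

    def test_area_strictly_increasing_in_p(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(8, 2))
        areas = [
            np.pi * e.scale * np.sqrt(np.linalg.det(e.shape))
            for e in (centroid_ellipse(scores, p) for p in (0.5, 0.8, 0.95, 0.99))
        ]
        assert np.all(np.diff(areas) > 0)

    def test_duplicated_group_shrinks_region(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=(6, 2))
        e1 = centroid_ellipse(scores, 0.95)
        e2 = centroid_ellipse(np.vstack([scores, scores]), 0.95)
        np.testing.assert_allclose(e1.center, e2.center, atol=1e-12)
        area1 = np.pi * e1.scale * np.sqrt(np.linalg.det(e1.shape))
        area2 = np.pi * e2.scale * np.sqrt(np.linalg.det(e2.shape))
        assert area2 < area1

    def test_too_short_trail(self):
        with pytest.raises(ValueError, match="too short"):
            centroid_ellipse(np.zeros((2, 2)), 0.95)


class TestEllipsesOverlap:
    def test_unit_disks_centers_1_apart(self):
        e1 = Ellipse(np.array([0.0, 0.0]), np.eye(2), 1.0)
        e2 = Ellipse(np.array([1.0, 0.0]), np.eye(2), 1.0)
        assert ellipses_overlap(e1, e2)

    def test_unit_disks_centers_3_apart(self):
        e1 = Ellipse(np.array([0.0, 0.0]), np.eye(2), 1.0)
        e2 = Ellipse(np.array([3.0, 0.0]), np.eye(2), 1.0)
        assert not ellipses_overlap(e1, e2)

    def test_containment_counts_as_overlap(self):
        big = Ellipse(np.zeros(2), np.eye(2), 16.0)
        small = Ellipse(np.array([0.5, 0.0]), np.eye(2) * 0.01, 1.0)
        assert ellipses_overlap(big, small)
        assert ellipses_overlap(small, big)

    def test_tangent_disks_touching(self):
        e1 = Ellipse(np.zeros(2), np.eye(2), 1.0)
        e2 = Ellipse(np.array([2.0, 0.0]), np.eye(2), 1.0)
        assert ellipses_overlap(e1, e2)  # boundary touch at (1, 0)

    def test_non_positive_definite_shape(self):
        bad = Ellipse(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)
        good = Ellipse(np.zeros(2), np.eye(2), 1.0)
        with pytest.raises(ValueError, match="positive-definite"):
            ellipses_overlap(bad, good)

    def test_matches_sampling_oracle(self):
        rng = np.random.default_rng(15)
        mismatches = 0
        for _ in range(300):
            e1, e2 = random_ellipse(rng), random_ellipse(rng)
            if ellipses_overlap(e1, e2) != overlap_oracle(e1, e2):
                mismatches += 1
        assert mismatches == 0

    def test_symmetry(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            e1, e2 = random_ellipse(rng), random_ellipse(rng)
            assert ellipses_overlap(e1, e2) == ellipses_overlap(e2, e1)


class TestCompareTrails:
    def test_split_self_trail_verdict_same(self, small_population, default_config):
        _, _, table = small_population
        counts = table.groupby("trail_id").size()
        tid = counts[counts >= 6].index[0]
        a, b = split_trail(table, tid, seed=5)
        table2 = pd.concat(
            [table[table["trail_id"] != tid], a, b], ignore_index=True
        )
        res = compare_trails(table2, a["trail_id"].iloc[0], b["trail_id"].iloc[0],
                             default_config)
        assert res.verdict == "same"
        assert res.overlap

    def test_separated_individuals_verdict_different(self, default_config):
        spec = PopulationSpec(
            n_individuals=6, sigma_individual=5.0, sigma_noise=0.3, seed=20
        )
        _, table = generate_population(spec)
        trails = table.drop_duplicates("trail_id")
        t1 = trails[trails["animal_id"] == "A01"]["trail_id"].iloc[0]
        t2 = trails[trails["animal_id"] == "A02"]["trail_id"].iloc[0]
        res = compare_trails(table, t1, t2, default_config)
        assert res.verdict == "different"
        assert res.centroid_distance > 0

    def test_verdict_iff_overlap_and_symmetry(self, small_population, default_config):
        _, _, table = small_population
        counts = table.groupby("trail_id").size()
        trails = list(counts[counts >= 3].index[:4])
        for a, b in [(trails[0], trails[1]), (trails[2], trails[3])]:
            r1 = compare_trails(table, a, b, default_config)
            r2 = compare_trails(table, b, a, default_config)
            assert r1.overlap == (r1.verdict == "same")
            assert r1.overlap == r2.overlap
            assert r1.centroid_distance == pytest.approx(
                r2.centroid_distance, rel=1e-9
            )

    def test_short_trail_rejected(self, small_population, default_config):
        _, _, table = small_population
        short = table.groupby("trail_id").head(0)
        row = table.iloc[[0, 1]].copy()
        row["trail_id"] = "TOO-SHORT"
        table2 = pd.concat([table, row], ignore_index=True)
        good = table["trail_id"].iloc[-1]
        with pytest.raises(ValueError, match="TOO-SHORT"):
            compare_trails(table2, "TOO-SHORT", good, default_config)

    def test_selected_count_respects_config(self, small_population):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())
        cfg = AlgorithmConfig(n_variables=7)
        res = compare_trails(table, trails[0], trails[1], cfg)
        assert len(res.selected_variables) == 7

    def test_cross_validated_rate_range(self, small_population, default_config):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())
        res = compare_trails(table, trails[0], trails[2], default_config)
        assert 0.0 <= res.cross_validated_rate <= 100.0


class TestPairwiseInvariants:
    def test_rcv_row_duplication_leaves_verdict(self, small_population, default_config):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())
        a, b = trails[0], trails[3]
        res1 = compare_trails(table, a, b, default_config)
        owners = set(
            table.loc[table["trail_id"].isin([a, b]), "animal_id"].unique()
        )
        extra = table[~table["animal_id"].isin(owners)]
        doubled = pd.concat([table, extra], ignore_index=True)
        res2 = compare_trails(doubled, a, b, default_config)
        assert res1.verdict == res2.verdict
        assert [v for v, _ in res1.selected_variables] == [
            v for v, _ in res2.selected_variables
        ]

    def test_affine_rescaling_invariance(self, small_population, default_config):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())
        rng = np.random.default_rng(21)
        vcols = variable_columns(table)
        scaled = table.copy()
        a_coefs = rng.uniform(0.5, 2.0, size=len(vcols)) * rng.choice(
            [-1.0, 1.0], size=len(vcols)
        )
        b_coefs = rng.uniform(-10, 10, size=len(vcols))
        scaled[vcols] = table[vcols].to_numpy() * a_coefs + b_coefs
        for pair in [(trails[0], trails[1]), (trails[2], trails[5])]:
            r1 = compare_trails(table, *pair, default_config)
            r2 = compare_trails(scaled, *pair, default_config)
            assert r1.verdict == r2.verdict
            assert r1.centroid_distance == pytest.approx(
                r2.centroid_distance, abs=1e-6, rel=1e-6
            )

    def test_overlap_monotone_in_contour_probability(self, small_population):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())
        pairs = [(trails[i], trails[j]) for i in range(4) for j in range(i + 1, 4)]
        probs = [0.5, 0.8, 0.95, 0.99]
        for a, b in pairs:
            overlaps = [
                compare_trails(table, a, b, AlgorithmConfig(contour_probability=p)).overlap
                for p in probs
            ]
            # once overlapping at p, still overlapping at any larger p
            for lo, hi in zip(overlaps, overlaps[1:]):
                assert hi or not lo


class TestPairwiseMatrix:
    def test_two_trails(self, small_population, default_config):
        _, _, table = small_population
        trails = list(table["trail_id"].unique())[:2]
        sub = table[table["trail_id"].isin(trails)]
        # two trails of two different animals leave no RCV rows: pair flagged
        broken = pairwise_matrix(sub, default_config)
        assert broken.errors and np.isnan(broken.distances.iloc[0, 1])
        mats = pairwise_matrix(table, default_config, trails=trails)
        assert mats.distances.shape == (2, 2)
        assert mats.distances.iloc[0, 1] == mats.distances.iloc[1, 0] > 0
        assert mats.distances.iloc[0, 0] == 0.0

    def test_symmetry_and_consistency(self, small_population, small_matrices,
                                       default_config):
        _, _, table = small_population
        D = small_matrices.distances
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)
        assert small_matrices.errors == {}
        a, b = D.index[1], D.index[4]
        res = compare_trails(table, a, b, default_config)
        assert D.loc[a, b] == pytest.approx(res.centroid_distance, rel=1e-12)
        assert small_matrices.verdicts.loc[a, b] == res.overlap

    def test_short_trails_excluded_with_warning(self, small_population,
                                                default_config):
        _, _, table = small_population
        extra = table.iloc[[0, 1]].copy()
        extra["trail_id"] = "SHORTY"
        extra["animal_id"] = "A99"
        table2 = pd.concat([table, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="SHORTY"):
            mats = pairwise_matrix(table2, default_config)
        assert "SHORTY" not in mats.distances.index
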