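"""Mantel test, distance matrices, and the darkness regressions."""

import numpy as np
import pandas as pd
import pytest

from nestnorm.beach_color import BeachRecord, VolcanoRecord
from nestnorm.nesting import NestingIndex
from nestnorm.spatial import (
    darkness_vs_volcano,
    fit_log10_activity,
    mantel,
    mantel_exact,
    pairwise_absdiff,
    pairwise_geo,
)


def make_beaches(darkness, lats=None, lengths=None):
    n = len(darkness)
    lats = lats if lats is not None else np.linspace(8, 20, n)
    lengths = lengths if lengths is not None else np.full(n, 2.0)
    return [
        BeachRecord(f"b{i}", lats[i], -85.0, lats[i] + 0.01, -85.0, darkness[i], lengths[i])
        for i in range(n)
    ]


class TestDistanceMatrices:
    def test_meridian_degree_entries(self):
        beaches = make_beaches([0.2, 0.8], lats=np.array([0.0, 1.0]))
        # midpoints 0.005 and 1.005 deg -> one degree of latitude apart
        D = pairwise_geo(beaches)
        assert D.iloc[0, 1] == pytest.approx(111.195, abs=1e-2)
        assert D.iloc[1, 0] == D.iloc[0, 1]

    def test_identical_darkness_gives_zero_matrix(self):
        D = pairwise_absdiff([0.4, 0.4, 0.4])
        assert np.allclose(D.to_numpy(), 0.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        vals = rng.uniform(size=7)
        beaches = make_beaches(vals)
        for D in (pairwise_geo(beaches), pairwise_absdiff(vals)):
            M = D.to_numpy()
            assert np.allclose(M, M.T, atol=1e-9)
            assert np.allclose(np.diag(M), 0.0)
            assert (M >= 0).all()


class TestMantel:
    def test_perfect_self_correlation(self, symmetric_matrix_factory):
        A = symmetric_matrix_factory(5, seed=1)
        res = mantel(A, A, n_perm=9999, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value <= 0.01
        assert res.p_value >= 1 / (9999 + 1)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_sampled_p_matches_exhaustive_enumeration(self, n, symmetric_matrix_factory):
        A = symmetric_matrix_factory(n, seed=10 + n)
        B = symmetric_matrix_factory(n, seed=20 + n)
        _, p_exact = mantel_exact(A, B)
        n_perm = 9999
        p_sampled = mantel(A, B, n_perm=n_perm, seed=3).p_value
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * se + 2 / n_perm

    def test_invariant_under_common_relabeling(self, symmetric_matrix_factory, rng):
        A = symmetric_matrix_factory(6, seed=5)
        B = symmetric_matrix_factory(6, seed=6)
        perm = rng.permutation(6)
        r1 = mantel(A, B, n_perm=9, seed=0).r_obs
        r2 = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=9, seed=0).r_obs
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_agrees_with_skbio(self, symmetric_matrix_factory):
        """Independent cross-check of the observed statistic and p-value."""
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        A = symmetric_matrix_factory(8, seed=30)
        B = symmetric_matrix_factory(8, seed=31)
        ours = mantel(A, B, n_perm=9999, seed=2)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(A), DistanceMatrix(B), permutations=9999, alternative="greater", seed=0
        )
        assert ours.r_obs == pytest.approx(float(r_ref), abs=1e-10)
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.02)

    def test_constant_matrix_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(ValueError):
            mantel(A, A, n_perm=9)


def make_index(p, ids):
    log10_p = pd.Series(
        {i: (np.log10(v) if v > 1e-12 else np.nan) for i, v in zip(ids, p)}, dtype=float
    )
    return NestingIndex(
        filled=pd.DataFrame(),
        p=pd.Series(p, index=ids),
        log10_p=log10_p,
        excluded=[i for i, v in zip(ids, p) if v <= 1e-12],
    )


class TestActivityRegression:
    def test_recovers_generative_darkness_slope(self, rng):
        darkness = rng.uniform(0.05, 0.95, size=40)
        p = 10.0 ** (-2.0 * darkness)
        p = p / p.sum()
        beaches = make_beaches(darkness)
        idx = make_index(p, [b.id for b in beaches])
        res = fit_log10_activity(idx, beaches)
        assert res.params["darkness"] == pytest.approx(-2.0, abs=1e-6)
        assert res.n == 40

    def test_null_slope_centered_on_zero(self):
        slopes = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            darkness = r.uniform(0.05, 0.95, size=50)
            p = r.dirichlet(np.ones(50))
            beaches = make_beaches(darkness)
            idx = make_index(p, [b.id for b in beaches])
            slopes.append(fit_log10_activity(idx, beaches).params["darkness"])
        slopes = np.asarray(slopes)
        assert abs(slopes.mean()) < 3 * slopes.std(ddof=1) / np.sqrt(len(slopes))

    def test_constant_multiplier_shifts_only_intercept(self, rng):
        darkness = rng.uniform(0.1, 0.9, size=20)
        p = 10.0 ** (-1.5 * darkness)
        beaches = make_beaches(darkness)
        ids = [b.id for b in beaches]
        res1 = fit_log10_activity(make_index(p, ids), beaches)
        res2 = fit_log10_activity(make_index(10.0 * p, ids), beaches)
        assert res2.params["darkness"] == pytest.approx(res1.params["darkness"], abs=1e-9)
        assert res2.params["const"] - res1.params["const"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_share_beaches_excluded_and_reported(self, rng):
        darkness = rng.uniform(0.1, 0.9, size=10)
        p = 10.0 ** (-2.0 * darkness)
        p[3] = 0.0
        beaches = make_beaches(darkness)
        idx = make_index(p, [b.id for b in beaches])
        res = fit_log10_activity(idx, beaches)
        assert res.n == 9
        assert "b3" in res.excluded

    def test_matches_normal_equations(self, rng):
        darkness = rng.uniform(0.1, 0.9, size=12)
        p = rng.dirichlet(np.ones(12))
        beaches = make_beaches(darkness)
        idx = make_index(p, [b.id for b in beaches])
        res = fit_log10_activity(idx, beaches)
        X = np.column_stack([np.ones(12), darkness])
        y = np.log10(p)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert res.params["darkness"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_darkness_rejected(self, rng):
        beaches = make_beaches(np.full(5, 0.5))
        idx = make_index(np.full(5, 0.2), [b.id for b in beaches])
        with pytest.raises(ValueError):
            fit_log10_activity(idx, beaches)


class TestDarknessVsVolcano:
    VOLCANOS = [VolcanoRecord("v0", 10.0, -85.0), VolcanoRecord("v1", 16.0, -85.0)]

    def test_generative_relationship_detected(self, rng):
        lats = np.linspace(8, 20, 60)
        beaches0 = make_beaches(np.full(60, 0.5), lats=lats)
        from nestnorm.beach_color import nearest_volcano_km

        dist = np.array([nearest_volcano_km(b, self.VOLCANOS) for b in beaches0])
        darkness = np.clip(0.9 - 0.002 * dist + rng.normal(0, 0.03, 60), 0.0, 1.0)
        beaches = make_beaches(darkness, lats=lats)
        table = darkness_vs_volcano(beaches, self.VOLCANOS)
        dist_row = table[table.model == "darkness ~ distance"].iloc[0]
        null_row = table[table.model == "intercept only"].iloc[0]
        assert null_row.delta_aic - dist_row.delta_aic > 10
        assert dist_row.slope < 0

    def test_null_relationship_weakly_discriminated(self):
        deltas = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            beaches = make_beaches(r.uniform(0.1, 0.9, size=30), lats=np.linspace(8, 20, 30))
            table = darkness_vs_volcano(beaches, self.VOLCANOS)
            deltas.append(table[table.model == "darkness ~ distance"].iloc[0].delta_aic)
        # under the null the distance model rarely earns strong support
        assert np.median(deltas) < 4

    def test_weights_sum_to_one(self, rng):
        beaches = make_beaches(rng.uniform(0.1, 0.9, size=10))
        table = darkness_vs_volcano(beaches, self.VOLCANOS)
        assert table.akaike_weight.sum() == pytest.approx(1.0, abs=1e-9)
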