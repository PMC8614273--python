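"""Spatio-temporal nesting model: likelihood, fitting, AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest

from nestnorm.nesting import (
    NestCountTable,
    NestingActivityModel,
    akaike_weights,
    expected_nests,
    gaussian_negloglik,
    select_models,
    temporal_totals,
)
from nestnorm.simulate import ScenarioConfig, gen_beaches, gen_nest_counts, true_shares


def make_table(N, beaches=None, years=None):
    N = np.asarray(N, dtype=float)
    beaches = beaches or [f"b{j}" for j in range(N.shape[1])]
    years = years or list(range(2000, 2000 + N.shape[0]))
    return NestCountTable(beaches, years, N)


class TestTemporalTotals:
    def test_constant(self):
        assert np.allclose(temporal_totals("constant", [100.0], 3), [100, 100, 100])

    def test_exponential_reduces_to_constant_at_r0(self):
        assert np.allclose(temporal_totals("exponential", [100.0, 0.0], 4), 100.0)

    def test_exponential_doubling(self):
        assert np.allclose(
            temporal_totals("exponential", [100.0, math.log(2)], 3), [100, 200, 400]
        )

    def test_year_specific_passthrough(self):
        assert np.allclose(temporal_totals("year_specific", [5.0, 7.0], 2), [5, 7])

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            temporal_totals("constant", [-1.0], 3)


class TestExpectedNests:
    def test_single_beach_rows_equal_totals(self):
        E = expected_nests([10.0, 20.0], [1.0])
        assert np.allclose(E[:, 0], [10, 20])

    def test_small_example(self):
        assert np.allclose(expected_nests([10.0], [0.25, 0.75]), [[2.5, 7.5]])

    def test_row_sums_conserved(self, rng):
        T = rng.uniform(10, 100, size=6)
        p = rng.dirichlet(np.ones(4))
        E = expected_nests(T, p)
        assert np.allclose(E.sum(axis=1), T)


class TestGaussianNegloglik:
    def test_observation_at_mean_unit_sd(self):
        # one observed cell with N = E and S -> 1 contributes 0.5 ln(2 pi)
        table = make_table([[5.0]])
        nll = gaussian_negloglik(table, "constant", [5.0], [1.0], a=1e-12, b=1.0)
        assert nll == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-9)

    def test_missing_cells_contribute_nothing(self):
        full = make_table([[5.0], [7.0]])
        holed = make_table([[5.0], [np.nan]])
        nll_full = gaussian_negloglik(full, "constant", [6.0], [1.0], 0.5, 1.0)
        nll_holed = gaussian_negloglik(holed, "constant", [6.0], [1.0], 0.5, 1.0)
        one_cell = 0.5 * math.log(2 * math.pi * (0.5 * 5 + 1) ** 2) + (5 - 6) ** 2 / (
            2 * (0.5 * 5 + 1) ** 2
        )
        assert nll_holed == pytest.approx(one_cell, abs=1e-9)
        assert nll_holed < nll_full

    def test_matches_hand_summed_two_cells(self):
        # 2 years x 1 beach, constant T=5, a=0.5, b=1
        table = make_table([[3.0], [7.0]])
        expected = 0.0
        for n in (3.0, 7.0):
            s = 0.5 * n + 1.0
            expected += 0.5 * math.log(2 * math.pi * s * s) + (n - 5.0) ** 2 / (2 * s * s)
        got = gaussian_negloglik(table, "constant", [5.0], [1.0], 0.5, 1.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invalid_error_params_rejected(self):
        table = make_table([[3.0]])
        with pytest.raises(ValueError):
            gaussian_negloglik(table, "constant", [5.0], [1.0], a=-0.1, b=1.0)


class TestAkaikeWeights:
    def test_printed_model_selection_table(self):
        delta, w = akaike_weights([2254.397, 2247.399, 2241.867])
        assert np.round(delta, 2).tolist() == [12.53, 5.53, 0.0]
        assert round(w[0], 3) == 0.002
        assert round(w[1], 2) == 0.06
        assert round(w[2], 2) == 0.94

    def test_single_model(self):
        _, w = akaike_weights([123.4])
        assert w[0] == pytest.approx(1.0)

    def test_two_equal_aics(self):
        _, w = akaike_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([np.inf, 1.0])


class TestFitting:
    def test_noiseless_constant_recovery(self):
        p_true = np.array([0.5, 0.3, 0.2])
        E = np.outer(np.full(6, 1000.0), p_true)
        res = NestingActivityModel(make_table(E), "constant").fit(seed=0, restarts=3)
        assert np.abs(res.p - p_true).max() < 1e-3
        assert res.T[0] == pytest.approx(1000.0, rel=1e-3)

    def test_simplex_constraint(self):
        E = np.outer([100.0, 150.0], [0.7, 0.3])
        res = NestingActivityModel(make_table(E), "year_specific").fit(seed=0, restarts=2)
        assert res.p.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.p >= 0)

    def test_exponential_rate_near_zero_on_constant_data(self):
        cfg = ScenarioConfig(
            seed=11, n_beaches=4, years=tuple(range(2000, 2010)),
            temporal_kind="constant", mean_total=1000.0, obs_prob=1.0, a=0.05, b=2.0,
        )
        beaches, _ = gen_beaches(cfg)
        table = NestCountTable.from_dataframe(gen_nest_counts(cfg, beaches))
        res = NestingActivityModel(table, "exponential").fit(seed=0, restarts=3)
        assert abs(res.temporal_params[1]) < 0.02  # growth rate ~ 0

    def test_identifiability_warning_when_underdetermined(self):
        N = np.full((3, 4), np.nan)
        N[0, :2] = [5.0, 7.0]
        N[1, 2] = 4.0
        res = NestingActivityModel(make_table(N), "year_specific").fit(seed=0, restarts=1)
        assert res.identifiability_warning
        assert "warning" in res.summary()


class TestModelSelection:
    def test_nesting_inequality_and_table_invariants(self):
        cfg = ScenarioConfig(
            seed=21, n_beaches=5, years=tuple(range(2000, 2010)),
            obs_prob=0.7, a=0.1, b=2.0, mean_total=1000.0,
        )
        beaches, _ = gen_beaches(cfg)
        table = NestCountTable.from_dataframe(gen_nest_counts(cfg, beaches))
        sel, best = select_models(table, seed=1)
        nll = {row.model: None for row in sel.itertuples()}
        fits = {k: NestingActivityModel(table, k).fit(seed=1) for k in nll}
        assert fits["year_specific"].negloglik <= fits["exponential"].negloglik + 1e-6
        assert fits["exponential"].negloglik <= fits["constant"].negloglik + 1e-6
        assert (sel.delta_aic >= 0).all()
        assert (sel.delta_aic == 0).sum() == 1
        assert sel.akaike_weight.sum() == pytest.approx(1.0, abs=1e-9)
        assert sel.loc[sel.delta_aic.idxmin(), "akaike_weight"] == sel.akaike_weight.max()
        assert best.aic == sel.aic.min()

    def test_year_specific_selected_when_totals_vary_strongly(self):
        cfg = ScenarioConfig(
            seed=31, n_beaches=4, years=tuple(range(2000, 2008)),
            temporal_kind="year_specific",
            temporal_params=[200.0, 3000.0, 150.0, 5000.0, 120.0, 2500.0, 90.0, 4200.0],
            obs_prob=1.0, a=0.05, b=2.0,
        )
        beaches, _ = gen_beaches(cfg)
        table = NestCountTable.from_dataframe(gen_nest_counts(cfg, beaches))
        sel, best = select_models(table, seed=2)
        assert best.kind == "year_specific"

    def test_requires_two_specs(self):
        with pytest.raises(ValueError):
            select_models(make_table([[1.0]]), ["constant"])


class TestNestingIndex:
    def test_fully_observed_table_is_returned_verbatim(self):
        N = np.outer([100.0, 150.0], [0.6, 0.4])
        table = make_table(N)
        res = NestingActivityModel(table, "year_specific").fit(seed=0, restarts=2)
        idx = res.index()
        assert np.allclose(idx.filled.to_numpy(), N)

    def test_fully_missing_year_imputed_with_expectation(self):
        N = np.array([[60.0, 40.0], [np.nan, np.nan], [66.0, 44.0]])
        table = make_table(N)
        res = NestingActivityModel(table, "year_specific").fit(seed=0, restarts=2)
        idx = res.index()
        imputed = idx.filled.to_numpy()[1]
        assert np.allclose(imputed, res.T[1] * res.p, atol=1e-8)
        assert imputed.sum() == pytest.approx(res.T[1], abs=1e-6)

    def test_index_shares_sum_to_one(self):
        N = np.outer([100.0, 150.0], [0.6, 0.4])
        res = NestingActivityModel(make_table(N), "constant").fit(seed=0, restarts=2)
        idx = res.index()
        assert idx.p.sum() == pytest.approx(1.0, abs=1e-10)


class TestParameterRecovery:
    def test_year_specific_share_recovery(self):
        """Shares recovered from sparse noisy tables, averaged over seeds."""
        maes = []
        for seed in range(8):
            cfg = ScenarioConfig(
                seed=seed, n_beaches=5, years=tuple(range(2000, 2010)),
                obs_prob=0.7, a=0.1, b=2.0, mean_total=1000.0,
            )
            beaches, _ = gen_beaches(cfg)
            table = NestCountTable.from_dataframe(gen_nest_counts(cfg, beaches))
            res = NestingActivityModel(table, "year_specific").fit(seed=seed)
            maes.append(np.abs(res.p - true_shares(cfg, beaches)).mean())
        assert float(np.mean(maes)) < 0.02
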