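"""Compositional correlation estimation: internals, oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from guildnet import (
    SparCC,
    aggregate_by_genus,
    basis_variances,
    bootstrap_pvalues,
    estimate_fractions,
    logratio_variances,
    simulate_genus_table,
    sparcc_correlations,
)
from guildnet._exceptions import GenusGuildConflictError, MethodAssumptionError
from guildnet.simulate import compound_block_correlation


def _assignments(rows):
    return pd.DataFrame(rows, columns=["taxon_id", "guild_class", "genus"])


class TestAggregateByGenus:
    def test_same_genus_taxa_summed(self):
        counts = pd.DataFrame({"p1": [3, 4, 2]}, index=["t1", "t2", "t3"])
        ass = _assignments(
            [
                ("t1", "PATHOGEN", "Fusarium"),
                ("t2", "PATHOGEN", "Fusarium"),
                ("t3", "SAPROTROPH", "Mortierella"),
            ]
        )
        gt = aggregate_by_genus(counts, ass)
        assert gt.counts.loc["Fusarium", "p1"] == 7
        assert gt.guilds["Fusarium"] == "PATHOGEN"

    def test_non_target_classes_dropped(self):
        counts = pd.DataFrame({"p1": [3, 4]}, index=["t1", "t2"])
        ass = _assignments([("t1", "OTHER", "X"), ("t2", "UNASSIGNED", "")])
        gt = aggregate_by_genus(counts, ass)
        assert gt.counts.empty

    def test_guild_conflict_names_genus(self):
        counts = pd.DataFrame({"p1": [3, 4]}, index=["t1", "t2"])
        ass = _assignments(
            [("t1", "PATHOGEN", "Fusarium"), ("t2", "SAPROTROPH", "Fusarium")]
        )
        with pytest.raises(GenusGuildConflictError, match="Fusarium"):
            aggregate_by_genus(counts, ass)

    def test_guild_pure_input_keeps_all_genera(self):
        counts = pd.DataFrame({"p1": range(5), "p2": range(5)},
                              index=[f"t{i}" for i in range(5)])
        ass = _assignments([(f"t{i}", "SAPROTROPH", f"G{i}") for i in range(5)])
        gt = aggregate_by_genus(counts, ass)
        assert gt.counts.shape[0] == 5


class TestEstimateFractions:
    def test_minimum_size_enforced(self):
        with pytest.raises(MethodAssumptionError):
            estimate_fractions(np.ones((3, 10)))
        with pytest.raises(MethodAssumptionError):
            estimate_fractions(np.ones((4, 3)))

    def test_all_equal_counts_give_quarter(self):
        f = estimate_fractions(np.ones((4, 4)))
        np.testing.assert_allclose(f, 0.25)

    def test_hand_arithmetic(self):
        counts = np.array([[3.0], [1.0], [0.0], [0.0]])
        counts = np.tile(counts, (1, 4))
        f = estimate_fractions(counts, pseudocount=1)
        np.testing.assert_allclose(f[:, 0], [4 / 8, 2 / 8, 1 / 8, 1 / 8])

    def test_all_zero_genera_symmetric(self):
        f = estimate_fractions(np.zeros((4, 4)))
        np.testing.assert_allclose(f, 0.25)

    @given(st.integers(min_value=0, max_value=5))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(6, 8))
        f = estimate_fractions(counts)
        np.testing.assert_allclose(f.sum(axis=0), 1.0)


class TestLogratioVariances:
    def test_proportional_rows_have_zero_variance(self):
        f = np.vstack([np.array([0.1, 0.2, 0.4, 0.3]) for _ in range(2)])
        f = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.1], [0.4, 0.3]])
        f[1] = 2 * f[0]  # exactly proportional pair
        t = logratio_variances(f)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_two_plot_hand_variance(self):
        # log-ratios {0, 2} -> sample variance (n-1 denominator) = 2
        f = np.array(
            [[0.5, 0.5], [0.5, 0.5 * np.exp(-2)], [0.1, 0.1], [0.2, 0.2]]
        )
        t = logratio_variances(f / f.sum(axis=0))
        assert t[0, 1] == pytest.approx(2.0)

    def test_plot_permutation_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(5), size=7).T
        t1 = logratio_variances(f)
        t2 = logratio_variances(f[:, rng.permutation(7)])
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_single_plot_rejected(self):
        with pytest.raises(MethodAssumptionError):
            logratio_variances(np.full((4, 1), 0.25))


class TestBasisVariances:
    def test_symmetric_constant_t_analytic(self):
        # all t_ij = c, p = 4 -> omega_i = 3c/(p-2+p) = c/2
        c = 1.8
        t = np.full((4, 4), c)
        np.fill_diagonal(t, 0.0)
        np.testing.assert_allclose(basis_variances(t), c / 2)

    def test_zero_t_floors_omega(self):
        omega = basis_variances(np.zeros((4, 4)))
        assert (omega == 1e-10).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_solve_oracle(self, seed):
        """Exclusion-modified system equals an independently built dense solve."""
        rng = np.random.default_rng(seed)
        a = rng.random((4, 4))
        t = (a + a.T) / 2
        np.fill_diagonal(t, 0.0)
        excluded = ((0, 2),)
        # oracle: build M and rhs from scratch, elementwise
        p = 4
        m = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                m[i, j] = (p - 2) + 1 if i == j else 1
        rhs = t.sum(axis=1).copy()
        for i, j in excluded:
            m[i, j] = m[j, i] = 0
            m[i, i] -= 1
            m[j, j] -= 1
            rhs[i] -= t[i, j]
            rhs[j] -= t[i, j]
        oracle = np.linalg.inv(m) @ rhs
        mine = basis_variances(t, excluded)
        np.testing.assert_allclose(mine, np.maximum(oracle, 1e-10), atol=1e-10)


class TestSparccCorrelations:
    def test_proportional_pair_gets_rho_one(self):
        rng = np.random.default_rng(3)
        base = rng.dirichlet(np.ones(5), size=12).T * 1000
        counts = base.round() + 1.0  # strictly positive for pseudocount 0
        counts[1] = 2 * counts[0]  # perfectly proportional pair
        res = sparcc_correlations(pd.DataFrame(counts, dtype=float), pseudocount=0)
        assert res.rho[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_result_matrix_properties(self):
        table, _ = simulate_genus_table(10, 30, seed=5)
        res = sparcc_correlations(table)
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(np.diag(res.rho), 1.0)
        assert (np.abs(res.rho) <= 1.0).all()
        assert (res.omega > 0).all()
        assert (res.t_matrix >= 0).all()

    def test_scale_invariance_without_pseudocount(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 100, size=(5, 10)).astype(float)
        scaled = counts.copy()
        scaled[:, 0] *= 7.0
        r1 = sparcc_correlations(pd.DataFrame(counts), pseudocount=0)
        r2 = sparcc_correlations(pd.DataFrame(scaled), pseudocount=0)
        np.testing.assert_allclose(r1.rho, r2.rho, atol=1e-12)

    def test_planted_block_recovery(self):
        corr = compound_block_correlation(50, [(i * 5, 5, 0.7) for i in range(6)])
        table, _ = simulate_genus_table(50, 120, corr=corr, depth=2000,
                                        genus_sd=1.0, seed=3)
        res = sparcc_correlations(table)
        iu = np.triu_indices(50, 1)
        r = np.corrcoef(corr[iu], res.rho[iu])[0, 1]
        assert r >= 0.7

    def test_null_data_small_correlations(self):
        table, _ = simulate_genus_table(50, 200, corr=None, depth=2000,
                                        genus_sd=1.0, seed=4)
        res = sparcc_correlations(table)
        iu = np.triu_indices(50, 1)
        assert np.abs(res.rho[iu]).mean() < 0.1

    def test_exclusions_capped(self):
        table, _ = simulate_genus_table(12, 40, seed=9)
        res = sparcc_correlations(table, exclusion_threshold=0.0, max_exclusions=3)
        assert len(res.excluded_pairs) == 3


class TestBootstrapPvalues:
    def test_all_positive_boundary_formula(self):
        """A pair positive in every resample gets p = 2/101 at n_boot = 100."""
        rng = np.random.default_rng(1)
        shared = rng.lognormal(0, 1, size=200)
        counts = np.vstack(
            [
                shared * 50,
                shared * 30,
                rng.integers(1, 50, 200),
                rng.integers(1, 50, 200),
                rng.integers(1, 50, 200),
            ]
        ).round()
        p = bootstrap_pvalues(pd.DataFrame(counts, dtype=float), n_boot=100, seed=2)
        assert p[0, 1] == pytest.approx(2 / 101)

    def test_pvalues_symmetric_in_unit_interval(self):
        table, _ = simulate_genus_table(8, 30, seed=6)
        p = bootstrap_pvalues(table, n_boot=40, seed=3)
        np.testing.assert_allclose(p, p.T)
        assert (p > 0).all() and (p <= 1).all()
        assert (np.diag(p) == 1.0).all()

    def test_small_n_boot_rejected(self):
        table, _ = simulate_genus_table(5, 10, seed=0)
        with pytest.raises(MethodAssumptionError):
            bootstrap_pvalues(table, n_boot=10)

    def test_deterministic_given_seed(self):
        table, _ = simulate_genus_table(6, 20, seed=1)
        p1 = bootstrap_pvalues(table, n_boot=25, seed=11)
        p2 = bootstrap_pvalues(table, n_boot=25, seed=11)
        np.testing.assert_array_equal(p1, p2)

    def test_power_on_strong_planted_pair(self):
        """rho = 0.9 planted pair at n = 200 plots is nearly always significant."""
        corr = compound_block_correlation(6, [(0, 2, 0.9)])
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            table, _ = simulate_genus_table(6, 200, corr=corr, depth=2000,
                                            genus_sd=1.0, seed=50 + s)
            p = bootstrap_pvalues(table, n_boot=100, seed=s)
            hits += p[0, 1] <= 0.05
        assert hits >= int(0.95 * n_rep)


class TestSparccEstimator:
    def test_sklearn_protocol(self):
        table, _ = simulate_genus_table(6, 25, seed=2)
        est = SparCC(n_boot=10, random_state=1)
        with pytest.raises(MethodAssumptionError):
            est.fit(table.T)  # n_boot below minimum propagates
        est = SparCC(n_boot=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.fit(table.T)  # plots x genera
        assert cloned.rho_.shape == (6, 6)
        assert cloned.pvalues_ is None
        assert cloned.genera_ == list(table.index)

    def test_estimator_matches_functions(self):
        table, _ = simulate_genus_table(7, 30, seed=4)
        est = SparCC(n_boot=25, random_state=9).fit(table.T)
        res = sparcc_correlations(table)
        np.testing.assert_allclose(est.rho_, res.rho)
        np.testing.assert_array_equal(
            est.pvalues_, bootstrap_pvalues(table, n_boot=25, seed=9)
        )
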