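"""Exact descriptors: closed forms, identities, and the linear-solver oracle."""

import dataclasses

import numpy as np
import pytest

from tcellfate import (
    AbsorptionError,
    StarModel,
    build_generator,
    compute_descriptors,
    death_location_probabilities,
    division_count_pmf,
    lifetime_lst,
    mean_divisions,
    mean_divisions_by_location,
    mean_genealogy_size,
    mean_lifetime,
    solve_first_step,
)


def blood_only(mu_B=2e-4, lam_B=0.0):
    return StarModel(xi_in=np.zeros(0), xi_out=np.zeros(0),
                     mu=np.zeros(0), lam=np.zeros(0),
                     mu_B=mu_B, lam_B=lam_B)


class TestMeanLifetime:
    def test_blood_only_is_exponential(self):
        assert mean_lifetime(blood_only(mu_B=2e-4))[0] == pytest.approx(5000.0)

    def test_uniform_killing_is_position_independent(self, random_models):
        """With one death rate everywhere the lifetime is Exp(mu) regardless
        of the migration structure."""
        for m in random_models(5):
            mu = 3.3e-4
            uni = dataclasses.replace(
                m, mu=np.full(m.M, mu), mu_B=mu)
            np.testing.assert_allclose(
                mean_lifetime(uni), 1.0 / mu, rtol=1e-10)

    def test_no_death_is_signalled(self):
        m = StarModel(xi_in=[0.1], xi_out=[0.2], mu=[0.0], lam=[0.0],
                      mu_B=0.0, lam_B=0.0)
        with pytest.raises(AbsorptionError, match="infinite"):
            mean_lifetime(m)

    def test_increasing_death_never_lengthens_life(self, random_models):
        for m in random_models(10):
            base = mean_lifetime(m)
            harder = dataclasses.replace(m, mu=m.mu * 1.5, mu_B=m.mu_B * 1.5)
            assert np.all(mean_lifetime(harder) <= base + 1e-12)


class TestMeanDivisions:
    def test_zero_division_rates(self, random_models):
        for m in random_models(3):
            frozen = dataclasses.replace(m, lam=np.zeros(m.M), lam_B=0.0)
            np.testing.assert_allclose(mean_divisions(frozen), 0.0)

    def test_uniform_rates_give_lambda_over_mu(self, random_models):
        """Uniform division/death: the race outcome is independent of position."""
        lam, mu = 2.4e-5, 3.1e-5
        for m in random_models(5):
            uni = dataclasses.replace(
                m, lam=np.full(m.M, lam), mu=np.full(m.M, mu),
                lam_B=lam, mu_B=mu)
            np.testing.assert_allclose(
                mean_divisions(uni), lam / mu, rtol=1e-10)

    def test_split_rows_sum_to_total(self, random_models):
        for m in random_models(10):
            by_loc = mean_divisions_by_location(m)
            np.testing.assert_allclose(
                by_loc.sum(axis=1), mean_divisions(m), rtol=1e-10)

    def test_no_blood_division_empties_blood_column(self, random_models):
        for m in random_models(3):
            quiet = dataclasses.replace(m, lam_B=0.0)
            np.testing.assert_allclose(
                mean_divisions_by_location(quiet)[:, 0], 0.0)

    def test_single_compartment_location_ratio(self):
        """m_hat_B(B) / m_hat_B(C1) = lam_B (mu_C1 + xi_C1B) / (xi_BC1 lam_C1)."""
        m = StarModel(xi_in=[0.07], xi_out=[0.03], mu=[2e-4], lam=[1.3e-4],
                      mu_B=1e-4, lam_B=9e-5)
        by_loc = mean_divisions_by_location(m)
        expected = m.lam_B * (m.mu[0] + m.xi_out[0]) / (m.xi_in[0] * m.lam[0])
        assert by_loc[0, 0] / by_loc[0, 1] == pytest.approx(expected, rel=1e-10)


class TestDeathLocation:
    def test_rows_are_distributions(self, random_models):
        for m in random_models(10):
            beta = death_location_probabilities(m)
            np.testing.assert_allclose(beta.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(beta >= 0)

    def test_no_migration_dies_in_place(self):
        m = StarModel(xi_in=[0.0], xi_out=[0.1], mu=[1e-4], lam=[0.0],
                      mu_B=1e-4, lam_B=0.0)
        beta = death_location_probabilities(m)
        assert beta[0, 0] == pytest.approx(1.0)

    def test_immortal_blood_empties_blood_column(self, random_models):
        for m in random_models(3):
            safe = dataclasses.replace(m, mu_B=0.0)
            np.testing.assert_allclose(
                death_location_probabilities(safe)[:, 0], 0.0)


class TestGenealogy:
    def test_no_division_means_no_progeny(self, random_models):
        for m in random_models(3):
            frozen = dataclasses.replace(m, lam=np.zeros(m.M), lam_B=0.0)
            mt, finite = mean_genealogy_size(frozen)
            assert finite
            np.testing.assert_allclose(mt, 0.0)

    def test_blood_only_closed_form(self):
        m = blood_only(mu_B=3e-4, lam_B=1e-4)
        mt, finite = mean_genealogy_size(m)
        assert finite
        assert mt[0] == pytest.approx(2 * 1e-4 / (3e-4 - 1e-4))

    def test_supercritical_flags_infinity(self):
        m = blood_only(mu_B=1e-4, lam_B=3e-4)
        mt, finite = mean_genealogy_size(m)
        assert not finite
        assert np.isinf(mt).all()


class TestLifetimeLST:
    def test_at_zero_is_one(self, random_models):
        for m in random_models(3):
            np.testing.assert_allclose(lifetime_lst(m, 0.0), 1.0, atol=1e-10)

    def test_blood_only_exponential_transform(self):
        m = blood_only(mu_B=2e-4)
        for s in (1e-5, 1e-4, 1e-3):
            assert lifetime_lst(m, s)[0] == pytest.approx(2e-4 / (2e-4 + s))

    def test_uniform_killing_transform(self, random_models):
        mu = 4e-4
        for m in random_models(3):
            uni = dataclasses.replace(m, mu=np.full(m.M, mu), mu_B=mu)
            np.testing.assert_allclose(
                lifetime_lst(uni, 1e-4), mu / (mu + 1e-4), rtol=1e-10)

    def test_derivative_at_zero_recovers_mean(self, random_models):
        m = random_models(1)[0]
        h = 1e-9
        deriv = (lifetime_lst(m, h) - lifetime_lst(m, 0.0)) / h
        np.testing.assert_allclose(deriv, -mean_lifetime(m), rtol=1e-4)

    def test_negative_argument_rejected(self, table1):
        with pytest.raises(ValueError, match=">= 0"):
            lifetime_lst(table1, -1.0)


class TestDivisionCountPMF:
    def test_uniform_rates_are_geometric(self, table1):
        """Uniform division/death: each stage is won by division with
        probability lam/(lam+mu), independent of where the cell wanders."""
        lam, mu = 1.458e-5, 1.478e-5
        pmf = division_count_pmf(table1, "B", n_max=500, tail_tol=1e-10)
        n = np.arange(pmf.p.size)
        geometric = (lam / (lam + mu)) ** n * mu / (lam + mu)
        np.testing.assert_allclose(pmf.p, geometric, rtol=1e-9)

    def test_no_division_is_point_mass(self, random_models):
        for m in random_models(3):
            frozen = dataclasses.replace(m, lam=np.zeros(m.M), lam_B=0.0)
            pmf = division_count_pmf(frozen, 0)
            assert pmf.p[0] == pytest.approx(1.0)

    def test_mean_matches_closed_form(self, random_models):
        for m in random_models(5, regime="subcritical"):
            pmf = division_count_pmf(m, 0, n_max=50_000, tail_tol=1e-12)
            assert pmf.tail < 1e-10
            assert pmf.mean() == pytest.approx(
                mean_divisions(m)[0], rel=1e-6)

    def test_mass_accounting(self, table1):
        pmf = division_count_pmf(table1, "C1", n_max=50, tail_tol=0.0)
        assert 0 <= pmf.tail <= 1
        assert np.sum(pmf.p) + pmf.tail == pytest.approx(1.0, abs=1e-12)

    def test_immortal_model_rejected(self):
        m = StarModel(xi_in=[0.1], xi_out=[0.2], mu=[0.0], lam=[1e-4],
                      mu_B=0.0, lam_B=1e-4)
        with pytest.raises(AbsorptionError, match="spectral radius"):
            division_count_pmf(m, 0)


class TestFirstStepOracle:
    """The closed forms against the generic linear solve on the generator."""

    def test_definitional_rewards(self, table1):
        gen = build_generator(table1)
        lam = gen.division
        np.testing.assert_allclose(
            solve_first_step(gen, np.ones(6)), mean_lifetime(table1),
            rtol=1e-12)
        np.testing.assert_allclose(
            solve_first_step(gen, lam), mean_divisions(table1), rtol=1e-12)
        beta = death_location_probabilities(table1)
        for j in range(6):
            reward = np.zeros(6)
            reward[j] = gen.death_rates[j]
            np.testing.assert_allclose(
                solve_first_step(gen, reward), beta[:, j], rtol=1e-12)

    def test_closed_forms_match_oracle_on_random_models(self, random_models):
        """Every closed form agrees with the linear solve to 1e-9 relative."""
        for m in random_models(100, regime="subcritical", seed=4242):
            gen = build_generator(m)
            n = m.M + 1
            lam = gen.division
            np.testing.assert_allclose(
                mean_lifetime(m), solve_first_step(gen, np.ones(n)),
                rtol=1e-9)
            np.testing.assert_allclose(
                mean_divisions(m), solve_first_step(gen, lam), rtol=1e-9)
            by_loc = mean_divisions_by_location(m)
            beta = death_location_probabilities(m)
            for j in range(n):
                ej = np.zeros(n)
                ej[j] = 1.0
                np.testing.assert_allclose(
                    by_loc[:, j], solve_first_step(gen, lam * ej),
                    rtol=1e-9, atol=1e-15)
                np.testing.assert_allclose(
                    beta[:, j],
                    solve_first_step(gen, gen.death_rates * ej),
                    rtol=1e-9, atol=1e-15)
            mt, finite = mean_genealogy_size(m)
            assert finite
            np.testing.assert_allclose(
                mt, solve_first_step(gen, 2 * lam, division_feedback=1.0),
                rtol=1e-9)

    def test_unreachable_absorption_is_named(self):
        m = StarModel(xi_in=[0.1], xi_out=[0.2], mu=[0.0], lam=[0.0],
                      mu_B=0.0, lam_B=0.0)
        gen = build_generator(m)
        with pytest.raises(AbsorptionError, match="singular"):
            solve_first_step(gen, np.ones(2))


class TestDescriptorSet:
    def test_invariants_and_serialization(self, table1):
        ds = compute_descriptors(table1)
        np.testing.assert_allclose(ds.beta.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            ds.m_hat_by_loc.sum(axis=1), ds.m_hat, rtol=1e-10)
        assert ds.genealogy_finite
        df = ds.to_frame()
        assert set(df.columns) == {
            "start", "statistic", "location", "value", "units", "method"}
        row = df[(df.start == "B") & (df.statistic == "mean_lifetime")]
        assert row.value.iloc[0] == pytest.approx(ds.m[0])
        d = ds.to_json_dict()
        assert d["genealogy_finite"] is True
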