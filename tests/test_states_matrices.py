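"""State space, intensity/transition/emission matrices, sojourn times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from ckdhmm.matrices import (annual_transition_diagram, apply_age_multiplier,
                             build_emission_matrix, build_intensity_matrix,
                             expm_taylor_batch, mean_sojourn, p_living,
                             transition_probability_matrix, tri_eig_living)
from ckdhmm.parameters import CovariateProfile, ModelParameters, Multiplier
from ckdhmm.states import STATE_SPACE

rates = st.floats(1e-4, 0.5)


def rand_params(seed):
    rng = np.random.default_rng(seed)
    return ModelParameters(progression_rates=rng.uniform(0.005, 0.3, 4),
                           death_rates=rng.uniform(0.005, 0.3, 5))


class TestStateSpace:
    def test_ordering_and_indexing(self):
        assert STATE_SPACE.index("G1_2") == 0
        assert STATE_SPACE.index("DEATH") == 5
        assert STATE_SPACE.n_living == 5
        with pytest.raises(KeyError):
            STATE_SPACE.index("G6")

    def test_egfr_ranges_partition(self):
        # every positive eGFR maps to exactly one stage, in severity order
        for egfr, stage in [(90, "G1_2"), (60.5, "G1_2"), (50, "G3A"),
                            (45, "G3B"), (30, "G4"),
                            (14.9, "G5"), (0.1, "G5")]:
            assert STATE_SPACE.stage_of_egfr(egfr) == stage
        with pytest.raises(ValueError):
            STATE_SPACE.stage_of_egfr(0)


class TestIntensityMatrix:
    def test_zero_rates_zero_matrix(self):
        p = ModelParameters(progression_rates=np.zeros(4),
                            death_rates=np.zeros(5))
        Q = build_intensity_matrix(p).matrix
        assert np.all(Q == 0)

    def test_reference_profile_is_identity_on_rates(self):
        p = rand_params(1)
        Q = build_intensity_matrix(p, CovariateProfile(), age=60.0)
        np.testing.assert_allclose(Q.progression_rates, p.progression_rates)
        np.testing.assert_allclose(Q.death_rates, p.death_rates)

    def test_age_multiplier_on_rate_scale(self):
        p = ModelParameters(progression_rates=[0.010, 0.01, 0.01, 0.01],
                            death_rates=np.full(5, 0.01),
                            multipliers={"age": Multiplier(1.08, 1.09)})
        prof = CovariateProfile(age_at_entry=60.0)
        Q = build_intensity_matrix(p, prof, age=70.0)
        assert Q.matrix[0, 1] == pytest.approx(0.010 * 1.08 ** 10)
        assert Q.matrix[0, 1] == pytest.approx(0.021589, abs=5e-7)

    def test_covariate_multipliers_apply(self):
        p = rand_params(2).replace(multipliers={
            "male": Multiplier(1.5, 2.0), "cancer": Multiplier(1.2, 1.1)})
        prof = CovariateProfile(male=1, cancer=1)
        Q = build_intensity_matrix(p, prof, age=60.0)
        np.testing.assert_allclose(
            Q.progression_rates, p.progression_rates * 1.5 * 1.2)
        np.testing.assert_allclose(Q.death_rates, p.death_rates * 2.0 * 1.1)

    def test_row_sums_and_death_row(self):
        Q = build_intensity_matrix(rand_params(3)).matrix
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert np.all(Q[5] == 0)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            ModelParameters(progression_rates=[-0.1, 0, 0, 0],
                            death_rates=np.zeros(5))
        with pytest.raises(ValueError):
            CovariateProfile(albuminuria_stratum="nope")
        with pytest.raises(ValueError):
            CovariateProfile(age_at_entry=10)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_intensity_matrix(rand_params(4))
        np.testing.assert_allclose(transition_probability_matrix(Q, 0.0),
                                   np.eye(6), atol=1e-14)

    def test_two_state_exponential_survival(self):
        # a single exit rate q gives staying probability e^{-qt}
        p = ModelParameters(progression_rates=[0.1, 0, 0, 0],
                            death_rates=np.zeros(5))
        P = transition_probability_matrix(build_intensity_matrix(p), 1.0)
        assert P[0, 0] == pytest.approx(np.exp(-0.1), rel=1e-12)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.1), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_chapman_kolmogorov(self, seed):
        Q = build_intensity_matrix(rand_params(seed))
        s, t = 0.7, 2.3
        np.testing.assert_allclose(
            transition_probability_matrix(Q, s + t),
            transition_probability_matrix(Q, s)
            @ transition_probability_matrix(Q, t), atol=1e-8)

    @pytest.mark.parametrize("seed,t", [(0, 0.5), (5, 1.0), (9, 7.0)])
    def test_stochastic_and_unidirectional(self, seed, t):
        P = transition_probability_matrix(
            build_intensity_matrix(rand_params(seed)), t)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)
        assert np.all(P >= 0) and np.all(P <= 1)
        # no mass flows to a less severe living stage; death is absorbing
        assert np.allclose(np.tril(P[:5, :5], -1), 0, atol=1e-12)
        assert P[5, 5] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_eigen_engine_matches_expm(self, seed):
        p = rand_params(seed)
        lam, V, W = tri_eig_living(p.progression_rates[None, :],
                                   p.death_rates[None, :])
        for t in (0.3, 1.0, 4.0):
            ref = expm(t * build_intensity_matrix(p).living_block)
            got = p_living(lam, V, W, np.array([t]))[0]
            np.testing.assert_allclose(got, ref, atol=1e-11)

    def test_taylor_fallback_matches_expm_with_tied_rates(self):
        # equal exit rates are the degenerate case for the eigen route
        p = ModelParameters(progression_rates=np.full(4, 0.1),
                            death_rates=np.full(5, 0.05))
        A = 2.0 * build_intensity_matrix(p).living_block
        np.testing.assert_allclose(expm_taylor_batch(A[None])[0], expm(A),
                                   atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability_matrix(
                build_intensity_matrix(rand_params(0)), -1.0)


class TestMeanSojourn:
    def test_unit_exit_rate(self):
        p = ModelParameters(progression_rates=[0.6, 0, 0, 0],
                            death_rates=[0.4, 0, 0, 0, 0])
        s = mean_sojourn(build_intensity_matrix(p))
        assert s[0] == pytest.approx(1.0)
        assert np.isinf(s[1:]).all()

    def test_published_first_stage_value(self, unmeasured_params):
        # a total exit rate of 1/30.5 per year means 30.5 years in stage 1
        p = ModelParameters(progression_rates=[1 / 30.5, 0.1, 0.1, 0.1],
                            death_rates=np.zeros(5))
        s = mean_sojourn(build_intensity_matrix(p))
        assert s[0] == pytest.approx(30.5)

    def test_monotone_in_exit_rate(self):
        p1 = rand_params(7)
        p2 = ModelParameters(progression_rates=p1.progression_rates * 2,
                             death_rates=p1.death_rates * 2)
        s1 = mean_sojourn(build_intensity_matrix(p1))
        s2 = mean_sojourn(build_intensity_matrix(p2))
        assert np.all(s2 < s1)


class TestAgeMultiplierPresentation:
    def test_published_worked_examples(self):
        assert round(100 * apply_age_multiplier(0.010, 1.08, 10), 2) == 2.16
        assert round(100 * apply_age_multiplier(0.010, 1.08, 20), 2) == 4.66

    def test_zero_years_identity(self):
        assert apply_age_multiplier(0.37, 1.08, 0) == 0.37

    def test_cap_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert apply_age_multiplier(0.5, 1.1, 30) == 1.0

    @given(p=st.floats(1e-4, 0.02), m=st.floats(1.0, 1.1),
           y=st.integers(0, 20))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_first_order_agreement_with_rate_scale(self, p, m, y):
        # the probability-scale shortcut p * m^y tracks the rigorous
        # intensity-scale computation (rate scaled by m^y, then one-year
        # probability) to within ~5% relative for small probabilities
        rate = -np.log1p(-p)
        shortcut = p * m ** y
        exact = 1 - np.exp(-rate * m ** y)
        assert abs(shortcut - exact) / shortcut <= 0.056


class TestEmissionMatrix:
    def test_no_misclassification_is_identity(self):
        E = build_emission_matrix({}).matrix
        np.testing.assert_allclose(E, np.eye(6))

    def test_published_complement(self):
        E = build_emission_matrix({("G1_2", "G3A"): 0.029}).matrix
        assert E[0, 0] == pytest.approx(0.971)

    def test_outside_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            build_emission_matrix({("G1_2", "G4"): 0.01})
        with pytest.raises(ValueError, match="band"):
            build_emission_matrix({("G1_2", "G3B"): 0.01}, band_width=1)

    def test_row_mass_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            build_emission_matrix({("G3B", "G3A"): 0.6, ("G3B", "G4"): 0.5})

    def test_rows_sum_to_one(self, macro_params):
        np.testing.assert_allclose(macro_params.emission.sum(axis=1), 1,
                                   atol=1e-12)


class TestAnnualDiagram:
    def test_zero_intensities_stay_put(self):
        p = ModelParameters(progression_rates=np.zeros(4),
                            death_rates=np.zeros(5))
        d = annual_transition_diagram(p)
        np.testing.assert_allclose(d["stay"], 1.0)

    def test_matches_transition_matrix(self, macro_params):
        d = annual_transition_diagram(macro_params)
        P1 = transition_probability_matrix(
            build_intensity_matrix(macro_params), 1.0)
        for r in range(4):
            assert d["progress"].iloc[r] == pytest.approx(P1[r, r + 1])
            assert d["death"].iloc[r] == pytest.approx(P1[r, 5])
            assert d["stay"].iloc[r] == pytest.approx(P1[r, r])

    def test_reference_profile_published_values(self, unmeasured_params):
        d = annual_transition_diagram(unmeasured_params)
        assert round(100 * d["progress"].iloc[0], 1) == 1.1
        assert round(100 * d["death"].iloc[0], 1) == 0.7
        assert round(100 * d["stay"].iloc[0], 1) == 98.2
        assert round(100 * d["observed_G3A"].iloc[0], 1) == 2.9
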