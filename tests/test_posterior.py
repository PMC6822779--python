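import numpy as np
import pytest

from confsig import DiscriminabilityPrior, ExperimentConfig, PosteriorEngine, simulate_trials

from conftest import brute_posterior

D = DiscriminabilityPrior


def logistic_known_d(d, e_I, sigma_I=1.0):
    """Closed-form posterior of I=1 when discriminability is known."""
    return 1.0 / (1.0 + np.exp(-2.0 * d * e_I / sigma_I**2))


class TestPosteriorIdentity:
    @pytest.mark.parametrize(
        "prior", [D.discrete_uniform([0, 1]), D.continuous_uniform(0, 4), D.gamma(2, 1)]
    )
    def test_neutral_evidence_gives_half(self, prior):
        assert PosteriorEngine(prior).posterior_identity(0.0) == pytest.approx(0.5, abs=1e-12)

    def test_neutral_evidence_gives_half_general(self):
        eng = PosteriorEngine(D.discrete_uniform([0, 1, 2]), sigma_d=0.5)
        for e_d in (-1.0, 0.0, 2.7):
            assert eng.posterior_identity(0.0, e_d) == pytest.approx(0.5, abs=1e-12)

    def test_point_mass_prior_logistic_closed_form(self):
        eng = PosteriorEngine(D.discrete_uniform([1.0]))
        assert eng.posterior_identity(1.0) == pytest.approx(logistic_known_d(1, 1), abs=1e-12)

    def test_reliable_e_d_pins_discriminability(self):
        # sigma_d = 0.01 with e_d exactly at a support point: the prior
        # collapses onto d = 2 and the known-d closed form applies.
        eng = PosteriorEngine(D.discrete_uniform([0, 2]), sigma_d=0.01)
        assert eng.posterior_identity(1.0, 2.0) == pytest.approx(
            logistic_known_d(2, 1), abs=1e-4
        )

    def test_mirror_antisymmetry(self):
        eng = PosteriorEngine(D.gamma(1.5, 1.5))
        for e in (0.3, 1.7, 4.0):
            assert eng.posterior_identity(-e) == pytest.approx(
                1.0 - eng.posterior_identity(e), abs=1e-12
            )

    def test_extreme_evidence_no_overflow(self):
        eng = PosteriorEngine(D.discrete_uniform([0, 10]))
        p = eng.posterior_identity(np.array([60.0, -60.0]))
        assert 0.0 < p[1] < 1e-10 and 1.0 - 1e-10 < p[0] <= 1.0

    @pytest.mark.parametrize(
        "values", [[0.0, 1.0], [0.5, 2.5, 4.0], [0.0, 0.25, 1.0, 3.0, 4.0]]
    )
    def test_matches_direct_summation_standard(self, values):
        eng = PosteriorEngine(D.discrete_uniform(values), sigma_I=1.3)
        for e_I in (-4.0, -0.7, 0.0, 0.2, 2.5):
            expected = brute_posterior(values, 1.3, e_I)
            assert eng.posterior_identity(e_I) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("values", [[0.0, 1.0, 2.0], [0.0, 3.0]])
    def test_matches_direct_summation_general(self, values):
        eng = PosteriorEngine(D.discrete_uniform(values), sigma_I=0.8, sigma_d=0.5)
        for e_I, e_d in [(-2.0, 0.3), (0.4, 1.1), (1.5, 2.9), (3.0, -0.4)]:
            expected = brute_posterior(values, 0.8, e_I, 0.5, e_d)
            assert eng.posterior_identity(e_I, e_d) == pytest.approx(expected, abs=1e-12)


class TestConfidence:
    def test_neutral_evidence(self):
        assert PosteriorEngine(D.continuous_uniform(0, 2)).confidence(0.0, None, 1) == (
            pytest.approx(0.5, abs=1e-12)
        )

    def test_point_mass_mirror(self):
        eng = PosteriorEngine(D.discrete_uniform([1.0]))
        assert eng.confidence(-1.0, None, -1) == pytest.approx(
            logistic_known_d(1, 1), abs=1e-12
        )

    @pytest.mark.parametrize(
        "prior",
        [D.discrete_uniform([0, 1]), D.continuous_uniform(0, 2), D.gamma(1.5, 1.5)],
    )
    def test_general_reduces_to_standard_as_sigma_d_diverges(self, prior):
        std = PosteriorEngine(prior)
        gen = PosteriorEngine(prior, sigma_d=1e9)
        e_I = np.linspace(-4, 4, 33)
        for e_d in (-1.0, 0.7, 5.0):
            diff = gen.confidence(e_I, np.full_like(e_I, e_d), 1) - std.confidence(
                e_I, None, 1
            )
            assert np.max(np.abs(diff)) < 1e-6

    def test_reliable_e_d_recovers_known_d_logistic(self):
        # sigma_d = 1e-3: e_d near a support point makes the posterior
        # over d a point mass at the nearest support value.
        eng = PosteriorEngine(D.discrete_uniform([0, 1, 2]), sigma_d=1e-3)
        for e_d, d_near in [(0.9995, 1.0), (2.0003, 2.0), (0.0002, 0.0)]:
            for e_I in (0.3, 1.2, -0.8):
                got = eng.posterior_identity(e_I, e_d)
                assert got == pytest.approx(logistic_known_d(d_near, e_I), abs=1e-4)

    def test_monotone_in_identity_evidence(self):
        e_I = np.linspace(0, 8, 200)
        for eng in (
            PosteriorEngine(D.discrete_uniform([0, 1, 2])),
            PosteriorEngine(D.gamma(2, 1), sigma_d=0.5),
            PosteriorEngine(D.continuous_uniform(0, 4)),
        ):
            e_d = np.full_like(e_I, 1.0) if eng.is_general else None
            c = eng.confidence(e_I, e_d, 1)
            assert np.all(np.diff(c) >= -1e-12)

    def test_usage_errors(self):
        std = PosteriorEngine(D.discrete_uniform([0, 1]))
        gen = PosteriorEngine(D.discrete_uniform([0, 1]), sigma_d=0.5)
        with pytest.raises(ValueError):
            std.posterior_identity(1.0, 0.5)
        with pytest.raises(ValueError):
            gen.posterior_identity(1.0)


class TestScoreTable:
    def test_point_mass_fixture(self):
        from confsig import TrialTable, choose

        e_I = np.array([0.0, 1.0, -1.0])
        t = TrialTable(
            I=np.array([1, 1, -1], dtype=np.int8),
            d=np.ones(3),
            e_I=e_I,
            choice=choose(e_I),
            accuracy=np.array([1, 1, 1], dtype=np.int8),
        )
        scored = PosteriorEngine(D.discrete_uniform([1.0])).score(t)
        expected = [0.5, logistic_known_d(1, 1), logistic_known_d(1, 1)]
        np.testing.assert_allclose(scored.confidence, expected, atol=1e-12)

    def test_scoring_is_pure_and_in_range(self):
        cfg = ExperimentConfig(
            prior=D.discrete_uniform([0, 1, 2]), n_trials=100_000, seed=13
        )
        trials = simulate_trials(cfg)
        eng = PosteriorEngine(cfg.prior)
        a, b = eng.score(trials), eng.score(trials)
        np.testing.assert_array_equal(a.confidence, b.confidence)
        assert a.confidence.min() >= 0.5 and a.confidence.max() <= 1.0
        assert trials.confidence is None  # input untouched

    def test_vectorised_matches_scalar(self):
        cfg = ExperimentConfig(
            prior=D.discrete_uniform([0, 1]), sigma_d=0.5, n_trials=50, seed=4
        )
        trials = simulate_trials(cfg)
        eng = PosteriorEngine(cfg.prior, sigma_d=0.5)
        scored = eng.score(trials)
        for j in range(0, 50, 7):
            one = eng.confidence(trials.e_I[j], trials.e_d[j], int(trials.choice[j]))
            assert scored.confidence[j] == pytest.approx(one, abs=1e-14)

    def test_general_engine_requires_e_d_column(self):
        cfg = ExperimentConfig(prior=D.discrete_uniform([0, 1]), n_trials=10, seed=0)
        with pytest.raises(ValueError):
            PosteriorEngine(cfg.prior, sigma_d=0.5).score(simulate_trials(cfg))

    def test_standard_engine_ignores_e_d_column(self):
        # deliberate mismatch used by the identity-only entropy comparison
        cfg = ExperimentConfig(
            prior=D.discrete_uniform([0, 1]), sigma_d=0.5, n_trials=1_000, seed=0
        )
        trials = simulate_trials(cfg)
        scored = PosteriorEngine(cfg.prior).score(trials)
        ref = PosteriorEngine(cfg.prior).confidence(trials.e_I, None, trials.choice)
        np.testing.assert_array_equal(scored.confidence, ref)
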