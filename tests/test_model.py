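"""Unit and property tests for the template-inference model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plumm.model import (
    DEFAULT_LEVEL_PROBS,
    ModelParams,
    ParameterError,
    TemplatePair,
    apply_contrast,
    build_templates,
    delta_surprisal,
    filter_observations,
    observation_probability,
    parameter_sweep,
    posterior_update,
    run_inference,
    surprisal,
    transition_prior,
)
from plumm.rhythm import GRID, LEVEL_POSITIONS, QUARTER_POSITIONS, RhythmPattern, to_stream

from oracles import brute_force_total_surprisal

probability = st.floats(0.01, 0.99)


# ---------------------------------------------------------------------------
# contrast scaling and template construction
# ---------------------------------------------------------------------------

class TestApplyContrast:
    def test_full_contrast_is_identity(self, templates):
        np.testing.assert_allclose(apply_contrast(templates.metered, 1.0), templates.metered)

    def test_zero_contrast_flattens_to_mean(self):
        np.testing.assert_allclose(apply_contrast([0.8, 0.2], 0.0), [0.5, 0.5])

    def test_half_contrast_halves_spread(self):
        np.testing.assert_allclose(apply_contrast([0.8, 0.2], 0.5), [0.65, 0.35])

    @given(
        values=st.lists(probability, min_size=2, max_size=32),
        contrast=st.floats(0.0, 1.0),
    )
    def test_mean_preserved(self, values, contrast):
        out = apply_contrast(values, contrast)
        assert abs(out.mean() - np.mean(values)) < 1e-12

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_contrast_domain(self, bad):
        with pytest.raises(ParameterError):
            apply_contrast([0.5, 0.5], bad)


class TestBuildTemplates:
    def test_level_structure(self, templates):
        m = templates.metered
        for level, positions in enumerate(LEVEL_POSITIONS):
            vals = m[list(positions)]
            assert np.ptp(vals) == 0, f"level {level} positions must share a probability"
            assert vals[0] == pytest.approx(DEFAULT_LEVEL_PROBS[level])

    def test_downbeat_is_unique_maximum(self, templates):
        m = templates.metered
        assert m[0] > np.max(m[1:])

    def test_odd_positions_share_minimum(self, templates):
        odd = templates.metered[1::2]
        assert np.ptp(odd) == 0
        assert odd[0] == np.min(templates.metered)

    def test_unmetered_closed_form(self, templates):
        w, h, q, e, s, t = DEFAULT_LEVEL_PROBS
        expected = (w + h + 2 * q + 4 * e + 8 * s + 16 * t) / 32
        assert templates.unmetered == pytest.approx(expected, abs=1e-12)

    def test_unmetered_equals_metered_mean(self, templates):
        assert abs(templates.metered.mean() - templates.unmetered) < 1e-12

    @given(contrast=st.floats(0.0, 1.0))
    @settings(max_examples=25)
    def test_contrast_preserves_mean_and_ordering(self, contrast):
        pair = build_templates(contrast=contrast)
        assert abs(pair.metered.mean() - pair.unmetered) < 1e-12
        if contrast > 1e-9:
            levels = [pair.metered[p[0]] for p in LEVEL_POSITIONS]
            assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_non_monotone_level_probs_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            build_templates(level_probs=(0.9, 0.95, 0.8, 0.4, 0.15, 0.05))


# ---------------------------------------------------------------------------
# single-step operations
# ---------------------------------------------------------------------------

class TestStepOperations:
    def test_observation_probability_values(self):
        assert observation_probability(1.0, 0.8, 0.4, 1) == pytest.approx(0.8)
        assert observation_probability(0.5, 0.8, 0.4, 1) == pytest.approx(0.6)
        assert observation_probability(0.5, 0.8, 0.4, 0) == pytest.approx(0.4)

    @given(prior=probability, lam_m=probability, lam_u=probability)
    def test_observation_probability_normalizes(self, prior, lam_m, lam_u):
        total = observation_probability(prior, lam_m, lam_u, 1) + observation_probability(
            prior, lam_m, lam_u, 0
        )
        assert abs(total - 1.0) < 1e-12

    def test_posterior_values(self):
        assert posterior_update(0.5, 0.8, 0.4, 1) == pytest.approx(2 / 3)
        assert posterior_update(0.3, 0.6, 0.6, 1) == pytest.approx(0.3)  # uninformative
        assert posterior_update(0.0, 0.8, 0.4, 1) == 0.0  # absorbing zero prior

    def test_posterior_zero_evidence(self):
        with pytest.raises(ZeroDivisionError):
            posterior_update(1.0, 0.0, 0.0, 1)

    def test_transition_values(self):
        assert transition_prior(0.9, 0.5) == pytest.approx(0.5)
        assert transition_prior(0.1, 0.5) == pytest.approx(0.5)
        assert transition_prior(0.9, 0.01) == pytest.approx(0.892)
        assert transition_prior(0.7, 0.0) == pytest.approx(0.7)

    def test_surprisal_values(self):
        assert surprisal(1.0) == 0.0
        assert surprisal(0.6) == pytest.approx(0.5108, abs=1e-4)
        assert surprisal(0.1) == pytest.approx(2.3026, abs=1e-4)
        with pytest.raises(ValueError):
            surprisal(0.0)


# ---------------------------------------------------------------------------
# sequence filtering
# ---------------------------------------------------------------------------

class TestRunInference:
    def test_trace_lengths(self, templates, default_params, nine_fixtures):
        trace = run_inference(to_stream(nine_fixtures[0]), templates, default_params)
        for seq in (trace.priors, trace.posteriors, trace.obs_probs, trace.surprisal):
            assert len(seq) == 128
        assert trace.mean_surprisal == pytest.approx(trace.surprisal.mean())
        np.testing.assert_allclose(trace.surprisal, -np.log(trace.obs_probs))

    def test_trace_recursion_consistency(self, templates, default_params, nine_fixtures):
        """Each prior is the transition image of the preceding posterior."""
        trace = run_inference(to_stream(nine_fixtures[3]), templates, default_params)
        expected = transition_prior(trace.posteriors[:-1], default_params.p_switch)
        np.testing.assert_allclose(trace.priors[1:], expected, atol=1e-12)

    @given(
        data=st.data(),
        T=st.integers(1, 12),
        p_switch=st.floats(0.001, 0.999),
        initial_prior=st.floats(0.01, 0.99),
        lam_u=probability,
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_enumeration(self, data, T, p_switch, initial_prior, lam_u):
        """Recursive total surprisal equals -log of the enumerated marginal."""
        obs = np.array(data.draw(st.lists(st.integers(0, 1), min_size=T, max_size=T)))
        lam_m = np.array(data.draw(st.lists(probability, min_size=T, max_size=T)))
        params = ModelParams(p_switch=p_switch, contrast=1.0, initial_prior=initial_prior)
        trace = filter_observations(obs, lam_m, lam_u, params)
        expected = brute_force_total_surprisal(obs, lam_m, lam_u, p_switch, initial_prior)
        assert trace.total_surprisal == pytest.approx(expected, abs=1e-9)

    def test_matches_hmm_library_likelihood(self, templates, nine_fixtures):
        """Total surprisal agrees with an independent HMM forward pass."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        params = ModelParams(p_switch=0.1, initial_prior=0.4)
        obs = to_stream(nine_fixtures[4])
        trace = run_inference(obs, templates, params)
        model = hmm.CategoricalHMM(n_components=2, init_params="")
        model.startprob_ = np.array([0.4, 0.6])
        model.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        lam = templates.tile(obs.size)
        # hmmlearn wants stationary emissions; fold the cyclic template into
        # 32 distinct symbols (position, onset) with per-state probabilities
        sym = obs.astype(int) + 2 * (np.arange(obs.size) % 32)
        emis_m = np.zeros((1, 64))
        emis_u = np.zeros((1, 64))
        for p in range(32):
            emis_m[0, 2 * p] = 1.0 - templates.metered[p]
            emis_m[0, 2 * p + 1] = templates.metered[p]
            emis_u[0, 2 * p] = 1.0 - templates.unmetered
            emis_u[0, 2 * p + 1] = templates.unmetered
        # normalizing over the 64 symbols divides each state's emission by
        # 32, so the HMM likelihood is the model's times (1/32)^T
        model.emissionprob_ = np.vstack([emis_m, emis_u]) / 32.0
        loglik = model.score(sym.reshape(-1, 1))
        assert trace.total_surprisal == pytest.approx(
            -loglik - obs.size * np.log(32), rel=1e-9
        )

    def test_prior_bounds(self, templates, nine_fixtures):
        """With p_switch > 0 every propagated prior stays in [p, 1-p]."""
        params = ModelParams(p_switch=0.05)
        trace = run_inference(to_stream(nine_fixtures[8]), templates, params)
        assert np.all(trace.priors[1:] >= 0.05 - 1e-12)
        assert np.all(trace.priors[1:] <= 0.95 + 1e-12)
        assert np.all((trace.posteriors >= 0) & (trace.posteriors <= 1))

    def test_symmetric_switching_pins_prior(self, templates, nine_fixtures):
        params = ModelParams(p_switch=0.5)
        trace = run_inference(to_stream(nine_fixtures[4]), templates, params)
        np.testing.assert_allclose(trace.priors[1:], 0.5, atol=1e-12)

    @given(p_switch=st.floats(0.01, 0.49), start=probability)
    @settings(max_examples=25)
    def test_uninformative_evidence_drifts_to_half(self, p_switch, start):
        """With lam_m == lam_u the prior contracts to 0.5 at rate 1-2p."""
        T = 20
        params = ModelParams(p_switch=p_switch, initial_prior=start)
        trace = filter_observations(
            np.zeros(T, dtype=int), np.full(T, 0.3), 0.3, params
        )
        gaps = trace.priors - 0.5
        expected = (start - 0.5) * (1 - 2 * p_switch) ** np.arange(T)
        np.testing.assert_allclose(gaps, expected, atol=1e-10)

    def test_low_complexity_posterior_locks_onto_meter(self, templates, default_params, nine_fixtures):
        """A simple rhythm drives belief to the metered template quickly."""
        trace = run_inference(to_stream(nine_fixtures[0]), templates, default_params)
        assert np.max(trace.posteriors[:32]) > 0.9
        assert np.all(trace.posteriors[32:] > 0.8)

    def test_empty_stream_rejected(self, templates, default_params):
        with pytest.raises(ValueError):
            run_inference(np.array([], dtype=int), templates, default_params)


# ---------------------------------------------------------------------------
# delta surprisal
# ---------------------------------------------------------------------------

class TestDeltaSurprisal:
    def test_zero_when_quarters_already_present(self, templates, default_params):
        rhythm = RhythmPattern.from_positions([0, 8, 16, 24, 4])
        assert delta_surprisal(rhythm, templates, default_params) == 0.0

    def test_flat_template_closed_form(self, default_params):
        """At contrast 0, delta reduces to a counting formula (and is negative)."""
        pair = build_templates(contrast=0.0)
        lam = pair.unmetered
        rhythm = RhythmPattern.from_positions([0, 3, 15, 19, 31])
        k = sum(1 for p in QUARTER_POSITIONS if not rhythm.onsets[p]) * rhythm.repeats
        T = GRID * rhythm.repeats
        params = ModelParams(p_switch=0.01, contrast=0.0)
        expected = (k / T) * (np.log(lam) - np.log(1 - lam))
        assert delta_surprisal(rhythm, pair, params) == pytest.approx(expected, abs=1e-12)
        assert expected < 0

    def test_inverted_u_over_fixture_groups(self, templates, default_params, nine_fixtures):
        """Medium-complexity rhythms gain most from the metronome."""
        by_label = {}
        for f in nine_fixtures:
            by_label.setdefault(f.label, []).append(
                delta_surprisal(f, templates, default_params)
            )
        means = {k: np.mean(v) for k, v in by_label.items()}
        assert means["medium"] > means["low"] > means["high"]


class TestParameterSweep:
    def test_grid_cardinality(self, nine_fixtures):
        grid = parameter_sweep(nine_fixtures)
        assert len(grid) == 9 * 4 * 4
        assert grid["delta_surprisal"].notna().all()

    def test_delta_equals_plain_minus_metronome(self, nine_fixtures):
        grid = parameter_sweep(nine_fixtures, (0.01,), (1.0,))
        np.testing.assert_allclose(
            grid["delta_surprisal"],
            grid["mean_surprisal_plain"] - grid["mean_surprisal_metronome"],
        )

    def test_raising_p_switch_flattens_delta(self, nine_fixtures):
        grid = parameter_sweep(nine_fixtures, (0.01, 0.3), (1.0,))
        ranges = grid.groupby("p_switch")["delta_surprisal"].agg(np.ptp)
        assert ranges[0.3] < ranges[0.01]

    def test_lowering_contrast_flattens_and_lowers_delta(self, nine_fixtures):
        grid = parameter_sweep(nine_fixtures, (0.01,), (0.1, 1.0))
        by_c = grid.groupby("contrast")["delta_surprisal"]
        assert by_c.agg(np.ptp)[0.1] < by_c.agg(np.ptp)[1.0]
        assert by_c.mean()[0.1] < by_c.mean()[1.0]

    def test_empty_grid_rejected(self, nine_fixtures):
        with pytest.raises(ValueError):
            parameter_sweep(nine_fixtures, (), (1.0,))
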