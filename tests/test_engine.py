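"""Mixture engine: weight dynamics, the three compression modes, and
equality between the fast kernel and the stepwise python engine."""

import numpy as np
import pytest

import nrcomp as nr
from nrcomp import MixtureConfig, ModelSpec
from nrcomp.engine import EngineState, engine_init, update_weights

from oracles import brute_adaptive_code_length


class TestConfigValidation:
    def test_requires_models(self):
        with pytest.raises(ValueError):
            MixtureConfig(models=())

    def test_gamma_range(self):
        with pytest.raises(ValueError):
            MixtureConfig(models=(ModelSpec(3, 1.0),), gamma=1.0)

    def test_tolerant_model_needs_same_depth_plain(self):
        with pytest.raises(ValueError, match="same-depth"):
            MixtureConfig(models=(ModelSpec(5, 0.1, tolerance=2), ModelSpec(3, 1.0)))

    def test_initial_weights_uniform(self):
        st5 = engine_init(MixtureConfig(models=tuple(ModelSpec(k, 1.0) for k in (1, 2, 3, 4, 5))))
        assert np.allclose(st5.weights, 0.2)
        st1 = engine_init(MixtureConfig(models=(ModelSpec(2, 1.0),)))
        assert st1.weights.tolist() == [1.0]


class TestWeightUpdate:
    def test_hand_computed_forgetting_update(self):
        # w = (.5, .5), gamma = .95, P = (.9, .25):
        # .5**.95 = .517947...; normalize (.466152, .129487)
        w = update_weights(np.array([0.5, 0.5]), np.array([0.9, 0.25]), 0.95)
        assert w[0] == pytest.approx(0.78261, abs=1e-4)
        assert w[1] == pytest.approx(0.21739, abs=1e-4)

    def test_gamma_zero_forgets_everything(self):
        w = update_weights(np.array([0.5, 0.5]), np.array([0.9, 0.1]), 0.0)
        assert np.allclose(w, [0.9, 0.1])

    def test_weights_stay_normalized_and_floored(self):
        w = np.array([1e-30, 1.0 - 1e-30])
        w2 = update_weights(w, np.array([0.25, 0.25]), 0.95)
        assert w2.sum() == pytest.approx(1.0, abs=1e-12)
        # floored before the final renormalization: no model ever dies
        assert w2.min() >= 0.99e-12


class TestStep:
    def test_first_symbol_of_fresh_model_costs_two_bits(self):
        st = engine_init(MixtureConfig(models=(ModelSpec(1, 1.0),)))
        assert st.step(2) == pytest.approx(2.0)

    def test_rejects_bad_symbol(self):
        st = engine_init(MixtureConfig(models=(ModelSpec(1, 1.0),)))
        with pytest.raises(ValueError):
            st.step(4)


class TestKernelEqualsStepwiseEngine:
    def test_reference_free_profiles_identical(self, small_mixture):
        x = nr.generate_repeat_rich(1500, 3, 300, 0.02, 9)
        fast = nr.compress(x, small_mixture)
        st = EngineState(small_mixture, expected_symbols=len(x))
        slow = st.run(x.symbols)
        assert np.max(np.abs(slow - fast.profile)) < 1e-9
        assert fast.total_bits == pytest.approx(slow.sum(), abs=1e-6)

    def test_relative_mode_profiles_identical(self, small_mixture):
        y = nr.generate_random(1200, 3)
        x = nr.mutate_substitutions(y, 0.05, 4)
        fast = nr.compress_relative(x, y, small_mixture)
        st = EngineState(small_mixture, expected_symbols=len(y))
        st.run(y.symbols)              # training pass (bits discarded)
        st.freeze().reset_coding_state()
        slow = st.run(x.symbols)
        assert np.max(np.abs(slow - fast.profile)) < 1e-9


class TestCompress:
    def test_single_model_equals_brute_force_adaptive_coder(self):
        x = nr.generate_random(4000, 17)
        cfg = MixtureConfig(models=(ModelSpec(3, 0.5),))
        got = nr.compress(x, cfg).total_bits
        expected = brute_adaptive_code_length(x.symbols, 3, 0.5)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_periodic_input_becomes_nearly_free(self):
        x = np.tile(np.arange(4, dtype=np.int8), 25_000)
        cfg = MixtureConfig(models=(ModelSpec(8, 1.0),))
        prof = nr.compress(x, cfg).profile
        assert prof[-50_000:].mean() < 0.05

    def test_total_is_profile_sum_and_length_matches(self, small_mixture):
        x = nr.generate_random(3000, 2)
        res = nr.compress(x, small_mixture)
        assert len(res) == 3000
        assert res.total_bits == pytest.approx(res.profile.sum(), abs=1e-6)
        assert res.mode == "reference-free"

    def test_empty_input_rejected(self, small_mixture):
        with pytest.raises(ValueError):
            nr.compress(np.empty(0, np.int8), small_mixture)

    def test_duplicate_model_copies_share_weight_and_barely_matter(self):
        # identical copies always hold identical weights; the blend shifts
        # only through the extra share of mixture mass the duplicate holds,
        # which perturbs the total code length marginally
        x = nr.generate_random(5000, 21)
        base = MixtureConfig(models=(ModelSpec(6, 1.0), ModelSpec(2, 1.0)), gamma=0.9)
        doubled = MixtureConfig(
            models=(ModelSpec(6, 1.0), ModelSpec(6, 1.0), ModelSpec(2, 1.0)),
            gamma=0.9)
        a = nr.compress(x, base)
        b = nr.compress(x, doubled)
        w = b.diagnostics["final_weights"]
        assert w[0] == pytest.approx(w[1], rel=1e-12)
        assert b.total_bits == pytest.approx(a.total_bits, rel=0.01)

    def test_probability_and_weight_normalization(self, small_mixture):
        x = nr.generate_repeat_rich(20_000, 4, 2000, 0.05, 3)
        res = nr.compress(x, small_mixture)
        assert res.diagnostics["max_prob_sum_error"] < 1e-9
        assert res.diagnostics["max_weight_sum_error"] < 1e-12


class TestConjoint:
    def test_profile_covers_concatenation_with_boundary(self, small_mixture):
        x = nr.generate_random(1000, 1)
        y = nr.generate_random(1500, 2)
        res = nr.compress_conjoint(x, y, small_mixture)
        assert len(res) == 2500
        assert res.boundary == 1500
        assert res.mode == "conjoint"

    def test_second_copy_is_nearly_free(self):
        cfg = nr.preset("synthetic-ref-free")
        x = nr.generate_random(50_000, 7)
        res = nr.compress_conjoint(x, x, cfg)
        first = res.profile[: res.boundary].mean()
        second = res.profile[res.boundary :].mean()
        assert second < 0.2 < 1.8 < first

    def test_independent_halves_cost_the_sum_of_parts(self):
        cfg = nr.preset("synthetic-ref-free")
        x = nr.generate_random(50_000, 8)
        y = nr.generate_random(50_000, 9)
        total = nr.compress_conjoint(x, y, cfg).total_bits
        parts = nr.compress(x, cfg).total_bits + nr.compress(y, cfg).total_bits
        assert total == pytest.approx(parts, rel=0.02)


class TestRelative:
    def test_self_description_is_cheap(self):
        cfg = nr.preset("synthetic-relative")
        y = nr.generate_random(30_000, 5)
        res = nr.compress_relative(y, y, cfg)
        assert res.bits_per_symbol < 0.2
        assert res.mode == "relative"

    def test_repeated_calls_bit_identical_and_stateless(self, small_mixture):
        y = nr.generate_random(8000, 11)
        x = nr.mutate_substitutions(y, 0.03, 12)
        z = nr.generate_random(8000, 13)
        ref = nr.train_reference(y, small_mixture)
        a = ref.code(x)
        ref.code(z)  # unrelated work must not disturb later calls
        b = ref.code(x)
        assert np.array_equal(a.profile, b.profile)
        fresh = nr.compress_relative(x, y, small_mixture)
        assert np.array_equal(a.profile, fresh.profile)

    def test_intra_target_repeat_stays_expensive(self):
        # a block repeated inside x but absent from y is charged full price
        # per copy by the frozen-reference coder, unlike reference-free mode
        cfg_rel = nr.preset("synthetic-relative")
        cfg_free = nr.preset("synthetic-ref-free")
        g = nr.generate_random(10_000, 31).symbols
        x = np.concatenate([g, g])
        y = nr.generate_random(20_000, 32)
        rel = nr.compress_relative(x, y, cfg_rel)
        free = nr.compress(x, cfg_free)
        second_half = slice(10_000, 20_000)
        assert rel.profile[second_half].mean() > 1.8
        assert free.profile[second_half].mean() < 0.2
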