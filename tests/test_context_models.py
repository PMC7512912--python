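"""Context-model memories: smoothed prediction, inverted-repeat updates,
cache-hash eviction, freezing, and the tolerant-model state machine."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nrcomp import (FrozenMemoryError, ModelMemory, ModelSpec, TolerantState,
                    cm_predict, cm_update, encode, freeze, stcm_step)

from oracles import brute_window_counts


def train_on(memory: ModelMemory, text: str) -> ModelMemory:
    syms = encode(text).symbols
    k = memory.depth
    for i in range(len(syms) - k):
        memory.update(syms[i : i + k + 1])
    return memory


class TestPrediction:
    def test_empty_counts_fall_back_to_uniform(self):
        mem = ModelMemory(depth=3)
        assert np.allclose(cm_predict(mem, "ACG", alpha=1.0), 0.25)

    def test_order1_counts_on_AACA(self):
        # windows AA, AC, CA -> context A holds {A:1, C:1}
        mem = train_on(ModelMemory(depth=1), "AACA")
        assert list(mem.counts("A")) == [1, 1, 0, 0]
        pv = cm_predict(mem, "A", alpha=1.0)
        assert pv[0] == pytest.approx(2 / 6)
        assert pv[1] == pytest.approx(2 / 6)
        assert pv[2] == pv[3] == pytest.approx(1 / 6)

    def test_small_alpha_concentrates_on_observed_symbol(self):
        mem = ModelMemory(depth=2)
        for _ in range(1000):
            mem.update("ACA")
        pv = cm_predict(mem, "AC", alpha=0.002)
        assert pv[0] == pytest.approx(1000.002 / 1000.008)

    def test_invalid_alpha_rejected(self):
        mem = ModelMemory(depth=2)
        with pytest.raises(ValueError):
            cm_predict(mem, "AC", alpha=0.0)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=60),
           st.sampled_from([0.002, 0.1, 1.0]))
    def test_prediction_is_a_distribution(self, text, alpha):
        mem = train_on(ModelMemory(depth=2), text)
        ctx = text[:2]
        assert cm_predict(mem, ctx, alpha).sum() == pytest.approx(1.0, abs=1e-12)


class TestUpdates:
    def test_window_increments_context_symbol(self):
        mem = ModelMemory(depth=2)
        cm_update(mem, "ACG")
        assert list(mem.counts("AC")) == [0, 0, 1, 0]

    def test_inverted_repeats_also_count_rc_window(self):
        # rc("ACG") = "CGT": context CG gains symbol T
        mem = ModelMemory(depth=2, inverted_repeats=True)
        cm_update(mem, "ACG")
        assert list(mem.counts("AC")) == [0, 0, 1, 0]
        assert list(mem.counts("CG")) == [0, 0, 0, 1]

    def test_counts_equal_brute_force_window_counts(self):
        rng = np.random.default_rng(4)
        syms = rng.integers(0, 4, 3000, dtype=np.int8)
        for k in (1, 3, 13):  # dense and hashed storage
            mem = ModelMemory(depth=k, expected_contexts=4000)
            for i in range(len(syms) - k):
                mem.update(syms[i : i + k + 1])
            expected = brute_window_counts(syms, k)
            assert mem.total_count_mass() == sum(expected.values())
            for window, n in list(expected.items())[:200]:
                assert mem.counts(np.array(window[:-1]))[window[-1]] == n

    def test_ir_doubles_total_count_mass(self):
        rng = np.random.default_rng(5)
        syms = rng.integers(0, 4, 500, dtype=np.int8)
        mem = ModelMemory(depth=2, inverted_repeats=True)
        n_windows = len(syms) - 2
        for i in range(n_windows):
            mem.update(syms[i : i + 3])
        assert mem.total_count_mass() == 2 * n_windows


class TestCacheHash:
    def test_bucket_keeps_only_latest_entry_when_full(self):
        mem = ModelMemory(depth=13, cache_bound=1, expected_contexts=32)
        # find two distinct contexts landing in the same bucket
        first = 12345
        second = next(
            c for c in range(first + 1, first + 200_000)
            if mem.bucket_of(c) == mem.bucket_of(first)
        )
        ctx = lambda code: np.array(
            [(code >> (2 * (12 - j))) & 3 for j in range(13)], dtype=np.int8)
        mem.update(np.append(ctx(first), 2))
        assert mem.counts(first)[2] == 1
        mem.update(np.append(ctx(second), 1))
        assert mem.counts(second)[1] == 1   # newer context retained
        assert mem.counts(first).sum() == 0  # older one evicted

    def test_occupancy_never_exceeds_bucket_capacity(self):
        mem = ModelMemory(depth=13, cache_bound=2, expected_contexts=64)
        rng = np.random.default_rng(0)
        for _ in range(3000):
            mem.update(rng.integers(0, 4, 14, dtype=np.int8))
        fills = mem.hbfill
        assert fills.max() <= 2
        assert mem.n_contexts() == int(fills.sum())


class TestFreeze:
    def test_frozen_memory_rejects_updates(self):
        mem = train_on(ModelMemory(depth=2), "ACGTACGT")
        freeze(mem)
        with pytest.raises(FrozenMemoryError):
            cm_update(mem, "ACG")

    def test_freeze_preserves_predictions_and_is_idempotent(self):
        mem = train_on(ModelMemory(depth=2), "ACGTAACC")
        before = cm_predict(mem, "AC", 0.5)
        mass = mem.total_count_mass()
        freeze(freeze(mem))
        assert np.array_equal(before, cm_predict(mem, "AC", 0.5))
        assert mem.total_count_mass() == mass

    def test_frozen_empty_memory_predicts_uniform(self):
        mem = freeze(ModelMemory(depth=4))
        assert np.allclose(cm_predict(mem, "ACGT", 1.0), 0.25)


class TestTolerantModel:
    def _shared_always_A(self):
        mem = ModelMemory(depth=2)
        for _ in range(5):
            mem.update("ACA")  # wrong ctx; ensure ctx CA -> A dominates
            mem.update("CAA")
        return mem

    def test_hit_appends_true_symbol(self):
        shared = self._shared_always_A()
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=2)
        state = TolerantState(history=encode("CA").symbols)
        _, new = stcm_step(state, shared, spec, true_symbol=0, true_past="AA")
        assert list(new.history) == [0, 0]  # "AA": A appended
        assert new.miss_count == 0

    def test_miss_appends_predicted_symbol(self):
        shared = self._shared_always_A()
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=2)
        state = TolerantState(history=encode("CA").symbols)
        _, new = stcm_step(state, shared, spec, true_symbol=1, true_past="AC")
        assert list(new.history) == [0, 0]  # prediction A substituted in
        assert new.miss_count == 1

    def test_exceeding_tolerance_resets_to_true_past(self):
        shared = self._shared_always_A()
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=1)
        state = TolerantState(history=encode("CA").symbols)
        _, state = stcm_step(state, shared, spec, 1, true_past="AC")
        assert state.miss_count == 1
        # second consecutive miss exceeds tolerance=1 -> reset
        _, state = stcm_step(state, shared, spec, 2, true_past="CG")
        assert list(state.history) == list(encode("CG").symbols)
        assert state.miss_count == 0

    def test_requires_positive_tolerance(self):
        shared = ModelMemory(depth=2)
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=0)
        with pytest.raises(ValueError):
            stcm_step(TolerantState(np.zeros(2, np.int8)), shared, spec, 0, "AA")

    def test_never_resets_on_perfectly_predictable_source(self):
        period = encode("ACGT").symbols
        mem = ModelMemory(depth=2)
        syms = np.tile(period, 50)
        for i in range(len(syms) - 2):
            mem.update(syms[i : i + 3])
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=1)
        state = TolerantState(history=syms[:2])
        for i in range(2, 100):
            s = int(syms[i % len(syms)])
            _, state = stcm_step(state, mem, spec, s, syms[i - 1 : i + 1])
            assert state.miss_count == 0

    def test_resets_regularly_on_uniform_random_input(self):
        rng = np.random.default_rng(12)
        syms = rng.integers(0, 4, 400, dtype=np.int8)
        mem = train_on(ModelMemory(depth=2), "ACGTAACCGGTT" * 4)
        spec = ModelSpec(depth=2, alpha=0.1, tolerance=1)
        state = TolerantState(history=syms[:2])
        resets = 0
        misses = state.miss_count
        for i in range(2, len(syms)):
            prev = state.miss_count
            _, state = stcm_step(state, mem, spec, int(syms[i]), syms[i - 1 : i + 1])
            if prev > 0 and state.miss_count == 0:
                resets += 1
        # ~3/4 miss rate with tolerance 1 -> a reset every few symbols
        assert resets > 50
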