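"""Finite-context models: count memories, alpha-smoothed prediction,
inverted-repeat updates, cache-hash bounding, freezing, and the
substitution-tolerant context model state machine.

An order-``k`` context model predicts the next nucleotide from smoothed
counts of the ``k``-mer it follows:

    P(s | c) = (n_s(c) + alpha) / (sum_s' n_s'(c) + 4 * alpha)

``alpha`` interpolates between the empirical frequency distribution
(alpha -> 0) and the uniform distribution (alpha -> inf).  Deep models use a
small alpha so that a single observed continuation dominates quickly.

A substitution-tolerant model (tolerance t > 0) shares the count memory of
the same-depth plain model but keeps a *private* context history: on a
misprediction it substitutes its own most probable symbol into that history,
tolerating up to ``t`` such substitutions before resetting the history to
the true past.  This lets a deep context survive isolated substitutions
that would otherwise destroy it for ``k`` symbols.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

from . import _kernel
from ._kernel import next_pow2
from .sequence import as_symbols

#: models at or below this depth store counts densely (4**k rows)
DENSE_MAX_DEPTH = 11


class FrozenMemoryError(RuntimeError):
    """Raised on any attempt to mutate a frozen model memory."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Parameters of one context model.

    ``tolerance == 0`` means a plain context model; ``tolerance > 0`` marks a
    substitution-tolerant model that shares the memory of the same-depth
    plain model in a mixture.
    """

    depth: int
    alpha: float
    inverted_repeats: bool = False
    tolerance: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


def kmer_code(kmer: Union[str, np.ndarray, list]) -> int:
    """Pack a k-mer (string or codes) into its 2-bit integer code."""
    arr = as_symbols(kmer)
    code = 0
    for s in arr:
        code = (code << 2) | int(s)
    return code


class ModelMemory:
    """A context -> symbol-count store for one model depth.

    Parameters
    ----------
    depth:
        Context order k.
    inverted_repeats:
        If set, every update additionally counts the reverse complement of
        the (k+1)-mer window.
    cache_bound:
        Cache-hash bucket capacity B.  0 means unbounded.  The bound applies
        to hashed storage (depths above :data:`DENSE_MAX_DEPTH`); dense
        tables address every context directly and never evict.
    expected_contexts:
        Sizing hint for hashed storage (roughly the number of distinct
        contexts the store will see).
    """

    def __init__(self, depth: int, inverted_repeats: bool = False,
                 cache_bound: int = 0, expected_contexts: int = 1 << 12):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if cache_bound < 0:
            raise ValueError("cache_bound must be >= 0")
        self.depth = int(depth)
        self.inverted_repeats = bool(inverted_repeats)
        self.cache_bound = int(cache_bound)
        self.frozen = False
        self.mask = (1 << (2 * depth)) - 1
        nctx = min(4 ** depth, max(int(expected_contexts), 1))

        # single-store buffers in the kernel layout (offsets of length 1)
        self.doff = np.zeros(1, np.int64)
        self.hoff = np.zeros(1, np.int64)
        self.hboff = np.zeros(1, np.int64)
        self.hctr = np.zeros(1, np.int64)
        if depth <= DENSE_MAX_DEPTH:
            self.kind = 0
            self.dbuf = np.zeros(4 ** depth * 4, np.int32)
            self.hkeys = np.empty(0, np.int64)
            self.hcnt = np.empty(0, np.int32)
            self.hage = np.empty(0, np.int64)
            self.hbfill = np.empty(0, np.int64)
            self.hnb = np.zeros(1, np.int64)
            self.hB = np.zeros(1, np.int64)
            self.hcap = np.zeros(1, np.int64)
        elif cache_bound == 0:
            self.kind = 1
            cap = next_pow2(2 * nctx + 64)
            self.dbuf = np.empty(0, np.int32)
            self.hkeys = np.full(cap, -1, np.int64)
            self.hcnt = np.zeros(cap * 4, np.int32)
            self.hage = np.empty(0, np.int64)
            self.hbfill = np.empty(0, np.int64)
            self.hnb = np.zeros(1, np.int64)
            self.hB = np.zeros(1, np.int64)
            self.hcap = np.array([cap], np.int64)
        else:
            self.kind = 2
            B = cache_bound
            nbuckets = next_pow2(max(16, (3 * nctx) // B + 1))
            slots = nbuckets * B
            self.dbuf = np.empty(0, np.int32)
            self.hkeys = np.full(slots, -1, np.int64)
            self.hcnt = np.zeros(slots * 4, np.int32)
            self.hage = np.zeros(slots, np.int64)
            self.hbfill = np.zeros(nbuckets, np.int64)
            self.hnb = np.array([nbuckets], np.int64)
            self.hB = np.array([B], np.int64)
            self.hcap = np.array([slots], np.int64)

    # -- queries ----------------------------------------------------------

    def counts(self, context) -> np.ndarray:
        """The four stored counts for a context (zeros if absent)."""
        code = self._code(context)
        c = _kernel.mem_fetch(self.kind, code, self.dbuf, self.doff,
                              self.hkeys, self.hcnt, self.hoff,
                              self.hnb, self.hB, self.hcap)
        return np.array(c, dtype=np.int64)

    def predict(self, context, alpha: float) -> np.ndarray:
        """Alpha-smoothed probability 4-vector for the next symbol."""
        if not (alpha > 0):
            raise ValueError("alpha must be > 0")
        c = self.counts(context).astype(np.float64)
        return (c + alpha) / (c.sum() + 4.0 * alpha)

    def total_count_mass(self) -> int:
        """Sum of all stored counts (across every context)."""
        if self.kind == 0:
            return int(self.dbuf.sum())
        live = self.hkeys != -1
        return int(self.hcnt.reshape(-1, 4)[live].sum())

    def n_contexts(self) -> int:
        """Number of distinct contexts currently stored."""
        if self.kind == 0:
            return int((self.dbuf.reshape(-1, 4).sum(axis=1) > 0).sum())
        return int((self.hkeys != -1).sum())

    # -- mutation ---------------------------------------------------------

    def update(self, window) -> "ModelMemory":
        """Count one (k+1)-mer window: context = first k symbols, symbol =
        the last; with inverted repeats, also count the reverse-complement
        window.  Raises :class:`FrozenMemoryError` when frozen."""
        if self.frozen:
            raise FrozenMemoryError("cannot update a frozen model memory")
        arr = as_symbols(window)
        if arr.size != self.depth + 1:
            raise ValueError(f"window must have length depth+1 = {self.depth + 1}")
        ctx = kmer_code(arr[:-1])
        self._incr(ctx, int(arr[-1]))
        if self.inverted_repeats:
            rc_ctx = kmer_code(3 - arr[1:][::-1])
            self._incr(rc_ctx, int(3 - arr[0]))
        return self

    def freeze(self) -> "ModelMemory":
        """Mark the memory static; idempotent, counts untouched."""
        self.frozen = True
        return self

    # -- internals --------------------------------------------------------

    def _code(self, context) -> int:
        if isinstance(context, (int, np.integer)):
            return int(context)
        arr = as_symbols(context)
        if arr.size != self.depth:
            raise ValueError(f"context must have length depth = {self.depth}")
        return kmer_code(arr)

    def _incr(self, ctx: int, sym: int) -> None:
        _kernel.mem_incr(self.kind, ctx, sym, self.dbuf, self.doff,
                         self.hkeys, self.hcnt, self.hage, self.hbfill,
                         self.hctr, self.hoff, self.hboff,
                         self.hnb, self.hB, self.hcap)

    def bucket_of(self, context) -> int:
        """Cache-hash bucket index of a context (hashed stores only)."""
        if self.kind == 0:
            raise ValueError("dense stores have no buckets")
        h = int(_kernel._mix64(self._code(context)))
        if self.kind == 1:
            return h & (int(self.hcap[0]) - 1)
        return h & (int(self.hnb[0]) - 1)


# -- functional operation aliases ----------------------------------------


def cm_predict(memory: ModelMemory, context, alpha: float) -> np.ndarray:
    """Probability 4-vector for the next symbol after ``context``."""
    return memory.predict(context, alpha)


def cm_update(memory: ModelMemory, window) -> ModelMemory:
    """Count one (k+1)-mer window (and its reverse complement if enabled)."""
    return memory.update(window)


def freeze(memory: ModelMemory) -> ModelMemory:
    """Set the memory static: predictions stay available, updates error."""
    return memory.freeze()


@dataclasses.dataclass(frozen=True)
class TolerantState:
    """Private state of a substitution-tolerant context model.

    ``history`` holds the last k symbols as the model believes them (it may
    differ from the true past by up to ``miss_count`` substituted symbols).
    """

    history: np.ndarray
    miss_count: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.history, dtype=np.int8).copy()
        arr.setflags(write=False)
        object.__setattr__(self, "history", arr)
        if self.miss_count < 0:
            raise ValueError("miss_count must be >= 0")


def stcm_step(state: TolerantState, shared: ModelMemory, spec: ModelSpec,
              true_symbol: int, true_past) -> tuple[np.ndarray, TolerantState]:
    """Advance a substitution-tolerant model by one symbol.

    Predicts from the private history using the shared (same-depth plain
    model) memory and the tolerant spec's alpha.  If the true symbol equals
    the prediction argmax (ties broken A < C < G < T) it is appended to the
    history; otherwise the *predicted* symbol is appended and the miss
    counter increments.  Exceeding the tolerance resets the history to
    ``true_past`` (the last k true symbols, current symbol included) and
    zeroes the counter.
    """
    if spec.tolerance <= 0:
        raise ValueError("stcm_step requires a tolerant spec (tolerance > 0)")
    if shared.depth != spec.depth:
        raise ValueError("shared memory depth must match the tolerant spec depth")
    hist = np.asarray(state.history, dtype=np.int8)
    if hist.size != spec.depth:
        raise ValueError("history length must equal the model depth")
    pvec = shared.predict(hist, spec.alpha)
    am = int(np.argmax(pvec))  # first max == lowest symbol on ties
    sym = int(true_symbol)
    if sym == am:
        new_hist = np.concatenate([hist[1:], [sym]])
        new_miss = state.miss_count
    else:
        new_hist = np.concatenate([hist[1:], [am]])
        new_miss = state.miss_count + 1
        if new_miss > spec.tolerance:
            tp = as_symbols(true_past)
            if tp.size != spec.depth:
                raise ValueError("true_past length must equal the model depth")
            new_hist = tp
            new_miss = 0
    return pvec, TolerantState(history=new_hist.astype(np.int8), miss_count=new_miss)
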