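"""Soft-blended mixture of context models producing per-symbol code lengths.

The coder blends the predictions of several context models (plain and
substitution-tolerant) with performance-tracked weights:

    P(x_i) = sum_m  w_m * P_m(x_i | context_m),
    w_m   <-  normalize( w_m ** gamma * P_m(x_i) ),

where ``gamma`` in [0, 1) is a forgetting factor: it decays the influence of
old performance so the mixture can shift mass to whichever model currently
predicts best.  Mixing uses the weights as they stood *before* observing the
symbol — the causal (decodable) resolution.  The per-symbol ideal code
length is ``-log2 P(x_i)``; no bitstream is emitted, compression is used
purely as a measurement device.

Three modes are provided:

* :func:`compress` — C(x): adaptive pass over x, counts start at zero.
* :func:`compress_conjoint` — C(yx): one adaptive pass over the
  concatenation, reference first.
* :func:`compress_relative` — C(x||y): counts are trained on y, the
  memories are frozen ("set static"), weights restart uniform, and x is
  coded read-only.  Only the weights and the tolerant private histories
  adapt during the coding of x.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence as TypingSequence, Union

import numpy as np

from . import _kernel
from ._kernel import next_pow2
from .models import DENSE_MAX_DEPTH, ModelMemory, ModelSpec, TolerantState, stcm_step
from .sequence import Sequence, as_symbols


@dataclasses.dataclass(frozen=True)
class MixtureConfig:
    """Full parameterization of a model mixture.

    ``gamma`` is shared by every model (per-model tuning yields only
    marginal gains).  ``cache_hash`` bounds the per-bucket entry count of
    hashed (deep) model memories; 0 disables the bound.
    """

    models: tuple
    gamma: float = 0.95
    cache_hash: int = 0

    def __post_init__(self) -> None:
        models = tuple(self.models)
        object.__setattr__(self, "models", models)
        if not models:
            raise ValueError("a mixture needs at least one model")
        if not all(isinstance(m, ModelSpec) for m in models):
            raise TypeError("models must be ModelSpec instances")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if self.cache_hash < 0:
            raise ValueError("cache_hash must be >= 0")
        plain_depths = {m.depth for m in models if m.tolerance == 0}
        for m in models:
            if m.tolerance > 0 and m.depth not in plain_depths:
                raise ValueError(
                    f"tolerant model of depth {m.depth} has no same-depth plain model"
                )

    @property
    def max_depth(self) -> int:
        return max(m.depth for m in self.models)


@dataclasses.dataclass
class CompressionResult:
    """Bit totals and the per-symbol information profile of one coding pass."""

    total_bits: float
    profile: np.ndarray
    mode: str
    config: MixtureConfig
    boundary: Optional[int] = None  # conjoint mode: index where x starts
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.profile.size)

    @property
    def bits_per_symbol(self) -> float:
        return self.total_bits / max(self.profile.size, 1)


# ---------------------------------------------------------------------------
# flat store assembly for the kernels


class _Stores:
    """Flat count-store buffers for every plain model of a mixture."""

    def __init__(self, config: MixtureConfig, expected_symbols: int):
        specs = config.models
        M = len(specs)
        self.config = config
        self.kmax = config.max_depth
        self.ks = np.array([m.depth for m in specs], np.int64)
        self.alphas = np.array([m.alpha for m in specs], np.float64)
        self.irs = np.array([1 if m.inverted_repeats else 0 for m in specs], np.int64)
        self.tols = np.array([m.tolerance for m in specs], np.int64)
        self.masks = np.array([(1 << (2 * m.depth)) - 1 for m in specs], np.int64)
        self.kinds = np.zeros(M, np.int64)
        self.sids = np.zeros(M, np.int64)
        self.pairs = np.arange(M, dtype=np.int64)

        first_plain = {}
        for i, m in enumerate(specs):
            if m.tolerance == 0 and m.depth not in first_plain:
                first_plain[m.depth] = i

        dsizes: list[int] = []
        hspecs: list[tuple[int, int, int, int]] = []  # (kind, cap_slots, nbuckets, B)
        for i, m in enumerate(specs):
            if m.tolerance > 0:
                p = first_plain[m.depth]
                self.pairs[i] = p
                continue
            nctx = min(4 ** m.depth, expected_symbols + 1)
            if m.depth <= DENSE_MAX_DEPTH:
                self.kinds[i] = 0
                self.sids[i] = len(dsizes)
                dsizes.append(4 ** m.depth * 4)
            elif config.cache_hash == 0:
                cap = next_pow2(2 * nctx + 64)
                self.kinds[i] = 1
                self.sids[i] = len(hspecs)
                hspecs.append((1, cap, 0, 1))
            else:
                B = config.cache_hash
                nbuckets = next_pow2(max(16, (3 * nctx) // B + 1))
                self.kinds[i] = 2
                self.sids[i] = len(hspecs)
                hspecs.append((2, nbuckets * B, nbuckets, B))
        # tolerant models borrow the paired plain model's store
        for i, m in enumerate(specs):
            if m.tolerance > 0:
                p = self.pairs[i]
                self.kinds[i] = self.kinds[p]
                self.sids[i] = self.sids[p]

        self.doff = np.zeros(max(len(dsizes), 1), np.int64)
        off = 0
        for j, sz in enumerate(dsizes):
            self.doff[j] = off
            off += sz
        self.dbuf = np.zeros(off, np.int32)

        nh = max(len(hspecs), 1)
        self.hoff = np.zeros(nh, np.int64)
        self.hboff = np.zeros(nh, np.int64)
        self.hnb = np.zeros(nh, np.int64)
        self.hB = np.ones(nh, np.int64)
        self.hcap = np.ones(nh, np.int64)
        self.hctr = np.zeros(nh, np.int64)
        soff = boff = 0
        for j, (kind, slots, nbuckets, B) in enumerate(hspecs):
            self.hoff[j] = soff
            self.hboff[j] = boff
            self.hnb[j] = nbuckets
            self.hB[j] = B
            self.hcap[j] = slots if kind == 1 else nbuckets * B
            soff += slots
            boff += nbuckets
        self.hkeys = np.full(soff, -1, np.int64)
        self.hcnt = np.zeros(soff * 4, np.int32)
        self.hage = np.zeros(soff, np.int64)
        self.hbfill = np.zeros(boff, np.int64)

    # -- passes -----------------------------------------------------------

    def _pad(self, symbols: np.ndarray) -> np.ndarray:
        out = np.zeros(symbols.size + self.kmax, np.int8)
        out[self.kmax:] = symbols
        return out

    def count(self, symbols: np.ndarray) -> None:
        """Training pass: plain-model count updates only (no coding)."""
        plain = self.tols == 0
        _kernel.count_pass(
            self._pad(symbols), self.kmax,
            self.ks[plain], self.irs[plain], self.kinds[plain], self.sids[plain],
            self.masks[plain],
            self.dbuf, self.doff, self.hkeys, self.hcnt, self.hage, self.hbfill,
            self.hctr, self.hoff, self.hboff, self.hnb, self.hB, self.hcap,
        )

    def code(self, symbols: np.ndarray, update: bool):
        """Coding pass; returns (profile, diagnostics)."""
        bits = np.empty(symbols.size, np.float64)
        w = np.full(len(self.config.models), 1.0 / len(self.config.models))
        total, perr, werr = _kernel.code_pass(
            self._pad(symbols), self.kmax,
            self.ks, self.alphas, self.irs, self.tols, self.pairs,
            self.kinds, self.sids, self.masks,
            self.dbuf, self.doff, self.hkeys, self.hcnt, self.hage, self.hbfill,
            self.hctr, self.hoff, self.hboff, self.hnb, self.hB, self.hcap,
            w, self.config.gamma, update, bits,
        )
        diags = {
            "max_prob_sum_error": float(perr),
            "max_weight_sum_error": float(werr),
            "final_weights": w,
        }
        return bits, diags


# ---------------------------------------------------------------------------
# public compression modes


def _symbols_nonempty(x, name: str) -> np.ndarray:
    arr = as_symbols(x)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def compress(x: Union[Sequence, np.ndarray], config: MixtureConfig) -> CompressionResult:
    """Reference-free compression C(x): one adaptive pass over x."""
    syms = _symbols_nonempty(x, "x")
    stores = _Stores(config, syms.size)
    bits, diags = stores.code(syms, update=True)
    return CompressionResult(float(bits.sum()), bits, "reference-free", config,
                             diagnostics=diags)


def compress_conjoint(x, y, config: MixtureConfig) -> CompressionResult:
    """Conjoint compression C(yx): one adaptive pass over y then x.

    The profile covers the full concatenation; ``boundary`` is the index
    where x starts (= len(y)).
    """
    xs = _symbols_nonempty(x, "x")
    ys = _symbols_nonempty(y, "y")
    cat = np.concatenate([ys, xs])
    stores = _Stores(config, cat.size)
    bits, diags = stores.code(cat, update=True)
    return CompressionResult(float(bits.sum()), bits, "conjoint", config,
                             boundary=int(ys.size), diagnostics=diags)


class ReferenceModel:
    """Frozen model memories trained on a reference sequence y.

    Repeated :meth:`code` calls are independent: the counts never change
    after training, and the mixture weights and tolerant histories restart
    fresh for every target.  Train once, measure many targets.
    """

    def __init__(self, y, config: MixtureConfig):
        ys = _symbols_nonempty(y, "y")
        self.config = config
        self.reference_length = int(ys.size)
        self._stores = _Stores(config, ys.size)
        self._stores.count(ys)

    def code(self, x) -> CompressionResult:
        """C(x||y): code x read-only against the frozen reference memory."""
        xs = _symbols_nonempty(x, "x")
        bits, diags = self._stores.code(xs, update=False)
        return CompressionResult(float(bits.sum()), bits, "relative", self.config,
                                 diagnostics=diags)


def train_reference(y, config: MixtureConfig) -> ReferenceModel:
    """Build the frozen memory of y once, for repeated relative coding."""
    return ReferenceModel(y, config)


def compress_relative(x, y, config: MixtureConfig) -> CompressionResult:
    """Relative compression C(x||y): train on y, freeze, code x read-only."""
    return ReferenceModel(y, config).code(x)


def update_weights(w: np.ndarray, pm: np.ndarray, gamma: float) -> np.ndarray:
    """One mixture weight update: ``w_m <- norm(w_m**gamma * P_m(symbol))``.

    After normalization the weights are floored at 1e-12 and renormalized so
    no model can die permanently under finite precision.
    """
    w2 = np.asarray(w, dtype=np.float64) ** gamma * np.asarray(pm, dtype=np.float64)
    w2 = w2 / w2.sum()
    w2 = np.maximum(w2, _kernel.WEIGHT_FLOOR)
    return w2 / w2.sum()


# ---------------------------------------------------------------------------
# step-by-step engine (pure python; mirrors the kernel exactly)


class EngineState:
    """Explicit, stepwise mixture state built on :class:`ModelMemory`.

    This is the slow, inspectable twin of the kernel used by
    :func:`compress`; the two are held equal by the test suite.  Contexts
    start padded with symbol A.
    """

    def __init__(self, config: MixtureConfig, expected_symbols: int = 1 << 12):
        self.config = config
        M = len(config.models)
        self.weights = np.full(M, 1.0 / M)
        self.position = 0
        self.memories: list[ModelMemory] = []
        self.tolerant: dict[int, TolerantState] = {}
        self._contexts: list[np.ndarray] = []
        first_plain: dict[int, ModelMemory] = {}
        plain_mems: dict[int, ModelMemory] = {}
        for i, spec in enumerate(config.models):
            if spec.tolerance == 0:
                cache = config.cache_hash if spec.depth > DENSE_MAX_DEPTH else 0
                mem = ModelMemory(spec.depth, spec.inverted_repeats, cache,
                                  expected_contexts=expected_symbols + 1)
                plain_mems[i] = mem
                if spec.depth not in first_plain:
                    first_plain[spec.depth] = mem
        for i, spec in enumerate(config.models):
            if spec.tolerance == 0:
                mem = plain_mems[i]
            else:
                mem = first_plain[spec.depth]
                self.tolerant[i] = TolerantState(np.zeros(spec.depth, np.int8))
            self.memories.append(mem)
            self._contexts.append(np.zeros(spec.depth + 1, np.int8))

    def freeze(self) -> "EngineState":
        for mem in self.memories:
            mem.freeze()
        return self

    def reset_coding_state(self) -> "EngineState":
        """Restart weights, contexts and tolerant histories (counts kept).

        This is the phase boundary of relative mode: after training on the
        reference and freezing, the coding of the target begins with uniform
        weights and an all-A padded past.
        """
        self.weights = np.full_like(self.weights, 1.0 / self.weights.size)
        self.position = 0
        for i, spec in enumerate(self.config.models):
            self._contexts[i] = np.zeros(spec.depth + 1, np.int8)
            if spec.tolerance > 0:
                self.tolerant[i] = TolerantState(np.zeros(spec.depth, np.int8))
        return self

    def step(self, symbol: int) -> float:
        """Code one symbol; returns its ideal code length in bits."""
        s = int(symbol)
        if s not in (0, 1, 2, 3):
            raise ValueError("symbol must be one of 0, 1, 2, 3")
        cfg = self.config
        M = len(cfg.models)
        pm = np.empty(M)
        pvecs: dict[int, np.ndarray] = {}
        for i, spec in enumerate(cfg.models):
            if spec.tolerance == 0:
                ctx = self._contexts[i][:-1]
                pv = self.memories[i].predict(ctx, spec.alpha)
            else:
                pv = self.memories[i].predict(self.tolerant[i].history, spec.alpha)
                pvecs[i] = pv
            pm[i] = pv[s]
        P = float(self.weights @ pm)
        bits = -np.log2(P)
        self.weights = update_weights(self.weights, pm, cfg.gamma)
        # tolerant private histories advance on the pre-update counts
        for i, spec in enumerate(cfg.models):
            if spec.tolerance == 0:
                continue
            true_past = self._contexts[i]
            true_past[-1] = s
            _, self.tolerant[i] = stcm_step(
                self.tolerant[i], self.memories[i], spec, s, true_past[1:])
            self._contexts[i] = np.concatenate([true_past[1:], [0]]).astype(np.int8)
        # memory updates and context advance for plain models
        updated = set()
        for i, spec in enumerate(cfg.models):
            if spec.tolerance > 0:
                continue
            window = self._contexts[i]
            window[-1] = s
            mem = self.memories[i]
            if not mem.frozen and id(mem) not in updated:
                mem.update(window)
                updated.add(id(mem))
            self._contexts[i] = np.concatenate([window[1:], [0]]).astype(np.int8)
        self.position += 1
        return float(bits)

    def run(self, symbols) -> np.ndarray:
        arr = as_symbols(symbols)
        return np.array([self.step(s) for s in arr])


def engine_init(config: MixtureConfig, expected_symbols: int = 1 << 12) -> EngineState:
    """Fresh engine: zero counts, uniform weights."""
    return EngineState(config, expected_symbols)
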