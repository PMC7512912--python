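# Methods

## The model

`nrcomp` treats a DNA sequence as a stream over {A, C, G, T} and measures
information with a sequential, adaptive coder.  The coder is a weighted
mixture of finite-context models (FCMs).  An order-`k` FCM stores, for
every `k`-mer context it has seen, four counters of the symbols that
followed, and predicts

    P(s | c) = (n_s(c) + α) / (Σ_s' n_s'(c) + 4α),

the Laplace-family estimator: `α` interpolates between the empirical
conditional frequencies (`α → 0`) and the uniform distribution
(`α → ∞`).  Deep models use small `α` so a single observed continuation
dominates quickly; shallow models use `α = 1` and act as robust
fallbacks.

The mixture blends the per-model predictions with weights tracking recent
performance:

    P(x_i) = Σ_m w_m,i · P_m(x_i),      w_m,i ∝ (w_m,i−1)^γ · P_m(x_i),

with a single forgetting factor `γ ∈ [0, 1)` shared by all models
(per-model tuning buys little).  The per-symbol information is
`−log₂ P(x_i)`; its sum is the code length `C(·)`.  No bitstream is
emitted — compression is used strictly as measurement, so the reported
bits are the ideal arithmetic-coding length.

Assumptions: the sequence is linear (no circularity handling), the
alphabet is exactly 4 symbols (non-ACGT input characters are replaced at
encoding time and recorded), and information is measured in bits against
the 2-bit-per-base ceiling.

### Substitution-tolerant models

A tolerant model (tolerance `t > 0`) shares the count memory of the
same-depth plain model but keeps a private context history.  At each step
it predicts from that history; if the true symbol differs from its most
probable symbol (ties broken A < C < G < T), it substitutes its *own
prediction* into the history and counts a miss.  After `t + 1` such
misses the history resets to the true past (current symbol included) and
the counter clears.  The effect is that a deep context survives isolated
substitutions which would otherwise invalidate it for `k` symbols — the
mechanism that keeps depth-17 models useful on sequences diverged by a
few percent.  The tolerant model never writes counts; its paired plain
model owns the memory.

### Inverted repeats

Models flagged for inverted repeats additionally count, for every
`(k+1)`-mer window, the reverse-complemented window (context
`rc(w₂…w_{k+1})`, symbol `complement(w₁)`).  This is an update-time
program only: prediction never queries the reverse-complement context.
With it, a repeat that appears reverse-complemented elsewhere in the
sequence is modelled at full depth.

### Memory layout and the cache-hash

Counts for depths ≤ 11 live in dense tables addressed directly by the
2-bit-packed context (4^k rows; at most 64 MB for depth 11).  Deeper
models hash the packed context (which is itself the exact key — 2k ≤ 40
bits) into either an open-addressing table sized so it cannot fill
(unbounded mode) or a *cache-hash*: buckets of `B` slots where, once a
bucket is full, the oldest entry (FIFO by insertion) is evicted, so each
bucket retains only its `B` most recent contexts.  Within a bucket,
probing starts at a second hash of the key, keeping lookups O(1) even at
`B = 250`.  The bound applies to hashed stores only; dense tables cannot
collide.  Bucket counts scale with the expected number of distinct
contexts, so at the sequence lengths this package targets eviction is a
rare event rather than the steady state.

## The three compression modes

* **Reference-free `C(x)`** — counts start at zero; one adaptive pass.
* **Conjoint `C(yx)`** — one adaptive pass over the concatenation,
  reference first; the result records the boundary so the profile can be
  split.  `C(x,y)` is approximated by `C(yx)` (the description needed to
  split a concatenation is asymptotically negligible).
* **Relative `C(x‖y)`** — a counting-only pass over `y` populates the
  memories; they are then frozen (any further update raises), the mixture
  weights restart uniform, and `x` is coded read-only.  Only the weights
  and the tolerant private histories adapt while coding `x`; repeated
  calls are therefore bit-identical and order-independent, and a
  reference can be trained once and reused against many targets
  (`train_reference` / `ReferenceModel.code`).

The measures are `NC(x) = C(x)/2|x|`,
`NCD(x,y) = (C(xy) − min{C(x),C(y)}) / max{C(x),C(y)}` (conjoint form,
the default; the conditional form uses the chain rule
`C(x|y) = C(yx) − C(y)` and clamps a negative conditional to zero,
flagging it), and `NRC(x‖y) = C(x‖y)/2|x|`.  The normalization constant
stays at 2 bits per symbol even when the input contained replaced
characters.

## Numerical and ordering choices

* **Causality.**  The weight-update recurrence, taken literally at index
  `i`, would need `P_m(x_i)` before coding `x_i`.  The only decodable
  reading — and the one implemented — mixes with the weights as they
  stood after symbol `i−1`, then updates them with the observed symbol.
* **Warm-up.**  The first `k` positions of every model use a context
  left-padded with symbol A, keeping profile length equal to sequence
  length (the alternative, charging a flat 2 bits/symbol during warm-up,
  would truncate profiles).
* **Weight floor.**  After each normalization, weights are clamped to
  ≥ 1e-12 and renormalized so no model dies permanently under finite
  precision; without it a long stretch that starves a model could zero it
  out forever.
* **Tie-breaks.**  Argmax ties in the tolerant model resolve in symbol
  order A < C < G < T.
* **Phase boundary of relative mode.**  Weights restart uniform and
  tolerant histories restart from the target's (all-A-padded) past:
  training performance on the reference should not bias the start of the
  target's coding.
* **Degenerate inputs.**  Empty sequences are rejected by every
  compression mode and measure; `mutate` with a rate outside [0, 1],
  invalid mixture parameters (no models, γ outside [0, 1), tolerant model
  without a same-depth plain partner) all raise immediately.
* **Implementation.**  The coding loop is a numba kernel over flat numpy
  buffers.  A pure-python stepwise engine (`EngineState`) implements the
  identical contract, and the test suite holds the two equal to within
  1e-9 bits per position on configurations exercising every feature
  (tolerant pairing, inverted repeats, cache-hash eviction, freezing).

## Presets

| preset | γ | cache | models (depth:α[:t][, IR]) |
|---|---|---|---|
| synthetic-relative | 0.95 | 30 | 17:0.02:t5, 17:0.002, 14:0.1:t3, 14:0.005, 11:0.01, 8:0.1, 5:1 |
| synthetic-ref-free | 0.95 | 30 | 17:0.1:t5, 17:0.005, 14:1:t3, 14:0.01, 11:0.1, 8:1, 5:1, 3:1 |
| mtDNA | 0.95 | — | 13:0.1:t5, 13:0.005 IR, 10:0.01 IR, 6:1, 3:1 |
| mRNA | 0.88 | 200 | 20:0.1:t5, 20:0.005 IR, 14:0.02 IR, 13:0.05, 11:0.1, 9:1, 4:1 |
| gDNA | 0.88 | 250 | 20:0.1:t5, 20:0.005 IR, 14:0.02 IR, 13:0.05, 11:0.1, 9:1 |

Each `*-relative` variant keeps the same models with the depth-14 alpha
tightened to 0.01 where such a model exists (a frozen, fully populated
memory supports a sharper estimator); the mtDNA set has no depth-14
model, so `mtDNA-relative` coincides with `mtDNA`.  The synthetic presets
are intended for uniform-background simulation studies; the others for
their respective data scales.

## Synthetic data: what it emulates, and what it does not

The generators produce the study conditions exercised by the tests:

* `generate_random` — i.i.d. uniform DNA, the incompressible baseline.
* `mutate_substitutions` — i.i.d. per-site substitutions; a selected site
  always changes (drawn from the three other bases), so the nominal rate
  is exactly the expected Hamming fraction.  An identity-preserving draw
  would silently deflate every rate-indexed curve.
* `generate_blocks` — labelled block architectures where regions of one
  sequence are plain, reverse-complemented or mutated copies of regions
  of the other; coordinates are 0-based half-open, annotations exported
  as BED.  `rearrangement_demo_plan` ships the 14-region architecture
  (novel high/low-entropy regions, inter-sequence copies at 1%, and an
  intra-target duplicate absent from the reference) used to contrast the
  three coding modes.
* `generate_repeat_rich` — a uniform backbone with internal, optionally
  mutated, re-pasted substrings; the copy/paste-with-substitution core of
  read-free genome simulators, without their sequencing-read features.

These sequences have uniform base composition, stationary statistics and
exactly known ground truth.  Real genomes add skewed composition,
heterogeneous repeat families, low-complexity tracts and assembly
artefacts; a test passing on these conditions demonstrates the coder's
mechanics and the measures' contracts, not performance claims on real
data.

## Similarity-map calibration

Profiles are smoothed with a centered moving average (window 501,
shrinking at the edges) and segmented at a threshold with a minimum run
length (100).  The default threshold is 1.5 bits: on synthetic data,
unrelated background codes at ~2.0 bits/symbol after smoothing while
copies up to ~5% divergence average well under 1 bit with brief
excursions slightly above it, so 1.0 — the half-ceiling value that might
seem natural — fragments copies at the upper end of that divergence
range, while 1.5 separates the two populations cleanly.  All three
parameters are exposed as arguments and CLI flags.

## Experiment drivers and problem sizes

The shipped experiment drivers (and the acceptance script) run at desk
scale: 100 kb pairs for the mutation-rate sweeps, 10 kb blocks for the
rearrangement architecture, 16 kb and 1 Mb references for the
mutation-load expectation curves — sizes chosen so every study completes
in seconds to a few minutes on one core while leaving the measured
effects far above coder noise.  A `--max-length` guard in the drivers
refuses multi-megabase inputs unless `--force` is given, keeping the
desk-scale contract explicit.  At the 16 kb scale single-run NRC values
carry visible sampling noise, so the expectation study averages a few
replicate mutants per point and assesses concavity of the curve globally
(sign of a fitted quadratic) rather than per consecutive triple; at 1 Mb
single runs are smooth enough for pointwise checks.

## Known limitations

* No decompression: code lengths are ideal, not produced by an entropy
  coder, so they can differ from a real bitstream by its header and
  carry-over overheads.
* Relative coding of a target unrelated to its reference costs slightly
  more than 2 bits/symbol (the mixture pays a small adaptation overhead
  against confidently wrong frozen deep models), so NRC saturates
  marginally above 1; comparisons between near-saturated NRC and NCD
  values at the third decimal are not meaningful.
* The similarity map reports low-information segments per side; it does
  not infer which reference coordinates a target segment matches (the
  coder keeps no positional traceback).
* No escape/exclusion mechanisms (PPM-style), no adaptive alpha, no
  per-model γ, no ambiguity-code-aware modelling; sequences are treated
  as linear.
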