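# nrcomp

Compression-based, alignment-free comparison of DNA sequences.

`nrcomp` measures how much information two DNA sequences share — without
aligning them — by asking a lossless compressor how many bits it needs to
describe one sequence, alone or with the help of the other.  It implements
the three normalized measures used in compression-based comparative
genomics, on top of a mixture-of-context-models coder built for DNA:

* **NC** (Normalized Compression)
  `NC(x) = C(x) / (|x| · log₂|A|)` — how compressible a sequence is on its
  own (≈ 1 for incompressible sequences; |A| = 4 for DNA, so the
  denominator is 2|x| bits).
* **NCD** (Normalized Compression Distance)
  `NCD(x,y) = (C(xy) − min{C(x),C(y)}) / max{C(x),C(y)}` — a symmetric
  distance: how far two sequences are in information content.  The conjoint
  term `C(xy)` is approximated by compressing the concatenation; the
  conditional form `max{C(x|y),C(y|x)} / max{C(x),C(y)}` via the chain rule
  `C(x|y) = C(yx) − C(y)` is also provided.
* **NRC** (Normalized Relative Compression)
  `NRC(x‖y) = C(x‖y) / (2|x|)` — the fraction of `x` that *cannot* be
  described using information from `y` alone.  `C(x‖y)` trains the models
  on `y`, freezes them, and codes `x` read-only.  NRC is asymmetric, and it
  deliberately ignores repeats inside `x`: coding `n` copies of `x` costs
  `n` times coding `x` once.

The two distances answer different questions: NCD asks *how similar are
these two sequences*, NRC asks *how much of this sequence is new relative
to that one*.  The per-symbol code lengths behind `C(x‖y)` additionally
form an **information profile** along the sequence; low-information runs
mark regions describable from the reference (rearranged copies,
conserved segments), which `nrcomp` segments and reports as two-sided
similarity maps.

## The coder

All three measures are backed by one sequential coder: a soft-blended
mixture of finite-context (Markov) models of several depths.  Each model
predicts the next base from smoothed k-mer counts,
`P(s|c) = (n_s(c) + α) / (Σ n(c) + 4α)`, and the mixture combines the
predictions with weights updated as `w_m ∝ w_m^γ · P_m(x_i)`, where
`γ ∈ [0,1)` is a forgetting factor.  Deep models optionally count reverse
complements (inverted repeats), keep memory bounded with a cache-hash, and
come paired with *substitution-tolerant* twins that share their counts but
forgive up to `t` mispredictions before resetting their context — which is
what lets a depth-17 context survive isolated SNP-like substitutions.  The
coder never emits a bitstream; the measure is the ideal code length
`Σ −log₂ P(x_i)`.

Named presets (`synthetic-ref-free`, `synthetic-relative`, `mtDNA`,
`mRNA`, `gDNA`, and `*-relative` variants) bundle the model sets for each
data scale.

## Worked example

Simulate a 100 kb reference, derive a copy with 5% substitutions, and
measure it both ways:

```bash
nrcomp simulate --kind random -n 100000 --seed 1 --out y.fa
nrcomp simulate --kind mutate --template y.fa --rate 0.05 --seed 2 --out x.fa
nrcomp nrc x.fa y.fa --preset synthetic-relative
nrcomp ncd x.fa y.fa --preset synthetic-ref-free
```

The NRC report (abridged):

```json
{
  "measure": "NRC",
  "value": 0.30708224622233893,
  "components": { "C(x||y)": 61416.44924446779, "|x|": 100000 }
}
```

and the NCD report:

```json
{
  "measure": "NCD",
  "form": "conjoint",
  "value": 0.39635847895711146,
  "components": { "C(x)": 200200.4, "C(y)": 200223.9, "C(xy)": 279560.9 }
}
```

Reading the numbers: the reference-free cost `C(x) ≈ 200 200` bits is
2 bits per base — a uniform random sequence is incompressible
(`NC(y) = 1.0011`).  Described *relative to y*, the same `x` costs only
61 416 bits: 69% of it is reconstructible from the reference, and the
NRC of 0.307 is the informational footprint of the 5% substitutions
(each substitution also damages the contexts around it, which is why
0.307 ≫ 0.05).  The NCD of 0.396 gives the symmetric view of the same
divergence.

Other entry points: `nrcomp profile` (per-symbol information profiles as
TSV), `nrcomp map` (two-sided similarity maps as BED/SVG),
`nrcomp sweep-mutations` and `nrcomp expectation` (NCD/NRC as functions
of substitution rate), `nrcomp blocks-profile` (profile comparison on a
planted rearrangement architecture).  Everything is also available as a
library — see `docs/methods.md` for the model details and design choices.

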