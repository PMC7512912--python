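"""Named model-mixture presets.

The presets pair a data scale with a hand-tuned mixture: shallow
high-alpha models absorb novel or noisy stretches, deep low-alpha models
(with substitution-tolerant twins sharing their memory) capture long exact
and near-exact repeats.  ``*-relative`` presets are intended for coding a
target against a frozen reference; the others for reference-free and
conjoint passes.

* ``synthetic-ref-free`` / ``synthetic-relative`` — uniform-background
  synthetic benchmarks (gamma 0.95, cache-hash 30).
* ``mtDNA`` — mitochondrial genomes, ~16 kb (five models, gamma 0.95,
  unbounded memory: the sequences are tiny).
* ``mRNA`` — transcript collections (gamma 0.88, cache-hash 200).
* ``gDNA`` — whole nuclear genomes (gamma 0.88, cache-hash 250).
* the ``-relative`` variant of each keeps the same models, with the
  depth-14 alpha tightened to 0.01 where such a model exists (a frozen,
  fully-populated memory supports a sharper estimator).
"""

from __future__ import annotations

from .engine import MixtureConfig
from .models import ModelSpec

CM = ModelSpec


def _stcm(depth: int, alpha: float, tolerance: int) -> ModelSpec:
    return ModelSpec(depth=depth, alpha=alpha, tolerance=tolerance)


PRESETS: dict[str, MixtureConfig] = {
    "synthetic-relative": MixtureConfig(
        models=(
            _stcm(17, 0.02, 5),
            CM(17, 0.002),
            _stcm(14, 0.1, 3),
            CM(14, 0.005),
            CM(11, 0.01),
            CM(8, 0.1),
            CM(5, 1.0),
        ),
        gamma=0.95,
        cache_hash=30,
    ),
    "synthetic-ref-free": MixtureConfig(
        models=(
            _stcm(17, 0.1, 5),
            CM(17, 0.005),
            _stcm(14, 1.0, 3),
            CM(14, 0.01),
            CM(11, 0.1),
            CM(8, 1.0),
            CM(5, 1.0),
            CM(3, 1.0),
        ),
        gamma=0.95,
        cache_hash=30,
    ),
    "mtDNA": MixtureConfig(
        models=(
            _stcm(13, 0.1, 5),
            CM(13, 0.005, inverted_repeats=True),
            CM(10, 0.01, inverted_repeats=True),
            CM(6, 1.0),
            CM(3, 1.0),
        ),
        gamma=0.95,
        cache_hash=0,
    ),
    "mRNA": MixtureConfig(
        models=(
            _stcm(20, 0.1, 5),
            CM(20, 0.005, inverted_repeats=True),
            CM(14, 0.02, inverted_repeats=True),
            CM(13, 0.05),
            CM(11, 0.1),
            CM(9, 1.0),
            CM(4, 1.0),
        ),
        gamma=0.88,
        cache_hash=200,
    ),
    "gDNA": MixtureConfig(
        models=(
            _stcm(20, 0.1, 5),
            CM(20, 0.005, inverted_repeats=True),
            CM(14, 0.02, inverted_repeats=True),
            CM(13, 0.05),
            CM(11, 0.1),
            CM(9, 1.0),
        ),
        gamma=0.88,
        cache_hash=250,
    ),
}


def _relative_variant(cfg: MixtureConfig) -> MixtureConfig:
    models = tuple(
        ModelSpec(m.depth, 0.01, m.inverted_repeats, m.tolerance)
        if (m.depth == 14 and m.tolerance == 0)
        else m
        for m in cfg.models
    )
    return MixtureConfig(models=models, gamma=cfg.gamma, cache_hash=cfg.cache_hash)


PRESETS["mtDNA-relative"] = _relative_variant(PRESETS["mtDNA"])
PRESETS["mRNA-relative"] = _relative_variant(PRESETS["mRNA"])
PRESETS["gDNA-relative"] = _relative_variant(PRESETS["gDNA"])


def preset(name: str) -> MixtureConfig:
    """Look up a named preset; raises ``KeyError`` with the known names."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
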