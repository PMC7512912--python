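"""Normalized compression measures: NC, NCD (conjoint and conditional), NRC.

With C(.) the mixture coder's ideal code length in bits and the DNA
alphabet fixed at 4 symbols (log2 |A| = 2 bits):

* ``NC(x) = C(x) / (2 |x|)`` — how compressible x is on its own; about 1
  for incompressible input.
* ``NCD(x, y)`` — a normalized distance: conjoint form
  ``(C(xy) - min{C(x), C(y)}) / max{C(x), C(y)}`` with C(xy) approximated
  by coding the concatenation, or conditional form
  ``max{C(x|y), C(y|x)} / max{C(x), C(y)}`` with the conditionals obtained
  through the chain rule ``C(x|y) = C(yx) - C(y)``.
* ``NRC(x||y) = C(x||y) / (2 |x|)`` — the fraction of x that cannot be
  described using information from y alone.  Generally asymmetric, and
  insensitive to repeats *within* x (coding n concatenated copies of x
  costs about n times coding x once).

The normalization constant stays at 2 bits per symbol even when the input
contained replaced (non-ACGT) characters.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

from .engine import (MixtureConfig, ReferenceModel, compress, compress_conjoint,
                     compress_relative)
from .sequence import Sequence, as_symbols

LOG2_ALPHABET = 2.0  # log2 of the 4-letter DNA alphabet


@dataclasses.dataclass(frozen=True)
class MeasureResult:
    """A normalized measure value plus the raw bit totals behind it."""

    value: float
    components: dict
    mode: str

    def __float__(self) -> float:
        return self.value


def nc(x, config: MixtureConfig) -> MeasureResult:
    """Normalized Compression NC(x) = C(x) / (2 |x|)."""
    n = as_symbols(x).size
    if n == 0:
        raise ValueError("x must be non-empty")
    cx = compress(x, config).total_bits
    return MeasureResult(cx / (LOG2_ALPHABET * n), {"C(x)": cx, "|x|": n}, "nc")


def ncd_conjoint(x, y, config: MixtureConfig) -> MeasureResult:
    """NCD via conjoint compression: (C(xy) - min) / max.

    C(xy) is approximated by one adaptive pass over the concatenation,
    reference (y) first; the two concatenation orders agree up to coder
    noise for a compressor respecting the normality properties.
    """
    cx = compress(x, config).total_bits
    cy = compress(y, config).total_bits
    cxy = compress_conjoint(x, y, config).total_bits
    value = (cxy - min(cx, cy)) / max(cx, cy)
    return MeasureResult(
        value, {"C(x)": cx, "C(y)": cy, "C(xy)": cxy}, "ncd-conjoint"
    )


def ncd_conditional(x, y, config: MixtureConfig) -> MeasureResult:
    """NCD via the chain rule: max{C(x|y), C(y|x)} / max{C(x), C(y)}.

    ``C(x|y) = C(yx) - C(y)`` can come out slightly negative under an
    imperfect compressor; negative conditionals are clamped to zero and
    flagged in the components.
    """
    cx = compress(x, config).total_bits
    cy = compress(y, config).total_bits
    cyx = compress_conjoint(x, y, config).total_bits  # pass over y.x
    cxy = compress_conjoint(y, x, config).total_bits  # pass over x.y
    cond_x = cyx - cy
    cond_y = cxy - cx
    clamped = cond_x < 0 or cond_y < 0
    cond_x = max(cond_x, 0.0)
    cond_y = max(cond_y, 0.0)
    value = max(cond_x, cond_y) / max(cx, cy)
    return MeasureResult(
        value,
        {"C(x)": cx, "C(y)": cy, "C(yx)": cyx, "C(xy)": cxy,
         "C(x|y)": cond_x, "C(y|x)": cond_y, "clamped": clamped},
        "ncd-conditional",
    )


def nrc(x, y: Union[Sequence, np.ndarray, ReferenceModel],
        config: MixtureConfig | None = None) -> MeasureResult:
    """Normalized Relative Compression NRC(x||y) = C(x||y) / (2 |x|).

    ``y`` may be a sequence (a reference model is trained on the spot) or a
    pre-trained :class:`ReferenceModel`, which amortizes the training pass
    across many targets.
    """
    n = as_symbols(x).size
    if n == 0:
        raise ValueError("x must be non-empty")
    if isinstance(y, ReferenceModel):
        cxy = y.code(x).total_bits
    else:
        if config is None:
            raise ValueError("config is required when y is a raw sequence")
        cxy = compress_relative(x, y, config).total_bits
    return MeasureResult(
        cxy / (LOG2_ALPHABET * n), {"C(x||y)": cxy, "|x|": n}, "nrc"
    )
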