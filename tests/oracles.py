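"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package internals: plain python
dictionaries and loops, so they can certify the optimized implementation.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict


def brute_adaptive_code_length(symbols, k: int, alpha: float) -> float:
    """Ideal adaptive code length of a single order-k model, dict-based.

    Contexts are left-padded with symbol 0 (A); prediction precedes the
    count update, matching any sequential (decodable) coder.
    """
    counts = defaultdict(lambda: [0, 0, 0, 0])
    pad = [0] * k + [int(s) for s in symbols]
    total = 0.0
    for i in range(len(symbols)):
        ctx = tuple(pad[i : i + k])
        s = pad[i + k]
        c = counts[ctx]
        total += -math.log2((c[s] + alpha) / (sum(c) + 4 * alpha))
        c[s] += 1
    return total


def brute_window_counts(symbols, k: int) -> Counter:
    """Occurrence counts of (k+1)-mers of a raw (unpadded) sequence."""
    syms = [int(s) for s in symbols]
    return Counter(
        tuple(syms[i : i + k + 1]) for i in range(len(syms) - k)
    )


def brute_reverse_complement(symbols) -> list[int]:
    return [3 - int(s) for s in reversed(list(symbols))]


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
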