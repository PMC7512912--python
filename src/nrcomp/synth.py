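"""Synthetic DNA generators for controlled comparison experiments.

Four sequence families cover the study conditions exercised throughout the
package:

* i.i.d. uniform random DNA (the incompressible baseline);
* i.i.d. substitution mutants of an existing sequence, at a given per-site
  rate (a selected site always changes, so the nominal rate is the expected
  Hamming fraction);
* block architectures in which labelled regions of one sequence are plain,
  reverse-complemented, or mutated copies of regions of the other — used to
  probe how the relative coder and the conjoint coder see rearrangements;
* repeat-rich sequences in which substrings of a random backbone are
  re-pasted elsewhere, emulating the redundancy of real genomic DNA.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from os import PathLike
from typing import Iterable, Union

import numpy as np

from .sequence import Sequence, as_symbols, reverse_complement

#: block content source kinds
SOURCES = ("random", "low-entropy", "copy", "rc-copy")

#: motif length used for low-entropy (tiled-repeat) blocks
LOW_ENTROPY_MOTIF = 16


@dataclasses.dataclass(frozen=True)
class Block:
    """One region of a two-sequence block plan.

    ``source`` is one of ``random`` (uniform i.i.d.), ``low-entropy`` (a short
    random motif tiled to length), ``copy`` / ``rc-copy`` (a substitution
    mutant of a previously defined block, optionally reverse-complemented;
    ``source_label`` names it).  ``rate`` is the per-site substitution rate
    applied to the block content.  ``target`` routes the block into sequence
    ``"x"`` or ``"y"``.
    """

    label: str
    target: str
    length: int
    source: str
    rate: float = 0.0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.target not in ("x", "y"):
            raise ValueError(f"block {self.label!r}: target must be 'x' or 'y'")
        if self.length <= 0:
            raise ValueError(f"block {self.label!r}: length must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"block {self.label!r}: unknown source {self.source!r}")
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"block {self.label!r}: rate must lie in [0, 1]")
        if self.source in ("copy", "rc-copy") and not self.source_label:
            raise ValueError(f"block {self.label!r}: copy blocks need a source_label")


BlockPlan = list  # list[Block]

Annotation = tuple  # (label, target, start, end) with 0-based half-open coords


def generate_random(n: int, seed: int, id: str = "random") -> Sequence:
    """Uniform i.i.d. DNA of length ``n``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return Sequence(id=id, symbols=rng.integers(0, 4, size=n, dtype=np.int8))


def _mutate_array(symbols: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if not (0.0 <= rate <= 1.0):
        raise ValueError("substitution rate must lie in [0, 1]")
    out = symbols.astype(np.int8).copy()
    if out.size == 0 or rate == 0.0:
        return out
    hit = rng.random(out.size) < rate
    # offset in {1,2,3} guarantees the substituted symbol differs
    offsets = rng.integers(1, 4, size=out.size, dtype=np.int8)
    out[hit] = (out[hit] + offsets[hit]) % 4
    return out


def mutate_substitutions(x: Sequence, rate: float, seed: int) -> Sequence:
    """Independent per-site substitutions at probability ``rate``.

    A selected site is replaced by one of the three *other* nucleotides, so
    the expected Hamming distance to ``x`` is exactly ``rate * len(x)``.
    """
    rng = np.random.default_rng(seed)
    return Sequence(id=f"{x.id}|sub={rate:g}", symbols=_mutate_array(x.symbols, rate, rng))


def _low_entropy(length: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    motif = rng.integers(0, 4, size=min(LOW_ENTROPY_MOTIF, length), dtype=np.int8)
    reps = -(-length // motif.size)
    tiled = np.tile(motif, reps)[:length]
    return _mutate_array(tiled, rate, rng)


def generate_blocks(plan: BlockPlan, seed: int):
    """Materialize a block plan into a pair of sequences.

    Returns ``(x, y, annotations)`` where annotations are
    ``(label, target, start, end)`` tuples with 0-based half-open coordinates
    inside the target sequence.  Copy blocks must reference a previously
    defined label; their content is the referenced block's content (prefix, if
    the copy is shorter) mutated at the block's rate, reverse-complemented for
    ``rc-copy``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(plan), 1))
    contents: dict[str, np.ndarray] = {}
    parts: dict[str, list[np.ndarray]] = {"x": [], "y": []}
    offsets = {"x": 0, "y": 0}
    annotations: list[Annotation] = []
    for block, child in zip(plan, children):
        rng = np.random.default_rng(child)
        if block.source == "random":
            content = _mutate_array(
                rng.integers(0, 4, size=block.length, dtype=np.int8), block.rate, rng
            )
        elif block.source == "low-entropy":
            content = _low_entropy(block.length, block.rate, rng)
        else:
            if block.source_label not in contents:
                raise ValueError(
                    f"block {block.label!r} references undefined block {block.source_label!r}"
                )
            src = contents[block.source_label]
            if block.length > src.size:
                raise ValueError(
                    f"block {block.label!r} longer than its source {block.source_label!r}"
                )
            content = src[: block.length]
            if block.source == "rc-copy":
                content = reverse_complement(content)
            content = _mutate_array(content, block.rate, rng)
        if block.label in contents:
            raise ValueError(f"duplicate block label {block.label!r}")
        contents[block.label] = content
        parts[block.target].append(content)
        start = offsets[block.target]
        offsets[block.target] += block.length
        annotations.append((block.label, block.target, start, start + block.length))

    def _cat(key: str) -> Sequence:
        arrs = parts[key]
        symbols = np.concatenate(arrs) if arrs else np.empty(0, dtype=np.int8)
        return Sequence(id=key, symbols=symbols)

    return _cat("x"), _cat("y"), annotations


def generate_repeat_rich(
    n: int, n_copies: int, copy_len: int, sub_rate: float, seed: int, id: str = "repeat-rich"
) -> Sequence:
    """A random backbone with internal (mutated) repeats.

    ``n_copies`` substrings of length ``copy_len``, sampled from the pristine
    backbone, are pasted back at random non-overlapping destinations with
    per-site substitution rate ``sub_rate``.
    """
    if n < 0 or n_copies < 0 or copy_len < 0:
        raise ValueError("sizes must be non-negative")
    if n_copies * copy_len > n:
        raise ValueError("repeats do not fit: n_copies * copy_len exceeds n")
    rng = np.random.default_rng(seed)
    backbone = rng.integers(0, 4, size=n, dtype=np.int8)
    out = backbone.copy()
    if n_copies and copy_len:
        free = n - n_copies * copy_len
        cuts = np.sort(rng.integers(0, free + 1, size=n_copies))
        dests = cuts + np.arange(n_copies) * copy_len
        srcs = rng.integers(0, n - copy_len + 1, size=n_copies)
        for d, s in zip(dests, srcs):
            out[d : d + copy_len] = _mutate_array(backbone[s : s + copy_len], sub_rate, rng)
    return Sequence(id=id, symbols=out)


def rearrangement_demo_plan(block_len: int = 10_000) -> BlockPlan:
    """The 14-region rearrangement architecture used by the profile demo.

    Sequence *y* carries regions B, C (random, high entropy), D, F, H
    (low entropy); sequence *x* carries A (random), E and L (copies of B at
    1% substitutions), G (random), I (copy of F), J (copy of C at 1%),
    K (copy of D), M (copy of G) and N (random).  M is an *intra-x* repeat:
    its source G never appears in y, so a coder restricted to information
    from y must treat M as novel while a reference-free or conjoint coder
    sees it as a repeat.
    """
    L = block_len
    return [
        Block("B", "y", L, "random"),
        Block("C", "y", L, "random"),
        Block("D", "y", L, "low-entropy"),
        Block("F", "y", L, "low-entropy"),
        Block("H", "y", L, "low-entropy"),
        Block("A", "x", L, "random"),
        Block("E", "x", L, "copy", rate=0.01, source_label="B"),
        Block("G", "x", L, "random"),
        Block("I", "x", L, "copy", source_label="F"),
        Block("J", "x", L, "copy", rate=0.01, source_label="C"),
        Block("K", "x", L, "copy", source_label="D"),
        Block("L", "x", L, "copy", rate=0.01, source_label="B"),
        Block("M", "x", L, "copy", source_label="G"),
        Block("N", "x", L, "random"),
    ]


def load_block_plan(path: Union[str, PathLike]) -> BlockPlan:
    """Read a block plan from text: one block per line,
    ``label target length source[:source_label] rate`` (whitespace separated,
    ``#`` comments allowed)."""
    plan: BlockPlan = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            label, target, length, source, rate = fields
            source_label = ""
            if ":" in source:
                source, source_label = source.split(":", 1)
            plan.append(
                Block(label, target, int(length), source, float(rate), source_label)
            )
    return plan


def write_annotations_bed(annotations: Iterable[Annotation], path: Union[str, PathLike]) -> None:
    """Write block annotations as BED-style TSV (target, start, end, label)."""
    with open(path, "w") as fh:
        for label, target, start, end in annotations:
            fh.write(f"{target}\t{start}\t{end}\t{label}\n")
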