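"""DNA sequences over the 4-symbol alphabet, with FASTA input/output.

All downstream machinery (context models, the mixture coder, the normalized
measures) works on integer-coded sequences over {A, C, G, T} = {0, 1, 2, 3}.
Characters outside the alphabet (``N``, IUPAC ambiguity codes, gaps, ...) are
replaced on input by a uniformly drawn nucleotide; the replacement is
deterministic per (seed, position) and the affected positions are recorded so
that provenance is never lost.
"""

from __future__ import annotations

import dataclasses
from os import PathLike
from typing import Iterable, Sequence as TypingSequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq as BioSeq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

SymbolsLike = Union[str, TypingSequence[int], np.ndarray]


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclasses.dataclass(frozen=True, eq=False)
class Sequence:
    """An immutable DNA sequence.

    Parameters
    ----------
    id:
        Record identifier (FASTA header up to the first whitespace).
    symbols:
        Integer codes in {0, 1, 2, 3} for {A, C, G, T}; stored read-only.
    replaced_positions:
        0-based indices where a non-ACGT input character was substituted by a
        random nucleotide during encoding.
    """

    id: str
    symbols: np.ndarray
    replaced_positions: frozenset = frozenset()

    def __post_init__(self) -> None:
        arr = np.asarray(self.symbols, dtype=np.int8)
        if arr.ndim != 1:
            raise ValueError("symbols must be one-dimensional")
        if arr.size and (arr.min() < 0 or arr.max() > 3):
            raise ValueError("symbol codes must lie in {0, 1, 2, 3}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "symbols", arr)
        repl = frozenset(int(p) for p in self.replaced_positions)
        if any(p < 0 or p >= arr.size for p in repl):
            raise ValueError("replaced_positions out of range")
        object.__setattr__(self, "replaced_positions", repl)

    def __len__(self) -> int:
        return int(self.symbols.size)

    def __str__(self) -> str:
        return decode(self)

    def with_symbols(self, symbols: np.ndarray, id: str | None = None) -> "Sequence":
        """A copy of this record with new symbols (provenance dropped)."""
        return Sequence(id=self.id if id is None else id, symbols=symbols)


def as_symbols(x: Union[Sequence, SymbolsLike]) -> np.ndarray:
    """Coerce a :class:`Sequence`, string or array to an int8 code array."""
    if isinstance(x, Sequence):
        return x.symbols
    if isinstance(x, str):
        codes = _ENCODE[np.frombuffer(x.encode("ascii"), dtype=np.uint8)]
        if codes.size and codes.min() < 0:
            raise ValueError("string contains non-ACGT characters; use encode()")
        return codes
    arr = np.asarray(x, dtype=np.int8)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("symbol codes must lie in {0, 1, 2, 3}")
    return arr


def encode(raw: str, seed: int = 0, id: str = "") -> Sequence:
    """Encode raw text into a :class:`Sequence`.

    A/C/G/T (case-insensitive) map to codes 0..3.  Every other character is
    replaced by a symbol drawn uniformly from the alphabet using an RNG
    seeded by ``(seed, position)``, so a record re-encoded with the same seed
    is reproduced bit for bit regardless of context.
    """
    data = np.frombuffer(raw.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[data].copy()
    bad = np.flatnonzero(codes < 0)
    for pos in bad:
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(pos)])
        codes[pos] = rng.integers(0, 4)
    return Sequence(id=id, symbols=codes, replaced_positions=frozenset(int(p) for p in bad))


def decode(seq: Union[Sequence, np.ndarray]) -> str:
    """Integer codes back to an ACGT string."""
    arr = as_symbols(seq)
    return _DECODE[arr.astype(np.intp)].tobytes().decode("ascii")


def reverse_complement(seq: Union[Sequence, SymbolsLike]) -> np.ndarray:
    """Reverse complement of a code array (A<->T, C<->G, order reversed)."""
    arr = as_symbols(seq)
    return (3 - arr[::-1]).astype(np.int8)


def read_fasta(path: Union[str, PathLike], seed: int = 0) -> list[Sequence]:
    """Read every record of a FASTA file (wrapped or single-line).

    Record ids are taken from the header up to the first whitespace.  Raises
    :class:`FastaError` if the file holds no records.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(encode(str(rec.seq), seed=seed, id=rec.id))
    if not records:
        raise FastaError(f"no records in FASTA file: {path}")
    return records


def write_fasta(seqs: Iterable[Sequence], path: Union[str, PathLike], width: int = 70) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    records = [SeqRecord(BioSeq(decode(s)), id=s.id or "seq", description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
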