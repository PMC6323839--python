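"""Alignment-free sequence encodings.

Two families of compositions map a DNA sequence of length N to a numeric
vector:

* **g-spaced base pairs** — for each ordered pair of bases (s, t), the count
  D_g(s, t) of positions i with sequence[i] = s and sequence[i + g + 1] = t
  (exactly g bases skipped between the pair; g = 0 is the contiguous
  dinucleotide), divided by N - 1.  The N - 1 denominator is used for every
  gap size, so a single-gap block sums to (N - 1 - g)/(N - 1) rather than 1.
  Each gap size contributes 16 features.

* **contiguous k-mers** — the count of each of the 4^k length-k words
  divided by the number of windows N - k + 1; a k-block sums to 1.

Because both are compositions, sequences of unequal length (the norm for
length-variable barcode regions such as fungal ITS) encode to vectors of
identical dimension with no alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import InvalidSequenceError, ReferenceLibrary

BASES = "ACGT"

#: The 16 ordered base pairs in lexicographic order AA, AC, ..., TT.
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _codes(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.min(initial=0) < 0:
        bad = sorted({c for c in sequence.upper() if c not in BASES})
        raise InvalidSequenceError(f"invalid base(s) {', '.join(bad)} in sequence")
    return codes.astype(np.intp)


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of an encoding.

    ``gap_sizes`` selects g-spaced base-pair blocks, ``kmer_orders``
    contiguous k-mer blocks; either may be empty, both non-empty gives a
    hybrid encoding.  Blocks are laid out gap blocks first in ascending g,
    then k-mer blocks in ascending k; within a block, words are
    lexicographic over A < C < G < T.  Column order is therefore fully
    determined by the spec, which makes encodings stable across sessions
    for model persistence.
    """

    gap_sizes: tuple[int, ...] = ()
    kmer_orders: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        gaps = tuple(sorted(set(int(g) for g in self.gap_sizes)))
        kmers = tuple(sorted(set(int(k) for k in self.kmer_orders)))
        if any(g < 0 for g in gaps):
            raise ValueError("gap sizes must be non-negative")
        if any(k < 1 for k in kmers):
            raise ValueError("k-mer orders must be positive")
        if not gaps and not kmers:
            raise ValueError("FeatureSpec needs at least one gap size or k-mer order")
        object.__setattr__(self, "gap_sizes", gaps)
        object.__setattr__(self, "kmer_orders", kmers)

    @classmethod
    def gapped(cls, gap_sizes: Iterable[int] = (1, 2, 3, 4, 5),
               include_gap0: bool = False) -> "FeatureSpec":
        """Gapped base-pair spec; ``include_gap0`` adds the contiguous
        dinucleotide block (g = 0), giving 96 features for gaps 1..5."""
        gaps = tuple(gap_sizes)
        if include_gap0:
            gaps = (0,) + gaps
        return cls(gap_sizes=gaps)

    @classmethod
    def kmer(cls, orders: Iterable[int] = (1, 2, 3, 4)) -> "FeatureSpec":
        return cls(kmer_orders=tuple(orders))

    @property
    def n_features(self) -> int:
        """Dimensionality p = 16·|gap_sizes| + Σ 4^k."""
        return 16 * len(self.gap_sizes) + sum(4 ** k for k in self.kmer_orders)

    @property
    def min_length(self) -> int:
        """Shortest sequence the spec can encode without error."""
        need = 2 if self.gap_sizes else 1
        if self.kmer_orders:
            need = max(need, max(self.kmer_orders))
        return need

    def column_names(self) -> list[str]:
        names = [f"g{g}_{pair}" for g in self.gap_sizes for pair in DINUCLEOTIDES]
        for k in self.kmer_orders:
            names.extend(
                f"k{k}_{''.join(word)}" for word in product(BASES, repeat=k)
            )
        return names

    def to_dict(self) -> dict:
        return {"gap_sizes": list(self.gap_sizes), "kmer_orders": list(self.kmer_orders)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(gap_sizes=tuple(d.get("gap_sizes", ())),
                   kmer_orders=tuple(d.get("kmer_orders", ())))


def gapped_pair_frequencies(sequence: str, g: int) -> np.ndarray:
    """Frequencies of the 16 ordered base pairs at gap ``g``.

    Entry (s, t) is D_g(s, t)/(N - 1) where D_g counts positions i with
    sequence[i] = s and sequence[i + g + 1] = t.  Pairs are ordered
    AA, AC, ..., TT.  The 16 values sum to max(0, N - 1 - g)/(N - 1).
    """
    if g < 0:
        raise ValueError("gap size must be non-negative")
    codes = _codes(sequence)
    n = codes.size
    if n < 2:
        raise InvalidSequenceError(
            f"sequence of length {n} has no base pair (need N >= 2)"
        )
    span = g + 1
    counts = np.zeros(16, dtype=np.int64)
    if n > span:
        pair_idx = codes[:-span] * 4 + codes[span:]
        counts = np.bincount(pair_idx, minlength=16)
    return counts / (n - 1)


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Composition of contiguous k-mers: counts over the N - k + 1 windows,
    normalized to sum to 1.  Words are lexicographic over A < C < G < T."""
    if k < 1:
        raise ValueError("k must be positive")
    codes = _codes(sequence)
    n = codes.size
    if n < k:
        raise InvalidSequenceError(f"sequence of length {n} is shorter than k={k}")
    n_windows = n - k + 1
    idx = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j:j + n_windows]
    counts = np.bincount(idx, minlength=4 ** k)
    return counts / n_windows


def encode_sequence(sequence: str, spec: FeatureSpec) -> np.ndarray:
    """Concatenate the blocks of ``spec`` for one sequence (length p)."""
    blocks = [gapped_pair_frequencies(sequence, g) for g in spec.gap_sizes]
    blocks += [kmer_frequencies(sequence, k) for k in spec.kmer_orders]
    return np.concatenate(blocks)


@dataclass
class FeatureMatrix:
    """Numeric encoding of a library: records × p values in [0, 1].

    Rows align with ``record_ids`` and ``labels``; ``column_names`` identify
    features and must match between a model and the data it predicts.
    """

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    record_ids: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            values=self.values[rows],
            column_names=self.column_names,
            labels=self.labels[rows],
            record_ids=[self.record_ids[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "species", self.labels)
        df.insert(0, "record_id", self.record_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def encode_dataset(lib: ReferenceLibrary, spec: FeatureSpec) -> FeatureMatrix:
    """Encode every record of ``lib`` under ``spec``.

    Row i encodes record i; identical sequences yield identical rows.  A
    record too short for any block raises an error naming the record.
    """
    if len(lib) == 0:
        raise ValueError("cannot encode an empty library")
    rows = np.empty((len(lib), spec.n_features), dtype=np.float64)
    for i, rec in enumerate(lib):
        try:
            rows[i] = encode_sequence(rec.sequence, spec)
        except InvalidSequenceError as exc:
            raise InvalidSequenceError(f"record {rec.record_id!r}: {exc}") from exc
    return FeatureMatrix(
        values=rows,
        column_names=spec.column_names(),
        labels=np.array([rec.species for rec in lib], dtype=object),
        record_ids=[rec.record_id for rec in lib],
    )
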