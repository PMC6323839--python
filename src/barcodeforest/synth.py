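"""Seeded synthetic barcode reference libraries.

Emulates the structure of a curated barcode reference library — many species
classes, few sequences per species, high between-species divergence,
tunable within-species variability — so the encoder, classifier and
cross-validation machinery are testable without downloading any repository
data.

Model: each species gets an ancestor sequence drawn uniformly over
{A, C, G, T}^length (two independent ancestors therefore agree at ~25% of
positions, far below any realistic intraspecific identity, which makes
species well separated by construction).  Each library sequence is an
independent copy of its species' ancestor with per-base substitutions at
``within_sub_rate`` (to a uniformly chosen *different* base, Jukes-Cantor
style) and, optionally, 1-base indels at ``indel_rate``.  Indels default to
off so Hamming-distance oracles stay exact; switching them on exercises the
length-robustness of composition features.

An optional two-level scheme (genus ancestors, then species ancestors
mutated from them) produces harder benchmarks with related species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .features import BASES
from .io import BarcodeRecord, ReferenceLibrary


@dataclass(frozen=True)
class SimulationParams:
    """Design of a synthetic library.

    length defaults to 600, a typical fungal ITS barcode length;
    within_sub_rate is the per-base substitution probability applied
    independently to each copy of the species ancestor; indel_rate the
    per-base probability of a 1-base insertion or deletion (default 0).
    """

    n_species: int
    seqs_per_species: int
    length: int = 600
    within_sub_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.seqs_per_species < 1:
            raise ValueError("seqs_per_species must be >= 1")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        for name in ("within_sub_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


class SyntheticLibrary(ReferenceLibrary):
    """A generated reference library that remembers each species' ancestor,
    so matched query sets can be drawn from the same truth."""

    def __init__(self, records: Iterable[BarcodeRecord], ancestors: dict[str, str]):
        super().__init__(records)
        self.ancestors = dict(ancestors)


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _mutate(rng: np.random.Generator, ancestor: np.ndarray,
            sub_rate: float, indel_rate: float) -> np.ndarray:
    codes = ancestor.copy()
    if sub_rate > 0:
        mask = rng.random(codes.size) < sub_rate
        n_sub = int(mask.sum())
        if n_sub:
            # shift by 1..3 mod 4: always a different base, uniformly chosen
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_sub)) % 4
    if indel_rate > 0:
        events = rng.random(codes.size) < indel_rate
        if events.any():
            out: list[int] = []
            for i, base in enumerate(codes):
                if events[i]:
                    if rng.random() < 0.5:
                        continue  # deletion
                    out.append(int(rng.integers(0, 4)))  # insertion before i
                out.append(int(base))
            codes = np.asarray(out, dtype=codes.dtype)
    return codes


def generate_library(params: SimulationParams) -> SyntheticLibrary:
    """Generate a library of ``n_species`` × ``seqs_per_species`` records.

    Species are labelled ``sp0001`` ... in order; record ids are
    ``sp0001-01`` etc., and headers written by :func:`~barcodeforest.io.write_fasta`
    follow the ``id|species`` dialect.  Same seed, same library — byte for
    byte.
    """
    rng = np.random.default_rng(params.seed)
    records: list[BarcodeRecord] = []
    ancestors: dict[str, str] = {}
    for s in range(params.n_species):
        species = f"sp{s + 1:04d}"
        ancestor = rng.integers(0, 4, size=params.length)
        ancestors[species] = _decode(ancestor)
        for j in range(params.seqs_per_species):
            codes = _mutate(rng, ancestor, params.within_sub_rate, params.indel_rate)
            records.append(
                BarcodeRecord(f"{species}-{j + 1:02d}", species, _decode(codes))
            )
    return SyntheticLibrary(records, ancestors)


def generate_two_level_library(n_genera: int, species_per_genus: int,
                               seqs_per_species: int, length: int = 600,
                               genus_sub_rate: float = 0.10,
                               within_sub_rate: float = 0.01,
                               indel_rate: float = 0.0,
                               seed: int = 0) -> SyntheticLibrary:
    """Two-level variant: genus ancestors are drawn uniformly, species
    ancestors are mutants of their genus ancestor at ``genus_sub_rate``,
    so congeneric species are related — a harder benchmark than fully
    independent ancestors."""
    rng = np.random.default_rng(seed)
    records: list[BarcodeRecord] = []
    ancestors: dict[str, str] = {}
    s = 0
    for _ in range(n_genera):
        genus_anc = rng.integers(0, 4, size=length)
        for _ in range(species_per_genus):
            s += 1
            species = f"sp{s:04d}"
            sp_anc = _mutate(rng, genus_anc, genus_sub_rate, 0.0)
            ancestors[species] = _decode(sp_anc)
            for j in range(seqs_per_species):
                codes = _mutate(rng, sp_anc, within_sub_rate, indel_rate)
                records.append(
                    BarcodeRecord(f"{species}-{j + 1:02d}", species, _decode(codes))
                )
    return SyntheticLibrary(records, ancestors)


def generate_query_set(lib: ReferenceLibrary, per_species: int,
                       within_sub_rate: float, seed: int) -> ReferenceLibrary:
    """Draw ``per_species`` fresh mutants of each species' ancestor, labelled
    with the true species for scoring.

    For a :class:`SyntheticLibrary` the retained ancestors are used; for a
    plain library each species' first record stands in as its ancestor.
    """
    if per_species < 1:
        raise ValueError("per_species must be >= 1")
    if not 0.0 <= within_sub_rate < 1.0:
        raise ValueError("within_sub_rate must be in [0, 1)")
    if isinstance(lib, SyntheticLibrary):
        ancestors = lib.ancestors
    else:
        ancestors = {
            sp: lib.records[positions[0]].sequence
            for sp, positions in lib.species_index.items()
        }
    missing = set(ancestors) - set(lib.species_index)
    if missing:
        raise ValueError(f"ancestors for unknown species: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    code_of = {b: i for i, b in enumerate(BASES)}
    records = []
    for sp in lib.species_index:
        anc = np.array([code_of[b] for b in ancestors[sp]], dtype=np.int64)
        for j in range(per_species):
            codes = _mutate(rng, anc, within_sub_rate, 0.0)
            records.append(
                BarcodeRecord(f"query-{sp}-{j + 1:02d}", sp, _decode(codes))
            )
    return ReferenceLibrary(records)
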