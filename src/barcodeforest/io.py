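"""Reading, validating and filtering labelled barcode libraries.

Reference libraries arrive as FASTA with pipe-delimited headers in the style
of BOLD exports (``recordid|species|...``).  The first pipe field is the
record identifier; the species label sits at a configurable 1-based field
index (default 2).  Query files carry no labels and are read with the
``UNKNOWN_SPECIES`` sentinel.

Sequences are DNA over {A, C, G, T}.  Ambiguity codes (N, R, Y, ...) are not
interpreted: depending on policy a record containing them is either rejected
with an error or dropped from the library with a logged reason, which mirrors
the usual curation step of excluding sequences with non-standard bases when
building a barcode reference library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Species sentinel used for query records whose label is unknown.
UNKNOWN_SPECIES = "unknown"

_VALID_BASES = frozenset("ACGT")


class BarcodeError(ValueError):
    """Base class for barcode-library errors."""


class HeaderError(BarcodeError):
    """A FASTA header does not contain the requested pipe-delimited field."""


class InvalidSequenceError(BarcodeError):
    """A sequence violates the {A,C,G,T} alphabet or minimum-length rule."""


class EmptyLibraryError(BarcodeError):
    """An operation produced (or received) a library with no usable records."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One labelled barcode sequence.

    Attributes
    ----------
    record_id : str
        Free-text identifier (first pipe field of the FASTA header).
    species : str
        Class label; ``UNKNOWN_SPECIES`` for query records.
    sequence : str
        Nucleotide string over {A, C, G, T}, upper case, length >= 2
        once validated.
    """

    record_id: str
    species: str
    sequence: str


class ReferenceLibrary:
    """Ordered collection of :class:`BarcodeRecord` with a species index."""

    def __init__(self, records: Iterable[BarcodeRecord]):
        self.records: tuple[BarcodeRecord, ...] = tuple(records)
        index: dict[str, list[int]] = {}
        for pos, rec in enumerate(self.records):
            index.setdefault(rec.species, []).append(pos)
        self.species_index: dict[str, tuple[int, ...]] = {
            sp: tuple(positions) for sp, positions in index.items()
        }

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceLibrary):
            return NotImplemented
        return self.records == other.records

    @property
    def n_species(self) -> int:
        """Number of distinct species labels H."""
        return len(self.species_index)

    @property
    def species(self) -> tuple[str, ...]:
        """Species labels in first-appearance order."""
        return tuple(self.species_index)

    def species_counts(self) -> dict[str, int]:
        return {sp: len(pos) for sp, pos in self.species_index.items()}

    def subset(self, positions: Iterable[int]) -> "ReferenceLibrary":
        """New library holding the records at ``positions`` (input order kept)."""
        return ReferenceLibrary(self.records[p] for p in positions)


def _parse_header(description: str, species_field: int | None) -> tuple[str, str]:
    fields = description.split("|")
    record_id = fields[0].strip()
    if species_field is None:
        return record_id, UNKNOWN_SPECIES
    if species_field < 1:
        raise ValueError("species_field is 1-based and must be >= 1")
    if len(fields) < species_field:
        raise HeaderError(
            f"header {description!r} has {len(fields)} pipe-delimited field(s); "
            f"species_field={species_field} is out of range"
        )
    species = fields[species_field - 1].strip()
    if not species:
        raise HeaderError(f"header {description!r}: species field is empty")
    return record_id, species


def read_fasta(path: str | Path, species_field: int | None = 2) -> ReferenceLibrary:
    """Read a barcode library from FASTA with pipe-delimited headers.

    Parameters
    ----------
    path : path
        FASTA file; multi-line sequence bodies are accepted.
    species_field : int or None
        1-based index of the pipe-delimited header field holding the species
        label (default 2, matching ``id|species|...`` exports).  ``None``
        reads an unlabelled query file: every record gets the
        ``UNKNOWN_SPECIES`` sentinel.

    Raises
    ------
    HeaderError
        If any header has fewer pipe fields than ``species_field``.
    EmptyLibraryError
        If the file holds no FASTA entries.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        record_id, species = _parse_header(entry.description, species_field)
        records.append(BarcodeRecord(record_id, species, str(entry.seq)))
    if not records:
        raise EmptyLibraryError(f"no FASTA entries found in {path}")
    return ReferenceLibrary(records)


def write_fasta(lib: ReferenceLibrary, path: str | Path) -> None:
    """Write ``lib`` as single-line FASTA with ``id|species`` headers.

    Round-trips with ``read_fasta(path, species_field=2)``.
    """
    entries = (
        SeqRecord(Seq(rec.sequence), id=f"{rec.record_id}|{rec.species}", description="")
        for rec in lib
    )
    SeqIO.write(entries, str(path), "fasta-2line")


def validate_record(rec: BarcodeRecord, policy: str = "reject") -> BarcodeRecord | None:
    """Normalize a record to upper case and enforce the sequence alphabet.

    Returns the normalized record when valid.  A record containing a base
    outside {A, C, G, T}, or shorter than 2 bases (no base pair can be
    formed), is rejected: under ``policy="reject"`` an
    :class:`InvalidSequenceError` is raised, under ``policy="drop"`` the
    record is excluded — ``None`` is returned and the reason logged.

    Idempotent: validating an already-valid record returns an equal record.
    """
    if policy not in ("reject", "drop"):
        raise ValueError(f"unknown policy {policy!r}; expected 'reject' or 'drop'")
    if not rec.species:
        raise InvalidSequenceError(f"record {rec.record_id!r}: empty species label")
    seq = rec.sequence.upper()
    reason = None
    if len(seq) < 2:
        reason = "too short (no base pair can be formed)"
    else:
        bad = sorted(set(seq) - _VALID_BASES)
        if bad:
            reason = f"non-standard base {', '.join(bad)}"
    if reason is not None:
        if policy == "reject":
            raise InvalidSequenceError(f"record {rec.record_id!r}: {reason}")
        logger.warning("dropping record %r: %s", rec.record_id, reason)
        return None
    return replace(rec, sequence=seq)


def clean_library(lib: ReferenceLibrary, policy: str = "drop") -> ReferenceLibrary:
    """Validate every record of ``lib`` under ``policy``.

    With ``policy="drop"`` (the default used for library construction)
    invalid records are excluded with a logged reason; with ``"reject"`` the
    first invalid record raises.
    """
    kept = []
    for rec in lib:
        validated = validate_record(rec, policy=policy)
        if validated is not None:
            kept.append(validated)
    if not kept:
        raise EmptyLibraryError("no valid records remain after validation")
    return ReferenceLibrary(kept)


def filter_min_sequences(lib: ReferenceLibrary, min_per_species: int = 3) -> ReferenceLibrary:
    """Drop species represented by fewer than ``min_per_species`` records.

    Few-sequence species cannot support the per-species cross-validation
    design, so reference curation excludes them (default threshold 3).
    """
    if min_per_species < 1:
        raise ValueError("min_per_species must be >= 1")
    keep_species = {
        sp for sp, positions in lib.species_index.items()
        if len(positions) >= min_per_species
    }
    removed = lib.n_species - len(keep_species)
    if removed:
        logger.info(
            "filter_min_sequences: removed %d species with < %d sequences",
            removed, min_per_species,
        )
    if not keep_species:
        raise EmptyLibraryError(
            f"no species has >= {min_per_species} sequences; library would be empty"
        )
    # preserve the original record order
    positions = sorted(
        pos for sp in keep_species for pos in lib.species_index[sp]
    )
    return lib.subset(positions)


def subsample_k_per_species(lib: ReferenceLibrary, k: int, seed: int) -> ReferenceLibrary:
    """Randomly keep exactly ``k`` records per species (without replacement).

    Species with fewer than ``k`` records are dropped with a logged warning.
    Sampling is seeded and reproducible; record order within the output
    follows the original library order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    # iterate species in library order so the RNG stream is well defined
    for sp, positions in lib.species_index.items():
        if len(positions) < k:
            logger.warning(
                "subsample_k_per_species: dropping species %r (%d < %d sequences)",
                sp, len(positions), k,
            )
            continue
        picked = rng.choice(len(positions), size=k, replace=False)
        chosen.extend(positions[i] for i in picked)
    if not chosen:
        raise EmptyLibraryError(f"no species has >= {k} sequences; nothing to subsample")
    return lib.subset(sorted(chosen))
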