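"""Sequence and metadata I/O, plus the fragment filter applied before network analysis.

Protein domain sequences enter the pipeline as FASTA records with a 7-rank
taxonomic lineage (kingdom..species) attached from a tab-separated metadata
table. Sequences covering less than 95% of the family model are treated as
fragments and excluded before any pairwise alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The seven taxonomic ranks carried per sequence, in lineage order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Residue alphabet: the 20 standard amino acids plus the ambiguity code X.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

EMPTY_LINEAGE = ("",) * 7


class ValidationError(ValueError):
    """Raised when an input record or table violates the documented contract."""


@dataclass
class SequenceRecord:
    """One protein domain sequence with its lineage and fragment flag.

    ``residues`` is restricted to the 20 standard amino acids plus ``X``;
    other ambiguity codes are rejected so that substitution-matrix scoring
    stays well-defined downstream.
    """

    id: str
    residues: str
    taxonomy: tuple[str, ...] = EMPTY_LINEAGE
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        self.taxonomy = tuple(self.taxonomy)
        if len(self.taxonomy) != 7:
            raise ValidationError(
                f"record {self.id!r}: taxonomy must have 7 ranks, got {len(self.taxonomy)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def rank(self, name: str) -> str:
        """Lineage value at a named rank (empty string when unknown)."""
        return self.taxonomy[RANKS.index(name)]


@dataclass
class FamilyModelRef:
    """Reference family model against which per-record coverage was computed.

    Coverage is the fraction of model columns spanned by the record's
    alignment to the family model; the model itself is external, so only
    its length and the resulting per-record coverages are kept.
    """

    model_length: int
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_length <= 0:
            raise ValidationError("model_length must be positive")
        for rid, c in self.coverage.items():
            if not 0.0 <= c <= 1.0:
                raise ValidationError(f"coverage for {rid!r} outside [0,1]: {c}")

    @classmethod
    def from_spans(
        cls, model_length: int, spans: Mapping[str, tuple[int, int]]
    ) -> "FamilyModelRef":
        """Build coverages from per-record (start, end) model-column spans (1-based, inclusive)."""
        cov = {}
        for rid, (start, end) in spans.items():
            if not 1 <= start <= end <= model_length:
                raise ValidationError(f"span for {rid!r} outside model: {(start, end)}")
            cov[rid] = (end - start + 1) / model_length
        return cls(model_length, cov)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    The header token before the first whitespace becomes the record id;
    duplicate ids and non-amino-acid characters are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValidationError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, residues=str(entry.seq)))
    if not records:
        raise ValidationError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def _parse_table(path: str | Path, n_columns: int) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != n_columns:
                raise ValidationError(
                    f"{path}: line {lineno}: expected {n_columns} columns, got {len(cells)}"
                )
            rows.append((lineno, cells))
    return rows


def attach_taxonomy(
    records: Sequence[SequenceRecord], table: str | Path
) -> list[SequenceRecord]:
    """Populate each record's 7-rank lineage from a tab-separated table.

    The table must have a header ``id kingdom phylum class order family genus
    species``; an optional trailing ``model_coverage`` column is tolerated
    (and read separately by :func:`read_coverage`). Records absent from the
    table keep an empty lineage and are logged as warnings.
    """
    raw = _read_metadata_rows(table)
    lineages = {rid: tuple(cells[1:8]) for rid, cells in raw.items()}
    out = []
    for rec in records:
        if rec.id in lineages:
            out.append(replace(rec, taxonomy=lineages[rec.id]))
        else:
            logger.warning("no taxonomy for %s; leaving lineage empty", rec.id)
            out.append(replace(rec, taxonomy=EMPTY_LINEAGE))
    return out


def _read_metadata_rows(table: str | Path) -> dict[str, list[str]]:
    with open(table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    expected = ["id", *RANKS]
    if header[: len(expected)] != expected:
        raise ValidationError(
            f"{table}: header must start with {' '.join(expected)!r}"
        )
    rows = _parse_table_skip_header(table, len(header))
    out: dict[str, list[str]] = {}
    for lineno, cells in rows:
        if cells[0] in out:
            raise ValidationError(f"{table}: line {lineno}: duplicate id {cells[0]!r}")
        out[cells[0]] = cells
    return out


def _parse_table_skip_header(path: str | Path, n_columns: int) -> list[tuple[int, list[str]]]:
    rows = _parse_table(path, n_columns)
    return rows[1:]


def read_coverage(table: str | Path) -> dict[str, float]:
    """Read per-record family-model coverage.

    Accepts either a two-column ``id<TAB>model_coverage`` file or the full
    metadata table with a trailing ``model_coverage`` column.
    """
    with open(table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if "model_coverage" not in header:
        raise ValidationError(f"{table}: no model_coverage column")
    idx = header.index("model_coverage")
    rows = _parse_table_skip_header(table, len(header))
    cov = {}
    for lineno, cells in rows:
        try:
            cov[cells[0]] = float(cells[idx])
        except ValueError as exc:
            raise ValidationError(
                f"{table}: line {lineno}: bad coverage {cells[idx]!r}"
            ) from exc
    return cov


def filter_fragments(
    records: Sequence[SequenceRecord],
    coverage: Mapping[str, float],
    min_coverage: float = 0.95,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, fragments) by family-model coverage.

    A record is a fragment iff its coverage is strictly below ``min_coverage``
    (the boundary value itself is kept). Fragments come back flagged; the two
    lists always partition the input.
    """
    kept, fragments = [], []
    for rec in records:
        if rec.id not in coverage:
            raise ValidationError(f"no model coverage for record {rec.id!r}")
        if coverage[rec.id] < min_coverage:
            fragments.append(replace(rec, is_fragment=True))
        else:
            kept.append(rec)
    logger.info(
        "fragment filter: kept %d, flagged %d of %d records (min coverage %.2f)",
        len(kept), len(fragments), len(records), min_coverage,
    )
    return kept, fragments
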