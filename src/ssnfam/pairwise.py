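"""All-vs-all pairwise local-alignment statistics defining SSN edges.

Edges of the similarity network come from optimal affine-gap local alignments
under BLOSUM62 with gap open 11 / extend 1 (the BLAST default scoring), turned
into bit scores and E-values with standard gapped Karlin-Altschul parameters:

    bits = (lambda * S - ln K) / ln 2,      E = m * n * 2^(-bits)

Alternatively, a precomputed BLAST tabular ("outfmt 6") hit table can be
imported. Either way, directional hits are collapsed to one entry per
unordered pair, keeping the minimum E-value, since SSN edges are undirected.

Composition-based score adjustment (a blastp default) is not applied, so
E-values can differ slightly from BLAST's for the same pair; component
structure at the thresholds used downstream is insensitive to this.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .seqio import SequenceRecord

#: Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1
#: (the standard published values used by BLAST for this scoring system).
KA_LAMBDA = 0.267
KA_K = 0.041

#: Floor applied to all E-values so log-binning over the threshold grid is
#: always defined (the grid bottoms out at 1e-120).
EVALUE_FLOOR = 1e-180

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal affine-gap local alignment summary for one ordered pair."""

    score: int
    identity_pct: float
    align_length: int


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    evalue: float
    bit_score: float
    identity_pct: float
    align_length: int

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise AlignmentError(f"self-hit {self.query_id!r} not allowed")
        if self.evalue <= 0:
            raise AlignmentError("evalue must be positive (apply the floor)")
        if self.identity_pct > 100.0:
            raise AlignmentError("identity above 100%")


def _as_biotite(residues: str) -> bseq.ProteinSequence:
    return bseq.ProteinSequence(residues)


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Optimal Smith-Waterman alignment under BLOSUM62 with affine gaps.

    The gap cost convention is BLAST's: a gap of length L costs
    ``gap_open + L * gap_extend``. Identity and alignment length are measured
    over the optimal local alignment path (gap columns count toward length).
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise AlignmentError("cannot align an empty sequence")
    # biotite charges (open, extend) as open + (L-1)*extend; shift open by one
    # extend so a length-L gap costs gap_open + L*gap_extend, as in BLAST.
    aln = balign.align_optimal(
        _as_biotite(sa),
        _as_biotite(sb),
        _BLOSUM62,
        gap_penalty=(-(gap_open + gap_extend), -gap_extend),
        local=True,
        max_number=1,
    )[0]
    length = aln.trace.shape[0]
    if length == 0 or aln.score <= 0:
        return LocalAlignment(score=max(aln.score, 0), identity_pct=0.0, align_length=0)
    identity = balign.get_sequence_identity(aln, mode="all")
    return LocalAlignment(
        score=int(aln.score),
        identity_pct=100.0 * identity,
        align_length=int(length),
    )


def bit_score(raw_score: float, ka_lambda: float = KA_LAMBDA, ka_k: float = KA_K) -> float:
    """Normalized (bit) score from a raw alignment score."""
    return (ka_lambda * raw_score - math.log(ka_k)) / math.log(2.0)


def compute_evalue(bit_score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value for a bit score in an m x n search space.

    Strictly decreasing in the bit score and floored at :data:`EVALUE_FLOOR`.
    """
    if m <= 0 or n <= 0:
        raise AlignmentError("search-space sizes m, n must be positive")
    # Work in log space: m*n*2^-bits underflows for strong hits.
    log10_e = math.log10(m) + math.log10(n) - bit_score * math.log10(2.0)
    return max(10.0 ** max(log10_e, -320.0), EVALUE_FLOOR)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class HitTable:
    """Best pairwise statistics per unordered sequence pair.

    Symmetrized by construction: adding a hit for (A,B) and one for (B,A)
    keeps the one with the smaller E-value (ties: larger bit score), which is
    the permissive convention for undirected SSN edges.
    """

    hits: dict[tuple[str, str], PairwiseHit] = field(default_factory=dict)
    #: search-space sizes used for statistics (query length varies per pair;
    #: n is the database residue total)
    n_residues: int = 0

    def add(self, hit: PairwiseHit) -> None:
        key = _pair_key(hit.query_id, hit.subject_id)
        old = self.hits.get(key)
        if old is None or (hit.evalue, -hit.bit_score) < (old.evalue, -old.bit_score):
            self.hits[key] = hit

    def get(self, a: str, b: str) -> PairwiseHit | None:
        return self.hits.get(_pair_key(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _pair_key(*pair) in self.hits

    def __len__(self) -> int:
        return len(self.hits)

    def pairs(self) -> Iterator[tuple[str, str, PairwiseHit]]:
        """Hits in deterministic (lexicographic pair) order."""
        for key in sorted(self.hits):
            yield key[0], key[1], self.hits[key]

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.hits:
            out.add(a)
            out.add(b)
        return out


def all_vs_all(
    records: Sequence[SequenceRecord],
    gap_open: int = 11,
    gap_extend: int = 1,
    ceiling: float = 1e-5,
    n_jobs: int = 1,
) -> HitTable:
    """Align every unordered pair once and keep hits with E <= ceiling.

    The default ceiling matches the loosest threshold analyzed downstream
    (1e-5). For each pair the E-value uses m = length of the lexicographically
    first sequence and n = total database residues, so the result does not
    depend on input order. Rows can be computed in parallel; the merged table
    is deterministic.
    """
    if len(records) < 2:
        raise AlignmentError("all-vs-all needs at least 2 records")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise AlignmentError("duplicate ids in all-vs-all input")
    ids = sorted(by_id)
    n_total = sum(r.length for r in records)
    pairs = list(itertools.combinations(ids, 2))

    def _row(chunk: list[tuple[str, str]]) -> list[PairwiseHit]:
        out = []
        for qa, qb in chunk:
            hit = _align_pair(by_id[qa], by_id[qb], gap_open, gap_extend, n_total)
            if hit is not None and hit.evalue <= ceiling:
                out.append(hit)
        return out

    if n_jobs > 1:
        from joblib import Parallel, delayed

        chunks = [pairs[i::n_jobs] for i in range(n_jobs)]
        results = Parallel(n_jobs=n_jobs)(delayed(_row)(c) for c in chunks)
        hit_lists = results
    else:
        hit_lists = [_row(pairs)]

    table = HitTable(n_residues=n_total)
    for hits in hit_lists:
        for hit in hits:
            table.add(hit)
    return table


def _align_pair(
    a: SequenceRecord, b: SequenceRecord, gap_open: int, gap_extend: int, n_total: int
) -> PairwiseHit | None:
    aln = local_align(a, b, gap_open, gap_extend)
    if aln.align_length == 0:
        return None
    bits = bit_score(aln.score)
    e = compute_evalue(bits, m=a.length, n=n_total)
    return PairwiseHit(
        query_id=a.id,
        subject_id=b.id,
        evalue=e,
        bit_score=bits,
        identity_pct=aln.identity_pct,
        align_length=aln.align_length,
    )


_OUTFMT6_COLUMNS = 12


def parse_blast_tabular(path: str | Path, evalue_floor: float = EVALUE_FLOOR) -> HitTable:
    """Import a 12-column BLAST tabular ("outfmt 6") file as a hit table.

    Directional rows and multiple HSPs per pair collapse to the minimum-E
    entry; self-rows are dropped; E-values printed as 0 are floored.
    """
    table = HitTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != _OUTFMT6_COLUMNS:
                raise AlignmentError(
                    f"{path}: line {lineno}: expected {_OUTFMT6_COLUMNS} columns, "
                    f"got {len(cells)}"
                )
            qid, sid = cells[0], cells[1]
            if qid == sid:
                continue
            try:
                pident = float(cells[2])
                length = int(cells[3])
                evalue = float(cells[10])
                bits = float(cells[11])
            except ValueError as exc:
                raise AlignmentError(f"{path}: line {lineno}: unparsable field") from exc
            table.add(
                PairwiseHit(
                    query_id=qid,
                    subject_id=sid,
                    evalue=max(evalue, evalue_floor),
                    bit_score=bits,
                    identity_pct=pident,
                    align_length=length,
                )
            )
    return table


def write_blast_tabular(
    table: HitTable, path: str | Path, lengths: Mapping[str, int] | None = None
) -> None:
    """Emit the hit table in the 12-column BLAST tabular dialect.

    Only the columns the SSN consumes are meaningful (ids, pident, length,
    evalue, bitscore); coordinate and mismatch columns are filled with
    placeholder values spanning the alignment length.
    """
    with open(path, "w") as fh:
        for a, b, hit in table.pairs():
            mismatch = round(hit.align_length * (1.0 - hit.identity_pct / 100.0))
            fh.write(
                "\t".join(
                    [
                        a,
                        b,
                        f"{hit.identity_pct:.2f}",
                        str(hit.align_length),
                        str(mismatch),
                        "0",
                        "1",
                        str(hit.align_length),
                        "1",
                        str(hit.align_length),
                        f"{hit.evalue:.2e}",
                        f"{hit.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
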