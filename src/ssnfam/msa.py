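"""Redundancy reduction and multiple sequence alignment for HMM training sets.

Before a subfamily's profile HMM is built, its member set is reduced to 75%
identity by greedy clustering (longest sequence first, each sequence joining
the first representative it matches at or above the identity threshold over a
local alignment) and the representatives are aligned with a progressive
aligner. The built-in aligner derives a guide tree from pairwise similarities
and merges profiles progressively; any external aligner can be plugged in as
a callable instead (a MAFFT wrapper is provided for convenience).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .pairwise import local_align
from .seqio import SequenceRecord, write_fasta

DEFAULT_REDUNDANCY_IDENTITY = 0.75

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


class MsaError(ValueError):
    pass


@dataclass
class Msa:
    """A gapped alignment: parallel lists of ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise MsaError("ids and rows differ in count")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise MsaError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def reduce_redundancy(
    seqs: Sequence[SequenceRecord],
    identity: float = DEFAULT_REDUNDANCY_IDENTITY,
) -> list[SequenceRecord]:
    """Greedy identity-threshold clustering; returns the representatives.

    Sequences are visited longest-first (ties by id); each joins the first
    existing representative it matches at >= ``identity`` over the optimal
    local alignment, else founds a new cluster. Every input is therefore
    within ``identity`` of some representative or is one itself.
    """
    if not seqs:
        raise MsaError("cannot reduce an empty sequence set")
    if not 0.0 < identity <= 1.0:
        raise MsaError(f"identity threshold outside (0, 1]: {identity}")
    ordered = sorted(seqs, key=lambda r: (-r.length, r.id))
    representatives: list[SequenceRecord] = []
    for rec in ordered:
        for rep in representatives:
            if local_align(rec, rep).identity_pct >= 100.0 * identity:
                break
        else:
            representatives.append(rec)
    return representatives


def build_msa(
    representatives: Sequence[SequenceRecord],
    aligner: Callable[[Sequence[SequenceRecord]], Msa] | None = None,
) -> Msa:
    """Align the representatives (progressive aligner unless one is supplied)."""
    if not representatives:
        raise MsaError("cannot align an empty sequence set")
    if aligner is not None:
        return aligner(representatives)
    if len(representatives) == 1:
        rec = representatives[0]
        return Msa(ids=[rec.id], rows=[rec.residues])
    seqs = [bseq.ProteinSequence(r.residues) for r in representatives]
    alignment, order, _, _ = balign.align_multiple(
        seqs, _BLOSUM62, gap_penalty=(-12, -1)
    )
    gapped = alignment.get_gapped_sequences()
    return Msa(ids=[r.id for r in representatives], rows=list(gapped))


def mafft_align(records: Sequence[SequenceRecord], strategy: str = "--globalpair") -> Msa:
    """External-aligner hook using MAFFT (iterative refinement strategy)."""
    if shutil.which("mafft") is None:
        raise MsaError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(records, infile)
        out = subprocess.run(
            ["mafft", strategy, "--maxiterate", "1000", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        aligned = {}
        current = None
        for line in out.stdout.splitlines():
            if line.startswith(">"):
                current = line[1:].split()[0]
                aligned[current] = []
            elif current is not None:
                aligned[current].append(line.strip())
    ids = [r.id for r in records]
    return Msa(ids=ids, rows=["".join(aligned[i]).upper() for i in ids])
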