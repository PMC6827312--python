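"""Optional HMMER backend (via pyhmmer) for the library's pluggable hook.

Builds one Plan7 HMM per subfamily from the same reduced/aligned training
sets and ranks sequences against the collection with HMMER's own pipeline.
Used as an independent cross-check of the simplified internal profile HMM
(best-model agreement); E-values are HMMER's and are not interchangeable
with the internal calibration.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pyhmmer

from .msa import Msa, build_msa, reduce_redundancy
from .seqio import SequenceRecord

_ALPHABET = pyhmmer.easel.Alphabet.amino()


def _hmm_from_msa(msa: Msa, name: str) -> pyhmmer.plan7.HMM:
    sequences = [
        pyhmmer.easel.TextSequence(name=i.encode(), sequence=row)
        for i, row in zip(msa.ids, msa.rows)
    ]
    dmsa = pyhmmer.easel.TextMSA(
        name=name.encode(), sequences=sequences
    ).digitize(_ALPHABET)
    builder = pyhmmer.plan7.Builder(_ALPHABET)
    background = pyhmmer.plan7.Background(_ALPHABET)
    hmm, _, _ = builder.build_msa(dmsa, background)
    return hmm


def build_hmms(
    subfamily_members: Mapping[str, Sequence[SequenceRecord]],
    redundancy_identity: float = 0.75,
) -> list[pyhmmer.plan7.HMM]:
    """One HMMER model per subfamily from reduced + aligned members."""
    hmms = []
    for name in sorted(subfamily_members):
        reps = reduce_redundancy(subfamily_members[name], identity=redundancy_identity)
        hmms.append(_hmm_from_msa(build_msa(reps), str(name)))
    return hmms


def best_models(
    records: Sequence[SequenceRecord], hmms: Sequence[pyhmmer.plan7.HMM]
) -> dict[str, str | None]:
    """id -> name of the best-scoring model (None if nothing hits)."""
    queries = [
        pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.residues).digitize(
            _ALPHABET
        )
        for r in records
    ]
    def _name(raw) -> str:
        return raw.decode() if isinstance(raw, bytes) else str(raw)

    best: dict[str, tuple[float, str]] = {}
    for hits in pyhmmer.hmmer.hmmsearch(hmms, queries, cpus=1):
        model = _name(hits.query.name)
        for hit in hits:
            rid = _name(hit.name)
            if rid not in best or hit.score > best[rid][0]:
                best[rid] = (hit.score, model)
    return {r.id: (best[r.id][1] if r.id in best else None) for r in records}
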