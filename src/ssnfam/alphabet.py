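"""Amino-acid alphabet, background frequencies, and BLOSUM62-derived tables."""

from __future__ import annotations

import functools

import numpy as np
import biotite.sequence.align as balign

#: Canonical 20-letter amino-acid order used for all emission vectors.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Background amino-acid frequencies (Robinson & Robinson composition, the
#: standard null used for protein profile scoring), in AA20 order.
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND /= BACKGROUND.sum()


@functools.lru_cache(maxsize=1)
def blosum62_scores() -> np.ndarray:
    """BLOSUM62 scores as a (20, 20) array in AA20 order."""
    mat = balign.SubstitutionMatrix.std_protein_matrix()
    alph = list(str(a) for a in mat.get_alphabet1())
    scores = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            scores[i, j] = mat.get_score(a, b)
    return scores


@functools.lru_cache(maxsize=1)
def blosum62_conditional() -> np.ndarray:
    """Substitution probabilities P(b | a), b != a, implied by BLOSUM62.

    BLOSUM62 entries are half-bit log-odds s = 2*log2(q_ab / (p_a p_b)), so
    the implied target frequencies are q_ab ∝ p_a p_b 2^(s/2). Rows are
    conditioned on the source residue with the diagonal removed, so a draw
    always changes the residue, with replacement biases matching the scoring
    matrix used downstream.
    """
    s = blosum62_scores()
    q = BACKGROUND[:, None] * BACKGROUND[None, :] * np.exp2(s / 2.0)
    np.fill_diagonal(q, 0.0)
    cond = q / q.sum(axis=1, keepdims=True)
    return cond


def encode(residues: str) -> np.ndarray:
    """Residues to integer codes (X and any non-standard letter -> 20)."""
    return np.array([AA_INDEX.get(ch, 20) for ch in residues], dtype=np.int64)
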