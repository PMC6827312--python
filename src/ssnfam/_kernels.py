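"""Numba kernels for log-space profile-HMM dynamic programming.

Both kernels run over a glocal profile architecture: N flank (self-looping,
background emission) -> begin -> match/insert/delete columns -> end -> C
flank. Emission terms are log-odds against the background, so flank and
insert emissions contribute zero and the result is a natural-log odds score
of the whole sequence against the model versus background.

Transition layout per column j (already log-transformed, disallowed cells at
-inf): tm[j] = M_j -> (M_{j+1}|E, I_j, D_{j+1}), ti[j] = I_j -> (...), and
td[j] = D_j -> (...); destination 0 at the last column is the end state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=False, inline="always")
def _lse2(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    # beyond ~36 nats the correction is below double precision
    if a - b > 36.0:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=False, fastmath=True)
def forward(xs, lem, tm, ti, td, lbm, lbd, lq_flank):
    """Natural-log forward odds of the sequence against the profile."""
    L = xs.shape[0]
    M = lem.shape[0]
    l_leave = math.log1p(-math.exp(lq_flank))

    Mv = np.full(M, NEG_INF)
    Iv = np.full(M, NEG_INF)
    Dv = np.full(M, NEG_INF)
    # i = 0: nothing emitted; B reachable, delete chain open
    logN = 0.0
    Dv[0] = l_leave + lbd
    for j in range(1, M):
        Dv[j] = Dv[j - 1] + td[j - 1, 2]
    logC = Mv[0]  # -inf
    e0 = _lse2(Dv[M - 1] + td[M - 1, 0], NEG_INF)
    logC = e0

    newM = np.empty(M)
    newI = np.empty(M)
    newD = np.empty(M)
    for i in range(L):
        x = xs[i]
        entry = logN + l_leave + lbm
        for j in range(M):
            if j == 0:
                acc = entry
            else:
                acc = _lse2(
                    _lse2(Mv[j - 1] + tm[j - 1, 0], Iv[j - 1] + ti[j - 1, 0]),
                    Dv[j - 1] + td[j - 1, 0],
                )
            newM[j] = acc + lem[j, x]
            newI[j] = _lse2(
                _lse2(Mv[j] + tm[j, 1], Iv[j] + ti[j, 1]), Dv[j] + td[j, 1]
            )
        logN = logN + lq_flank
        newD[0] = logN + l_leave + lbd
        for j in range(1, M):
            newD[j] = _lse2(
                _lse2(newM[j - 1] + tm[j - 1, 2], newI[j - 1] + ti[j - 1, 2]),
                newD[j - 1] + td[j - 1, 2],
            )
        for j in range(M):
            Mv[j] = newM[j]
            Iv[j] = newI[j]
            Dv[j] = newD[j]
        e_i = _lse2(
            _lse2(Mv[M - 1] + tm[M - 1, 0], Iv[M - 1] + ti[M - 1, 0]),
            Dv[M - 1] + td[M - 1, 0],
        )
        logC = _lse2(logC + lq_flank, e_i)
    return logC + l_leave


@njit(cache=False)
def viterbi(xs, lem, tm, ti, td, lbm, lbd, lq_flank):
    """Natural-log odds of the single best state path (same architecture)."""
    L = xs.shape[0]
    M = lem.shape[0]
    l_leave = math.log1p(-math.exp(lq_flank))

    Mv = np.full(M, NEG_INF)
    Iv = np.full(M, NEG_INF)
    Dv = np.full(M, NEG_INF)
    logN = 0.0
    Dv[0] = l_leave + lbd
    for j in range(1, M):
        Dv[j] = Dv[j - 1] + td[j - 1, 2]
    logC = Dv[M - 1] + td[M - 1, 0]

    newM = np.empty(M)
    newI = np.empty(M)
    newD = np.empty(M)
    for i in range(L):
        x = xs[i]
        entry = logN + l_leave + lbm
        for j in range(M):
            if j == 0:
                acc = entry
            else:
                acc = max(
                    Mv[j - 1] + tm[j - 1, 0],
                    Iv[j - 1] + ti[j - 1, 0],
                    Dv[j - 1] + td[j - 1, 0],
                )
            newM[j] = acc + lem[j, x]
            newI[j] = max(Mv[j] + tm[j, 1], Iv[j] + ti[j, 1], Dv[j] + td[j, 1])
        logN = logN + lq_flank
        newD[0] = logN + l_leave + lbd
        for j in range(1, M):
            newD[j] = max(
                newM[j - 1] + tm[j - 1, 2],
                newI[j - 1] + ti[j - 1, 2],
                newD[j - 1] + td[j - 1, 2],
            )
        for j in range(M):
            Mv[j] = newM[j]
            Iv[j] = newI[j]
            Dv[j] = newD[j]
        e_i = max(
            Mv[M - 1] + tm[M - 1, 0],
            Iv[M - 1] + ti[M - 1, 0],
            Dv[M - 1] + td[M - 1, 0],
        )
        logC = max(logC + lq_flank, e_i)
    return logC + l_leave
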