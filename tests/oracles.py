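"""Independent brute-force oracles, written before the implementations they check.

Kept deliberately separate from the package: the local-alignment oracle is a
plain-Python Gotoh dynamic program over Biopython's BLOSUM62 (not biotite's
aligner), and the component oracle is a plain breadth-first search.
"""

from __future__ import annotations

from collections import deque

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local affine-gap alignment score; gap of length L costs open + L*extend."""
    la, lb = len(a), len(b)
    NEG = -10**9
    H = [[0] * (lb + 1) for _ in range(la + 1)]   # end in match/mismatch or empty
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    best = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = int(_BLOSUM62[a[i - 1], b[j - 1]])
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + s,
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def bfs_components(nodes: list[str], edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    """Connected components by breadth-first search."""
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen: set[str] = set()
    out = set()
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        out.add(frozenset(comp))
    return out
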