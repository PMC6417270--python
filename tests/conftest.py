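"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results along a different route
from the package code: a naive sliding-window motif matcher, a
memoized-recursion Smith–Waterman scorer, a pure-Python list-based MCL,
and tree path lengths computed on the generating topology.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

from upomine.io_formats import CANONICAL, ProteinRecord
from upomine.motifs import default_registry, parse_pattern

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, n: int, alphabet: str = CANONICAL) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def make_record(residues: str, rid: str = "rec") -> ProteinRecord:
    return ProteinRecord(rid, residues, source="synthetic")


# --- naive sliding-window motif matcher -----------------------------------


def naive_motif_scan(pattern_str: str, residues: str) -> list[tuple[int, int, str]]:
    """Check every window position against the residue classes directly."""
    classes = parse_pattern(pattern_str)
    L = len(classes)
    out = []
    for start in range(len(residues) - L + 1):
        ok = True
        for off, cls in enumerate(classes):
            c = residues[start + off]
            if cls is None:
                continue
            if c not in cls:
                ok = False
                break
        if ok:
            window = residues[start : start + L]
            out.append((start + 1, start + L, window))
    return out


# --- independent Smith-Waterman scorer -------------------------------------


def oracle_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Best local alignment score by memoized recursion over (i, j, state).

    Affine gaps: a gap of length g costs gap_open + g*gap_extend.
    Alignments start and end on an aligned residue pair; the empty
    alignment scores 0.
    """
    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def cont(i: int, j: int, last: str) -> float:
        best = 0.0  # the alignment may end here
        if i < la and j < lb:
            best = max(best, matrix[a[i], b[j]] + cont(i + 1, j + 1, "M"))
        if i < la:
            cost = gap_extend if last == "D" else gap_open + gap_extend
            best = max(best, -cost + cont(i + 1, j, "D"))
        if j < lb:
            cost = gap_extend if last == "I" else gap_open + gap_extend
            best = max(best, -cost + cont(i, j + 1, "I"))
        return best

    best = 0.0
    for i in range(la):
        for j in range(lb):
            best = max(best, matrix[a[i], b[j]] + cont(i + 1, j + 1, "M"))
    return max(best, 0.0)


# --- pure-Python MCL fixed-point oracle ------------------------------------


def oracle_mcl_partition(
    ids: list[str],
    edges: dict,
    inflation: float,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> set[frozenset]:
    """List-based MCL run to a tight fixed point; returns the partition."""
    ids = sorted(ids)
    idx = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    M = [[0.0] * n for _ in range(n)]
    for edge, w in edges.items():
        pair = sorted(edge)
        if len(pair) == 1:
            continue
        u, v = idx[pair[0]], idx[pair[1]]
        M[u][v] = M[v][u] = float(w)
    for i in range(n):
        col_max = max(M[r][i] for r in range(n))
        M[i][i] = col_max if col_max > 0 else 1.0

    def normalize(A):
        for c in range(n):
            s = sum(A[r][c] for r in range(n))
            for r in range(n):
                A[r][c] /= s
        return A

    M = normalize(M)
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        sq = [[sum(M[r][k] * M[k][c] for k in range(n)) for c in range(n)]
              for r in range(n)]
        M = normalize([[v ** inflation for v in row] for row in sq])
        delta = max(
            abs(M[r][c] - prev[r][c]) for r in range(n) for c in range(n)
        )
        if delta < tol:
            break

    # attractor interpretation: connect i-j on positive entries
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r in range(n):
        for c in range(n):
            if M[r][c] > 1e-9:
                parent[find(r)] = find(c)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(ids[i])
    return {frozenset(g) for g in groups.values()}


# --- random additive trees for NJ ------------------------------------------


def random_additive_matrix(rng, n_taxa: int):
    """Distances realized as path lengths on a random binary tree.

    Returns (ids, matrix) where matrix[i][j] is the exact tree path
    length between taxa i and j.  Branch lengths are multiples of 0.1
    in [0.1, 1.0], so the matrix is additive by construction.
    """
    import networkx as nx

    ids = [f"T{i}" for i in range(n_taxa)]
    g = nx.Graph()
    nodes = list(ids)
    nxt = 0
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        internal = f"N{nxt}"
        nxt += 1
        g.add_edge(a, internal, weight=0.1 * int(rng.integers(1, 11)))
        g.add_edge(b, internal, weight=0.1 * int(rng.integers(1, 11)))
        nodes.append(internal)
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    D = np.zeros((n_taxa, n_taxa))
    for i, u in enumerate(ids):
        for j, v in enumerate(ids):
            if i != j:
                D[i, j] = lengths[u][v]
    D = (D + D.T) / 2  # exact symmetry against float noise
    return ids, D
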