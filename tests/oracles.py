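"""Independent brute-force oracles used only by the tests.

These re-derive expected values by direct enumeration or textbook
dynamic programming, independently of the package's implementation
paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices


def sw_affine_score(a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float) -> float:
    """Exhaustive Smith–Waterman affine-gap DP.

    Gap of length k costs gap_open + (k-1)*gap_extend. Three-state
    recurrences (match, gap-in-b, gap-in-a) with a zero floor on the
    match state.
    """
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def translate_codon_lookup(dna: str) -> str:
    """Independent codon-table translation (bacterial code), stopping at
    the first stop codon; fully ambiguous codons give X."""
    table = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
        "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
        "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
        "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
        "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
        "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
        "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
        "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
    }
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        aa = table.get(codon, "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def five_taxon_topologies(labels: list[str]):
    """All 15 unrooted binary 5-taxon topologies, each given as its pair
    of cherry bipartitions (frozensets of two labels)."""
    tops = []
    for cherry1 in combinations(labels, 2):
        rest = [l for l in labels if l not in cherry1]
        for cherry2 in combinations(rest, 2):
            pair = frozenset({frozenset(cherry1), frozenset(cherry2)})
            if pair not in tops:
                tops.append(pair)
    return tops


def _paths_for_topology(labels: list[str], cherries) -> tuple[np.ndarray, list]:
    """Design matrix mapping branch lengths to pairwise path lengths for a
    5-taxon topology (A,B)(C,D)E-style: 5 pendant + 2 internal branches."""
    (c1, c2) = [sorted(c) for c in sorted(cherries, key=sorted)]
    odd = [l for l in labels if l not in c1 + c2][0]
    order = c1 + c2 + [odd]
    branches = order + ["int1", "int2"]  # int1 joins cherry1, int2 joins cherry2
    pairs = list(combinations(sorted(labels), 2))
    X = np.zeros((len(pairs), len(branches)))
    on_path = {
        tuple(sorted(c1)): [],
        tuple(sorted(c2)): [],
    }

    def internal_between(x, y):
        inx = [x in c1, x in c2]
        iny = [y in c1, y in c2]
        used = []
        if inx != iny or (not any(inx)):
            if x in c1 or y in c1:
                used.append("int1")
            if x in c2 or y in c2:
                used.append("int2")
        return used

    for r, (x, y) in enumerate(pairs):
        X[r, branches.index(x)] = 1
        X[r, branches.index(y)] = 1
        for b in internal_between(x, y):
            X[r, branches.index(b)] = 1
    return X, pairs


def best_topology_least_squares(labels: list[str], dist: dict[tuple[str, str], float]):
    """Least-squares branch-length fit on every 5-taxon topology; returns
    the cherry-pair set of the minimum-SSQ topology."""
    labels = sorted(labels)
    best = None
    for cherries in five_taxon_topologies(labels):
        X, pairs = _paths_for_topology(labels, cherries)
        y = np.array([dist[p] for p in pairs])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssq = float(((X @ coef - y) ** 2).sum())
        if best is None or ssq < best[0] - 1e-12:
            best = (ssq, cherries)
    return best[1]
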