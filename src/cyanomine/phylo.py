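"""Poisson-corrected neighbor-joining phylogenetics for transporter proteins.

Pairwise distances use the Poisson correction d = −ln(1 − p) on the
proportion p of differing sites, with pairwise deletion of gapped
columns. Trees are built with the Saitou–Nei neighbor-joining algorithm
(Studier–Keppler Q-matrix), given bootstrap supports by column
resampling, and midpoint rooted. A bundled center-star progressive
aligner (pairwise-alignment-guided) produces the multiple alignment;
the downstream contracts are on distances, NJ, and rooting, not on
alignment identity with any particular external aligner.
"""

from __future__ import annotations

import logging
import math
from io import StringIO
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode

log = logging.getLogger(__name__)

GAP_CHARS = set("-.")


class SaturationError(ValueError):
    """Raised when a p-distance is saturated (p ≥ 1) or no sites compare."""


# ---------------------------------------------------------------------------
# distances


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites with pairwise gap deletion."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal lengths")
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise SaturationError("no comparable (gap-free) sites")
    return mismatches / compared


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = −ln(1 − p)."""
    p = p_distance(a, b)
    if p >= 1.0:
        raise SaturationError(f"saturated p-distance (p = {p})")
    return -math.log(1.0 - p)


def distance_matrix(alignment: Sequence[tuple[str, str]], columns: np.ndarray | None = None) -> DistanceMatrix:
    """Poisson-corrected distance matrix from a labeled alignment; an
    optional column index array restricts/resamples the sites."""
    labels = [name for name, _ in alignment]
    rows = [seq for _, seq in alignment]
    if columns is not None:
        rows = ["".join(seq[j] for j in columns) for seq in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(rows[i], rows[j])
    return DistanceMatrix(d, labels)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ with the Studier–Keppler Q-criterion.

    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch of the same join, preserving the
    joined pair's distance. The returned tree is unrooted, represented
    with a trifurcating root; on an additive matrix it reconstructs the
    generating topology and branch lengths exactly.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(len(labels)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi = max(0.0, vi + vj)
            vj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(vi), float(vj)
        parent = TreeNode(children=[child_i, child_j])
        nodes[i] = parent
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - dij)
        active.remove(j)

    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, v in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        node.length = float(max(0.0, v))
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def patristic_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(labels))
    return np.array([[dm[x, y] for y in labels] for x in labels])


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions as canonical tip-name sets (the side not
    containing the alphabetically first tip)."""
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    universe = frozenset(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips):
            parts.add(universe - side if ref in side else side)
    return parts


# ---------------------------------------------------------------------------
# bootstrap and rooting


def bootstrap_support(
    alignment: Sequence[tuple[str, str]],
    replicates: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree from the full alignment with per-internal-edge supports from
    column-resampled replicates (percent of replicates containing each
    original bipartition). Saturated replicates are redrawn."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible bootstrapping")
    rng = np.random.default_rng(seed)
    length = len(alignment[0][1])
    tree = neighbor_joining(distance_matrix(alignment))
    original = bipartitions(tree)
    counts = {part: 0 for part in original}
    done = attempts = 0
    while done < replicates and attempts < 20 * replicates:
        attempts += 1
        cols = rng.integers(0, length, size=length)
        try:
            rep_tree = neighbor_joining(distance_matrix(alignment, cols))
        except SaturationError:
            continue
        done += 1
        for part in bipartitions(rep_tree) & original:
            counts[part] += 1
    if done < replicates:
        log.warning("only %d/%d bootstrap replicates usable (saturation)", done, replicates)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        tips = sorted(t.name for t in tree.tips())
        if tips[0] in side:
            side = frozenset(tips) - side
        if side in counts:
            node.support = round(100.0 * counts[side] / max(done, 1))
            node.name = None
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path."""
    work = tree.copy()
    total = sum(n.length or 0.0 for n in work.traverse())
    if total == 0.0:
        log.warning("all branch lengths zero; keeping arbitrary internal root")
        return work
    return work.root_at_midpoint()


def to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def phylip_matrix(dm: DistanceMatrix) -> str:
    lines = [f"{len(dm.ids)}"]
    for label in dm.ids:
        row = " ".join(f"{dm[label, other]:.6f}" for other in dm.ids)
        lines.append(f"{label:<12s}{row}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# multiple alignment (center star)


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0  # free terminal gaps: transporter
    aligner.end_deletion_score = 0.0   # types differ by whole modules
    return aligner


def align_proteins(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Center-star progressive multiple alignment.

    The center is the sequence with the highest summed pairwise score;
    all others are aligned to it pairwise and merged under the
    once-a-gap-always-a-gap rule.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return list(seqs)
    aligner = _global_aligner()
    k = len(seqs)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            scores[i, j] = scores[j, i] = aligner.score(seqs[i][1], seqs[j][1])
    center_idx = int(np.argmax(scores.sum(axis=1)))
    center_label, center = seqs[center_idx]
    m = len(center)

    per_seq: list[tuple[int, list[str], dict[int, str]]] = []  # (orig index, aligned chars, inserts)
    max_ins = [0] * (m + 1)
    for idx, (label, seq) in enumerate(seqs):
        if idx == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        aligned = ["-"] * m
        inserts: dict[int, str] = {}
        slot = 0
        for cc, sc in zip(c_row, s_row):
            if cc == "-":
                inserts[slot] = inserts.get(slot, "") + sc
            else:
                aligned[slot] = sc
                slot += 1
        for pos, chars in inserts.items():
            max_ins[pos] = max(max_ins[pos], len(chars))
        per_seq.append((idx, aligned, inserts))

    def build_row(aligned: list[str] | None, inserts: dict[int, str]) -> str:
        out = []
        for slot in range(m + 1):
            chunk = inserts.get(slot, "")
            out.append(chunk + "-" * (max_ins[slot] - len(chunk)))
            if slot < m:
                out.append(center[slot] if aligned is None else aligned[slot])
        return "".join(out)

    rows: dict[int, str] = {center_idx: build_row(None, {})}
    for idx, aligned, inserts in per_seq:
        rows[idx] = build_row(aligned, inserts)
    return [(seqs[i][0], rows[i]) for i in range(k)]


def transporter_tree(
    named_seqs: Sequence[tuple[str, str]],
    replicates: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """Full tree pipeline for C39 transporter proteins: center-star
    alignment, Poisson distances, NJ with bootstrap supports, midpoint
    rooting."""
    aligned = align_proteins(named_seqs)
    tree = bootstrap_support(aligned, replicates=replicates, seed=seed)
    return midpoint_root(tree)
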