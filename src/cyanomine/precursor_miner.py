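"""Precursor peptide mining around bacteriocin gene clusters.

Candidate precursor ORFs are collected within a window (default ±20 kb)
around each cluster: annotated small CDS plus unannotated six-frame ORFs
in intergenic stretches, 25–170 aa. Candidates are screened for an
N-terminal leader ending in a double-glycine cleavage site, following
the consensus M(R/K)ELX₃E(I/L)X₂(I/V)XG(G/A), or for the HetP-type
leader K-I-x-D-L-x-Y-L-E-x₁₀-G-G. Matching candidates are split into
leader and core at the cleavage site, assigned to a known precursor
family (NHLP, N11P, HetP, DUF37) by similarity at E < 0.1, and profiled
for net charge, isoelectric point, and molecular weight in the style of
EMBOSS Pepstats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from .cluster_miner import GeneCluster
from .seqio import GenomeRecord, reverse_complement, translate
from .simsearch import (
    FAMILY_EVALUE,
    AlignmentParams,
    ReferenceFamily,
    evalue,
    local_align,
)

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000
DEFAULT_MIN_AA = 25
DEFAULT_MAX_AA = 170
LEADER_SEARCH_LIMIT = 70  # leaders live in the N-terminal region

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class MotifModel:
    """Position-constrained residue classes; None admits any residue."""

    name: str
    positions: tuple[frozenset | None, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def match_at(self, protein: str, offset: int) -> bool:
        if offset < 0 or offset + len(self) > len(protein):
            return False
        return all(
            allowed is None or protein[offset + i] in allowed
            for i, allowed in enumerate(self.positions)
        )


def _classes(spec: str) -> tuple[frozenset | None, ...]:
    out = []
    for token in spec.split():
        out.append(None if token == "x" else frozenset(token))
    return tuple(out)


#: double-glycine leader consensus M(R/K)ELX3E(I/L)X2(I/V)XG(G/A)
GG_LEADER = MotifModel("GG_LEADER", _classes("M RK E L x x x E IL x x IV x G GA"))

#: HetP-type leader KIxDLxYLEx10GG
HETP_LEADER = MotifModel(
    "HETP_LEADER", _classes("K I x D L x Y L E x x x x x x x x x x G G")
)


@dataclass
class MotifMatch:
    motif: str  # GG | HETP
    offset: int
    cleavage_index: int  # core starts at protein[cleavage_index:]


@dataclass
class OrfCandidate:
    """A small ORF inside a scan window, before motif screening."""

    orf_id: str
    genome_id: str
    start: int
    end: int
    strand: int
    protein: str
    annotated: bool


@dataclass
class PrecursorCandidate:
    orf_id: str
    genome_id: str
    start: int
    end: int
    strand: int
    protein: str
    motif: str  # GG | HETP | NONE
    cleavage_index: int
    leader: str
    core: str
    family: str  # NHLP | N11P | HETP | DUF37 | OTHER
    novel: bool
    net_charge: float
    isoelectric_point: float
    mol_weight: float
    cluster_group: str = "UNCLASSIFIED"
    cluster_index: int = -1

    def __post_init__(self) -> None:
        if self.leader + self.core != self.protein:
            raise ValueError("leader‖core must reconstruct the protein")

    @property
    def length(self) -> int:
        return len(self.protein)


# ---------------------------------------------------------------------------
# leader motifs


def match_leader_motif(
    protein: str,
    model: MotifModel,
    search_limit: int = LEADER_SEARCH_LIMIT,
) -> MotifMatch | None:
    """Rightmost motif match fully within the N-terminal ``search_limit``
    residues; the cleavage site follows the motif's terminal dipeptide."""
    if len(protein) < len(model):
        return None
    last = min(search_limit, len(protein)) - len(model)
    for offset in range(last, -1, -1):
        if model.match_at(protein, offset):
            name = "GG" if model.name == "GG_LEADER" else "HETP"
            return MotifMatch(name, offset, offset + len(model))
    return None


def match_permissive_gg(protein: str, search_limit: int = LEADER_SEARCH_LIMIT) -> MotifMatch | None:
    """Bare Gly-Gly / Gly-Ala dipeptide screen (permissive mode): rightmost
    G(G/A) ending within the N-terminal search window."""
    limit = min(search_limit, len(protein) - 1)
    for i in range(limit - 1, 0, -1):
        if protein[i] == "G" and protein[i + 1] in "GA":
            return MotifMatch("GG", i, i + 2)
    return None


# ---------------------------------------------------------------------------
# small-ORF scanning


def _orfs_in_segment(seq: str, offset: int, strand: int, min_aa: int, max_aa: int):
    """Maximal ORFs (first start codon to in-frame stop) in one strand of a
    window segment; coordinates are mapped back to genome space."""
    n = len(seq)
    for frame in range(3):
        prev_stop = frame  # position after the previous stop codon
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                # find the first start codon in [prev_stop, pos)
                for s in range(prev_stop, pos, 3):
                    if seq[s : s + 3] in START_CODONS:
                        aa_len = (pos - s) // 3
                        if min_aa <= aa_len <= max_aa:
                            body = seq[s + 3 : pos]
                            protein = "M" + translate(body) if body else "M"
                            if len(protein) == aa_len:  # no internal stop
                                if strand == +1:
                                    g_start, g_end = offset + s, offset + pos + 3
                                else:
                                    g_start, g_end = offset + n - (pos + 3), offset + n - s
                                yield g_start, g_end, strand, protein
                        break
                prev_stop = pos + 3


def _window_segments(genome: GenomeRecord, window: tuple[int, int]) -> list[tuple[int, str]]:
    """(offset, subsequence) segments covering the window; circular
    replicons wrap across the origin, linear ones clip at contig ends."""
    n = len(genome.sequence)
    start, end = window
    if genome.topology == "circular" and (start < 0 or end > n):
        segs = []
        lo, hi = start % n, end % n
        if start < 0:
            segs.append((lo - n, genome.sequence[lo:]))
            segs.append((0, genome.sequence[: min(end, n)]))
        else:
            segs.append((start, genome.sequence[start:n]))
            segs.append((n, genome.sequence[:hi]))
        # offsets may be outside [0, n); callers take coordinates mod n
        return segs
    clipped = (max(0, start), min(n, end))
    if clipped != (start, end):
        log.info("genome %s: window %s clipped to %s at contig ends", genome.id, window, clipped)
    return [(clipped[0], genome.sequence[clipped[0] : clipped[1]])]


def find_small_orfs(
    genome: GenomeRecord,
    window: tuple[int, int],
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
) -> list[OrfCandidate]:
    """Annotated small CDS plus unannotated intergenic six-frame ORFs in
    the window, within the [min_aa, max_aa] length bounds."""
    n = len(genome.sequence)
    out: list[OrfCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    w_lo, w_hi = max(0, window[0]), min(n, window[1])
    cds_intervals = [(f.start, f.end) for f in genome.cds]
    for f in genome.cds:
        if f.end <= w_lo or f.start >= w_hi:
            continue
        prot = f.translation
        if prot is None:
            dna = f.extract(genome.sequence)
            prot = translate(dna[: len(dna) - len(dna) % 3])
        if min_aa <= len(prot) <= max_aa:
            key = (f.start, f.end, f.strand)
            if key not in seen:
                seen.add(key)
                out.append(OrfCandidate(f.locus_tag, genome.id, f.start, f.end, f.strand, prot, True))
    for offset, seg in _window_segments(genome, window):
        for strand, s in ((+1, seg), (-1, reverse_complement(seg))):
            for g_start, g_end, st, protein in _orfs_in_segment(s, offset, strand, min_aa, max_aa):
                g_start %= n
                g_end = g_end % n or n
                if g_end <= g_start:
                    log.info("genome %s: skipping origin-crossing ORF", genome.id)
                    continue
                if any(g_start < ce and cs < g_end for cs, ce in cds_intervals):
                    continue  # not intergenic
                key = (g_start, g_end, st)
                if key in seen:
                    continue
                seen.add(key)
                orf_id = f"{genome.id}_orf_{g_start}_{g_end}_{'p' if st > 0 else 'm'}"
                out.append(OrfCandidate(orf_id, genome.id, g_start, g_end, st, protein, False))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


# ---------------------------------------------------------------------------
# family assignment and physicochemical features


def assign_family(
    protein: str,
    seed_families: dict[str, ReferenceFamily],
    threshold: float = FAMILY_EVALUE,
    params: AlignmentParams | None = None,
) -> str:
    """Family of the best-scoring seed hit with E < threshold, else OTHER."""
    params = params or AlignmentParams()
    n_db = sum(len(s) for fam in seed_families.values() for _, s in fam.members)
    best_family, best_score = "OTHER", -math.inf
    for name, family in seed_families.items():
        for _, seed in family.members:
            score, _, _ = local_align(protein, seed, params.matrix, params.gap_open, params.gap_extend)
            if score > best_score and evalue(score, len(protein), n_db, params.K, params.lam) < threshold:
                best_family, best_score = name, score
    return best_family


@lru_cache(maxsize=None)
def _pka_table() -> dict[str, float]:
    path = resources.files("cyanomine") / "data" / "pepstats_pka.tsv"
    table = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


# average residue masses (Da); X contributes a mean residue mass
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,
}
_WATER = 18.0153


def net_charge(protein: str, pH: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge over D,E,C,Y,H,K,R and the termini."""
    if not protein:
        raise ValueError("empty sequence")
    pka = _pka_table()
    counts = {aa: protein.count(aa) for aa in "DECYHKR"}
    charge = 1.0 / (1.0 + 10 ** (pH - pka["NTERM"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["CTERM"] - pH))
    for aa in "HKR":
        charge += counts[aa] / (1.0 + 10 ** (pH - pka[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (pka[aa] - pH))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def molecular_weight(protein: str) -> float:
    if not protein:
        raise ValueError("empty sequence")
    return sum(_RESIDUE_MASS[aa] for aa in protein) + _WATER


def peptide_features(protein: str) -> tuple[float, float, float]:
    """(net charge at pH 7, isoelectric point, average molecular weight)."""
    return net_charge(protein), isoelectric_point(protein), molecular_weight(protein)


# ---------------------------------------------------------------------------
# the mining driver


def screen_orf(
    orf: OrfCandidate,
    seed_families: dict[str, ReferenceFamily],
    family_threshold: float = FAMILY_EVALUE,
    permissive: bool = False,
    params: AlignmentParams | None = None,
) -> PrecursorCandidate | None:
    """Motif-screen one ORF; returns a PrecursorCandidate or None."""
    match = match_leader_motif(orf.protein, GG_LEADER)
    if match is None:
        match = match_leader_motif(orf.protein, HETP_LEADER)
    if match is None and permissive:
        match = match_permissive_gg(orf.protein)
    if match is None or match.cleavage_index >= len(orf.protein):
        return None
    leader = orf.protein[: match.cleavage_index]
    core = orf.protein[match.cleavage_index :]
    family = assign_family(orf.protein, seed_families, family_threshold, params)
    charge, pi, mw = peptide_features(orf.protein)
    return PrecursorCandidate(
        orf.orf_id, orf.genome_id, orf.start, orf.end, orf.strand, orf.protein,
        match.motif, match.cleavage_index, leader, core, family,
        novel=not orf.annotated, net_charge=charge, isoelectric_point=pi, mol_weight=mw,
    )


def mine_precursors(
    genome: GenomeRecord,
    clusters: Sequence[GeneCluster],
    seed_families: dict[str, ReferenceFamily] | None = None,
    window: int = DEFAULT_WINDOW,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
    family_threshold: float = FAMILY_EVALUE,
    permissive: bool = False,
    params: AlignmentParams | None = None,
) -> list[PrecursorCandidate]:
    """Mine precursor candidates in the windows around each cluster.

    ORFs falling into more than one cluster window are attributed to the
    nearest cluster (distance from ORF midpoint to cluster span; ties go
    to the earlier cluster and are logged).
    """
    if seed_families is None:
        from . import references

        seed_families = references.precursor_seed_families()
    member_keys = {
        (f.start, f.end) for c in clusters for f, _ in c.members if c.genome_id == genome.id
    }
    found: dict[tuple[int, int, int], tuple[OrfCandidate, int, int]] = {}
    for ci, cluster in enumerate(clusters):
        if cluster.genome_id != genome.id:
            continue
        win = (cluster.span[0] - window, cluster.span[1] + window)
        for orf in find_small_orfs(genome, win, min_aa, max_aa):
            if (orf.start, orf.end) in member_keys:
                continue
            mid = (orf.start + orf.end) // 2
            dist = max(cluster.span[0] - mid, mid - cluster.span[1], 0)
            key = (orf.start, orf.end, orf.strand)
            if key in found:
                if dist == found[key][2]:
                    log.info("ORF %s equidistant to clusters %d and %d; keeping %d",
                             orf.orf_id, found[key][1], ci, found[key][1])
                if dist < found[key][2]:
                    found[key] = (orf, ci, dist)
            else:
                found[key] = (orf, ci, dist)
    out = []
    for orf, ci, _ in found.values():
        cand = screen_orf(orf, seed_families, family_threshold, permissive, params)
        if cand is not None:
            cand.cluster_index = ci
            cand.cluster_group = clusters[ci].group
            out.append(cand)
    out.sort(key=lambda p: (p.start, p.end, p.strand))
    return out


def precursor_table(precursors: Iterable[PrecursorCandidate]) -> str:
    cols = ["id", "genome", "cluster_group", "family", "motif", "length",
            "leader", "core", "net_charge", "pI", "mol_weight", "novel",
            "start", "end", "strand"]
    lines = ["\t".join(cols)]
    for p in precursors:
        lines.append("\t".join(str(x) for x in (
            p.orf_id, p.genome_id, p.cluster_group, p.family, p.motif, p.length,
            p.leader, p.core, f"{p.net_charge:.2f}", f"{p.isoelectric_point:.2f}",
            f"{p.mol_weight:.1f}", int(p.novel), p.start, p.end, p.strand,
        )))
    return "\n".join(lines) + "\n"
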