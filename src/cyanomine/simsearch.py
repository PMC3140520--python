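"""Similarity search: local alignment with E-value significance.

A database-search layer over Smith–Waterman local alignment with affine
gaps, used to detect anchor-family homologs (transporters, HlyD, LanM,
peptidases) in a proteome and to assign precursor candidates to known
families. Significance follows Karlin–Altschul statistics,
``E = K·m·n·exp(-λS)``, with m the query length and n the summed length
of the scanned proteome, matching database-search semantics.

Gap cost convention: a gap of length k costs ``gap_open + (k-1)·gap_extend``
(the opening charge covers the first gapped residue).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import GenomeRecord, read_fasta

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_PROTEIN = set(AMINO_ACIDS + "X")

# Karlin-Altschul constants for gapped BLOSUM62 (11/1) searches.
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267

ANCHOR_EVALUE = 1e-5    # anchor-protein screens
FAMILY_EVALUE = 0.1     # precursor family assignment
DOMAIN_EVALUE = 1e-3    # short intra-protein domains

FAMILY_NAMES = (
    "C39_ABC_TRANSPORTER", "HLYD", "LANM", "SURA", "S8_PEPTIDASE",
    "M16_PEPTIDASE", "ABC_NO_PEPTIDASE",
    "NHLP_SEED", "N11P_SEED", "HETP_SEED", "DUF37_SEED",
)


@dataclass
class ReferenceFamily:
    """A named set of reference protein sequences used as search queries."""

    name: str
    members: list[tuple[str, str]]  # (id, sequence)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference family {self.name} has no members")
        for mid, seq in self.members:
            bad = set(seq) - _VALID_PROTEIN
            if bad:
                raise ValueError(f"{self.name}/{mid}: non-amino-acid characters {sorted(bad)}")


@dataclass
class AnchorHit:
    query_family: str
    subject_locus: str
    score: float
    evalue: float
    aligned_span: tuple[int, int]  # subject coordinates, half-open

    def __post_init__(self) -> None:
        if self.evalue < 0 or not math.isfinite(self.score):
            raise ValueError("invalid hit statistics")


@dataclass
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float = DEFAULT_K
    lam: float = DEFAULT_LAMBDA


def _check_protein(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"empty {what} sequence")
    bad = set(seq) - _VALID_PROTEIN
    if bad:
        raise ValueError(f"{what}: non-amino-acid characters {sorted(bad)}")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = mode
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    with_spans: bool = True,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Optimal Smith–Waterman local score of a vs b with affine gaps.

    Returns (score, a_span, b_span) with half-open outermost aligned
    intervals; spans are (0, 0) when with_spans=False or the optimal
    score is 0.
    """
    _check_protein(a, "first")
    _check_protein(b, "second")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    if not with_spans:
        return float(aligner.score(a, b)), (0, 0), (0, 0)
    alignments = aligner.align(a, b)
    score = float(alignments.score)
    if score <= 0:
        return score, (0, 0), (0, 0)
    aln = alignments[0]
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return score, a_span, b_span


def evalue(raw_score: float, m: int, n: int, K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(-λS)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return K * m * n * math.exp(-lam * raw_score)


def scan_proteome(
    genome: GenomeRecord,
    family: ReferenceFamily,
    threshold: float = ANCHOR_EVALUE,
    params: AlignmentParams | None = None,
    database_length: int | None = None,
) -> list[AnchorHit]:
    """Best hit per CDS against a reference family, kept when E < threshold.

    ``database_length`` (n in the E-value) defaults to the summed length
    of the scanned proteome; pass the multi-genome total when scanning a
    genome collection so E-values share one database size.
    """
    params = params or AlignmentParams()
    proteome = genome.proteome()
    if not proteome:
        log.warning("genome %s has no CDS translations; empty scan", genome.id)
        return []
    n_db = database_length if database_length is not None else sum(len(p) for _, p in proteome)
    hits = []
    for locus, protein in sorted(proteome):
        if not protein:
            continue
        best = None
        for _, query in family.members:
            score, _, span = local_align(
                query, protein, params.matrix, params.gap_open, params.gap_extend
            )
            e = evalue(score, len(query), n_db, params.K, params.lam)
            if best is None or score > best[0]:
                best = (score, e, span)
        score, e, span = best
        if e < threshold:
            hits.append(AnchorHit(family.name, locus, score, e, span))
    return hits


def load_reference_families(path: str | Path) -> dict[str, ReferenceFamily]:
    """Read reference families from FASTA; the family name is the first
    whitespace-separated token of the description after the sequence id
    (``>seq_id FAMILY_NAME``), falling back to the id itself."""
    groups: dict[str, list[tuple[str, str]]] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        fam = parts[1] if len(parts) > 1 else rec.id
        groups.setdefault(fam, []).append((rec.id, str(rec.seq).upper()))
    return {name: ReferenceFamily(name, members) for name, members in groups.items()}


def hits_table(hits: Iterable[AnchorHit]) -> str:
    lines = ["family\tlocus_tag\tscore\tevalue\tsubject_start\tsubject_end"]
    for h in hits:
        lines.append(
            f"{h.query_family}\t{h.subject_locus}\t{h.score:.1f}\t{h.evalue:.3g}\t{h.aligned_span[0]}\t{h.aligned_span[1]}"
        )
    return "\n".join(lines) + "\n"
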