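"""Synthetic genomes with planted bacteriocin gene clusters and precursors.

Every pipeline stage is testable offline: the generator plants gene
clusters of each architecture group, precursor ORFs with the stated
leader motifs inside the ±20 kb windows, motif-free decoy ORFs, and
records everything in a truth table.

How proteins are synthesized
----------------------------
Anchor proteins are concatenations of the bundled domain seed proteins.
C39 transporter lineages carry hierarchical divergence so that the
synthetic data reproduces the clade structure of real transporter
phylogenies: the long, short, and fused types each diverge from the
base concatenation at ``type_divergence`` (default 0.15 substitutions
per site), each cluster group's transporter diverges from its type
ancestor at ``group_divergence`` (default 0.05), and individual genes
add ``mutation_rate`` noise on top. Precursors are mutated copies of
the bundled family seeds; genes are back-translated with uniform
synonymous codons (bacterial code) and planted on either strand.
``mutation_rate`` is applied in protein space (substitutions never
create internal stops), which is what the protein-level screens see.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from . import references
from .precursor_miner import GG_LEADER, HETP_LEADER, match_leader_motif
from .seqio import GeneFeature, GenomeRecord, reverse_complement
from .simsearch import AMINO_ACIDS

log = logging.getLogger(__name__)


class PlanError(ValueError):
    """Raised when planted objects cannot be placed as requested."""


GROUP_ROLES: dict[str, list[str]] = {
    "I": ["TRANSPORTER_LONG", "HLYD", "SURA"],
    "II": ["TRANSPORTER_LONG", "HLYD", "SURA", "M16_PROTEIN"],
    "III": ["TRANSPORTER_SHORT", "HLYD"],
    "IV": ["LANM", "TRANSPORTER_SHORT", "HLYD", "ABC_NO_PEPTIDASE"],
    "V": ["TRANSPORTER_SHORT", "ABC_NO_PEPTIDASE", "HLYD", "CAP_ED_BIMODULAR"],
    "VI": ["TRANSPORTER_LONG", "S8_PROTEIN", "HLYD", "SURA"],
    "VII": ["TRANSPORTER_FUSED", "HLYD"],
    "UNCLASSIFIED": ["HLYD"],
}

FAMILY_MOTIF = {"NHLP": "GG", "N11P": "GG", "DUF37": "GG", "HETP": "HETP"}

_CLUSTER_SPACING = 60_000
_EDGE_MARGIN = 30_000
_PRECURSOR_STEP = 1_200
_PLACEMENT_MARGIN = 30

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


@dataclass
class PlannedCluster:
    group: str
    replicon: int = 0
    position: int | None = None
    roles: list[str] | None = None
    orientation: list[int] | None = None

    def member_roles(self) -> list[str]:
        return list(self.roles) if self.roles is not None else list(GROUP_ROLES[self.group])


@dataclass
class PlannedPrecursor:
    family: str  # NHLP | N11P | HETP | DUF37
    cluster: int = 0
    offset: int | None = None  # nt from cluster span to ORF start; None = auto slot
    strand: int = +1
    annotated: bool = False


@dataclass
class SyntheticPlan:
    seed: int
    clusters: list[PlannedCluster] = field(default_factory=list)
    precursors: list[PlannedPrecursor] = field(default_factory=list)
    n_replicons: int = 1
    replicon_length: int | None = None  # None = auto-sized
    mutation_rate: float = 0.0
    decoys: int = 0
    type_divergence: float = 0.15
    group_divergence: float = 0.05
    sources: list[str] | None = None      # per replicon; default chromosome
    topologies: list[str] | None = None   # per replicon; default linear


@dataclass
class TruthRecord:
    id: str
    kind: str  # cluster | gene | precursor | decoy
    replicon: str
    start: int
    end: int
    strand: int
    group: str = ""
    family: str = ""
    motif: str = ""
    role: str = ""
    cleavage_index: int = -1
    novel: bool = False
    protein: str = ""


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_tsv(self) -> str:
        cols = ["id", "kind", "replicon", "start", "end", "strand", "group",
                "family", "motif", "role", "cleavage_index", "novel", "protein"]
        lines = ["\t".join(cols)]
        for r in self.records:
            lines.append("\t".join(str(getattr(r, c)) for c in cols))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps([r.__dict__ for r in self.records], indent=2)


# ---------------------------------------------------------------------------
# sequence synthesis helpers


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution to a uniformly chosen different residue."""
    if rate <= 0:
        return protein
    out = []
    for aa in protein:
        if rng.random() < rate:
            pool = AMINO_ACIDS.replace(aa, "") if aa in AMINO_ACIDS else AMINO_ACIDS
            out.append(pool[rng.integers(0, len(pool))])
        else:
            out.append(aa)
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codons under the bacterial code."""
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def _random_dna(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _transporter_lineages(plan: SyntheticPlan, rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """Per-group transporter ancestors with hierarchical divergence."""
    c39 = references._seed("C39_PEPTIDASE")
    tm = references._seed("ABC_TM_REGION")
    atp = references._seed("ATP_BINDING_CASSETTE")
    cap = references._seed("CAP_ED")
    core = c39 + tm + atp
    td = plan.type_divergence
    type_anc = {
        "TRANSPORTER_SHORT": mutate_protein(core, td, rng),
        "TRANSPORTER_LONG": mutate_protein(cap, td, rng) + mutate_protein(core, td, rng),
    }
    type_anc["TRANSPORTER_FUSED"] = type_anc["TRANSPORTER_SHORT"] + mutate_protein(tm + atp, td, rng)
    out: dict[str, dict[str, str]] = {}
    for group in GROUP_ROLES:
        out[group] = {
            role: mutate_protein(anc, plan.group_divergence, rng)
            for role, anc in type_anc.items()
        }
    return out


def _role_protein(
    role: str, group: str, lineages: dict[str, dict[str, str]], rng: np.random.Generator, rate: float
) -> str:
    if role in ("TRANSPORTER_LONG", "TRANSPORTER_SHORT", "TRANSPORTER_FUSED"):
        base = lineages[group][role]
    elif role == "ABC_NO_PEPTIDASE":
        base = (
            references._seed("CAP_ED")
            + references._seed("ABC_TM_REGION")
            + references._seed("ATP_BINDING_CASSETTE")
        )
    elif role == "CAP_ED_BIMODULAR":
        cap = references._seed("CAP_ED")
        base = cap + cap
    else:
        seed_domain = {
            "HLYD": "TYPE_I_HLYD", "SURA": "ROTAMASE", "LANM": "LANM",
            "S8_PROTEIN": "S8_PEPTIDASE", "M16_PROTEIN": "M16_PEPTIDASE",
        }[role]
        base = references._seed(seed_domain)
    return mutate_protein(base, rate, rng)


def _random_decoy_protein(rng: np.random.Generator) -> str:
    """A small motif-free protein (checked against both leader models)."""
    for _ in range(100):
        length = int(rng.integers(30, 61))
        body = "".join(AMINO_ACIDS[rng.integers(0, 20)] for _ in range(length - 1))
        protein = "M" + body
        if match_leader_motif(protein, GG_LEADER) is None and match_leader_motif(protein, HETP_LEADER) is None:
            return protein
    raise PlanError("could not draw a motif-free decoy")  # pragma: no cover


# ---------------------------------------------------------------------------
# generation


class _Replicon:
    def __init__(self, idx: int, length: int, rng: np.random.Generator):
        self.id = f"SYNREP{idx + 1}"
        self.seq = _random_dna(length, rng)
        self.occupied: list[tuple[int, int]] = []
        self.features: list[GeneFeature] = []

    def reserve(self, start: int, end: int, what: str) -> None:
        if start < 0 or end > len(self.seq):
            raise PlanError(f"{what}: interval [{start}, {end}) outside replicon {self.id}")
        for s, e in self.occupied:
            if start < e + _PLACEMENT_MARGIN and s < end + _PLACEMENT_MARGIN:
                raise PlanError(f"{what}: overlaps an existing planted object on {self.id}")
        self.occupied.append((start, end))

    def write(self, start: int, dna: str) -> None:
        arr = np.frombuffer(dna.encode(), dtype=np.uint8)
        idx = np.zeros(len(arr), dtype=np.int64)
        for i, b in enumerate(_BASES):
            idx[arr == b] = i
        self.seq[start : start + len(arr)] = idx

    def to_record(self, topology: str, source: str) -> GenomeRecord:
        seq = bytes(_BASES[self.seq]).decode()
        return GenomeRecord(self.id, seq, list(self.features), topology=topology, source=source)


def _plant_gene(
    rep: _Replicon, start: int, protein: str, strand: int, tag: str,
    annotated: bool, rng: np.random.Generator, what: str,
) -> tuple[int, int]:
    dna = back_translate(protein, rng) + "TAA"
    if not annotated:
        dna = "TAA" + dna  # in-frame guard so the ORF starts at the planted ATG
    if strand == -1:
        dna = reverse_complement(dna)
    end = start + len(dna)
    rep.reserve(start, end, what)
    rep.write(start, dna)
    if annotated:
        rep.features.append(GeneFeature(tag, start, end, strand, kind="CDS", translation=protein))
        return start, end
    # truth coordinates of the ORF itself (guard excluded)
    if strand == +1:
        return start + 3, end
    return start, end - 3


def generate(plan: SyntheticPlan) -> tuple[list[GenomeRecord], TruthTable]:
    """Materialize a plan into GenomeRecords plus a truth table.

    Deterministic: the same plan (including seed) yields byte-identical
    output. Raises PlanError before emitting anything when placements
    overlap or fall outside a replicon.
    """
    rng = np.random.default_rng(plan.seed)
    per_rep = [sum(1 for c in plan.clusters if c.replicon == ri) for ri in range(plan.n_replicons)]
    if any(c.replicon >= plan.n_replicons for c in plan.clusters):
        raise PlanError("cluster assigned to a replicon outside the plan")
    length = plan.replicon_length or (_CLUSTER_SPACING * max(max(per_rep, default=0), 1) + 2 * _EDGE_MARGIN)
    reps = [_Replicon(ri, length, rng) for ri in range(plan.n_replicons)]
    lineages = _transporter_lineages(plan, rng)
    leader_lengths = references.precursor_leader_lengths()
    seeds = references.precursor_seed_families()

    truth: list[TruthRecord] = []
    gene_counter = 0
    spans: list[tuple[int, tuple[int, int]]] = []  # (replicon idx, cluster span)

    # clusters
    rep_slot = [0] * plan.n_replicons
    for ci, pc in enumerate(plan.clusters):
        rep = reps[pc.replicon]
        if pc.position is not None:
            start = pc.position
        else:
            start = _EDGE_MARGIN + rep_slot[pc.replicon] * _CLUSTER_SPACING
            rep_slot[pc.replicon] += 1
        roles = pc.member_roles()
        orientation = pc.orientation or [+1] * len(roles)
        if len(orientation) != len(roles):
            raise PlanError(f"cluster {ci}: orientation pattern length mismatch")
        cur = start
        gene_intervals = []
        for role, strand in zip(roles, orientation):
            protein = _role_protein(role, pc.group, lineages, rng, plan.mutation_rate)
            gene_counter += 1
            tag = f"SYN_{gene_counter:04d}"
            s, e = _plant_gene(rep, cur, protein, strand, tag, True, rng, f"cluster {ci} gene {role}")
            truth.append(TruthRecord(tag, "gene", rep.id, s, e, strand, group=pc.group, role=role, protein=protein))
            gene_intervals.append((s, e))
            cur = e + int(rng.integers(120, 240))
        span = (min(s for s, _ in gene_intervals), max(e for _, e in gene_intervals))
        spans.append((pc.replicon, span))
        truth.append(TruthRecord(f"cluster_{ci}", "cluster", rep.id, span[0], span[1], +1, group=pc.group))

    # precursors and decoys share per-cluster slot counters
    slot_counter = [0] * max(len(plan.clusters), 1)

    def next_position(cluster_idx: int, approx_len: int, offset: int | None) -> int:
        ri, span = spans[cluster_idx]
        if offset is None:
            slot = slot_counter[cluster_idx]
            slot_counter[cluster_idx] += 1
            k = slot // 2 + 1
            offset = _PRECURSOR_STEP * k if slot % 2 == 0 else -_PRECURSOR_STEP * k
        if offset >= 0:
            pos = span[1] + offset
            dist = offset + approx_len
        else:
            pos = span[0] + offset
            dist = -offset
            if -offset < approx_len:
                raise PlanError("upstream precursor overlaps its cluster")
        if dist > 20_000:
            raise PlanError("precursor offset exceeds the 20 kb window")
        return pos

    for pi, pp in enumerate(plan.precursors):
        if pp.cluster >= len(plan.clusters):
            raise PlanError(f"precursor {pi} references missing cluster {pp.cluster}")
        fam = pp.family
        if fam not in seeds:
            raise PlanError(f"unknown precursor family {fam}")
        members = seeds[fam].members
        mi = int(rng.integers(0, len(members)))
        seed_id, seed_seq = members[mi]
        protein = mutate_protein(seed_seq, plan.mutation_rate, rng)
        ri, _ = spans[pp.cluster]
        rep = reps[ri]
        approx = 3 * len(protein) + 9
        pos = next_position(pp.cluster, approx, pp.offset)
        gene_counter += 1
        tag = f"SYN_{gene_counter:04d}" if pp.annotated else f"prec_{pi}"
        s, e = _plant_gene(rep, pos, protein, pp.strand, tag, pp.annotated, rng, f"precursor {pi}")
        truth.append(TruthRecord(
            tag, "precursor", rep.id, s, e, pp.strand,
            family=fam, motif=FAMILY_MOTIF[fam], cleavage_index=leader_lengths[seed_id],
            novel=not pp.annotated, protein=protein,
            group=plan.clusters[pp.cluster].group,
        ))

    if plan.decoys and not plan.clusters:
        raise PlanError("decoys are planted relative to clusters; plan has none")
    for di in range(plan.decoys):
        cluster_idx = di % max(len(plan.clusters), 1)
        ri, _ = spans[cluster_idx]
        rep = reps[ri]
        protein = _random_decoy_protein(rng)
        annotated = di % 2 == 0
        strand = +1 if di % 4 < 2 else -1
        approx = 3 * len(protein) + 9
        pos = next_position(cluster_idx, approx, None)
        gene_counter += 1
        tag = f"SYN_{gene_counter:04d}" if annotated else f"decoy_{di}"
        s, e = _plant_gene(rep, pos, protein, strand, tag, annotated, rng, f"decoy {di}")
        truth.append(TruthRecord(tag, "decoy", rep.id, s, e, strand, novel=not annotated, protein=protein))

    sources = plan.sources or ["chromosome"] * plan.n_replicons
    topologies = plan.topologies or ["linear"] * plan.n_replicons
    genomes = [rep.to_record(topologies[ri], sources[ri]) for ri, rep in enumerate(reps)]
    return genomes, TruthTable(truth)


# ---------------------------------------------------------------------------
# stock plans (the study conditions used by the tests)


def seven_group_plan(seed: int, mutation_rate: float = 0.0) -> SyntheticPlan:
    """One cluster of each of the seven groups on a single replicon."""
    clusters = [PlannedCluster(group=g) for g in ("I", "II", "III", "IV", "V", "VI", "VII")]
    return SyntheticPlan(seed=seed, clusters=clusters, mutation_rate=mutation_rate)


def precursor_plan(
    seed: int,
    n_precursors: int = 30,
    decoys: int = 30,
    mutation_rate: float = 0.0,
) -> SyntheticPlan:
    """Two clusters with planted precursors of all four families, mixed
    strands and annotation states, plus motif-free decoys."""
    clusters = [PlannedCluster(group="II"), PlannedCluster(group="V")]
    fams = ["NHLP", "N11P", "HETP", "DUF37"]
    precursors = [
        PlannedPrecursor(
            family=fams[i % 4],
            cluster=i % 2,
            strand=+1 if (i // 2) % 2 == 0 else -1,
            annotated=i % 3 == 0,
        )
        for i in range(n_precursors)
    ]
    return SyntheticPlan(
        seed=seed, clusters=clusters, precursors=precursors,
        decoys=decoys, mutation_rate=mutation_rate,
    )
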