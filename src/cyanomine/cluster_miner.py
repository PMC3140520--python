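"""Cluster assembly and seven-group classification.

Anchor-bearing genes are chained into candidate gene clusters by
single-linkage co-location (intergenic gap ≤ ``max_gap``, strand
ignored) and each cluster is classified from the multiset of member
roles into groups I–VII or UNCLASSIFIED:

I    long-type transporter clusters (HlyD and SurA typical)
II   group I plus additional modification genes (e.g. M16 peptidase)
III  short-type transporter clusters
IV   LanM (lanthionine synthetase) clusters — lantipeptides
V    short-type transporter plus a peptidase-free ABC transporter
VI   S8 peptidase with a long-type transporter
VII  transporter fusion clusters
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .architecture import ProteinArchitecture
from .seqio import GeneFeature, GenomeRecord
from .simsearch import AnchorHit

log = logging.getLogger(__name__)

GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII", "UNCLASSIFIED")

DEFAULT_MAX_GAP = 10_000

_MODIFICATION_ROLES = {"M16_PROTEIN", "OTHER"}
_TRANSPORTER_ROLES = {"TRANSPORTER_LONG", "TRANSPORTER_SHORT", "TRANSPORTER_FUSED"}


@dataclass
class GeneCluster:
    genome_id: str
    members: list[tuple[GeneFeature, ProteinArchitecture]]
    span: tuple[int, int]
    group: str
    on_plasmid: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster without members")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group}")

    @property
    def roles(self) -> list[str]:
        return [arch.role for _, arch in self.members]

    def transporters(self) -> list[tuple[GeneFeature, ProteinArchitecture]]:
        """Members carrying a C39 peptidase transporter role (tree input)."""
        return [(f, a) for f, a in self.members if a.role in _TRANSPORTER_ROLES]


def classify_cluster(roles: Iterable[str]) -> str:
    """Group label from the multiset of member roles; first matching rule wins."""
    roles = list(roles)
    have = set(roles)
    matched = []
    if "TRANSPORTER_FUSED" in have:
        matched.append("VII")
    if "LANM" in have and (have & (_TRANSPORTER_ROLES | {"ABC_NO_PEPTIDASE"})):
        matched.append("IV")
    if "S8_PROTEIN" in have and "TRANSPORTER_LONG" in have:
        matched.append("VI")
    if "TRANSPORTER_SHORT" in have and "ABC_NO_PEPTIDASE" in have:
        matched.append("V")
    if "TRANSPORTER_SHORT" in have and "ABC_NO_PEPTIDASE" not in have and "LANM" not in have:
        matched.append("III")
    if "TRANSPORTER_LONG" in have and "SURA" in have and (have & _MODIFICATION_ROLES):
        matched.append("II")
    if "TRANSPORTER_LONG" in have:
        matched.append("I")
    if not matched:
        return "UNCLASSIFIED"
    if len(matched) > 1:
        log.debug("cluster matched rules %s; keeping %s", matched, matched[0])
    return matched[0]


def build_clusters(
    hits: Sequence[AnchorHit],
    architectures: Mapping[str, ProteinArchitecture],
    genome: GenomeRecord,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GeneCluster]:
    """Single-linkage chaining of anchor-bearing CDS into clusters.

    Chains break when the intergenic gap between consecutive anchor
    genes exceeds ``max_gap`` (default 10 kb). Strand is ignored:
    divergently transcribed members still belong to one cluster.
    """
    anchor_tags = {h.subject_locus for h in hits}
    by_tag = {f.locus_tag: f for f in genome.cds}
    missing = anchor_tags - set(by_tag)
    if missing:
        raise ValueError(f"hits reference CDS absent from genome {genome.id}: {sorted(missing)}")
    anchors = sorted((by_tag[t] for t in anchor_tags), key=lambda f: (f.start, f.end))
    if not anchors:
        return []
    chains: list[list[GeneFeature]] = [[anchors[0]]]
    for feat in anchors[1:]:
        prev = chains[-1][-1]
        if feat.start - prev.end <= max_gap:
            chains[-1].append(feat)
        else:
            chains.append([feat])
    clusters = []
    for chain in chains:
        members = [(f, architectures[f.locus_tag]) for f in chain]
        span = (min(f.start for f in chain), max(f.end for f in chain))
        group = classify_cluster(a.role for _, a in members)
        clusters.append(
            GeneCluster(genome.id, members, span, group, on_plasmid=(genome.source == "plasmid"))
        )
    return clusters


def cluster_table(clusters: Iterable[GeneCluster]) -> str:
    lines = ["genome\tgroup\tstart\tend\tn_members\ton_plasmid\tmember_roles"]
    for c in clusters:
        lines.append(
            f"{c.genome_id}\t{c.group}\t{c.span[0]}\t{c.span[1]}\t{len(c.members)}"
            f"\t{int(c.on_plasmid)}\t{','.join(c.roles)}"
        )
    return "\n".join(lines) + "\n"


def clusters_json(clusters: Iterable[GeneCluster]) -> str:
    payload = [
        {
            "genome": c.genome_id,
            "group": c.group,
            "span": list(c.span),
            "on_plasmid": c.on_plasmid,
            "members": [
                {
                    "locus_tag": f.locus_tag,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "role": a.role,
                    "domains": a.domain_string(),
                }
                for f, a in c.members
            ],
        }
        for c in clusters
    ]
    return json.dumps(payload, indent=2)
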