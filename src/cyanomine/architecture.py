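"""Domain architecture annotation and transporter-role assignment.

Each anchor protein is tiled with domains from a closed vocabulary
(C39 peptidase, ABC transmembrane region, ATP-binding cassette, CAP_ED,
type-I HlyD, rotamase, LanM, S8/M16 peptidase, DUF37) and the ordered
tiling is mapped deterministically to a functional role. The roles are
the vocabulary of the seven-group cluster classification: the short-type
transporter is C39‖TM‖ATPase, the long type carries an extra N-terminal
CAP_ED nucleotide-binding extension (~300 aa), and the fused type joins
a short transporter with a second peptidase-free ABC transporter module.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import references
from .simsearch import (
    DOMAIN_EVALUE,
    AlignmentParams,
    ReferenceFamily,
    evalue,
    local_align,
)

log = logging.getLogger(__name__)

ROLES = (
    "TRANSPORTER_LONG", "TRANSPORTER_SHORT", "TRANSPORTER_FUSED",
    "ABC_NO_PEPTIDASE", "HLYD", "SURA", "LANM", "S8_PROTEIN", "M16_PROTEIN",
    "CAP_ED_BIMODULAR", "OTHER",
)

# long-type geometry: CAP_ED extension starts near the N terminus and
# pushes the C39 peptidase well into the protein (~300 aa extension)
_CAP_ED_MAX_START = 350
_LONG_C39_MIN_START = 200

_MAX_HITS_PER_DOMAIN = 6
_OVERLAP_FRACTION = 0.20


@dataclass
class DomainAnnotation:
    domain: str
    interval: tuple[int, int]  # protein coordinates, half-open
    score: float

    def __post_init__(self) -> None:
        if self.domain not in references.DOMAIN_NAMES:
            raise ValueError(f"unknown domain {self.domain}")

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class ProteinArchitecture:
    locus_tag: str
    domains: list[DomainAnnotation]  # ordered N -> C
    role: str

    def domain_string(self) -> str:
        short = {
            "C39_PEPTIDASE": "C39", "ABC_TM_REGION": "TM",
            "ATP_BINDING_CASSETTE": "ATPase", "CAP_ED": "CAP_ED",
            "TYPE_I_HLYD": "HlyD", "ROTAMASE": "Rotamase", "LANM": "LanM",
            "S8_PEPTIDASE": "S8", "M16_PEPTIDASE": "M16", "DUF37": "DUF37",
        }
        return "+".join(short[d.domain] for d in self.domains)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def annotate_domains(
    protein: str,
    domain_refs: dict[str, ReferenceFamily] | None = None,
    threshold: float = DOMAIN_EVALUE,
    params: AlignmentParams | None = None,
) -> list[DomainAnnotation]:
    """Greedy best non-overlapping domain tiling of one protein.

    Repeats of the same domain (needed for the fused transporter's two
    ATP-binding cassettes) are found by masking accepted matches with X
    and re-aligning. Candidate matches are kept when E < ``threshold``
    with m·n the query and protein lengths; overlaps exceeding 20% of the
    shorter interval are resolved in favor of the higher score.
    """
    if not protein:
        return []
    domain_refs = domain_refs or references.domain_reference_families()
    params = params or AlignmentParams()
    candidates: list[DomainAnnotation] = []
    for name, family in domain_refs.items():
        masked = protein
        for _ in range(_MAX_HITS_PER_DOMAIN):
            best = None
            for _, query in family.members:
                score, _, span = local_align(query, masked, params.matrix, params.gap_open, params.gap_extend)
                if best is None or score > best[0]:
                    best = (score, span, len(query))
            score, span, qlen = best
            if span[1] <= span[0]:
                break
            e = evalue(score, qlen, len(protein), params.K, params.lam)
            if e >= threshold:
                break
            candidates.append(DomainAnnotation(name, span, score))
            masked = masked[: span[0]] + "X" * (span[1] - span[0]) + masked[span[1] :]
    # greedy tiling by descending score
    accepted: list[DomainAnnotation] = []
    for cand in sorted(candidates, key=lambda d: -d.score):
        if all(
            _overlap(cand.interval, a.interval) <= _OVERLAP_FRACTION * min(cand.length, a.length)
            for a in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda d: d.start)
    return accepted


def assign_role(domains: Sequence[DomainAnnotation], length: int) -> str:
    """Deterministic role from an ordered domain list.

    Precedence: fused transporter (two ATP-binding cassettes, one C39),
    then long/short transporter, peptidase-free ABC transporter,
    CAP_ED-bimodular, then single-domain roles; anything else is OTHER.
    """
    ordered = sorted(domains, key=lambda d: d.start)
    counts = Counter(d.domain for d in ordered)
    has = lambda n: counts[n] > 0  # noqa: E731

    if counts["ATP_BINDING_CASSETTE"] >= 2 and counts["C39_PEPTIDASE"] == 1:
        return "TRANSPORTER_FUSED"
    if has("C39_PEPTIDASE") and has("ABC_TM_REGION") and has("ATP_BINDING_CASSETTE"):
        c39_start = min(d.start for d in ordered if d.domain == "C39_PEPTIDASE")
        cap_starts = [d.start for d in ordered if d.domain == "CAP_ED"]
        if cap_starts and min(cap_starts) <= _CAP_ED_MAX_START and c39_start >= _LONG_C39_MIN_START:
            return "TRANSPORTER_LONG"
        if not cap_starts:
            return "TRANSPORTER_SHORT"
        return "OTHER"
    if has("ABC_TM_REGION") and has("ATP_BINDING_CASSETTE") and not has("C39_PEPTIDASE"):
        return "ABC_NO_PEPTIDASE"
    if counts["CAP_ED"] == 2 and sum(counts.values()) == 2:
        return "CAP_ED_BIMODULAR"
    for domain, role in (
        ("LANM", "LANM"),
        ("S8_PEPTIDASE", "S8_PROTEIN"),
        ("M16_PEPTIDASE", "M16_PROTEIN"),
        ("TYPE_I_HLYD", "HLYD"),
        ("ROTAMASE", "SURA"),
    ):
        if has(domain):
            return role
    return "OTHER"


def annotate_protein(
    locus_tag: str,
    protein: str,
    domain_refs: dict[str, ReferenceFamily] | None = None,
    threshold: float = DOMAIN_EVALUE,
    params: AlignmentParams | None = None,
) -> ProteinArchitecture:
    domains = annotate_domains(protein, domain_refs, threshold, params)
    return ProteinArchitecture(locus_tag, domains, assign_role(domains, len(protein)))


def architecture_table(architectures: Iterable[ProteinArchitecture]) -> str:
    lines = ["locus_tag\trole\tdomains"]
    for a in architectures:
        lines.append(f"{a.locus_tag}\t{a.role}\t{a.domain_string()}")
    return "\n".join(lines) + "\n"
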