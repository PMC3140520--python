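"""Bundled reference fixtures: domain seeds, anchor families, precursor seeds.

The bundled FASTA files are SYNTHETIC sequences generated once with a
fixed random seed; they stand in for curated domain and family
representatives so the whole pipeline is exercisable offline. Real
screens substitute curated FASTA files via
:func:`cyanomine.simsearch.load_reference_families`.

Anchor families are composed from the domain seeds the same way the
biological proteins are composed from domains: the C39
peptidase-containing ABC transporter is C39‖TM‖ATPase (short type) with
an additional CAP_ED-prefixed long-type member, and the peptidase-free
ABC transporter is CAP_ED‖TM‖ATPase.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .simsearch import ReferenceFamily

DOMAIN_NAMES = (
    "C39_PEPTIDASE", "ABC_TM_REGION", "ATP_BINDING_CASSETTE", "CAP_ED",
    "TYPE_I_HLYD", "ROTAMASE", "LANM", "S8_PEPTIDASE", "M16_PEPTIDASE", "DUF37",
)

PRECURSOR_FAMILIES = ("NHLP", "N11P", "HETP", "DUF37")


def _data_path(name: str):
    return resources.files("cyanomine") / "data" / name


def _read_family_fasta(name: str) -> dict[str, list[tuple[str, str]]]:
    groups: dict[str, list[tuple[str, str]]] = {}
    with resources.as_file(_data_path(name)) as path:
        for line_block in path.read_text().split(">")[1:]:
            lines = line_block.strip().splitlines()
            header = lines[0].split()
            seq = "".join(lines[1:])
            fam = header[1] if len(header) > 1 else header[0]
            groups.setdefault(fam, []).append((header[0], seq))
    return groups


@lru_cache(maxsize=None)
def domain_seeds() -> dict[str, list[tuple[str, str]]]:
    """Per-domain seed protein sequences (synthetic fixtures)."""
    return _read_family_fasta("synthetic_domain_seeds.faa")


@lru_cache(maxsize=None)
def domain_reference_families() -> dict[str, ReferenceFamily]:
    return {name: ReferenceFamily(name, members) for name, members in domain_seeds().items()}


def _seed(domain: str, idx: int = 0) -> str:
    return domain_seeds()[domain][idx][1]


@lru_cache(maxsize=None)
def anchor_reference_families() -> dict[str, ReferenceFamily]:
    """Anchor-protein query families for the genome-wide homolog screens."""
    c39 = _seed("C39_PEPTIDASE")
    tm = _seed("ABC_TM_REGION")
    atp = _seed("ATP_BINDING_CASSETTE")
    cap = _seed("CAP_ED")
    fams = {
        "C39_ABC_TRANSPORTER": [
            ("c39abc_short", c39 + tm + atp),
            ("c39abc_long", cap + c39 + tm + atp),
        ],
        "ABC_NO_PEPTIDASE": [("abc_nopep", cap + tm + atp)],
        "HLYD": [(mid, s) for mid, s in domain_seeds()["TYPE_I_HLYD"]],
        "SURA": [(mid, s) for mid, s in domain_seeds()["ROTAMASE"]],
        "LANM": [(mid, s) for mid, s in domain_seeds()["LANM"]],
        "S8_PEPTIDASE": [(mid, s) for mid, s in domain_seeds()["S8_PEPTIDASE"]],
        "M16_PEPTIDASE": [(mid, s) for mid, s in domain_seeds()["M16_PEPTIDASE"]],
    }
    return {name: ReferenceFamily(name, members) for name, members in fams.items()}


@lru_cache(maxsize=None)
def precursor_seed_families() -> dict[str, ReferenceFamily]:
    """Precursor family seed sets (NHLP, N11P, HETP, DUF37) for blast-style
    family assignment at the permissive E < 0.1 threshold."""
    groups = _read_family_fasta("synthetic_precursor_seeds.faa")
    return {name: ReferenceFamily(name, groups[name]) for name in PRECURSOR_FAMILIES}


@lru_cache(maxsize=None)
def precursor_leader_lengths() -> dict[str, int]:
    """Leader length (cleavage index) per precursor seed, from the third
    whitespace-separated token of each FASTA header."""
    lengths: dict[str, int] = {}
    with resources.as_file(_data_path("synthetic_precursor_seeds.faa")) as path:
        for block in path.read_text().split(">")[1:]:
            header = block.strip().splitlines()[0].split()
            lengths[header[0]] = int(header[2])
    return lengths
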