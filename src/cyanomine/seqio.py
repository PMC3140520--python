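"""Genome and sequence I/O with coordinate-safe feature access.

All coordinates inside the package are 0-based half-open; GenBank's
1-based inclusive convention is converted at the file boundary.
Compound (``join``) locations collapse to their outermost span — bacterial
CDS are treated as plain intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GeneFeature:
    """A located, stranded feature on a replicon (0-based half-open)."""

    locus_tag: str
    start: int
    end: int
    strand: int
    kind: str = "CDS"
    translation: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.locus_tag}")
        if self.strand not in (+1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def extract(self, sequence: str) -> str:
        """Strand-aware nucleotide sequence of this feature."""
        sub = sequence[self.start : self.end]
        return sub if self.strand == +1 else reverse_complement(sub)


@dataclass
class GenomeRecord:
    """One replicon: sequence plus an ordered list of features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "linear"  # linear | circular
    source: str = "unknown"  # chromosome | plasmid | unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.locus_tag} extends past replicon end ({f.end} > {n})")
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def proteome(self) -> list[tuple[str, str]]:
        """(locus_tag, protein) for every CDS, translating when needed."""
        out = []
        for f in self.cds:
            prot = f.translation
            if prot is None:
                dna = f.extract(self.sequence)
                prot = translate(dna[: len(dna) - len(dna) % 3])
            out.append((f.locus_tag, prot))
        return out


def reverse_complement(dna: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    if set(dna) - NUCLEOTIDES:
        raise ValueError(f"non-nucleotide characters: {sorted(set(dna) - NUCLEOTIDES)}")
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, table: int = 11) -> str:
    """Translate a CDS; stops terminate, fully ambiguous codons give X.

    The bacterial/archaeal code (11) is the default. Length must be a
    multiple of 3.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    if set(dna) - NUCLEOTIDES:
        raise ValueError("non-nucleotide characters in CDS")
    return str(Seq(dna).translate(table=table, to_stop=True))


# ---------------------------------------------------------------------------
# GenBank I/O


def _feature_from_biopython(bf, sequence: str) -> GeneFeature | None:
    kind = bf.type if bf.type in ("CDS", "tRNA") else "other"
    loc = bf.location
    if loc is None:
        return None
    start, end = int(loc.start), int(loc.end)  # outermost span of any join
    strand = -1 if loc.strand == -1 else +1
    quals = bf.qualifiers
    tag = (quals.get("locus_tag") or quals.get("gene") or quals.get("protein_id") or [None])[0]
    translation = (quals.get("translation") or [None])[0]
    if tag is None:
        tag = f"{kind}_{start}_{end}"
    return GeneFeature(tag, start, end, strand, kind=kind, translation=translation)


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecords (one per LOCUS).

    CDS features keep their ``/translation`` qualifier when present; a
    translation inconsistent with the coordinates is kept with a warning.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"no LOCUS records found in {path}")
    for rec in parsed:
        seq = str(rec.seq).upper()
        if not seq or set(seq) - NUCLEOTIDES:
            raise FormatError(f"LOCUS {rec.name}: missing or non-nucleotide ORIGIN sequence")
        source = "unknown"
        feats: list[GeneFeature] = []
        for bf in rec.features:
            if bf.type == "source":
                if "plasmid" in bf.qualifiers:
                    source = "plasmid"
                elif "chromosome" in bf.qualifiers:
                    source = "chromosome"
                continue
            if bf.type not in ("CDS", "tRNA"):
                continue
            try:
                gf = _feature_from_biopython(bf, seq)
            except ValueError as exc:
                raise FormatError(f"LOCUS {rec.name}: {exc}") from exc
            if gf is None:
                continue
            if gf.kind == "CDS" and gf.translation is not None:
                span = gf.length_nt
                # allow for the stop codon not being part of the translation
                if span not in (3 * len(gf.translation) + 3, 3 * len(gf.translation)):
                    log.warning(
                        "LOCUS %s: CDS %s translation length %d inconsistent with span %d; keeping provided translation",
                        rec.name, gf.locus_tag, len(gf.translation), span,
                    )
            feats.append(gf)
        topology = rec.annotations.get("topology", "linear")
        records.append(GenomeRecord(rec.id or rec.name, seq, feats, topology=topology, source=source))
    return records


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords as a GenBank flat file (round-trips with read_genbank)."""
    out = []
    for g in records:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16].replace(" ", "_"), description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        src_quals = {"organism": ["synthetic construct"]}
        if g.source == "plasmid":
            src_quals["plasmid"] = [g.id]
        elif g.source == "chromosome":
            src_quals["chromosome"] = ["1"]
        rec.features.append(
            SeqFeature(FeatureLocation(0, len(g.sequence)), type="source", qualifiers=src_quals)
        )
        for f in g.features:
            quals = {"locus_tag": [f.locus_tag]}
            if f.kind == "CDS":
                quals["transl_table"] = ["11"]
                if f.translation is not None:
                    quals["translation"] = [f.translation]
            rec.features.append(
                SeqFeature(FeatureLocation(f.start, f.end, strand=f.strand), type=f.kind, qualifiers=quals)
            )
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA and tables


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; description text after the first blank is dropped from the id."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def feature_table(genome: GenomeRecord) -> str:
    """Tab-separated feature export (locus_tag, start, end, strand, kind)."""
    lines = ["locus_tag\tstart\tend\tstrand\tkind"]
    for f in genome.features:
        lines.append(f"{f.locus_tag}\t{f.start}\t{f.end}\t{f.strand:+d}\t{f.kind}")
    return "\n".join(lines) + "\n"
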