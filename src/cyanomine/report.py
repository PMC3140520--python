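"""Mining summaries (per-genome cluster counts, per-group precursor
tallies) and the end-to-end pipeline driver.

The summary arithmetic mirrors the survey-style report tables: a
genomes × groups cluster count matrix with totals, and a per-group
precursor table with family counts (NHLP, N11P, HetP, DUF37, Other),
subtotals, novel counts, size ranges, and the average number of
precursors per gene cluster (2 decimals). The same arithmetic runs on
mined objects and on transcribed count tables, including the bundled
counts from the published 58-genome cyanobacterial survey.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import references
from .architecture import ProteinArchitecture, annotate_protein, architecture_table
from .cluster_miner import (
    DEFAULT_MAX_GAP,
    GROUPS,
    GeneCluster,
    build_clusters,
    cluster_table,
    clusters_json,
)
from .logo import build_pfm
from .phylo import to_newick, transporter_tree
from .precursor_miner import (
    DEFAULT_MAX_AA,
    DEFAULT_MIN_AA,
    DEFAULT_WINDOW,
    PrecursorCandidate,
    mine_precursors,
    precursor_table,
)
from .seqio import GenomeRecord, read_genbank, write_fasta, write_genbank
from .simsearch import ANCHOR_EVALUE, FAMILY_EVALUE, hits_table, scan_proteome

log = logging.getLogger(__name__)

FAMILY_COLUMNS = ["NHLP", "N11P", "HETP", "DUF37", "OTHER"]


@dataclass
class MiningSummary:
    cluster_counts: pd.DataFrame     # genomes x (groups..., total)
    precursor_summary: pd.DataFrame  # groups x (families..., subtotal, novel, min_aa, max_aa, average)
    totals: dict

    def to_json(self) -> str:
        payload = {
            "cluster_counts": self.cluster_counts.to_dict(orient="index"),
            "precursor_summary": self.precursor_summary.to_dict(orient="index"),
            "totals": self.totals,
        }
        return json.dumps(payload, indent=2)


def _group_totals(cluster_df: pd.DataFrame) -> pd.Series:
    return cluster_df[list(GROUPS)].sum()


def _precursor_totals(precursor_df: pd.DataFrame, cluster_totals: pd.Series) -> dict:
    fam = precursor_df[FAMILY_COLUMNS]
    subtotals = fam.sum(axis=1)
    averages = {
        g: round(float(subtotals.get(g, 0)) / cluster_totals[g], 2)
        for g in precursor_df.index
        if cluster_totals.get(g, 0)
    }
    present = precursor_df[subtotals > 0]
    totals = {
        "clusters_per_group": {g: int(cluster_totals[g]) for g in cluster_totals.index},
        "total_clusters": int(cluster_totals.sum()),
        "family_totals": {f: int(fam[f].sum()) for f in FAMILY_COLUMNS},
        "total_precursors": int(fam.values.sum()),
        "nhlp_n11p_precursors": int(fam["NHLP"].sum() + fam["N11P"].sum()),
        "novel_precursors": int(precursor_df["novel"].sum()),
        "subtotals": {g: int(v) for g, v in subtotals.items()},
        "averages": averages,
        "size_range": (
            (int(present["min_aa"].min()), int(present["max_aa"].max()))
            if len(present)
            else (0, 0)
        ),
    }
    return totals


def summarize_counts(cluster_df: pd.DataFrame, precursor_df: pd.DataFrame) -> dict:
    """Totals/averages from transcribed count tables (no mined objects).

    ``cluster_df``: genomes (or any partition) x group columns;
    ``precursor_df``: groups x (min_aa, max_aa, family columns, novel).
    """
    return _precursor_totals(precursor_df, _group_totals(cluster_df))


def load_survey_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The bundled transcribed per-strain cluster counts and per-group
    precursor counts of the published 58-genome cyanobacterial survey."""
    base = resources.files("cyanomine") / "data"
    with resources.as_file(base / "survey_cluster_counts.tsv") as p:
        clusters = pd.read_csv(p, sep="\t", index_col=0)
    with resources.as_file(base / "survey_precursor_counts.tsv") as p:
        precursors = pd.read_csv(p, sep="\t", index_col=0)
    return clusters, precursors


def summarize(
    clusters: Sequence[GeneCluster], precursors: Sequence[PrecursorCandidate]
) -> MiningSummary:
    """Tabulate mined clusters and precursors into a MiningSummary."""
    genomes = sorted({c.genome_id for c in clusters})
    cluster_df = pd.DataFrame(0, index=genomes, columns=list(GROUPS), dtype=int)
    for c in clusters:
        cluster_df.loc[c.genome_id, c.group] += 1
    cluster_df["total"] = cluster_df.sum(axis=1)

    prec_df = pd.DataFrame(
        0, index=list(GROUPS), columns=FAMILY_COLUMNS + ["novel"], dtype=int
    )
    sizes: dict[str, list[int]] = {g: [] for g in GROUPS}
    for p in precursors:
        prec_df.loc[p.cluster_group, p.family] += 1
        prec_df.loc[p.cluster_group, "novel"] += int(p.novel)
        sizes[p.cluster_group].append(p.length)
    prec_df["min_aa"] = [min(sizes[g]) if sizes[g] else 0 for g in GROUPS]
    prec_df["max_aa"] = [max(sizes[g]) if sizes[g] else 0 for g in GROUPS]
    group_totals = _group_totals(cluster_df)
    totals = _precursor_totals(prec_df, group_totals)
    prec_df["subtotal"] = prec_df[FAMILY_COLUMNS].sum(axis=1)
    prec_df["average"] = [totals["averages"].get(g, 0.0) for g in GROUPS]
    return MiningSummary(cluster_df, prec_df, totals)


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineConfig:
    genomes: list[str] = field(default_factory=list)  # GenBank paths
    plan: dict | None = None                          # synthetic plan spec
    out_dir: str = "cyanomine_out"
    anchor_evalue: float = ANCHOR_EVALUE
    family_evalue: float = FAMILY_EVALUE
    max_gap: int = DEFAULT_MAX_GAP
    window: int = DEFAULT_WINDOW
    min_aa: int = DEFAULT_MIN_AA
    max_aa: int = DEFAULT_MAX_AA
    bootstrap: int = 1000
    seed: int = 1
    permissive_motif: bool = False
    anchor_fasta: str | None = None      # override bundled anchor families
    precursor_fasta: str | None = None   # override bundled precursor seeds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _plan_from_dict(d: dict):
    from . import synthetic_data as sd

    clusters = [
        sd.PlannedCluster(**c) if isinstance(c, dict) else sd.PlannedCluster(group=c)
        for c in d.get("clusters", [])
    ]
    precursors = [sd.PlannedPrecursor(**p) for p in d.get("precursors", [])]
    keys = {f.name for f in dataclasses.fields(sd.SyntheticPlan)} - {"clusters", "precursors"}
    rest = {k: v for k, v in d.items() if k in keys}
    return sd.SyntheticPlan(clusters=clusters, precursors=precursors, **rest)


def mine_genomes(
    genomes: Sequence[GenomeRecord], config: PipelineConfig
) -> tuple[list, dict[str, ProteinArchitecture], list[GeneCluster]]:
    """Anchor scan, architecture annotation, and cluster assembly."""
    if config.anchor_fasta:
        from .simsearch import load_reference_families

        anchor_fams = load_reference_families(config.anchor_fasta)
    else:
        anchor_fams = references.anchor_reference_families()
    db_n = sum(len(p) for g in genomes for _, p in g.proteome())
    all_hits = []
    clusters: list[GeneCluster] = []
    architectures: dict[str, ProteinArchitecture] = {}
    for genome in genomes:
        hits = []
        for fam in anchor_fams.values():
            hits.extend(
                scan_proteome(genome, fam, config.anchor_evalue, database_length=db_n)
            )
        all_hits.extend(hits)
        proteome = dict(genome.proteome())
        for locus in sorted({h.subject_locus for h in hits}):
            if locus not in architectures:
                architectures[locus] = annotate_protein(locus, proteome[locus])
        clusters.extend(build_clusters(hits, architectures, genome, config.max_gap))
    return all_hits, architectures, clusters


def tree_input(
    clusters: Sequence[GeneCluster], genomes: Sequence[GenomeRecord]
) -> list[tuple[str, str]]:
    """C39 transporter proteins labeled group_locus, excluding disrupted
    architectures (those lacking a C39 peptidase or ATP-binding cassette)."""
    proteomes = {g.id: dict(g.proteome()) for g in genomes}
    out = []
    for c in clusters:
        for feat, arch in c.transporters():
            domains = {d.domain for d in arch.domains}
            if not {"C39_PEPTIDASE", "ATP_BINDING_CASSETTE"} <= domains:
                log.info("excluding disrupted transporter %s from tree", feat.locus_tag)
                continue
            out.append((f"{c.group}_{feat.locus_tag}", proteomes[c.genome_id][feat.locus_tag]))
    return out


def run_pipeline(config: PipelineConfig) -> MiningSummary:
    """Run the full mining pipeline and write all artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "thresholds: anchor_evalue=%g family_evalue=%g max_gap=%d window=%d "
        "min_aa=%d max_aa=%d bootstrap=%d seed=%d",
        config.anchor_evalue, config.family_evalue, config.max_gap, config.window,
        config.min_aa, config.max_aa, config.bootstrap, config.seed,
    )
    if config.plan is not None:
        from .synthetic_data import generate

        plan = _plan_from_dict(dict(config.plan, seed=config.plan.get("seed", config.seed)))
        genomes, truth = generate(plan)
        write_genbank(genomes, out / "synthetic.gbk")
        (out / "truth.tsv").write_text(truth.to_tsv())
        (out / "truth.json").write_text(truth.to_json())
    elif config.genomes:
        genomes = [rec for path in config.genomes for rec in read_genbank(path)]
    else:
        raise ValueError("config must name input genomes or a synthetic plan")

    hits, architectures, clusters = mine_genomes(genomes, config)
    (out / "hits.tsv").write_text(hits_table(hits))
    (out / "architectures.tsv").write_text(architecture_table(architectures.values()))
    (out / "clusters.tsv").write_text(cluster_table(clusters))
    (out / "clusters.json").write_text(clusters_json(clusters))

    if config.precursor_fasta:
        from .simsearch import load_reference_families

        seed_fams = load_reference_families(config.precursor_fasta)
    else:
        seed_fams = references.precursor_seed_families()
    precursors = []
    for genome in genomes:
        precursors.extend(
            mine_precursors(
                genome, clusters, seed_fams,
                window=config.window, min_aa=config.min_aa, max_aa=config.max_aa,
                family_threshold=config.family_evalue, permissive=config.permissive_motif,
            )
        )
    (out / "precursors.tsv").write_text(precursor_table(precursors))
    write_fasta([(p.orf_id, p.protein) for p in precursors], out / "precursors.faa")
    write_fasta([(p.orf_id, p.core) for p in precursors], out / "cores.faa")

    gg_tails = [p.leader[-15:] for p in precursors if p.motif == "GG" and len(p.leader) >= 15]
    if gg_tails:
        (out / "leader_pfm.tsv").write_text(build_pfm(gg_tails).to_tsv())

    seqs = tree_input(clusters, genomes)
    if len(seqs) >= 3:
        tree = transporter_tree(seqs, replicates=config.bootstrap, seed=config.seed)
        (out / "tree.nwk").write_text(to_newick(tree) + "\n")
    else:
        log.info("fewer than 3 usable transporters; skipping tree")

    summary = summarize(clusters, precursors)
    (out / "summary.json").write_text(summary.to_json())
    summary.cluster_counts.to_csv(out / "cluster_counts.tsv", sep="\t")
    summary.precursor_summary.to_csv(out / "precursor_summary.tsv", sep="\t")
    return summary
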