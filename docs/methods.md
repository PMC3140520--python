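# Methods

## The mining model

The pipeline assumes the anchor-first structure of bacteriocin
(RiPP) biosynthetic loci in cyanobacteria: large, conserved transport
and modification genes (C39 peptidase-containing ABC transporters, the
membrane-fusion protein HlyD, the peptidyl-prolyl isomerase SurA, the
lanthionine synthetase LanM, S8 and M16 peptidases) are easy to find by
homology, whereas the precursor genes — 25–170 aa, often unannotated —
are only findable once a cluster localizes the search. Mining therefore
proceeds: anchor homolog detection → cluster assembly → architecture
classification → windowed precursor search → family assignment and
feature computation → summary tables and a transporter phylogeny.

## Similarity search

Anchor and family screens use optimal Smith–Waterman local alignment
with affine gaps (BLOSUM62, gap open 11, extend 1; a gap of length k
costs `open + (k−1)·extend`, so the opening charge covers the first
gapped residue). Significance is Karlin–Altschul,
`E = K·m·n·exp(−λS)` with gapped constants K = 0.041, λ = 0.267,
m the query length and n the summed length of the scanned proteome
(database-search semantics). Thresholds: `E < 1e-5` for anchors,
`E < 1e-3` for intra-protein domain matches (domains are short, so the
anchor threshold would be needlessly strict), `E < 0.1` for precursor
family assignment. One best hit per CDS per family is kept — hits are
used only as presence/absence anchors. There is no word seeding,
two-hit heuristic, or composition-based statistic; this is exhaustive
alignment with BLAST-era significance arithmetic.

A consequence of the permissive family threshold worth knowing: at
`E < 0.1` roughly one in ten searches is expected to reach significance
by chance, so composition-preserving shuffles of a real precursor still
get a family label ~4–10% of the time depending on the family. The
upstream leader-consensus screen, not the family E-value, is what
controls precision.

## Domain architecture and cluster classification

Domains are tiled greedily by descending alignment score; repeats of
the same domain (the fused transporter's two ATP-binding cassettes) are
found by masking accepted spans with X and re-aligning; overlaps above
20% of the shorter interval lose to the higher score. Roles are a
deterministic function of the ordered tiling. The long transporter's
~300 aa N-terminal extension is operationalized as: a CAP_ED match
starting within the first 350 residues with the C39 peptidase starting
at least 200 residues into the protein.

Clusters are single-linkage chains of anchor-bearing CDS with
intergenic gaps ≤ 10 kb (strand ignored). Survey-style mining
traditionally judged co-location by eye in a genome browser; 10 kb is
this package's formalization — it comfortably contains
the observed architectures while staying well below the 20 kb precursor
window. Classification precedence (first match wins): fused transporter
⇒ VII; LanM with any transport machinery ⇒ IV; S8 protein with a
long transporter ⇒ VI; short transporter plus peptidase-free ABC
transporter ⇒ V; short transporter alone ⇒ III; long transporter with
SurA and an additional modification role (M16 or other) ⇒ II; long
transporter ⇒ I; else UNCLASSIFIED. HlyD is recorded but never
required: it occurs in every group, and requiring it would misclassify
degraded clusters.

## Precursor mining

Windows extend 20 kb on both sides of a cluster span, clipped at contig
ends (logged) and wrapped across the origin of circular replicons;
ORFs that would themselves cross the origin are skipped and logged.
Candidates are annotated CDS of 25–170 aa plus unannotated six-frame
ORFs (starts ATG/GTG/TTG, translated with the bacterial code, first
residue forced to M) that overlap no annotated CDS. The scan bounds are
deliberately wider than the 28–164 aa range observed in real surveys so
the observed range is an outcome, not an input.

Leader matching is strict by default: the full double-glycine consensus
M(R/K)ELX₃E(I/L)X₂(I/V)XG(G/A), then the HetP leader KIXDLXYLEX₁₀GG,
each reported at the rightmost match lying fully within the N-terminal
70 residues (leaders precede cores; the rightmost cleavage site
maximizes core integrity). A permissive mode accepting any G(G/A)
dipeptide is available behind a flag. Candidates that match a motif but
no family at `E < 0.1` keep family OTHER. When two cluster windows
overlap, a candidate is attributed to the nearest cluster; ties go to
the earlier cluster and are logged.

Net charge uses Henderson–Hasselbalch sums over D, E, C, Y, H, K, R and
the termini with the EMBOSS Pepstats pK table (bundled as
`data/pepstats_pka.tsv`); pI is found by bisection on pH ∈ [0, 14] to
|charge| < 1e-4; masses are average residue masses, with X contributing
110 Da and no charge.

## Logos

Position frequency matrices are plain per-column relative frequencies
of gap-free equal-length blocks; information content is
`log₂20 − H_j` with `0·log 0 := 0` and no pseudocounts or small-sample
correction by default (the cited logo tool's default); an optional
correction subtracts `19/(2·ln2·n)`.

## Phylogenetics

Distances are Poisson-corrected, `d = −ln(1 − p)`, with pairwise gap
deletion (complete deletion would discard most sites once transporter
types of different length are stacked in one alignment; the choice is
flagged in output). Saturated pairs (p ≥ 1, or no comparable sites)
raise an error. Neighbor joining is Saitou–Nei with the
Studier–Keppler Q-criterion; a negative branch length is clamped to
zero with the deficit moved to its sibling branch, preserving the
joined pair's distance; on additive matrices the algorithm reproduces
the generating topology and branch lengths exactly (tested against an
all-topology least-squares enumeration at 5 taxa). Bootstrap resamples
alignment columns with replacement, rebuilds the tree, and reports the
percentage of replicates containing each original internal bipartition;
replicates whose resampled distances saturate are redrawn (bounded, and
logged if the budget is exhausted). The default is 1,000 replicates —
supports on test-scale alignments are fully converged well below the
50,000 sometimes used in surveys — and a seed is mandatory. Midpoint
rooting places the root halfway along the longest tip-to-tip path; an
all-zero-length tree keeps an arbitrary root with a warning.

The multiple alignment feeding the distance matrix is a bundled
center-star progressive aligner: the center is the sequence with the
highest summed pairwise score, all others are aligned to it globally
(BLOSUM62, 11/1, free terminal gaps, so missing modules become end
gaps) and merged under once-a-gap-always-a-gap. The package's contracts
are on the distances, NJ, and rooting; alignment identity with any
external aligner is not a contract. Transporters whose architecture
lacks a C39 peptidase or an ATP-binding cassette are treated as
disrupted and excluded from trees (logged).

## The synthetic-genome generator

The generator is the package's study-condition bed: it emulates the
statistical structure the mining method assumes and knows the ground
truth exactly.

- Background is i.i.d. uniform {A,C,G,T}. Real genomes have skewed GC
  and codon usage; neither matters to protein-space screens, so passing
  tests say nothing about nucleotide-composition effects.
- Anchor proteins are concatenations of bundled synthetic domain seed
  proteins (the fixtures in `data/synthetic_domain_seeds.faa` are
  random sequences generated once with a fixed seed — they stand in for
  curated domain representatives and carry no biological motif
  content). Genes are back-translated with uniform synonymous codons
  and planted as annotated CDS; per-site amino-acid substitutions at
  `mutation_rate` never create internal stops, which is the correct
  noise model for protein-level screens (a nucleotide-level model would
  conflate mutational noise with pseudogenization).
- C39 transporter lineages carry hierarchical divergence so the data
  reproduce the clade structure seen in real transporter trees: the
  long, short, and fused types diverge from the base concatenation at
  0.15 substitutions/site, each group's transporter diverges from its
  type ancestor at 0.05, and individual genes add `mutation_rate`. With
  those defaults, within-type distances stay well below between-type
  distances up to ~10% individual mutation, which is what makes the
  long vs short/fused clade-separation property assertable.
- Default cluster compositions per group follow the architecture
  definitions (e.g. group I = long transporter + HlyD + SurA; group V =
  short transporter + peptidase-free ABC transporter + HlyD + CAP_ED
  bimodular protein). Clusters are spaced 60 kb apart so adjacent
  precursor windows cannot collide.
- Precursors are mutated copies of the bundled family seeds
  (`data/synthetic_precursor_seeds.faa`, also synthetic: consensus
  leaders with X positions drawn from acid-leaning pools for NHLP/N11P
  and base-leaning pools for HetP/DUF37, cores mildly Gly/Cys/Ser/Thr
  enriched, each seed checked at build time for a unique leader match,
  the intended cleavage index, and the intended charge sign — NHLP/N11P
  acidic, HetP/DUF37 basic). Family OTHER is not planted by default: a
  consensus-matching leader alone can reach `E < 0.1` against the
  family seeds, so an OTHER truth label would be unstable by
  construction. Unannotated precursors are planted with an in-frame
  stop guard so the maximal ORF starts exactly at the planted start
  codon.
- Motif-free decoy ORFs (rejected against both leader models at build
  time) are planted inside the scan windows, half annotated, so
  precision is measurable, not just recall.
- Everything is driven by one `numpy` generator seeded from the plan:
  identical plans give byte-identical output.

What the generator does not emulate: phylogenetic covariance between
genomes, horizontal transfer, transposase-driven rearrangement,
pseudogenes, GC/codon bias, and real leader diversity beyond the stated
consensus. Recovery results on synthetic data therefore validate the
pipeline's mechanics and thresholds, not its sensitivity on diverged
natural sequences.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: seven-cluster
genomes of ~480 kb, 30 planted precursors + 30 decoys, bootstrap 100
for tree properties (1,000 default in the pipeline), 100-trial
empirical nulls. Tolerances: closed forms to 1e-5 (Poisson) and 1e-9
(information content); PFM column sums to 1e-9; pI bisection to 1e-4
charge units. Averages in summaries are rounded to 2 decimals to match
survey-table style. Ties in NJ's Q-matrix resolve to the lowest index
pair, making trees deterministic.

## Known limitations

- E-values use fixed gapped constants; they are not rescaled per
  scoring system or composition, so absolute significance is
  approximate (the thresholds were chosen for screening, not
  estimation).
- The ±20 kb window attributes each ORF to a single nearest cluster;
  precursors genuinely shared between clusters are counted once.
- The center-star aligner is adequate for distance estimation among
  homologous transporters but is not a general MSA replacement.
- The GenBank writer emits the subset of qualifiers the reader uses
  (locus_tag, translation, transl_table, plasmid/chromosome source);
  full qualifier fidelity is out of scope.
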