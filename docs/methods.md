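# Methods

This note documents the models and procedures `taxogen` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence handling

FASTA I/O goes through Biopython; gene coordinates are 1-based inclusive
(GFF convention) in a headered TSV (`gene_id, scaffold_id, start, end,
strand`). CDS are extracted on the coding strand and translated with the
bacterial genetic code (NCBI table 11, configurable): the trailing stop
codon is trimmed, and genes with a non-codon-multiple length or an
internal stop are excluded with a warning rather than silently kept —
the orthology stage must only ever see translatable genes. IUPAC
ambiguity codes are preserved on read; downstream they are excluded
sites (distance estimation) or never-matching residues (identity), so
leniency at parse time cannot inflate any statistic.

## Pairwise alignment

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`. Defaults mirror EMBOSS-needle practice: +1/−1 for
nucleotides, BLOSUM62 for proteins, gap open −10, gap extend −0.5, with
the convention that a gap of length L costs `open + (L−1)·extend`. The
test suite checks optimality against exhaustive enumeration of all
alignments for short sequences across random scoring schemes, so the
scoring convention is pinned by an oracle, not by trust in the library.

Identity has two denominators, both exposed because the literature is
inconsistent: `aligned_columns` (matches over columns where both
residues are non-gap; the default) and `shorter_seq` (matches over the
shorter input's length). Coverage of each sequence is aligned columns
over its full length; both coverages must pass the ortholog filter, so
the criterion is symmetric.

The local search used by dDDH is seed-and-extend: exact k-mers (k = 11)
shared between fragment and genome anchor diagonals, diagonals within a
band (32) are clustered, and each cluster's target window is locally
aligned to the whole fragment. Overlapping hits keep the higher score.
Requiring two seeds per cluster (the dDDH setting) suppresses the ~70
spurious single-seed diagonals expected per kilobase-scale fragment
against a few-hundred-kilobase genome while keeping genuinely homologous
regions, which at 70 % identity still yield ~20 exact 11-mers per
kilobase.

## Distances and trees

The K2P distance is `d = −½ ln((1 − 2P − Q)·√(1 − 2Q))` with P and Q
the transition (A↔G, C↔T) and transversion proportions. Site filtering
follows the "partial deletion, 95 % site coverage" convention: one
global column filter retains columns where ≥ 95 % of rows hold an
unambiguous base, then remaining gap/ambiguous cells are deleted
pairwise per taxon pair. Saturation (non-positive log argument) yields
`inf` with a warning; neighbor joining refuses non-finite input rather
than guessing. The delta-method standard error
`√((c₁²P + c₃²Q − (c₁P + c₃Q)²)/n)` is provided for recovery tests.

Neighbor joining is the canonical Saitou–Nei algorithm with two
behaviours fixed so runs are exactly reproducible: Q-criterion ties
(within 1e−9) are broken by lexicographic cluster label (a cluster is
labelled by its smallest leaf), and negative branch lengths are clamped
to zero with the deficit moved to the sibling branch. On additive
matrices NJ recovers the generating tree exactly (topology and path
lengths), which the tests verify against an independent enumeration of
all topologies with least-squares branch fitting.

Bootstrap supports resample columns of the *filtered* alignment with
replacement (the filter is applied once, not per replicate, mirroring
fixed-site-set practice); the support of each internal bipartition of
the original tree is the percentage of valid replicates containing it.
Replicates with a saturated pair are skipped and removed from the
denominator. Everything is driven by one integer seed; identical runs
produce byte-identical Newick.

## Orthology and relatedness indices

Ortholog detection is strict reciprocal best hits. A k-mer prefilter
(two shared protein 4-mers) replaces heuristic database seeding; every
candidate is globally aligned and filtered at 30 % identity and 0.70
mutual coverage, the thresholds the source annotation pipelines apply to
their BLASTP hits. An E-value cutoff is deliberately not emulated: it
requires database-dependent statistics, and on proteome-scale
comparisons it is dominated by the identity/coverage filter. Each RBH
pair's CDS pair is then globally aligned at the nucleotide level.

- **AGIOS** = unweighted mean nucleotide identity over ortholog pairs
  × 100 (a length-weighted variant exists but is off by default — the
  index is defined as a mean over orthologous ORFs, and unweighted is
  the plain reading).
- **AAI** = unweighted mean protein identity over the same pairs × 100.
- **dDDH**: genome A is cut into consecutive 1020 bp fragments (common
  fragment-based practice; configurable); each fragment's best HSP of
  length ≥ 100 on either strand contributes identical and total columns;
  `d = 1 − Σidentities/Σcolumns` is mapped through
  `dDDH(d) = 100 / (1 + exp((d − 0.0542)/0.01084))`.

The logistic coefficients are configuration, not physics: the
distance-to-DDH regression published with the original web service is
not reproducible offline, so the default model is the package's own
calibration, anchored at two conventional points — d = 0.045 (≈ 96 %
HSP identity, the ANI species boundary) maps to 70 % dDDH, and
midpoint/scale = 5 puts d = 0 at ≈ 99.3 %. Every `ComparisonResult`
carries `ddh_model_version` so numbers remain attributable to a
coefficient set, and comparisons against web-server values should be
treated as approximate.

## Demarcation rules

16S identity: ≥ 98.65 % is compatible with an existing species (flagged
as requiring genomic confirmation); strictly between 95 % and 98.65 %
suggests a new species within the genus; ≤ 95 % a possible new genus.
Genomic: dDDH < 70 % **and** AAI < 95 % (the conservative lower edge of
the 95–96 % band) support a distinct species; both at/above their
thresholds support conspecificity; disagreement is reported as
`inconclusive` with both facts in evidence — the conflict is flagged,
never auto-resolved. Boundary equality always resolves to the non-novel
side, matching the strict "greater than / lower than" phrasing of the
conventions. AGIOS is reported descriptively and excluded from the
verdict, since no demarcation threshold is established for it. The
combined report takes the genomic consensus as final (a high 16S
identity is only a hypothesis), falls back to a provisional 16S-only
call when no genomic comparisons exist, and degrades to `inconclusive`
on any disagreement. Verdicts are monotone: raising any identity or
relatedness value never increases novelty.

## Synthetic data

`simulate_ancestor` packs non-overlapping genes (ATG + stop-free sense
codons + stop) on both strands of one or more scaffolds, with Poisson
gene and intergenic lengths and i.i.d. base composition targeting the
requested G+C (default 40 %, a typical low-GC Firmicute value; defaults
of 200 genes × ~900 bp with ~150 bp intergenic spacers give a
~200 kb miniature genome that keeps the full pipeline tractable while
leaving every estimator in its asymptotic regime).

`evolve_k2p` assigns each site its endpoint state from the K2P
transition probabilities for branch length d (transitions
`¼ + ¼e^{−4βt} − ½e^{−2(α+β)t}`, transversions `½ − ½e^{−4βt}`, with
`αt = κd/(κ+2)`, `βt = d/(κ+2)`), so multiple hits are handled
analytically and the realized difference proportions are exact
bookkeeping. Default κ = 2, the classic transition bias observed in
bacterial sequence data.

`make_pair` evolves two descendants independently for d/2 each. Within
genes, start/stop codons are held fixed and any codon that would become
a stop is reverted — the analogue of purifying selection against
nonsense mutations, without which most simulated genes would be
untranslatable at realistic divergences. Ground-truth per-gene identity
is computed from the realized descendant CDS pairs (Hamming), so the
truth is exact regardless of those reversions. Gene loss removes
`round(fraction × n_genes)` genes (sequence and annotation) from
descendant B; indels (insertions/deletions of 1–10 bp) are restricted to
intergenic segments by default so per-gene identity stays analytic.

What the generator does **not** emulate: rearrangements, horizontal
transfer, paralogous gene families, codon-usage and strand-composition
biases, rate heterogeneity across sites, and sequencing artifacts.
Passing recovery tests therefore demonstrates estimator correctness
under the stated model, not robustness to every feature of real
assemblies; the accession-based validation script exists for the latter.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100 kb sequences × 20
replicates per divergence for K2P recovery (the delta-method SE at
100 kb makes the 2 % bias bound a sharp test), 200-gene (~200 kb)
genome pairs for AGIOS/AAI/RBH recovery, 40–60-gene genomes for the
dDDH series, 100 random additive matrices of ≤ 8 taxa for NJ, 200
random scoring schemes for alignment optimality, and 100 bootstrap
replicates on an 8-taxon, 500-column two-clade alignment with 50
diagnostic sites. Floating-point ties in NJ are compared at 1e−9;
alignment scores against the enumeration oracle at 1e−9; additivity at
1e−8. Degenerate inputs fail loudly: empty alignments after filtering,
zero identity denominators, saturated distances entering NJ, and
orthology on empty proteomes all raise or warn as documented in the
docstrings.

## Known limitations

The dDDH scale is calibrated, not regressed against wet-lab DDH, so
absolute dDDH values are comparable within this package but only
approximately against web-server output. The 16S screen uses global
alignment; tools built on local alignment can differ in the second
decimal of identity for partial-length queries. NJ is the only tree
method (no maximum likelihood), and the bootstrap reports NJ-only
supports.
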