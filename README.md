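# taxogen

Taxonogenomic bacterial species delineation as a tested, reusable Python
pipeline. When a new bacterial isolate is sequenced, the question "is
this a new species?" is answered today by combining a 16S rRNA identity
screen against the closest type strains with whole-genome relatedness
indices and a phylogenetic placement. `taxogen` implements that chain of
evidence end to end:

- **16S screening** — global Needleman–Wunsch identity of the 16S gene
  against reference sequences, interpreted with the standard thresholds
  (identity > 98.65 %: likely conspecific; 95 % < identity < 98.65 %:
  candidate new species within the genus; ≤ 95 %: possibly a new genus).
- **Phylogeny** — Kimura 2-parameter distances
  `d = −½ ln((1 − 2P − Q)·√(1 − 2Q))` (P, Q = transition/transversion
  proportions, pairwise deletion after a 95 % site-coverage column
  filter), Saitou–Nei neighbor joining, and nonparametric bootstrap
  supports (columns resampled with replacement, default 500 replicates).
- **Orthology** — reciprocal best hits between proteomes under exact
  global alignment (BLOSUM62, affine gaps), filtered at 30 % identity and
  0.70 mutual coverage.
- **Relatedness indices** — AGIOS (mean nucleotide identity of globally
  aligned orthologous ORF pairs), AAI (mean amino-acid identity of the
  ortholog pairs), and a fragment-based digital DNA–DNA hybridization:
  1020 bp fragments mapped by seeded local search on both strands, the
  distance `d = 1 − identities / total HSP length` passed through a
  logistic model to the DDH scale (70 % is the species boundary; AAI
  uses the 95–96 % band).
- **Verdict** — a rule table combining all calls into
  `same_species` / `new_species_same_genus` / `possible_new_genus` /
  `inconclusive`, with every threshold comparison recorded as evidence.

Because real genome comparisons depend on downloads, the package ships a
first-class synthetic-data module: annotated genome pairs forward-evolved
under the K2P model at a chosen distance and transition bias, with
configurable gene loss and intergenic indels, whose exact ground truth
(deleted genes, realized per-gene identity) lets every estimator be
checked by parameter recovery.

## Worked example

Simulate a genome pair at true divergence d = 0.12 with 5 % gene loss,
compare it, and classify the strain together with a 16S identity of
96.57 %:

```
$ taxogen simulate --n-genes 60 --gene-len-mean 600 --d 0.12 \
      --gene-loss 0.05 --seed 42 --out demo
$ taxogen compare --fasta-a demo/genome_A.fasta --genes-a demo/genes_A.tsv \
      --fasta-b demo/genome_B.fasta --genes-b demo/genes_B.tsv \
      --strain-a synthA_A --strain-b synthA_B --out demo/cr.json
{
  "aai": 78.03276877800799,
  "agios": 89.30996155498667,
  "ddh": 0.7883175699442723,
  "ddh_model_version": "logistic-f2-v1",
  "n_orthologs": 57,
  "strain_a": "synthA_A",
  "strain_b": "synthA_B"
}
$ taxogen classify --s16 96.57 --metrics demo/cr.json --strain synthA_A
Strain: synthA_A
Overall verdict: new_species_same_genus
Closest relative: synthA_B
16S: 16S identity 96.57% lies between 95.0% and 98.65%: candidate new species within the genus
Genomic vs synthA_B: dDDH 0.79% < 70.0% and AAI 78.03% < 95.0%: distinct species from synthA_B
```

Reading the numbers: of the 60 ancestral genes, 57 survive as reciprocal
best hits (3 were deleted in descendant B); their mean nucleotide
identity (AGIOS 89.3 %) reflects the ~0.11 realized substitution
fraction inside genes, and the amino-acid identity is lower (AAI 78.0 %)
because a nucleotide change hits one of three codon positions. At this
divergence the fragment-based dDDH is far below the 70 % species
boundary, so combined with the 16S identity the isolate is called a new
species within its genus.

The same stages are available as a library (`taxogen.msa.k2p_distance`,
`taxogen.phylo.bootstrap_supports`, `taxogen.orthology.find_orthologs`,
`taxogen.metrics.compare_genomes`, `taxogen.decision.species_report`, …);
see `docs/methods.md` for the model details and design choices.

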