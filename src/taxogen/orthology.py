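"""Reciprocal-best-hit ortholog detection between two proteomes.

A k-mer prefilter replaces heuristic database seeding; every surviving
candidate pair is globally aligned (BLOSUM62, affine gaps) and filtered
at 30% identity and 0.70 mutual coverage — the thresholds the upstream
annotation pipeline applies to its BLASTP hits. Pairs that are each
other's best hit in both directions are orthologs; their coding
sequences are then aligned at the nucleotide level, which is the input
to the AGIOS statistic.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .align import PairwiseAlignment, ScoringScheme, default_scheme, global_align
from .seqio import GenomeRecord, Sequence


class OrthologyWarning(UserWarning):
    pass


@dataclass
class HitRecord:
    query_id: str
    target_id: str
    identity: float
    coverage_query: float
    coverage_target: float
    score: float


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    protein_identity: float
    nucleotide_identity: float | None = None


@dataclass
class OrthologTable:
    strain_a: str
    strain_b: str
    pairs: list[OrthologPair]

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [(p.gene_a, p.gene_b, p.protein_identity, p.nucleotide_identity)
             for p in self.pairs],
            columns=["gene_id_a", "gene_id_b", "pident", "nident"],
        )
        df.to_csv(path, sep="\t", index=False)


def _kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i:i + k] for i in range(len(residues) - k + 1)}


def candidate_pairs(
    proteome_a: dict[str, Sequence],
    proteome_b: dict[str, Sequence],
    kmer: int = 4,
    min_shared: int = 2,
) -> list[tuple[str, str]]:
    """Pairs sharing at least `min_shared` distinct exact protein k-mers.

    A cheap superset of the truly alignable pairs: two unrelated 100-aa
    proteins almost never share two 4-mers, while genuinely homologous
    pairs share many.
    """
    if not proteome_a or not proteome_b:
        return []
    index: dict[str, list[str]] = defaultdict(list)
    for bid in sorted(proteome_b):
        for km in _kmer_set(proteome_b[bid].residues, kmer):
            index[km].append(bid)
    out: list[tuple[str, str]] = []
    for aid in sorted(proteome_a):
        shared: dict[str, int] = defaultdict(int)
        for km in _kmer_set(proteome_a[aid].residues, kmer):
            for bid in index.get(km, ()):
                shared[bid] += 1
        out.extend((aid, bid) for bid, c in sorted(shared.items())
                   if c >= min_shared)
    return out


def best_hits(
    proteome_a: dict[str, Sequence],
    proteome_b: dict[str, Sequence],
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
    scheme: ScoringScheme | None = None,
    kmer: int = 4,
    min_shared: int = 2,
    candidates: list[tuple[str, str]] | None = None,
) -> list[HitRecord]:
    """Best target hit per query under identity/coverage thresholds.

    Each candidate pair is globally aligned; hits with identity below
    `min_identity` or either coverage below `min_coverage` are dropped.
    Per query, the single highest-scoring surviving hit is kept (score
    ties break to the lexicographically smallest target id).
    """
    if not proteome_a or not proteome_b:
        warnings.warn("empty proteome: no hits computed", OrthologyWarning)
        return []
    scheme = scheme or default_scheme(next(iter(proteome_a.values())).alphabet)
    if candidates is None:
        candidates = candidate_pairs(proteome_a, proteome_b, kmer, min_shared)
    best: dict[str, HitRecord] = {}
    aln_cache: dict[tuple[str, str], PairwiseAlignment] = {}
    for aid, bid in candidates:
        aln = aln_cache.get((aid, bid))
        if aln is None:
            aln = global_align(proteome_a[aid], proteome_b[bid], scheme)
            aln_cache[(aid, bid)] = aln
        if aln.identity_fraction < min_identity:
            continue
        if aln.coverage_a < min_coverage or aln.coverage_b < min_coverage:
            continue
        hit = HitRecord(aid, bid, aln.identity_fraction,
                        aln.coverage_a, aln.coverage_b, aln.score)
        cur = best.get(aid)
        if cur is None or hit.score > cur.score or (
                hit.score == cur.score and hit.target_id < cur.target_id):
            best[aid] = hit
    return [best[aid] for aid in sorted(best)]


def reciprocal_best_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    genome_a: GenomeRecord | None = None,
    genome_b: GenomeRecord | None = None,
    nt_scheme: ScoringScheme | None = None,
) -> OrthologTable:
    """Ortholog pairs: (x, y) with best(x in B) = y and best(y in A) = x.

    When genome records are supplied, each ortholog pair's CDS pair is
    globally aligned and its nucleotide identity recorded (the AGIOS
    input); a missing CDS leaves the nucleotide identity absent with a
    warning.
    """
    fwd = {h.query_id: h for h in hits_ab}
    rev = {h.query_id: h.target_id for h in hits_ba}
    nt_scheme = nt_scheme or ScoringScheme.nucleotide_default()

    pairs: list[OrthologPair] = []
    for aid in sorted(fwd):
        hit = fwd[aid]
        bid = hit.target_id
        if rev.get(bid) != aid:
            continue
        nident: float | None = None
        if genome_a is not None and genome_b is not None:
            ca = genome_a.cds.get(aid)
            cb = genome_b.cds.get(bid)
            if ca is None or cb is None:
                warnings.warn(
                    f"ortholog pair ({aid}, {bid}) lacks a CDS; "
                    "nucleotide identity absent", OrthologyWarning)
            else:
                nident = global_align(ca, cb, nt_scheme).identity_fraction
        pairs.append(OrthologPair(aid, bid, hit.identity, nident))

    strain_a = genome_a.strain_id if genome_a else "A"
    strain_b = genome_b.strain_id if genome_b else "B"
    return OrthologTable(strain_a, strain_b, pairs)


def find_orthologs(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
) -> OrthologTable:
    """Convenience wrapper: RBH orthologs with nucleotide identities."""
    hits_ab = best_hits(genome_a.proteins, genome_b.proteins,
                        min_identity, min_coverage)
    hits_ba = best_hits(genome_b.proteins, genome_a.proteins,
                        min_identity, min_coverage)
    return reciprocal_best_hits(hits_ab, hits_ba, genome_a, genome_b)
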