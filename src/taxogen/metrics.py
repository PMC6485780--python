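"""Overall genome relatedness indices: AGIOS, AAI, fragment-based dDDH.

AGIOS (average genomic identity of orthologous gene sequences) is the
unweighted mean nucleotide identity of globally aligned orthologous ORF
pairs; AAI is the same mean at the protein level. dDDH emulates the
genome-to-genome distance approach: the query genome is cut into
consecutive fragments (default 1020 bp), each fragment is mapped onto
the subject with a seeded local search on both strands, and the distance

    d = 1 - (sum of identical positions in best HSPs) / (total HSP length)

is passed through a logistic model to a DDH-scale percentage. The
logistic coefficients are configuration (see `DdhModel`); the default is
calibrated so that d = 0.045 — about 96% HSP identity, the conventional
ANI species boundary — maps to 70% dDDH, and d = 0 maps to ~99.3%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .align import KmerIndex, ScoringScheme, local_search
from .orthology import OrthologTable, find_orthologs
from .seqio import GenomeRecord, Sequence, reverse_complement


class MetricsWarning(UserWarning):
    pass


@dataclass
class GenomeStats:
    total_bp: int
    gc_percent: float
    n_scaffolds: int
    n_genes: int
    coding_bp: int


@dataclass(frozen=True)
class DdhModel:
    """Logistic map from GGDC-style fragment distance to a dDDH percentage.

    dDDH(d) = 100 / (1 + exp((d - midpoint) / scale))

    Defaults anchor 70% dDDH at d = 0.045 (the ~96% identity species
    boundary) with midpoint/scale = 5, giving ~99.3% at d = 0. The
    version token travels with every ComparisonResult so results remain
    attributable to a coefficient set.
    """

    version: str = "logistic-f2-v1"
    midpoint: float = 0.0542
    scale: float = 0.01084

    def ddh_percent(self, d: float) -> float:
        z = (d - self.midpoint) / self.scale
        if z > 500:
            return 0.0
        return 100.0 / (1.0 + math.exp(z))


DEFAULT_DDH_MODEL = DdhModel()


@dataclass
class ComparisonResult:
    """AGIOS/AAI/dDDH/ortholog-count bundle for one genome pair."""

    strain_a: str
    strain_b: str
    n_orthologs: int
    agios: float
    aai: float
    ddh: float
    ddh_model_version: str = DEFAULT_DDH_MODEL.version

    def to_dict(self) -> dict:
        return {
            "strain_a": self.strain_a,
            "strain_b": self.strain_b,
            "n_orthologs": self.n_orthologs,
            "agios": self.agios,
            "aai": self.aai,
            "ddh": self.ddh,
            "ddh_model_version": self.ddh_model_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonResult":
        return cls(**d)


def genome_stats(g: GenomeRecord) -> GenomeStats:
    """Total size, G+C (over unambiguous bases), scaffold/gene counts,
    and the summed gene span (not de-duplicated; flagged if it exceeds
    the genome size)."""
    total = sum(len(s) for s in g.scaffolds)
    gc = acgt = 0
    for s in g.scaffolds:
        for base in "ACGT":
            n = s.residues.count(base)
            acgt += n
            if base in "GC":
                gc += n
    coding = sum(gene.span for gene in g.genes)
    if coding > total:
        warnings.warn(
            f"{g.strain_id}: summed gene spans ({coding}) exceed genome size "
            f"({total}); overlapping genes counted repeatedly", MetricsWarning)
    return GenomeStats(
        total_bp=total,
        gc_percent=100.0 * gc / acgt if acgt else 0.0,
        n_scaffolds=len(g.scaffolds),
        n_genes=len(g.genes),
        coding_bp=coding,
    )


def _mean_identity(values: list[float], lengths: list[int] | None,
                   weighted: bool) -> float:
    if weighted and lengths is not None:
        total = sum(lengths)
        return 100.0 * sum(v * w for v, w in zip(values, lengths)) / total
    return 100.0 * sum(values) / len(values)


def agios(table: OrthologTable, weighted: bool = False) -> float:
    """Mean nucleotide identity over orthologous ORF pairs, as a percentage.

    Unweighted by default (each ortholog pair counts once); pairs lacking
    a nucleotide identity are ignored.
    """
    vals = [p.nucleotide_identity for p in table.pairs
            if p.nucleotide_identity is not None]
    if not vals:
        raise ValueError("no orthologs with nucleotide identity")
    return _mean_identity(vals, None, weighted)


def aai(table: OrthologTable, weighted: bool = False) -> float:
    """Mean amino-acid identity over orthologous protein pairs, percentage."""
    if not table.pairs:
        raise ValueError("no orthologs")
    return _mean_identity([p.protein_identity for p in table.pairs],
                          None, weighted)


def _genome_string(g: GenomeRecord, spacer: str) -> str:
    return spacer.join(s.residues for s in g.scaffolds)


def fragment_ddh(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_bp: int = 1020,
    model: DdhModel | None = None,
    k: int = 11,
    band: int = 32,
    min_hsp_len: int = 100,
    min_seeds: int = 2,
    scheme: ScoringScheme | None = None,
) -> float:
    """Fragment-based digital DNA-DNA hybridization percentage.

    Genome A's scaffolds are cut into consecutive `fragment_bp` windows
    (a trailing piece shorter than a third of that is dropped); each
    fragment is searched against genome B on both strands and the best
    HSP of length >= `min_hsp_len` contributes its identical and total
    columns to the distance. If no fragment maps, dDDH is 0 with a
    warning.
    """
    model = model or DEFAULT_DDH_MODEL
    scheme = scheme or ScoringScheme.nucleotide_default()
    target = _genome_string(b, "N" * k)
    index = KmerIndex(target, k)

    total_matches = 0
    total_columns = 0
    n_fragments = n_mapped = 0
    for scaf in a.scaffolds:
        seq = scaf.residues
        for start in range(0, len(seq), fragment_bp):
            frag = seq[start:start + fragment_bp]
            if len(frag) < max(fragment_bp // 3, k):
                continue
            n_fragments += 1
            query = Sequence(f"{scaf.id}_{start}", frag)
            hits = local_search(query, target, k, band, scheme, index,
                                min_seeds)
            rc_query = Sequence(query.id, reverse_complement(frag))
            hits += [h for h in local_search(rc_query, target, k, band,
                                             scheme, index, min_seeds)]
            hits = [h for h in hits if h.aligned_columns >= min_hsp_len]
            if not hits:
                continue
            best = max(hits, key=lambda h: h.score)
            n_mapped += 1
            total_matches += best.matches
            total_columns += best.aligned_columns

    if total_columns == 0:
        warnings.warn("no fragment mapped; dDDH reported as 0", MetricsWarning)
        return 0.0
    d = 1.0 - total_matches / total_columns
    return model.ddh_percent(d)


def compare_genomes(
    a: GenomeRecord,
    b: GenomeRecord,
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
    fragment_bp: int = 1020,
    ddh_model: DdhModel | None = None,
) -> ComparisonResult:
    """Full pairwise comparison: RBH orthologs, AGIOS, AAI and dDDH."""
    model = ddh_model or DEFAULT_DDH_MODEL
    table = find_orthologs(a, b, min_identity, min_coverage)
    if not table.pairs:
        raise ValueError(
            f"no orthologs between {a.strain_id} and {b.strain_id}")
    return ComparisonResult(
        strain_a=a.strain_id,
        strain_b=b.strain_id,
        n_orthologs=len(table),
        agios=agios(table),
        aai=aai(table),
        ddh=fragment_ddh(a, b, fragment_bp=fragment_bp, model=model),
        ddh_model_version=model.version,
    )
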