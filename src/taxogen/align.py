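"""Pairwise alignment primitives.

Global Needleman-Wunsch with affine gaps drives the AGIOS/AAI identity
statistics; a seeded, banded local search provides the HSP-style hits the
fragment-based dDDH statistic is built from. The dynamic programming
itself is Biopython's PairwiseAligner; this module fixes the scoring
conventions, identity/coverage bookkeeping and hit post-processing.

Affine convention: a gap of length L scores gap_open + (L-1)*gap_extend
(the first gap column pays the opening penalty).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import NUCLEOTIDE, PROTEIN, Sequence, reverse_complement

_AMBIGUOUS = {NUCLEOTIDE: set("NRYSWKMBDHV"), PROTEIN: set("XBZJ")}


class AlignWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch or named protein matrix, plus affine gap penalties.

    Defaults mirror common EMBOSS-needle practice: +1/-1 for nucleotides,
    BLOSUM62 for proteins, gap open -10, gap extend -0.5.
    """

    match: float = 1.0
    mismatch: float = -1.0
    substitution_matrix: str | None = None
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(match=1.0, mismatch=-1.0, gap_open=-10.0, gap_extend=-0.5)

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(substitution_matrix="BLOSUM62", gap_open=-10.0, gap_extend=-0.5)

    def build_aligner(self, mode: str = "global") -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        if self.substitution_matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(
                self.substitution_matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


def default_scheme(alphabet: str) -> ScoringScheme:
    return (ScoringScheme.protein_default() if alphabet == PROTEIN
            else ScoringScheme.nucleotide_default())


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped strings and their summary statistics.

    identity_fraction is matches over columns where both residues are
    non-gap; ambiguity characters (N/X) never count as matches. Coverage
    of each input is (columns where both are non-gap) / input length, so
    a short sequence globally aligned to a long one has low coverage on
    the long side.
    """

    a_gapped: str
    b_gapped: str
    score: float
    identity_fraction: float = 0.0
    aligned_columns: int = 0
    matches: int = 0
    coverage_a: float = 0.0
    coverage_b: float = 0.0

    @classmethod
    def from_gapped(cls, a_gapped: str, b_gapped: str, score: float,
                    alphabet: str = NUCLEOTIDE) -> "PairwiseAlignment":
        if len(a_gapped) != len(b_gapped):
            raise ValueError("gapped strings differ in length")
        ambig = _AMBIGUOUS[alphabet]
        matches = aligned = 0
        for x, y in zip(a_gapped, b_gapped):
            if x != "-" and y != "-":
                aligned += 1
                if x == y and x not in ambig:
                    matches += 1
        len_a = len(a_gapped) - a_gapped.count("-")
        len_b = len(b_gapped) - b_gapped.count("-")
        return cls(
            a_gapped=a_gapped,
            b_gapped=b_gapped,
            score=score,
            identity_fraction=matches / aligned if aligned else 0.0,
            aligned_columns=aligned,
            matches=matches,
            coverage_a=aligned / len_a if len_a else 0.0,
            coverage_b=aligned / len_b if len_b else 0.0,
        )


def global_align(a: Sequence, b: Sequence,
                 scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    Traceback is deterministic (Biopython's alignment enumeration order is
    fixed for given inputs), so repeated runs yield identical gap strings.
    """
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    scheme = scheme or default_scheme(a.alphabet)
    aligner = scheme.build_aligner("global")
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    return PairwiseAlignment.from_gapped(best[0], best[1], float(best.score),
                                         a.alphabet)


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned_columns") -> float:
    """Identity as a percentage, under a stated denominator convention.

    ``aligned_columns``: matches / columns where both residues are non-gap.
    ``shorter_seq``: matches / length of the shorter input.
    """
    if mode == "aligned_columns":
        denom = aln.aligned_columns
    elif mode == "shorter_seq":
        len_a = len(aln.a_gapped) - aln.a_gapped.count("-")
        len_b = len(aln.b_gapped) - aln.b_gapped.count("-")
        denom = min(len_a, len_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ValueError("zero denominator for percent identity")
    return 100.0 * aln.matches / denom


class KmerIndex:
    """Exact k-mer position index over one nucleotide string."""

    def __init__(self, target: str, k: int = 11):
        self.k = k
        self.target = target
        self.positions: dict[str, list[int]] = defaultdict(list)
        for i in range(len(target) - k + 1):
            self.positions[target[i:i + k]].append(i)


@dataclass
class LocalHit(PairwiseAlignment):
    """An HSP-like local hit with target/query coordinates (0-based, end-exclusive)."""

    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    strand: str = "+"


def _hit_from_local(alignment, t_offset: int, alphabet: str,
                    strand: str = "+") -> LocalHit | None:
    blocks_q, blocks_t = alignment.aligned
    if len(blocks_q) == 0:
        return None
    a_parts: list[str] = []
    b_parts: list[str] = []
    q = alignment.sequences[0]
    t = alignment.sequences[1]
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_q is not None:
            a_parts.append(q[prev_q:qs])
            a_parts.append("-" * (ts - prev_t))
            b_parts.append("-" * (qs - prev_q))
            b_parts.append(t[prev_t:ts])
        a_parts.append(q[qs:qe])
        b_parts.append(t[ts:te])
        prev_q, prev_t = qe, te
    a_gapped = "".join(a_parts)
    b_gapped = "".join(b_parts)
    base = PairwiseAlignment.from_gapped(a_gapped, b_gapped,
                                         float(alignment.score), alphabet)
    return LocalHit(
        **base.__dict__,
        q_start=int(blocks_q[0][0]), q_end=int(blocks_q[-1][1]),
        t_start=t_offset + int(blocks_t[0][0]),
        t_end=t_offset + int(blocks_t[-1][1]),
        strand=strand,
    )


def local_search(
    query: Sequence,
    target: Sequence | str,
    k: int = 11,
    band: int = 32,
    scheme: ScoringScheme | None = None,
    index: KmerIndex | None = None,
    min_seeds: int = 1,
) -> list[LocalHit]:
    """Seeded banded local alignment of `query` against `target`.

    Shared exact k-mers anchor the search: seed hits are clustered by
    diagonal (within `band`), each cluster defines a target window which
    is locally aligned to the whole query. Overlapping hits are merged
    keeping the higher score; hits come back sorted by score descending.
    """
    q = query.residues
    t = target.residues if isinstance(target, Sequence) else target
    if k > len(q):
        warnings.warn("k-mer size exceeds query length; no search performed",
                      AlignWarning)
        return []
    if index is None:
        index = KmerIndex(t, k)
    elif index.k != k:
        raise ValueError("index built with a different k")
    scheme = scheme or ScoringScheme.nucleotide_default()
    aligner = scheme.build_aligner("local")

    seeds: list[int] = []  # diagonals (t_pos - q_pos)
    for i in range(len(q) - k + 1):
        for tp in index.positions.get(q[i:i + k], ()):
            seeds.append(tp - i)
    if not seeds:
        return []
    seeds.sort()

    # cluster diagonals within `band` of each other
    clusters: list[list[int]] = [[seeds[0]]]
    for d in seeds[1:]:
        if d - clusters[-1][-1] <= band:
            clusters[-1].append(d)
        else:
            clusters.append([d])

    hits: list[LocalHit] = []
    for cluster in clusters:
        if len(cluster) < min_seeds:
            continue
        dmin, dmax = cluster[0], cluster[-1]
        t0 = max(0, dmin - band)
        t1 = min(len(t), dmax + len(q) + band)
        if t1 <= t0:
            continue
        alns = aligner.align(q, t[t0:t1])
        if alns.score <= 0:
            continue
        hit = _hit_from_local(alns[0], t0, NUCLEOTIDE)
        if hit is not None:
            hits.append(hit)

    hits.sort(key=lambda h: (-h.score, h.t_start))
    kept: list[LocalHit] = []
    for h in hits:
        if all(h.t_end <= o.t_start or h.t_start >= o.t_end for o in kept):
            kept.append(h)
    return kept


def local_search_both_strands(
    query: Sequence,
    target: Sequence | str,
    k: int = 11,
    band: int = 32,
    scheme: ScoringScheme | None = None,
    index: KmerIndex | None = None,
    min_seeds: int = 1,
) -> list[LocalHit]:
    """Search the query and its reverse complement; hits tagged by strand."""
    fwd = local_search(query, target, k, band, scheme, index, min_seeds)
    rc = Sequence(query.id, reverse_complement(query.residues))
    rev = local_search(rc, target, k, band, scheme, index, min_seeds)
    for h in rev:
        h.strand = "-"
    merged = fwd + rev
    merged.sort(key=lambda h: (-h.score, h.t_start, h.strand))
    return merged
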