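"""Column filtering and Kimura 2-parameter distances from a multiple alignment.

The alignment itself is consumed as input (aligned FASTA); this module
implements the distance stage: a one-shot site-coverage filter (the
"partial deletion" setting of standard phylogenetics GUIs, default 95%),
pairwise-deletion transition/transversion counts, and the closed-form K2P
distance

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the transition and transversion proportions over the
sites compared for that pair. Ambiguity codes are excluded sites, not
mismatches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import Sequence, write_fasta

_VALID = set("ACGT")
_VALID_LUT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID_LUT[_b] = True
_CLASS_LUT = np.zeros(256, dtype=np.uint8)
_CLASS_LUT[ord("A")] = _CLASS_LUT[ord("G")] = 1  # purines
_CLASS_LUT[ord("C")] = _CLASS_LUT[ord("T")] = 2  # pyrimidines


class MsaWarning(UserWarning):
    pass


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by an ordered taxon list."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    @classmethod
    def from_sequences(cls, seqs: list[Sequence]) -> "MultipleAlignment":
        return cls([s.id for s in seqs], [s.residues for s in seqs])

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from .seqio import read_fasta
        return cls.from_sequences(read_fasta(path))

    def to_fasta(self, path, wrap: int = 60) -> None:
        write_fasta([Sequence(t, r) for t, r in zip(self.taxa, self.rows)],
                    path, wrap)


@dataclass
class PairCounts:
    """Sufficient statistics of the K2P model for one taxon pair."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("invalid pair counts")


@dataclass
class DistanceMatrix:
    """Symmetric taxon distance matrix; entries may be math.inf on saturation."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.values):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _column_ok_counts(msa: MultipleAlignment) -> np.ndarray:
    """Per-column count of rows with an unambiguous, non-gap nucleotide."""
    arr = np.array([list(r) for r in msa.rows])
    ok = np.isin(arr, list(_VALID))
    return ok.sum(axis=0)


def coverage_filter(msa: MultipleAlignment,
                    min_coverage: float = 0.95) -> MultipleAlignment:
    """Retain columns where the fraction of unambiguous rows >= min_coverage.

    Idempotent; raises if no column survives (advising a lower threshold).
    """
    n = len(msa.taxa)
    counts = _column_ok_counts(msa)
    keep = counts / n >= min_coverage
    if not keep.any():
        raise ValueError(
            "coverage filter removed every column; lower min_coverage")
    idx = np.flatnonzero(keep)
    rows = ["".join(r[i] for i in idx) for r in msa.rows]
    return MultipleAlignment(list(msa.taxa), rows)


def count_pair(msa: MultipleAlignment, taxon_i: str, taxon_j: str) -> PairCounts:
    """Transition/transversion proportions with pairwise deletion.

    Columns where either row holds a gap or an ambiguity code are skipped.
    Transitions are A<->G and C<->T; every other differing pair is a
    transversion.
    """
    ri, rj = msa.row(taxon_i), msa.row(taxon_j)
    a = np.frombuffer(ri.encode(), dtype=np.uint8)
    b = np.frombuffer(rj.encode(), dtype=np.uint8)
    mask = _VALID_LUT[a] & _VALID_LUT[b]
    n = int(mask.sum())
    diff = mask & (a != b)
    same_class = _CLASS_LUT[a] == _CLASS_LUT[b]  # purine vs pyrimidine
    ts = int((diff & same_class).sum())
    tv = int(diff.sum()) - ts
    if n == 0:
        raise ValueError(f"no comparable sites between {taxon_i} and {taxon_j}")
    return PairCounts(P=ts / n, Q=tv / n, n_sites=n)


def k2p_distance(pc: PairCounts) -> float:
    """Closed-form Kimura 2-parameter distance.

    Saturated pairs (log argument non-positive) come back as math.inf
    with a warning rather than an exception, so a single bad pair does
    not abort a whole matrix.
    """
    w1 = 1.0 - 2.0 * pc.P - pc.Q
    w2 = 1.0 - 2.0 * pc.Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn(
            f"saturated pair (P={pc.P:.4f}, Q={pc.Q:.4f}): distance undefined",
            MsaWarning,
        )
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_standard_error(pc: PairCounts) -> float:
    """Analytic standard error of the K2P estimate (delta method)."""
    w1 = 1.0 - 2.0 * pc.P - pc.Q
    w2 = 1.0 - 2.0 * pc.Q
    if w1 <= 0 or w2 <= 0 or pc.n_sites == 0:
        return math.inf
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 ** 2 * pc.P + c3 ** 2 * pc.Q - (c1 * pc.P + c3 * pc.Q) ** 2) / pc.n_sites
    return math.sqrt(max(var, 0.0))


def distance_matrix(msa: MultipleAlignment,
                    min_coverage: float = 0.95) -> DistanceMatrix:
    """Coverage-filter once, then K2P with pairwise deletion on every pair."""
    if len(msa.taxa) < 3:
        raise ValueError("need at least 3 taxa for a distance matrix")
    filtered = coverage_filter(msa, min_coverage)
    n = len(filtered.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pc = count_pair(filtered, filtered.taxa[i], filtered.taxa[j])
            d[i, j] = d[j, i] = k2p_distance(pc)
    return DistanceMatrix(list(filtered.taxa), d)
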