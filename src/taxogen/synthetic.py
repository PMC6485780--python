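"""Synthetic annotated genome pairs and alignments with known ground truth.

The generator exists so every downstream estimator can be checked by
parameter recovery: genome pairs diverge under a forward-simulated
Kimura 2-parameter process at a chosen distance d and
transition/transversion bias kappa, with configurable gene loss, small
intergenic indels and scaffold fragmentation. Ground truth (which genes
were deleted, the realized per-gene identity, realized transition and
transversion proportions) is bookkept from the realized descendant
sequences themselves, so it is exact by construction.

Within genes, substitutions that would create an in-frame stop codon are
reverted — real coding sequences are under exactly that selection, and
an unconstrained process would truncate most genes at translation. The
start and stop codons are held fixed. Indels are restricted to
intergenic regions by default, which keeps per-gene identity analytic.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa import MultipleAlignment
from .seqio import (GeneAnnotation, GenomeRecord, Sequence,
                    reverse_complement, translate_cds)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)   # A<->G, C<->T
_TRANSVERSION_1 = np.array([1, 0, 1, 0], dtype=np.uint8)  # A->C, C->A, G->C, T->A
_TRANSVERSION_2 = np.array([3, 2, 3, 2], dtype=np.uint8)  # A->T, C->G, G->T, T->G


def expected_pq(d: float, kappa: float) -> tuple[float, float]:
    """Analytic expected transition (P) and transversion (Q) proportions
    after evolving for distance d at transition/transversion ratio kappa."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(
        -2.0 * (alpha_t + beta_t))
    q = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return p, q


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def evolve_k2p(seq: Sequence | str, d: float, kappa: float = 2.0,
               seed=0) -> tuple[str, float, float]:
    """Evolve a nucleotide string under K2P for branch length d.

    Each site is assigned its endpoint state from the K2P transition
    probabilities (so multiple hits are accounted for analytically).
    Returns the evolved string and the realized transition and
    transversion difference proportions over unambiguous sites.
    Non-ACGT characters are left untouched.
    """
    if d < 0 or kappa <= 0:
        raise ValueError("need d >= 0 and kappa > 0")
    residues = seq.residues if isinstance(seq, Sequence) else seq
    rng = _as_rng(seed)
    arr = np.frombuffer(residues.encode(), dtype=np.uint8).copy()
    codes = _CODE[arr]
    valid = codes != 255
    n_valid = int(valid.sum())
    if d == 0 or n_valid == 0:
        return residues, 0.0, 0.0

    p_ts, q_tv = expected_pq(d, kappa)
    u = rng.random(arr.shape[0])
    v = rng.random(arr.shape[0])
    ts_mask = valid & (u < p_ts)
    tv_mask = valid & (u >= p_ts) & (u < p_ts + q_tv)
    tv1 = tv_mask & (v < 0.5)
    tv2 = tv_mask & (v >= 0.5)

    out = codes.copy()
    out[ts_mask] = _TRANSITION[codes[ts_mask]]
    out[tv1] = _TRANSVERSION_1[codes[tv1]]
    out[tv2] = _TRANSVERSION_2[codes[tv2]]

    evolved = arr.copy()
    evolved[valid] = _BASES[out[valid]]
    p_real = float(ts_mask.sum()) / n_valid
    q_real = float(tv_mask.sum()) / n_valid
    return evolved.tobytes().decode(), p_real, q_real


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """n_codons sense codons (no stops) with base composition near gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = rng.choice(4, size=(n_codons, 3), p=p)
    text = _BASES[codons].reshape(n_codons, 3)
    joined = [bytes(row).decode() for row in text]
    for i, c in enumerate(joined):
        while c in STOP_CODONS:
            c = bytes(_BASES[rng.choice(4, size=3, p=p)]).decode()
        joined[i] = c
    return "".join(joined)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=n, p=p)]).decode()


def simulate_ancestor(
    n_genes: int = 200,
    gene_len_mean: int = 900,
    intergenic_mean: int = 150,
    gc: float = 0.40,
    seed: int = 0,
    n_scaffolds: int = 1,
    strain_id: str = "ancestor",
) -> GenomeRecord:
    """A random annotated genome: non-overlapping genes on both strands,
    each CDS starting ATG and ending with a stop, no internal stops, base
    composition targeting `gc`."""
    if min(n_genes, gene_len_mean, intergenic_mean, n_scaffolds) <= 0:
        raise ValueError("parameters must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be a fraction in (0, 1)")
    if n_scaffolds > n_genes:
        raise ValueError("cannot place fewer genes than scaffolds")
    rng = np.random.default_rng(seed)

    per_scaffold = [n_genes // n_scaffolds] * n_scaffolds
    for i in range(n_genes % n_scaffolds):
        per_scaffold[i] += 1

    scaffolds: list[Sequence] = []
    genes: list[GeneAnnotation] = []
    cds: dict[str, Sequence] = {}
    proteins: dict[str, Sequence] = {}
    gene_no = 0
    for s_idx, count in enumerate(per_scaffold):
        scaffold_id = f"scaffold_{s_idx + 1}"
        parts: list[str] = []
        pos = 0
        lead = int(rng.poisson(intergenic_mean)) + 10
        parts.append(_random_bases(rng, lead, gc))
        pos += lead
        for _ in range(count):
            gene_no += 1
            gene_id = f"gene_{gene_no:05d}"
            internal = max(int(rng.poisson(max(gene_len_mean // 3 - 2, 12))), 10)
            body = "ATG" + _random_codons(rng, internal, gc) + \
                STOP_CODONS[rng.integers(0, 3)]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = body if strand == "+" else reverse_complement(body)
            start = pos + 1
            end = pos + len(body)
            parts.append(placed)
            pos = end
            genes.append(GeneAnnotation(gene_id, scaffold_id, start, end, strand))
            cds[gene_id] = Sequence(gene_id, body)
            proteins[gene_id] = Sequence(gene_id, translate_cds(body),
                                         alphabet="protein")
            gap = int(rng.poisson(intergenic_mean)) + 10
            parts.append(_random_bases(rng, gap, gc))
            pos += gap
        scaffolds.append(Sequence(scaffold_id, "".join(parts)))

    return GenomeRecord(strain_id, scaffolds, genes, cds, proteins)


def _evolve_cds(cds: str, d: float, kappa: float,
                rng: np.random.Generator) -> str:
    """Evolve a CDS keeping start/stop codons fixed and reverting any
    codon that would become a stop."""
    if len(cds) < 9:
        return cds
    middle, _, _ = evolve_k2p(cds[3:-3], d, kappa, rng)
    fixed = list(middle)
    for i in range(0, len(middle) - 2, 3):
        if middle[i:i + 3] in STOP_CODONS:
            fixed[i:i + 3] = cds[3 + i:6 + i]
    return cds[:3] + "".join(fixed) + cds[-3:]


def _apply_intergenic_indels(segment: str, indel_rate: float,
                             rng: np.random.Generator, gc: float = 0.4) -> str:
    if indel_rate <= 0 or not segment:
        return segment
    n_events = rng.poisson(indel_rate * len(segment))
    s = segment
    for _ in range(n_events):
        if not s:
            break
        pos = int(rng.integers(0, len(s)))
        size = int(rng.integers(1, 11))
        if rng.random() < 0.5:
            s = s[:pos] + _random_bases(rng, size, gc) + s[pos:]
        else:
            s = s[:pos] + s[pos + size:]
    return s


@dataclass
class SimulationTruth:
    """Exact bookkeeping of a simulated genome pair."""

    d_true: float
    kappa: float
    seed: int
    deleted_genes: set[str]
    realized_gene_identity: dict[str, float]
    realized_substitutions: dict[str, int]
    gene_loss_fraction: float = 0.0

    @property
    def mean_gene_identity(self) -> float:
        vals = list(self.realized_gene_identity.values())
        return sum(vals) / len(vals)

    def to_dict(self) -> dict:
        return {
            "d_true": self.d_true,
            "kappa": self.kappa,
            "seed": self.seed,
            "gene_loss_fraction": self.gene_loss_fraction,
            "deleted_genes": sorted(self.deleted_genes),
            "realized_gene_identity": self.realized_gene_identity,
            "realized_substitutions": self.realized_substitutions,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))


def _evolve_descendant(
    ancestor: GenomeRecord,
    branch: float,
    kappa: float,
    deleted: set[str],
    indel_rate: float,
    rng: np.random.Generator,
    strain_id: str,
) -> GenomeRecord:
    scaffolds: list[Sequence] = []
    genes: list[GeneAnnotation] = []
    cds: dict[str, Sequence] = {}
    proteins: dict[str, Sequence] = {}
    for scaf in ancestor.scaffolds:
        anc_genes = sorted((g for g in ancestor.genes
                            if g.scaffold_id == scaf.id),
                           key=lambda g: g.start)
        parts: list[str] = []
        pos = 0
        prev_end = 0
        for g in anc_genes:
            inter = scaf.residues[prev_end:g.start - 1]
            inter, _, _ = evolve_k2p(inter, branch, kappa, rng) if inter else (inter, 0, 0)
            inter = _apply_intergenic_indels(inter, indel_rate, rng)
            parts.append(inter)
            pos += len(inter)
            prev_end = g.end
            if g.gene_id in deleted:
                continue
            new_cds = _evolve_cds(ancestor.cds[g.gene_id].residues,
                                  branch, kappa, rng)
            placed = new_cds if g.strand == "+" else reverse_complement(new_cds)
            genes.append(GeneAnnotation(g.gene_id, scaf.id, pos + 1,
                                        pos + len(placed), g.strand))
            parts.append(placed)
            pos += len(placed)
            cds[g.gene_id] = Sequence(g.gene_id, new_cds)
            proteins[g.gene_id] = Sequence(g.gene_id, translate_cds(new_cds),
                                           alphabet="protein")
        tail = scaf.residues[prev_end:]
        tail, _, _ = evolve_k2p(tail, branch, kappa, rng) if tail else (tail, 0, 0)
        tail = _apply_intergenic_indels(tail, indel_rate, rng)
        parts.append(tail)
        scaffolds.append(Sequence(scaf.id, "".join(parts)))
    return GenomeRecord(strain_id, scaffolds, genes, cds, proteins)


def make_pair(
    ancestor: GenomeRecord,
    d: float,
    kappa: float = 2.0,
    gene_loss_fraction: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenomeRecord, GenomeRecord, SimulationTruth]:
    """Two descendants of `ancestor`, each evolved independently for d/2.

    Gene loss (descendant B only) removes both sequence and annotation of
    round(fraction * n_genes) randomly chosen genes; indels are applied
    to intergenic segments at `indel_rate` events per bp. Truth records
    the deletion set and, for every surviving gene, the realized identity
    between the two descendant CDS copies.
    """
    if not (0 <= gene_loss_fraction < 1):
        raise ValueError("gene_loss_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in ancestor.genes]
    n_del = int(round(gene_loss_fraction * len(gene_ids)))
    deleted = set(rng.choice(gene_ids, size=n_del, replace=False)) if n_del else set()

    genome_a = _evolve_descendant(ancestor, d / 2, kappa, set(), indel_rate,
                                  rng, ancestor.strain_id + "_A")
    genome_b = _evolve_descendant(ancestor, d / 2, kappa, deleted, indel_rate,
                                  rng, ancestor.strain_id + "_B")

    identity: dict[str, float] = {}
    subs: dict[str, int] = {}
    for gid in gene_ids:
        if gid in deleted:
            continue
        ca = genome_a.cds[gid].residues
        cb = genome_b.cds[gid].residues
        diff = sum(1 for x, y in zip(ca, cb) if x != y)
        subs[gid] = diff
        identity[gid] = 1.0 - diff / len(ca)

    truth = SimulationTruth(d, kappa, seed, deleted, identity, subs,
                            gene_loss_fraction)
    return genome_a, genome_b, truth


def two_clade_alignment(
    n_per_clade: int = 4,
    length: int = 500,
    n_diagnostic: int = 50,
    noise: float = 0.02,
    seed: int = 0,
) -> MultipleAlignment:
    """Gap-free MSA of two clades separated by fixed diagnostic sites.

    `n_diagnostic` randomly chosen columns carry a fixed transversion
    difference between the clades; every other cell independently
    mutates with probability `noise`, so within-clade rows differ but the
    clade split carries overwhelming signal.
    """
    rng = np.random.default_rng(seed)
    base = np.frombuffer(_random_bases(rng, length, 0.5).encode(),
                         dtype=np.uint8).copy()
    diag = rng.choice(length, size=n_diagnostic, replace=False)
    other = base.copy()
    codes = _CODE[other[diag]]
    other[diag] = _BASES[_TRANSVERSION_1[codes]]

    taxa: list[str] = []
    rows: list[str] = []
    for clade, template in (("A", base), ("B", other)):
        for i in range(n_per_clade):
            row = template.copy()
            mask = rng.random(length) < noise
            mask[diag] = False
            codes_m = _CODE[row[mask]]
            row[mask] = _BASES[(codes_m + rng.integers(1, 4, size=codes_m.size))
                               % 4]
            taxa.append(f"{clade}{i + 1}")
            rows.append(row.tobytes().decode())
    return MultipleAlignment(taxa, rows)
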