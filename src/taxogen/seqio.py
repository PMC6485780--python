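"""Sequence I/O and assembly of annotated genome records.

FASTA parsing goes through Bio.SeqIO; translation through Bio.Seq with the
bacterial genetic code (NCBI table 11) by default. The containers defined
here (`Sequence`, `GeneAnnotation`, `GenomeRecord`) are the atoms every
downstream stage works with: the 16S screen, the orthology search and the
genome relatedness indices all consume them.

Gene coordinates are 1-based inclusive (GFF convention) throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_RC = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                    "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class SeqIOWarning(UserWarning):
    """Non-fatal data issue encountered while reading sequences."""


def reverse_complement(residues: str) -> str:
    return residues.translate(_RC)[::-1]


@dataclass
class Sequence:
    """An identified nucleotide or amino-acid string.

    IUPAC ambiguity codes are preserved on read; downstream stages treat
    them as excluded sites (distances) or never-matching residues
    (identity), so leniency here does not leak into the statistics.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty body")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneAnnotation:
    """One CDS call: scaffold, 1-based inclusive span, strand."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: bad span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """Scaffolds + gene table + derived CDS/protein sequences for one strain."""

    strain_id: str
    scaffolds: list[Sequence]
    genes: list[GeneAnnotation] = field(default_factory=list)
    cds: dict[str, Sequence] = field(default_factory=dict)
    proteins: dict[str, Sequence] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def scaffold(self, scaffold_id: str) -> Sequence:
        for s in self.scaffolds:
            if s.id == scaffold_id:
                return s
        raise KeyError(scaffold_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "scaffolds": [{"id": s.id, "residues": s.residues} for s in self.scaffolds],
            "genes": [
                {"gene_id": g.gene_id, "scaffold_id": g.scaffold_id,
                 "start": g.start, "end": g.end, "strand": g.strand}
                for g in self.genes
            ],
            "cds": {k: v.residues for k, v in self.cds.items()},
            "proteins": {k: v.residues for k, v in self.proteins.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeRecord":
        return cls(
            strain_id=d["strain_id"],
            scaffolds=[Sequence(s["id"], s["residues"]) for s in d["scaffolds"]],
            genes=[GeneAnnotation(**g) for g in d["genes"]],
            cds={k: Sequence(k, v) for k, v in d["cds"].items()},
            proteins={k: Sequence(k, v, alphabet=PROTEIN)
                      for k, v in d["proteins"].items()},
        )

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load_manifest(cls, path: str | Path) -> "GenomeRecord":
        return cls.from_dict(json.loads(Path(path).read_text()))


def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> list[Sequence]:
    """Read a FASTA file into a list of `Sequence`, order preserved.

    Residues are uppercased; CR/LF line endings are tolerated. An empty
    file yields an empty list with a warning; a record with an empty body
    or a duplicated id is an error.
    """
    path = Path(path)
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", SeqIOWarning)
        return []
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        body = str(rec.seq).upper()
        if not body:
            raise ValueError(f"{path}: record {rec.id!r} has an empty body")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(Sequence(rec.id, body, desc, alphabet))
    return out


def write_fasta(seqs: list[Sequence], path: str | Path, wrap: int = 60) -> None:
    """Write sequences as FASTA wrapped at `wrap` columns; deterministic."""
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i:i + wrap] + "\n")


_GENE_TABLE_COLUMNS = ("gene_id", "scaffold_id", "start", "end", "strand")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a headered TSV of gene coordinates (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold_id": str})
    missing = [c for c in _GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    return [
        GeneAnnotation(row.gene_id, row.scaffold_id, int(row.start),
                       int(row.end), row.strand)
        for row in df.itertuples()
    ]


def write_gene_table(genes: list[GeneAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.scaffold_id, g.start, g.end, g.strand) for g in genes],
        columns=list(_GENE_TABLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def extract_cds(scaffold: Sequence, gene: GeneAnnotation) -> str:
    """Coding-strand CDS for a gene; reverse-complemented on '-'."""
    if gene.end > len(scaffold):
        raise ValueError(
            f"gene {gene.gene_id}: coordinate {gene.end} outside scaffold "
            f"{scaffold.id} (length {len(scaffold)})"
        )
    sub = scaffold.residues[gene.start - 1:gene.end]
    return reverse_complement(sub) if gene.strand == "-" else sub


def translate_cds(cds: str, genetic_code: int = 11) -> str:
    """Translate a CDS, trimming one trailing stop codon if present."""
    prot = str(Seq(cds).translate(table=genetic_code))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def load_genome(
    scaffold_fasta: str | Path,
    gene_table: str | Path,
    strain_id: str,
    genetic_code: int = 11,
) -> GenomeRecord:
    """Assemble a `GenomeRecord` from a scaffold FASTA and a gene-coordinate TSV.

    CDS are extracted (reverse-complemented on '-') and translated with
    the bacterial code. Genes whose length is not a codon multiple or
    whose translation contains an internal stop are excluded with a
    warning and listed in ``record.excluded``; a coordinate outside its
    scaffold is an error naming the gene.
    """
    scaffolds = read_fasta(scaffold_fasta, NUCLEOTIDE)
    annotations = read_gene_table(gene_table)
    by_id = {s.id: s for s in scaffolds}

    genes: list[GeneAnnotation] = []
    cds: dict[str, Sequence] = {}
    proteins: dict[str, Sequence] = {}
    excluded: list[tuple[str, str]] = []
    for g in annotations:
        if g.scaffold_id not in by_id:
            raise ValueError(f"gene {g.gene_id}: unknown scaffold {g.scaffold_id!r}")
        nt = extract_cds(by_id[g.scaffold_id], g)
        if len(nt) % 3 != 0:
            warnings.warn(
                f"gene {g.gene_id}: CDS length {len(nt)} not divisible by 3; excluded",
                SeqIOWarning,
            )
            excluded.append((g.gene_id, "length_not_codon_multiple"))
            continue
        aa = translate_cds(nt, genetic_code)
        if "*" in aa:
            warnings.warn(
                f"gene {g.gene_id}: internal stop codon in translation; excluded",
                SeqIOWarning,
            )
            excluded.append((g.gene_id, "internal_stop"))
            continue
        genes.append(g)
        cds[g.gene_id] = Sequence(g.gene_id, nt, alphabet=NUCLEOTIDE)
        proteins[g.gene_id] = Sequence(g.gene_id, aa, alphabet=PROTEIN)

    return GenomeRecord(strain_id, scaffolds, genes, cds, proteins, excluded)
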