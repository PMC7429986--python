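"""Reading, writing and compiling protein-coding gene products.

Input follows the PROKKA/Prodigal ``.faa`` convention: one record per
protein, header ``>id description...`` where everything after the first
whitespace is free-text annotation.  A trailing ``*`` (translated stop
codon) is stripped; an internal ``*`` is treated as an annotation fault
and rejected.  The ``X`` ambiguity code is accepted alongside the 20
canonical residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = CANONICAL_RESIDUES | {"X"}


@dataclass(frozen=True)
class GeneProduct:
    """One protein-coding sequence with its annotation and provenance."""

    id: str
    sequence: str
    annotation: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene product {self.id!r}: empty sequence")
        for ch in self.sequence:
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"gene product {self.id!r}: invalid residue {ch!r} "
                    "(expected one of the 20 canonical amino acids or X)"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneDatabase:
    """Ordered collection of gene products with per-source provenance."""

    products: list[GeneProduct] = field(default_factory=list)
    sources: list[tuple[str, str]] = field(default_factory=list)  # (organism, file)

    def __len__(self) -> int:
        return len(self.products)

    def __iter__(self):
        return iter(self.products)

    def __getitem__(self, gene_id: str) -> GeneProduct:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {p.id: p for p in self.products}
            return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        try:
            self[gene_id]
            return True
        except KeyError:
            return False

    def ids(self) -> list[str]:
        return [p.id for p in self.products]


def _clean_sequence(gene_id: str, raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise ValueError(
            f"record {gene_id!r}: internal stop codon '*' (annotation fault)"
        )
    if not seq:
        raise ValueError(f"record {gene_id!r}: empty sequence")
    for ch in seq:
        if ch not in VALID_RESIDUES:
            raise ValueError(f"record {gene_id!r}: invalid residue {ch!r}")
    return seq


def read_protein_fasta(path: str | Path, organism: str = "") -> list[GeneProduct]:
    """Parse a protein FASTA into gene products.

    The header is split at the first whitespace: the left part is the id,
    the remainder (possibly empty) is stored as the annotation.  Duplicate
    ids within one file are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    products: list[GeneProduct] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_sequence(rec.id, str(rec.seq))
        products.append(
            GeneProduct(id=rec.id, sequence=seq, annotation=rec.description[len(rec.id):].strip(),
                        organism=organism)
        )
    return products


def write_fasta(products: Iterable[GeneProduct], path: str | Path) -> None:
    """Write gene products as FASTA (`>id annotation` headers)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.annotation)
        for p in products
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>annotation`` table (no header)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, _, annotation = line.partition("\t")
            table[gene_id] = annotation
    return table


def apply_annotations(products: Sequence[GeneProduct], table: dict[str, str]) -> list[GeneProduct]:
    """Override header-derived annotations with a sidecar TSV table."""
    return [
        GeneProduct(p.id, p.sequence, table.get(p.id, p.annotation), p.organism)
        for p in products
    ]


def compile_database(sources: Sequence[tuple[str | Path, str]],
                     annotation_tables: dict[str, str | Path] | None = None) -> GeneDatabase:
    """Compile per-organism FASTA files into a single gene database.

    Parameters
    ----------
    sources
        ``(path, organism)`` pairs, in the order the database should keep.
    annotation_tables
        Optional mapping ``organism -> TSV path`` overriding annotations.

    Cross-file id collisions are an error naming both sources.
    """
    db = GeneDatabase()
    owner: dict[str, str] = {}
    for path, organism in sources:
        products = read_protein_fasta(path, organism)
        if annotation_tables and organism in annotation_tables:
            products = apply_annotations(products, read_annotation_tsv(annotation_tables[organism]))
        for p in products:
            if p.id in owner:
                raise ValueError(
                    f"id collision: {p.id!r} appears in {owner[p.id]} and {path}"
                )
            owner[p.id] = str(path)
        db.products.extend(products)
        db.sources.append((organism, str(path)))
    return db
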