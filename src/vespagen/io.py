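"""Readers and writers for the standard formats the toolkit consumes.

No scientific logic lives here.  Coordinates are 1-based inclusive
throughout (the GFF3 convention); any half-open arithmetic is confined to
this module.  Sequence case is preserved exactly — downstream modules rely
on lowercase letters to mean soft-masked (repeat-derived) sequence.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceSet",
    "Gene",
    "GeneAnnotationSet",
    "TaxonomyEvidence",
    "OrthogroupTable",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "extract_gene_sequences",
    "read_orthogroup_counts",
    "read_taxonomy_hits",
    "read_rescue_table",
    "read_newick",
    "write_newick",
]


class SequenceSet:
    """Ordered, case-preserving collection of named nucleotide sequences.

    Holds either an assembly (records are contigs/scaffolds) or a gene
    sequence set (records are genes).  Record ids must be unique and
    sequences non-empty; the original character case is kept exactly as
    read so that soft-masking information survives round trips.
    """

    def __init__(
        self,
        records: Sequence[tuple[str, str]],
        descriptions: Optional[dict[str, str]] = None,
        source_path: Optional[str] = None,
    ) -> None:
        self.records: list[tuple[str, str]] = list(records)
        self.descriptions: dict[str, str] = dict(descriptions or {})
        self.source_path = source_path
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id: {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")
        self._index = {rid: seq for rid, seq in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def __getitem__(self, rid: str) -> str:
        return self._index[rid]

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        """New SequenceSet restricted to `ids`, original order preserved."""
        keep = set(ids)
        missing = keep - set(self._index)
        if missing:
            raise KeyError(f"ids not in sequence set: {sorted(missing)}")
        return SequenceSet(
            [(rid, seq) for rid, seq in self.records if rid in keep],
            descriptions={
                rid: d for rid, d in self.descriptions.items() if rid in keep
            },
            source_path=self.source_path,
        )

    def __repr__(self) -> str:
        return f"SequenceSet({len(self)} records, {sum(self.lengths)} bp)"


@dataclass
class Gene:
    """One gene model: 1-based inclusive coordinates on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds_parts: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.cds_parts is not None:
            parts = sorted(self.cds_parts)
            for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"gene {self.gene_id}: overlapping cds_parts "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
            self.cds_parts = parts


@dataclass
class GeneAnnotationSet:
    """Carrier for GFF3 gene models (genes plus optional CDS parts)."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)


@dataclass
class TaxonomyEvidence:
    """Per-contig taxonomy-hit descriptions; an empty list means no hit."""

    hits: dict[str, list[str]] = field(default_factory=dict)

    def descriptions_for(self, contig_id: str) -> list[str]:
        return self.hits.get(contig_id, [])


class OrthogroupTable:
    """Species x orthogroup gene-count matrix.

    ``counts`` is a DataFrame indexed by orthogroup id with one integer
    column per species.  Every orthogroup must have at least one positive
    count.  ``unassigned`` optionally records, per species, the number of
    genes that were not placed in any orthogroup (needed for Table-2-style
    gene-total percentages).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        unassigned: Optional[dict[str, int]] = None,
    ) -> None:
        if counts.empty:
            raise ValueError("orthogroup table is empty")
        if (counts.values < 0).any():
            raise ValueError("negative gene counts in orthogroup table")
        zero_rows = counts.index[(counts.values == 0).all(axis=1)]
        if len(zero_rows):
            raise ValueError(
                f"orthogroups with no positive count: {list(zero_rows[:5])}"
            )
        self.counts = counts.astype(int)
        self.unassigned = dict(unassigned) if unassigned is not None else None
        if self.unassigned is not None:
            unknown = set(self.unassigned) - set(counts.columns)
            if unknown:
                raise ValueError(f"unassigned counts for unknown species: {unknown}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_orthogroups(self) -> int:
        return len(self.counts)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix (gene count >= 1)."""
        return self.counts > 0

    def __repr__(self) -> str:
        return (
            f"OrthogroupTable({self.n_orthogroups} orthogroups x "
            f"{len(self.species)} species)"
        )


# ---------------------------------------------------------------------------
# FASTA


def _opener(path):
    return gzip.open if str(path).endswith(".gz") else open


def read_fasta(path, preserve_case: bool = True) -> SequenceSet:
    """Read a (optionally gzip-compressed) FASTA file.

    The record id is the first whitespace-delimited token of the header;
    the full header line is retained in ``descriptions``.  Case is kept
    exactly unless ``preserve_case`` is false, in which case sequences are
    upper-cased.
    """
    path = Path(path)
    op = _opener(path)
    # SeqIO silently drops leading junk; enforce the FASTA precondition with
    # a line-numbered error instead.
    with op(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, sequence before first header "
                    f"at line {lineno}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    with op(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if not preserve_case:
                seq = seq.upper()
            if rec.id in descriptions:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            records.append((rec.id, seq))
            descriptions[rec.id] = rec.description
    return SequenceSet(records, descriptions=descriptions, source_path=str(path))


def write_fasta(seqs: SequenceSet, path, line_width: int = 80) -> None:
    """Write a SequenceSet as FASTA, wrapping sequence lines at `line_width`."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    op = _opener(path)
    with op(path, "wt") as fh:
        for rid, seq in seqs:
            desc = seqs.descriptions.get(rid, rid)
            fh.write(f">{desc}\n" if desc.startswith(rid) else f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path) -> GeneAnnotationSet:
    """Read gene models (gene + CDS, with optional mRNA intermediary) from GFF3.

    CDS features are linked to genes through Parent chains; a CDS whose
    Parent cannot be resolved is skipped with a warning.  When a gene has
    several mRNA isoforms the isoform with the largest total CDS length is
    used (parts must be non-overlapping).  A gene feature without an ID
    attribute is an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    # orphan CDS check
    for cds in db.features_of_type("CDS"):
        for parent_id in cds.attributes.get("Parent", []):
            try:
                db[parent_id]
            except gffutils.FeatureNotFoundError:
                warnings.warn(
                    f"CDS at {cds.seqid}:{cds.start}-{cds.end} has "
                    f"unresolvable Parent {parent_id!r}; skipped"
                )

    genes: list[Gene] = []
    for g in db.features_of_type("gene", order_by="start"):
        if "ID" not in g.attributes:
            raise ValueError(
                f"gene feature at {g.seqid}:{g.start}-{g.end} has no ID attribute"
            )
        gene_id = g.attributes["ID"][0]
        # CDS grouped by their immediate parent (mRNA or the gene itself)
        by_parent: dict[str, list[tuple[int, int]]] = {}
        for cds in db.children(g, featuretype="CDS"):
            for parent_id in cds.attributes.get("Parent", [g.id]):
                if parent_id not in known_ids:
                    continue
                by_parent.setdefault(parent_id, []).append((cds.start, cds.end))
        cds_parts: Optional[list[tuple[int, int]]] = None
        if by_parent:
            best = max(
                by_parent.values(),
                key=lambda parts: sum(e - s + 1 for s, e in parts),
            )
            cds_parts = sorted(set(best))
        strand = g.strand if g.strand in ("+", "-") else None
        if strand is None:
            raise ValueError(f"gene {gene_id}: missing or invalid strand")
        genes.append(
            Gene(
                gene_id=gene_id,
                contig_id=g.seqid,
                start=g.start,
                end=g.end,
                strand=strand,
                cds_parts=cds_parts,
            )
        )
    return GeneAnnotationSet(genes=genes)


def extract_gene_sequences(
    assembly: SequenceSet,
    annot: GeneAnnotationSet,
    mode: str = "cds",
) -> SequenceSet:
    """Extract per-gene sequences from an assembly.

    mode="gene_body": the contig substring start..end (1-based inclusive).
    mode="cds": concatenation of cds_parts in genomic order (genes without
    CDS parts fall back to the gene body span).  Minus-strand genes are
    reverse-complemented after extraction/concatenation.  Output ids are
    the gene ids; case is preserved.
    """
    if mode not in ("gene_body", "cds"):
        raise ValueError(f"mode must be 'gene_body' or 'cds', got {mode!r}")
    out: list[tuple[str, str]] = []
    for gene in annot:
        if gene.contig_id not in assembly:
            raise KeyError(
                f"gene {gene.gene_id}: contig {gene.contig_id!r} not in assembly"
            )
        contig = assembly[gene.contig_id]
        spans = (
            gene.cds_parts
            if (mode == "cds" and gene.cds_parts)
            else [(gene.start, gene.end)]
        )
        for s, e in spans:
            if s < 1 or e > len(contig):
                raise ValueError(
                    f"gene {gene.gene_id}: span {s}..{e} exceeds contig "
                    f"{gene.contig_id} length {len(contig)}"
                )
        seq = "".join(contig[s - 1 : e] for s, e in spans)
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append((gene.gene_id, seq))
    return SequenceSet(out)


# ---------------------------------------------------------------------------
# Orthogroup tables (OrthoFinder dialects)


def read_orthogroup_counts(path, dialect: str = "gene_count_tsv") -> OrthogroupTable:
    """Read an OrthoFinder-style orthogroup table.

    dialect="gene_count_tsv": `Orthogroups.GeneCount.tsv` — integer counts,
    an optional trailing "Total" column (dropped).
    dialect="membership_tsv": `Orthogroups.tsv` — comma-separated gene
    lists per cell; the count is the number of list entries, an empty cell
    is zero.
    """
    if dialect not in ("gene_count_tsv", "membership_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if dialect == "gene_count_tsv":
        if df.columns[-1] == "Total":
            df = df.iloc[:, :-1]
        try:
            counts = df.replace("", "0").astype(int)
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer gene count ({exc})") from exc
    else:
        counts = df.map(
            lambda cell: len([g for g in cell.split(",") if g.strip()])
        )
    return OrthogroupTable(counts)


# ---------------------------------------------------------------------------
# Curation evidence tables


def read_taxonomy_hits(path) -> TaxonomyEvidence:
    """Read `contig_id<TAB>description` rows (one per hit) into TaxonomyEvidence."""
    hits: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            hits.setdefault(parts[0], []).append(parts[1])
    return TaxonomyEvidence(hits=hits)


def read_rescue_table(path) -> dict[str, int]:
    """Read `contig_id<TAB>gene_id<TAB>orthogroup_id` rows; returns per-contig
    counts of genes assigned to a reference-clade orthogroup."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            counts[parts[0]] = counts.get(parts[0], 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"{path}: Newick parse error ({exc})") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("branch lengths required")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick, preserving labels and branch lengths."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
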