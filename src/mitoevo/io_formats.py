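"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (genomes and alignments), a GFF3 subset / TSV feature table,
Newick trees, TSV strain->species maps, and a minimal plain-text signed
gene-order format (one ``>taxon`` header line followed by whitespace-separated
gene names, ``-`` prefix meaning reverse strand)::

    >Phialocephala_subalpina
    rns cox1 -nad1 ...

All coordinates are 1-based inclusive (GenBank convention).  A feature that
crosses the origin of a circular genome is stored once with ``wraps_origin``
set rather than with end < start arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "GenomeRecord",
    "Feature",
    "GeneOrderRecord",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_gene_orders",
    "write_gene_orders",
    "read_feature_table",
    "write_feature_table",
    "read_newick",
    "read_species_map",
    "write_species_map",
    "gene_orders_from_features",
]

FEATURE_TYPES = ("gene_protein", "tRNA", "rRNA", "orf", "other")

#: mapping from common GFF3 "type" column values onto our feature classes
GFF3_TYPE_MAP = {
    "gene": "gene_protein",
    "cds": "gene_protein",
    "mrna": "gene_protein",
    "protein_coding_gene": "gene_protein",
    "trna": "tRNA",
    "trna_gene": "tRNA",
    "rrna": "rRNA",
    "rrna_gene": "rRNA",
    "orf": "orf",
    "open_reading_frame": "orf",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-ACGTN symbols {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    seq_id: str
    type: str
    start: int
    end: int
    strand: str
    name: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ParseError(f"feature {self.name!r}: unknown type {self.type!r}")
        if self.strand not in "+-":
            raise ParseError(f"feature {self.name!r}: strand must be + or -")
        if self.start < 1 or self.end < 1:
            raise ParseError(f"feature {self.name!r}: coordinates are 1-based")
        if not self.wraps_origin and self.start > self.end:
            raise ParseError(
                f"feature {self.name!r}: start > end without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for a wrapping feature")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, genome_length: int) -> range | list[int]:
        """1-based genome positions covered by the feature."""
        if self.end > genome_length or self.start > genome_length:
            raise ParseError(
                f"feature {self.name!r}: coordinates exceed genome length"
            )
        if self.wraps_origin:
            return list(range(self.start, genome_length + 1)) + list(
                range(1, self.end + 1)
            )
        return range(self.start, self.end + 1)


@dataclass
class GeneOrderRecord:
    """A named, signed, circular arrangement of genes.

    ``genes`` holds signed symbols such as ``"cox1"`` / ``"-nad1"``; each gene
    appears exactly once (sign ignored).
    """

    taxon: str
    genes: tuple[str, ...]
    alphabet: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        mags = [g.lstrip("-") for g in self.genes]
        seen: set[str] = set()
        for g in mags:
            if g in seen:
                raise ParseError(f"taxon {self.taxon!r}: duplicate gene {g!r}")
            seen.add(g)
        if self.alphabet is not None:
            self.alphabet = tuple(self.alphabet)
            extra = seen - set(self.alphabet)
            if extra:
                raise ParseError(
                    f"taxon {self.taxon!r}: unknown gene symbol(s) "
                    f"{sorted(extra)!r}"
                )

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g.lstrip("-") for g in self.genes)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read (possibly multi-record) FASTA; sequences are uppercased."""
    records: list[GenomeRecord] = []
    header: str | None = None
    chunks: list[str] = []
    seen_ids: set[str] = set()

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: record {header!r} has no sequence "
                             f"(near line {line_no})")
        if header in seen_ids:
            raise ParseError(f"{path}: duplicate record id {header!r}")
        seen_ids.add(header)
        records.append(GenomeRecord(id=header, sequence=seq))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {i}")
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: sequence before any header at line {i}"
                    )
                chunks.append(line)
        flush(-1)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[GenomeRecord],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> row mapping (gaps kept as '-')."""
    rows: dict[str, str] = {}
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    rows[header] = "".join(chunks).upper()
                header = line[1:].split()[0]
                if header in rows:
                    raise ParseError(f"{path}: duplicate sequence id {header!r}")
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence before header, line {i}")
                chunks.append(line)
    if header is not None:
        rows[header] = "".join(chunks).upper()
    if not rows:
        raise ParseError(f"{path}: no sequences")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    return rows


# ---------------------------------------------------------------------------
# Gene orders

def read_gene_orders(path: str | Path,
                     alphabet: Sequence[str] | None = None
                     ) -> list[GeneOrderRecord]:
    """Read the plain-text signed gene-order format.

    Unknown symbols (relative to ``alphabet``) and duplicated genes are hard
    errors: downstream rearrangement analysis requires equal gene content with
    each gene appearing exactly once.
    """
    records: list[GeneOrderRecord] = []
    taxon: str | None = None
    genes: list[str] = []

    def flush() -> None:
        nonlocal taxon, genes
        if taxon is None:
            return
        if not genes:
            raise ParseError(f"{path}: taxon {taxon!r} has no genes")
        records.append(GeneOrderRecord(taxon=taxon, genes=tuple(genes),
                                       alphabet=tuple(alphabet) if alphabet else None))
        taxon, genes = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                taxon = line[1:].strip()
                if not taxon:
                    raise ParseError(f"{path}: empty taxon name at line {i}")
            else:
                if taxon is None:
                    raise ParseError(f"{path}: genes before taxon at line {i}")
                genes.extend(line.split())
        flush()
    if not records:
        raise ParseError(f"{path}: no gene-order records")
    return records


def write_gene_orders(path: str | Path,
                      records: Iterable[GeneOrderRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.taxon}\n{' '.join(rec.genes)}\n")


# ---------------------------------------------------------------------------
# Feature tables (TSV dialect and GFF3 subset)

def _parse_gff3_name(attrs: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        for key in ("Name=", "ID=", "gene="):
            if part.startswith(key):
                return part[len(key):]
    return ""


def read_feature_table(path: str | Path,
                       genome_length: int | None = None) -> list[Feature]:
    """Read features from a TSV table or a GFF3 subset.

    TSV columns: ``seq_id  type  start  end  strand  name``.  GFF3 rows are
    recognized by their 9-column layout; the GFF3 type column is mapped onto
    our feature classes by :data:`GFF3_TYPE_MAP` (unknown types -> ``other``).
    """
    feats: list[Feature] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            try:
                if len(cols) >= 9:  # GFF3
                    seq_id, _src, gtype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
                    strand = cols[6]
                    name = _parse_gff3_name(cols[8])
                    ftype = GFF3_TYPE_MAP.get(gtype.lower(), "other")
                elif len(cols) >= 6:
                    seq_id, ftype, start, end, strand, name = cols[:6]
                else:
                    raise ParseError("expected 6 (TSV) or 9 (GFF3) columns")
                start_i, end_i = int(start), int(end)
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from None
            wraps = False
            if start_i > end_i:
                wraps = True  # origin-crossing feature encoded once
            try:
                feat = Feature(seq_id=seq_id, type=ftype, start=start_i,
                               end=end_i, strand=strand, name=name,
                               wraps_origin=wraps)
            except ParseError as exc:
                raise ParseError(f"{path}: row {i}: {exc}") from None
            if genome_length is not None and (
                    feat.start > genome_length or feat.end > genome_length):
                raise ParseError(
                    f"{path}: row {i}: coordinates exceed genome length "
                    f"{genome_length}")
            feats.append(feat)
    return feats


def write_feature_table(path: str | Path, features: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("#seq_id\ttype\tstart\tend\tstrand\tname\n")
        for f in features:
            fh.write(f"{f.seq_id}\t{f.type}\t{f.start}\t{f.end}\t"
                     f"{f.strand}\t{f.name}\n")


def gene_orders_from_features(features: Sequence[Feature],
                              genes: Sequence[str],
                              taxon: str) -> GeneOrderRecord:
    """Derive a signed gene order from an annotation: the named features are
    taken in genome-coordinate order, strand giving the sign."""
    wanted = {g: None for g in genes}
    picked = [f for f in features if f.name in wanted]
    missing = set(genes) - {f.name for f in picked}
    if missing:
        raise ParseError(f"taxon {taxon!r}: features missing for {sorted(missing)!r}")
    picked.sort(key=lambda f: f.start)
    signed = tuple(
        (f.name if f.strand == "+" else "-" + f.name) for f in picked
    )
    return GeneOrderRecord(taxon=taxon, genes=signed, alphabet=tuple(genes))


# ---------------------------------------------------------------------------
# Newick and species maps

def read_newick(path: str | Path, outgroup: str | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: Newick parse error: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"{path}: duplicate leaf names {dupes!r}")
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ParseError(f"{path}: outgroup {outgroup!r} not a leaf")
        tree.to_outgroup_position(node, update_bipartitions=False)
    return tree


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping strain id -> species name."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise ParseError(f"{path}: row {i}: expected strain<TAB>species")
            strain, species = cols[0], cols[1]
            if strain in mapping:
                raise ParseError(f"{path}: row {i}: duplicate strain {strain!r}")
            mapping[strain] = species
    if not mapping:
        raise ParseError(f"{path}: empty species map")
    return mapping


def write_species_map(path: str | Path, mapping: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for strain, species in mapping.items():
            fh.write(f"{strain}\t{species}\n")
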