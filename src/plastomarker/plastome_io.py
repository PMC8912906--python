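"""Plastome records: GenBank/FASTA input, annotation tables, BED output.

All coordinates exposed by the package are 0-based half-open on the forward
strand; the 1-based inclusive GenBank convention is converted at the parse
boundary (a location ``n..m`` becomes ``[n-1, m)``).  Sequences are stored
linearized at the deposited origin; a feature spanning the origin of a
circular record arrives from the parser as two location parts and is kept as
a two-exon annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plastomarker.errors import CoordinateError, ParseError

_ALLOWED = set("ACGTN")
_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


@dataclass
class GeneAnnotation:
    """A gene with one or more exons on the forward-strand coordinate system."""

    name: str
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # sorted, non-overlapping, 0-based half-open
    kind: str = "other"              # CDS | tRNA | rRNA | other

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s}, {e}) in {self.name}")
        self.exons = sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class PlastomeRecord:
    """A circular plastome sequence with gene annotations and provenance."""

    accession: str
    species: str
    individual_label: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ParseError(
                f"{self.accession}: ambiguity codes other than N rejected: "
                f"{sorted(bad)}")
        if not self.species or not self.individual_label:
            raise ValueError("species and individual_label must be non-empty")
        for g in self.genes:
            if g.span[1] > len(self.sequence) or g.span[0] < 0:
                raise CoordinateError(
                    f"feature {g.name} [{g.span[0]}, {g.span[1]}) outside "
                    f"sequence of length {len(self.sequence)}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def read_genbank(path, species: str | None = None,
                 individual_label: str | None = None) -> PlastomeRecord:
    """Parse a single-record GenBank flat file into a :class:`PlastomeRecord`.

    Genes are taken from CDS/tRNA/rRNA features; ``join()`` locations become
    multi-exon annotations.  ``species`` and ``individual_label`` default to
    the record's organism annotation and accession.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: record has no ORIGIN sequence")
    n = len(seq)
    genes: list[GeneAnnotation] = []
    for feat in rec.features:
        if feat.type not in _FEATURE_KINDS:
            continue
        name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                or feat.qualifiers.get("locus_tag") or ["?"])[0]
        exons = []
        for part in feat.location.parts:
            s, e = int(part.start), int(part.end)
            if e > n or s < 0:
                raise CoordinateError(
                    f"{path}: feature {name} location [{s}, {e}) exceeds "
                    f"sequence length {n}")
            exons.append((s, e))
        strand = "-" if (feat.location.strand or 1) < 0 else "+"
        genes.append(GeneAnnotation(name=name, strand=strand, exons=exons,
                                    kind=_FEATURE_KINDS[feat.type]))
    organism = rec.annotations.get("organism", "") or rec.id
    return PlastomeRecord(
        accession=rec.id or path.stem,
        species=species or organism,
        individual_label=individual_label or (rec.id or path.stem),
        sequence=seq,
        genes=genes,
    )


def write_fasta(record: PlastomeRecord, path) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.accession,
                    description=f"{record.species} {record.individual_label}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path, species: str | None = None,
               individual_label: str | None = None,
               annotation_table=None) -> PlastomeRecord:
    """Read a single-record FASTA, optionally attaching a gene table."""
    rec = SeqIO.read(str(path), "fasta")
    genes = read_gene_table(annotation_table) if annotation_table else []
    # description written by write_fasta: "<accession> <species> <label>"
    fields = rec.description.split()
    return PlastomeRecord(
        accession=rec.id,
        species=species or (" ".join(fields[1:-1]) if len(fields) > 2
                            else rec.id),
        individual_label=individual_label or (fields[-1] if len(fields) > 1
                                              else rec.id),
        sequence=str(rec.seq),
        genes=genes,
    )


def write_gene_table(genes: list[GeneAnnotation], path) -> None:
    """Write a TSV of gene annotations: name, strand, kind, exons (s-e,...)."""
    with open(path, "w") as fh:
        fh.write("name\tstrand\tkind\texons\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.name}\t{g.strand}\t{g.kind}\t{exons}\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("name\t"):
            raise ParseError(f"{path}: not a gene table (bad header)")
        for line in fh:
            if not line.strip():
                continue
            name, strand, kind, exons_txt = line.rstrip("\n").split("\t")
            exons = [tuple(int(x) for x in e.split("-"))
                     for e in exons_txt.split(",")]
            genes.append(GeneAnnotation(name=name, strand=strand,
                                        exons=exons, kind=kind))
    return genes


def write_regions(record: PlastomeRecord, structure, path) -> None:
    """Write the quadripartite partition as a 4-line BED file.

    Columns: chrom (accession), start, end, name — 0-based half-open.
    """
    if structure is None:
        raise ValueError("quadripartite structure absent: compute it first "
                         "with structure.detect_quadripartite")
    with open(path, "w") as fh:
        for name, iv in (("LSC", structure.lsc), ("IRb", structure.irb),
                         ("SSC", structure.ssc), ("IRa", structure.ira)):
            s, e = iv
            n = record.length_bp
            if e <= n:
                fh.write(f"{record.accession}\t{s}\t{e}\t{name}\n")
            else:  # region wraps the origin: split into two lines
                fh.write(f"{record.accession}\t{s}\t{n}\t{name}\n")
                fh.write(f"{record.accession}\t0\t{e - n}\t{name}\n")
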