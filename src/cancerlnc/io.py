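"""Readers and writers for the plain-text genomics formats the pipeline
consumes: GTF and BED12 gene models, BED4+ annotations, bedGraph signal
tracks, TSV expression matrices, FASTA sequences and one-ID-per-line lists.

Internally everything is 0-based half-open; GTF's 1-based inclusive
coordinates are converted at the boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import (
    AnnotationSet,
    DictSequences,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SequenceSource,
    SignalTrack,
)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    GTF files must carry ``gene_id`` attributes on every row; gene spans are
    taken from ``gene`` rows when present, otherwise from the exon envelope.
    The biotype comes from ``gene_type`` (or ``gene_biotype``) attributes.
    """
    if format == "gtf":
        return _read_gtf(Path(path))
    if format == "bed12":
        return _read_bed12(Path(path))
    raise ValidationError(f"unknown gene-model format {format!r} (gtf or bed12)")


def _read_gtf(path: Path) -> list[GeneModel]:
    bodies: dict[str, GenomicInterval] = {}
    biotypes: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"expected 9 tab-separated GTF fields", lineno)
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ParseError("missing gene_id attribute", lineno)
            try:
                iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
            except ValidationError as exc:
                raise ParseError(str(exc), lineno)
            if gene_id not in order:
                order.append(gene_id)
            bt = attr.get("gene_type") or attr.get("gene_biotype")
            if bt:
                biotypes[gene_id] = bt
            if feature == "gene":
                bodies[gene_id] = iv
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)

    genes = []
    for gid in order:
        ex = sorted(exons.get(gid, []), key=lambda e: e.start)
        body = bodies.get(gid)
        if body is None:
            if not ex:
                raise ValidationError(f"gene {gid!r} has neither gene row nor exons")
            body = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        if not ex:
            ex = [body]
        for e in ex:
            if e.start < body.start or e.end > body.end:
                raise ValidationError(
                    f"gene {gid!r}: exon [{e.start},{e.end}) outside gene span"
                )
        genes.append(
            GeneModel(gid, biotypes.get(gid, "lncRNA-intergenic"), body, tuple(ex))
        )
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            b = g.body
            fh.write(
                f"{b.chrom}\tcancerlnc\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tcancerlnc\texon\t{ex.start + 1}\t{ex.end}\t.\t{b.strand}\t.\t{attrs}\n"
                )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError("expected 12 BED12 columns", lineno)
            try:
                chrom, chrom_start, chrom_end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                block_count = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError("malformed BED12 numeric field", lineno)
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"blockCount={block_count} but {len(sizes)} sizes / "
                    f"{len(starts)} starts",
                    lineno,
                )
            strand = strand if strand in "+-" else "."
            try:
                body = GenomicInterval(chrom, chrom_start, chrom_end, strand)
                exons = tuple(
                    GenomicInterval(
                        chrom, chrom_start + s, chrom_start + s + sz, strand
                    )
                    for s, sz in zip(starts, sizes)
                )
                genes.append(GeneModel(name, "lncRNA-intergenic", body, exons))
            except ValidationError as exc:
                raise ParseError(str(exc), lineno)
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - b.start) for e in g.exons)
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed_annotations(
    path: str | Path,
    name: str,
    vocabulary: Iterable[str] | None = None,
    default_label: str | None = None,
) -> AnnotationSet:
    """Read a BED4+ file into an AnnotationSet; column 4 is the class
    label.  3-column rows take `default_label` (or `name`)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError("expected >= 3 BED columns", lineno)
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno)
            label = f[3] if len(f) > 3 else (default_label or name)
            records.append((iv, label))
    return AnnotationSet(name, records, vocabulary)


def write_bed_annotations(annot: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, label in sorted(annot, key=lambda r: (r[0].chrom, r[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_bedgraph(path: str | Path, name: str) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError("expected 4 bedGraph columns", lineno)
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                val = float(f[3])
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno)
            records.append((iv, val))
    return SignalTrack(name, records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            for iv, val in track.intervals(chrom):
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{val:g}\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene IDs in the first column and sample IDs in the
    header into a raw (un-normalized) ExpressionMatrix."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged or malformed TSV: {exc}")
    return ExpressionMatrix(df, normalized=False)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def write_fasta(seqs: DictSequences, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in seqs.chromosomes():
            fh.write(f">{chrom}\n")
            s = seqs.seqs[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


class FastaSequences(SequenceSource):
    """Random-access FASTA reader (faidx-backed)."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise ValidationError(f"chromosome {chrom!r} absent from FASTA")
        return str(self._fasta[chrom][max(0, start) : end])


def open_fasta(path: str | Path) -> FastaSequences:
    return FastaSequences(path)
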