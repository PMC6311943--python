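"""Genome-interval primitives and the in-memory containers built on them.

All coordinates in this package are 0-based, half-open (`[start, end)`),
the native convention of BED; format readers convert on the way in and
writers convert on the way out.  Strand is one of ``+``, ``-`` or ``.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Gene biotypes the pipeline distinguishes.  lncRNA subclasses follow the
#: positional relationship to protein-coding genes (antisense / intergenic /
#: overlapping).
BIOTYPES = (
    "lncRNA-antisense",
    "lncRNA-intergenic",
    "lncRNA-overlapping",
    "protein_coding",
    "miRNA",
)

LNCRNA_BIOTYPES = tuple(b for b in BIOTYPES if b.startswith("lncRNA"))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if
        they overlap or abut)."""
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        return max(0, self.start - other.end, other.start - self.end)


@dataclass(frozen=True)
class GeneModel:
    """One gene: body span plus an ordered, non-overlapping exon chain.

    The transcription start site (TSS) is the strand-aware 5' end of the
    body: ``body.start`` on the plus strand, ``body.end - 1`` on the minus
    strand.  Introns are the gaps between consecutive exons.
    """

    gene_id: str
    biotype: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.body.chrom:
                raise ValidationError(
                    f"{self.gene_id}: exon chromosome {ex.chrom} != body {self.body.chrom}"
                )
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValidationError(
                    f"{self.gene_id}: exon [{ex.start},{ex.end}) outside gene span "
                    f"[{self.body.start},{self.body.end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.strand != "-" else self.body.end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.body.chrom, a.end, b.start, self.strand)
                )
        return tuple(out)

    @property
    def is_lncrna(self) -> bool:
        return self.biotype in LNCRNA_BIOTYPES


def tss_flank(gene: GeneModel, w: int) -> GenomicInterval:
    """The merged up- and down-stream window ``[tss - w, tss + w)``,
    clipped at the chromosome origin.

    Up- and down-stream are treated as a single symmetric window; this is
    the reading under which the genomic (18) and epigenetic (27) feature
    blocks have self-consistent sizes.
    """
    if w <= 0:
        raise ValidationError(f"flank width must be positive, got {w}")
    tss = gene.tss
    return GenomicInterval(gene.body.chrom, max(0, tss - w), tss + w, gene.strand)


class AnnotationSet:
    """A named collection of labelled intervals (repeats, SNPs, somatic
    mutations, cancer-protein loci ...) with fast overlap queries."""

    def __init__(
        self,
        name: str,
        records: Iterable[tuple[GenomicInterval, str]],
        vocabulary: Iterable[str] | None = None,
    ):
        self.name = name
        self.records: list[tuple[GenomicInterval, str]] = list(records)
        if vocabulary is None:
            vocabulary = {lbl for _, lbl in self.records}
        self.vocabulary = frozenset(vocabulary)
        for iv, lbl in self.records:
            if lbl not in self.vocabulary:
                raise ValidationError(
                    f"{name}: label {lbl!r} not in declared vocabulary "
                    f"{sorted(self.vocabulary)}"
                )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[GenomicInterval, str]]:
        return iter(self.records)

    def _tree_for(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            # the payload carries the record index: duplicate records at the
            # same coordinates must count separately (IntervalTree is a set)
            for i, (iv, lbl) in enumerate(self.records):
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (i, lbl)
                )
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, region: GenomicInterval, class_label: str | None = None):
        """Yield (interval, label) records intersecting `region` by >= 1 bp."""
        if class_label is not None and class_label not in self.vocabulary:
            raise ValidationError(
                f"{self.name}: unknown class label {class_label!r}; "
                f"known labels: {sorted(self.vocabulary)}"
            )
        for hit in self._tree_for(region.chrom).overlap(region.start, region.end):
            _, lbl = hit.data
            if class_label is None or lbl == class_label:
                yield GenomicInterval(region.chrom, hit.begin, hit.end), lbl


def count_overlaps(
    region: GenomicInterval, annot: AnnotationSet, class_label: str | None = None
) -> int:
    """Number of `annot` records of `class_label` intersecting `region`
    by at least one base.  With ``class_label=None`` all records count."""
    return sum(1 for _ in annot.overlapping(region, class_label))


class SignalTrack:
    """A sparse per-base numeric signal (bedGraph semantics).

    Stored per chromosome as sorted, non-overlapping interval arrays;
    bases not covered by any interval have implicit value 0.
    """

    def __init__(
        self, name: str, records: Iterable[tuple[GenomicInterval, float]] = ()
    ):
        self.name = name
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, val in records:
            if not np.isfinite(val):
                raise ValidationError(f"{name}: non-finite value at {iv}")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(val)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{name}: overlapping intervals on {chrom}")
            self._chroms[chrom] = (starts, ends, vals)

    @classmethod
    def from_arrays(
        cls,
        name: str,
        per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "SignalTrack":
        """Build directly from pre-sorted (starts, ends, values) arrays."""
        track = cls(name, ())
        for chrom, (starts, ends, vals) in per_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            vals = np.asarray(vals, dtype=float)
            if np.any(starts[1:] < ends[:-1]) or np.any(starts >= ends):
                raise ValidationError(f"{name}: invalid interval arrays on {chrom}")
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"{name}: non-finite values on {chrom}")
            track._chroms[chrom] = (starts, ends, vals)
        return track

    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def intervals(self, chrom: str):
        starts, ends, vals = self._chroms.get(
            chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
        )
        for s, e, v in zip(starts, ends, vals):
            yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def mean(self, region: GenomicInterval) -> float:
        """Base-weighted mean signal over `region`; uncovered bases
        contribute 0."""
        if region.length <= 0:  # pragma: no cover - interval invariant
            raise ValidationError("zero-length region")
        if region.chrom not in self._chroms:
            return 0.0
        starts, ends, vals = self._chroms[region.chrom]
        # intervals are non-overlapping and sorted, so `ends` is sorted too
        i = int(np.searchsorted(ends, region.start, side="right"))
        j = int(np.searchsorted(starts, region.end, side="left"))
        if i >= j:
            return 0.0
        ov = np.minimum(ends[i:j], region.end) - np.maximum(starts[i:j], region.start)
        return float(np.dot(vals[i:j], ov) / region.length)


def mean_signal(track: SignalTrack, region: GenomicInterval) -> float:
    """Base-weighted mean of `track` over `region` (uncovered bases = 0)."""
    return track.mean(region)


class ExpressionMatrix:
    """A genes x samples count (or normalized-count) matrix."""

    def __init__(self, values: pd.DataFrame, normalized: bool = False):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene ID {dup!r} in expression matrix")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs in expression matrix")
        arr = values.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing expression value at gene {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        if (arr < 0).any():
            raise ValidationError("negative counts in expression matrix")
        self.values = values.astype(float)
        self.normalized = bool(normalized)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index


class SequenceSource:
    """Minimal random-access view over chromosome sequences."""

    def fetch(self, chrom: str, start: int, end: int) -> str:  # pragma: no cover
        raise NotImplementedError

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)


class DictSequences(SequenceSource):
    """In-memory sequences keyed by chromosome name."""

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = dict(seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def chromosomes(self) -> list[str]:
        return sorted(self.seqs)

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.seqs:
            raise ValidationError(f"chromosome {chrom!r} absent from sequence source")
        seq = self.seqs[chrom]
        return seq[max(0, start) : min(len(seq), end)].upper()


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(gene: GeneModel, seqs: SequenceSource) -> str:
    """Exon-union sequence of the gene in transcript (5'->3') orientation."""
    parts = [seqs.fetch_interval(ex) for ex in gene.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if gene.strand == "-" else seq
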