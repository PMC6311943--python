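"""Feature extraction: the genomic (18), expression (16) and epigenetic
(27) blocks, plus assembly of the full per-gene feature table.

Region conventions: "TSS +/- w" is the single merged window
``[tss - w, tss + w)``; exon and intron features use the union of the
gene's exons (resp. the gaps between them).  Intron features on
intronless genes are missing, never zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexnet import DEFAULT_DRIVER_GENES, network_feature_names
from .errors import ValidationError
from .intervals import (
    AnnotationSet,
    ExpressionMatrix,
    GeneModel,
    SequenceSource,
    SignalTrack,
    count_overlaps,
    spliced_sequence,
    tss_flank,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("genomic", "expression", "epigenetic", "network")

#: The 16 tissue panel of the multi-tissue expression compendium.
DEFAULT_TISSUES = (
    "adipose", "adrenal_gland", "brain", "breast", "colon", "heart",
    "kidney", "leukocyte", "liver", "lung", "lymph_node", "ovary",
    "prostate_gland", "skeletal_muscle", "testis", "thyroid_gland",
)

#: Nine histone-signal tracks: three marks in three cell lines.
DEFAULT_CELL_LINES = ("Gm12878", "K562", "H1hesc")
DEFAULT_MARKS = ("H3k4me1", "H3k4me3", "H3k27ac")
DEFAULT_TRACKS = tuple(
    f"{cl}{mk}" for cl in DEFAULT_CELL_LINES for mk in DEFAULT_MARKS
)

REPEAT_CLASSES = ("LINE", "LTR", "Satellite", "SINE")

_EPI_REGIONS = ("gene_body", "flank1k", "flank5k")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown feature category {self.category!r}")


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature inventory with category tags.

    The default manifest has 18 genomic + 16 expression + 27 epigenetic
    features plus one network feature per driver gene and four interaction/
    degree features (22 with the default 18-driver list; 83 in total).
    """

    specs: tuple[FeatureSpec, ...]
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    tracks: tuple[str, ...] = DEFAULT_TRACKS
    drivers: tuple[str, ...] = DEFAULT_DRIVER_GENES

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate feature names in manifest")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def categories(self) -> dict[str, str]:
        return {s.name: s.category for s in self.specs}

    def names_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown feature category {category!r}")
        return [s.name for s in self.specs if s.category == category]

    def digest(self) -> str:
        h = hashlib.sha256()
        for s in self.specs:
            h.update(f"{s.name}:{s.category};".encode())
        return h.hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "specs": [[s.name, s.category] for s in self.specs],
            "tissues": list(self.tissues),
            "tracks": list(self.tracks),
            "drivers": list(self.drivers),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            specs=tuple(FeatureSpec(n, c) for n, c in d["specs"]),
            tissues=tuple(d["tissues"]),
            tracks=tuple(d["tracks"]),
            drivers=tuple(d["drivers"]),
        )


def genomic_feature_names() -> list[str]:
    names = ["gc_flank1k", "gc_flank5k", "gc_gene_body", "gc_exon", "gc_intron",
             "cons_exon", "cons_intron", "cons_flank1k"]
    for cls in REPEAT_CLASSES:
        for region in ("gene_body", "flank1k"):
            names.append(f"{cls}_{region}")
    names += ["mirna_host_count", "micropeptide_length"]
    return names


def default_manifest(
    tissues: Sequence[str] = DEFAULT_TISSUES,
    tracks: Sequence[str] = DEFAULT_TRACKS,
    drivers: Sequence[str] = DEFAULT_DRIVER_GENES,
) -> FeatureManifest:
    specs: list[FeatureSpec] = []
    specs += [FeatureSpec(n, "genomic") for n in genomic_feature_names()]
    specs += [FeatureSpec(f"expr_{t}", "expression") for t in tissues]
    for tr in tracks:
        for region in _EPI_REGIONS:
            specs.append(FeatureSpec(f"{tr}_{region}", "epigenetic"))
    specs += [FeatureSpec(n, "network") for n in network_feature_names(drivers)]
    return FeatureManifest(
        tuple(specs), tuple(tissues), tuple(tracks), tuple(drivers)
    )


# ---------------------------------------------------------------------------
# sequence-level primitives


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes are excluded from the
    denominator.  Returns NaN (missing) for empty or all-N sequences."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return float("nan")
    return gc / denom


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_peptide_length(seq: str) -> int:
    """Length in codons (excluding the stop) of the longest ATG-initiated
    ORF terminated by a stop codon, over the 3 forward reading frames.
    Returns 0 when no complete ORF exists."""
    seq = seq.upper()
    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    best = 0
    for frame in range(3):
        open_atg = None  # earliest ATG since the last stop
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if open_atg is not None:
                    best = max(best, (i - open_atg) // 3)
                    open_atg = None
            elif codon == "ATG" and open_atg is None:
                open_atg = i
    return best


# ---------------------------------------------------------------------------
# per-gene feature blocks


def _regions_mean(track: SignalTrack, regions: Iterable) -> float:
    """Base-weighted mean over a union of disjoint regions; NaN if empty."""
    total = 0.0
    length = 0
    for r in regions:
        total += track.mean(r) * r.length
        length += r.length
    return total / length if length else float("nan")


def genomic_features(
    gene: GeneModel,
    seqs: SequenceSource,
    repeats: AnnotationSet,
    conservation: SignalTrack,
    mirnas: Iterable[GeneModel],
    manifest: FeatureManifest | None = None,
) -> dict[str, float]:
    """The 18 genomic features of one lncRNA.

    GC content of the merged 1 kb and 5 kb TSS flanks, gene body, exon
    union and intron union; mean conservation of exons, introns and the
    1 kb flank; LINE/LTR/Satellite/SINE counts in gene body and 1 kb
    flank; hosted miRNA count; micropeptide (longest-ORF) length of the
    spliced transcript.  Intron features on intronless genes are missing.
    """
    flank1k = tss_flank(gene, 1000)
    flank5k = tss_flank(gene, 5000)
    introns = gene.introns

    out: dict[str, float] = {}
    out["gc_flank1k"] = gc_content(seqs.fetch_interval(flank1k))
    out["gc_flank5k"] = gc_content(seqs.fetch_interval(flank5k))
    out["gc_gene_body"] = gc_content(seqs.fetch_interval(gene.body))
    out["gc_exon"] = gc_content("".join(seqs.fetch_interval(e) for e in gene.exons))
    out["gc_intron"] = (
        gc_content("".join(seqs.fetch_interval(i) for i in introns))
        if introns
        else float("nan")
    )
    out["cons_exon"] = _regions_mean(conservation, gene.exons)
    out["cons_intron"] = (
        _regions_mean(conservation, introns) if introns else float("nan")
    )
    out["cons_flank1k"] = conservation.mean(flank1k)
    for cls in REPEAT_CLASSES:
        out[f"{cls}_gene_body"] = count_overlaps(gene.body, repeats, cls)
        out[f"{cls}_flank1k"] = count_overlaps(flank1k, repeats, cls)
    out["mirna_host_count"] = sum(
        1 for m in mirnas if m.body.overlaps(gene.body)
    )
    transcript = spliced_sequence(gene, seqs)
    out["micropeptide_length"] = (
        longest_orf_peptide_length(transcript) if len(transcript) >= 3 else float("nan")
    )
    return out


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    Per sample j the factor is the median over reference genes i of
    ``count[i, j] / geometric_mean_i``; reference genes are those with
    strictly positive counts in every sample.
    """
    counts = m.values.to_numpy()
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene with all-positive counts; consider adding a pseudocount"
        )
    logc = np.log(counts[ref])
    log_geomean = logc.mean(axis=1, keepdims=True)
    ratios = np.exp(logc - log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normalize_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    if m.normalized:
        return m
    factors = size_factors(m)
    return ExpressionMatrix(m.values / factors.to_numpy(), normalized=True)


def expression_features(
    gene_id: str, m: ExpressionMatrix, manifest: FeatureManifest | None = None
) -> dict[str, float]:
    """The gene's normalized expression per tissue, one feature per tissue
    in the manifest's fixed order.  An absent gene yields a missing row."""
    manifest = manifest or default_manifest()
    if not m.normalized:
        raise ValidationError("expression features require a normalized matrix")
    tissues = list(manifest.tissues)
    missing = [t for t in tissues if t not in m.sample_ids]
    if missing:
        raise ValidationError(f"expression matrix lacks tissues: {missing}")
    if gene_id not in m:
        return {f"expr_{t}": float("nan") for t in tissues}
    row = m.values.loc[gene_id]
    return {f"expr_{t}": float(row[t]) for t in tissues}


def epigenetic_features(
    gene: GeneModel,
    tracks: Mapping[str, SignalTrack],
    manifest: FeatureManifest | None = None,
) -> dict[str, float]:
    """Mean signal of each of the 9 histone tracks over the gene body and
    the merged 1 kb and 5 kb TSS flanks (27 features)."""
    manifest = manifest or default_manifest()
    missing = [t for t in manifest.tracks if t not in tracks]
    if missing:
        raise ValidationError(f"missing epigenetic tracks: {missing}")
    regions = {
        "gene_body": gene.body,
        "flank1k": tss_flank(gene, 1000),
        "flank5k": tss_flank(gene, 5000),
    }
    out = {}
    for tr in manifest.tracks:
        for rname, region in regions.items():
            out[f"{tr}_{rname}"] = tracks[tr].mean(region)
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureTable:
    """Genes x features matrix with a missingness mask and category tags.

    ``values`` holds the (possibly imputed) numbers; ``mask`` is True where
    the underlying measurement was missing, regardless of imputation.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    categories: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.values.columns) != list(self.mask.columns) or len(
            self.values
        ) != len(self.mask):
            raise ValidationError("values and mask dimensions differ")
        unknown = [c for c in self.values.columns if c not in self.categories]
        if unknown:
            raise ValidationError(f"columns without category: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def columns_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown feature category {category!r}")
        return [c for c in self.values.columns if self.categories[c] == category]

    def matrix(
        self, gene_ids: Sequence[str], columns: Sequence[str] | None = None
    ) -> np.ndarray:
        cols = list(columns) if columns is not None else list(self.values.columns)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from feature table: {missing[:5]}")
        X = self.values.loc[list(gene_ids), cols].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValidationError(
                "feature matrix contains unimputed missing values; assemble "
                "with imputation='median' or 'zero'"
            )
        return X

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        meta = {
            "categories": self.categories,
            "metadata": self.metadata,
            "mask_true_cells": [
                [g, c]
                for g in self.mask.index
                for c in self.mask.columns
                if bool(self.mask.loc[g, c])
            ],
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        mask = pd.DataFrame(
            False, index=values.index, columns=values.columns, dtype=bool
        )
        for g, c in meta["mask_true_cells"]:
            mask.loc[g, c] = True
        return cls(values, mask, meta["categories"], meta.get("metadata", {}))


@dataclass
class ResourceBundle:
    """Everything feature assembly needs, already loaded into memory."""

    seqs: SequenceSource
    repeats: AnnotationSet
    conservation: SignalTrack
    mirnas: tuple[GeneModel, ...]
    tracks: Mapping[str, SignalTrack]
    expression: ExpressionMatrix  # normalized
    provenance: dict = field(default_factory=dict)


def assemble_feature_table(
    genes: Sequence[GeneModel],
    resources: ResourceBundle,
    network_block: pd.DataFrame,
    manifest: FeatureManifest | None = None,
    imputation: str = "median",
) -> FeatureTable:
    """One row per gene, columns in manifest order.

    Missing values (intronless-gene intron features, genes absent from the
    expression matrix, absent drivers ...) are flagged in the mask and
    imputed according to `imputation`: per-column median computed on the
    assembled population, zero, or left as NaN (``none``).
    """
    if imputation not in ("median", "zero", "none"):
        raise ValidationError(f"unknown imputation policy {imputation!r}")
    manifest = manifest or default_manifest()
    expr = resources.expression
    if not expr.normalized:
        raise ValidationError("resources.expression must be normalized")

    rows = {}
    for g in genes:
        row: dict[str, float] = {}
        row.update(
            genomic_features(
                g, resources.seqs, resources.repeats, resources.conservation,
                resources.mirnas, manifest,
            )
        )
        row.update(expression_features(g.gene_id, expr, manifest))
        row.update(epigenetic_features(g, resources.tracks, manifest))
        if g.gene_id in network_block.index:
            row.update(network_block.loc[g.gene_id].to_dict())
        rows[g.gene_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index")
    # enforce manifest column order; any feature never computed is missing
    values = values.reindex(columns=manifest.names)
    mask = values.isna()
    if imputation == "median":
        values = values.fillna(values.median(axis=0, skipna=True))
        values = values.fillna(0.0)  # columns that are entirely missing
    elif imputation == "zero":
        values = values.fillna(0.0)

    metadata = {
        "manifest_digest": manifest.digest(),
        "imputation": imputation,
        "n_genes": len(values),
        **resources.provenance,
    }
    return FeatureTable(values, mask, manifest.categories, metadata)
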