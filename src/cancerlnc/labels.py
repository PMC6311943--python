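"""Construction of the training label sets.

Positives are the curated cancer-related lncRNAs supplied by the user.
The negative pool contains lncRNAs (intergenic ones by default) with no
cancer-trait GWAS SNP within a 10 kb window around the gene body; balanced
training sets are drawn from that pool by repeated uniform sampling
without replacement (150 genes, 100 times by default), so each model sees
a roughly class-balanced problem while the ensemble sees the whole pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import AnnotationSet, GeneModel, GenomicInterval

#: Trait keywords used to restrict a GWAS catalog to cancer-associated SNPs.
CANCER_TRAIT_KEYWORDS = (
    "cancer",
    "carcinoma",
    "tumor",
    "leukemia",
    "lymphoma",
    "melanoma",
    "glioma",
)


@dataclass(frozen=True)
class LabelBundle:
    """Positive IDs, SNP-filtered negative pool, and the sampled balanced
    negative sets, together with the parameters that produced them."""

    positives: frozenset[str]
    negative_pool: frozenset[str]
    negative_sets: tuple[tuple[str, ...], ...]
    seed: int
    window_bp: int
    set_size: int

    def __post_init__(self):
        if self.positives & self.negative_pool:
            raise ValidationError("positives overlap the negative pool")
        for i, s in enumerate(self.negative_sets):
            ids = set(s)
            if len(ids) != len(s):
                raise ValidationError(f"negative set {i} contains duplicates")
            if not ids <= self.negative_pool:
                raise ValidationError(f"negative set {i} not a subset of the pool")
            if len(ids) != self.set_size:
                raise ValidationError(
                    f"negative set {i} has {len(ids)} entries, expected {self.set_size}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positives": sorted(self.positives),
            "negative_pool": sorted(self.negative_pool),
            "negative_sets": [list(s) for s in self.negative_sets],
            "seed": self.seed,
            "window_bp": self.window_bp,
            "set_size": self.set_size,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            positives=frozenset(d["positives"]),
            negative_pool=frozenset(d["negative_pool"]),
            negative_sets=tuple(tuple(s) for s in d["negative_sets"]),
            seed=int(d["seed"]),
            window_bp=int(d["window_bp"]),
            set_size=int(d["set_size"]),
        )


def filter_cancer_snps(
    snps: AnnotationSet, keywords: Sequence[str] = CANCER_TRAIT_KEYWORDS
) -> AnnotationSet:
    """Restrict a trait-labelled SNP catalog to cancer-associated traits by
    case-insensitive keyword match on the class label."""
    kws = tuple(k.lower() for k in keywords)
    records = [
        (iv, lbl)
        for iv, lbl in snps
        if any(k in lbl.lower() for k in kws)
    ]
    return AnnotationSet(f"{snps.name}:cancer", records)


def build_negative_pool(
    lncrnas: Iterable[GeneModel],
    snps: AnnotationSet | None,
    window_bp: int = 10_000,
    positives: Iterable[str] = (),
    intergenic_only: bool = True,
    exclude: Iterable[str] = (),
) -> frozenset[str]:
    """IDs of lncRNAs with no SNP within `window_bp` of the gene body.

    The window is ``[body.start - window_bp, body.end + window_bp)``
    clipped at 0.  `snps` should already be restricted to cancer-associated
    traits (see :func:`filter_cancer_snps`); ``snps=None`` means no SNP
    evidence, so every non-positive lncRNA enters the pool.  By default only
    intergenic lncRNAs are considered.  `exclude` removes further IDs (for
    example a held-out prediction set) from consideration.
    """
    genes = [g for g in lncrnas if g.is_lncrna]
    if intergenic_only:
        genes = [g for g in genes if g.biotype == "lncRNA-intergenic"]
    if not genes:
        raise ValidationError("no candidate lncRNAs supplied for the negative pool")
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    skip = frozenset(positives) | frozenset(exclude)

    pool = set()
    for g in genes:
        if g.gene_id in skip:
            continue
        window = GenomicInterval(
            g.body.chrom,
            max(0, g.body.start - window_bp),
            g.body.end + window_bp,
            g.strand,
        )
        if snps is None or not any(snps.overlapping(window)):
            pool.add(g.gene_id)
    return frozenset(pool)


def sample_negative_sets(
    pool: Iterable[str],
    n_sets: int = 100,
    size: int = 150,
    seed: int = 0,
) -> tuple[tuple[str, ...], ...]:
    """Draw `n_sets` independent uniform samples of `size` distinct IDs
    from the pool.  Sets may overlap each other; each is duplicate-free.
    Fully deterministic given the seed (pool order does not matter)."""
    pool_sorted = sorted(set(pool))
    if size > len(pool_sorted):
        raise ValidationError(
            f"requested set size {size} exceeds pool size {len(pool_sorted)}"
        )
    if n_sets <= 0:
        raise ValidationError("n_sets must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        idx = rng.choice(len(pool_sorted), size=size, replace=False)
        out.append(tuple(pool_sorted[i] for i in sorted(idx)))
    return tuple(out)


def build_label_bundle(
    lncrnas: Iterable[GeneModel],
    snps: AnnotationSet | None,
    positives: Iterable[str],
    window_bp: int = 10_000,
    n_sets: int = 100,
    set_size: int = 150,
    seed: int = 0,
    intergenic_only: bool = True,
    exclude: Iterable[str] = (),
) -> LabelBundle:
    """Convenience wrapper: SNP-filter the pool, then sample the balanced
    negative sets."""
    positives = frozenset(positives)
    pool = build_negative_pool(
        lncrnas, snps, window_bp=window_bp, positives=positives,
        intergenic_only=intergenic_only, exclude=exclude,
    )
    sets = sample_negative_sets(pool, n_sets=n_sets, size=set_size, seed=seed)
    return LabelBundle(
        positives=positives,
        negative_pool=pool,
        negative_sets=sets,
        seed=seed,
        window_bp=window_bp,
        set_size=set_size,
    )
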