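"""Systematic evaluation of features and predicted candidates.

Distributional contrasts between lncRNA sets use the two-sample
Kolmogorov-Smirnov test; candidate sets are further profiled by somatic
mutation burden, distance to the nearest cancer-related protein locus,
differential-expression fraction, and guilt-by-association GO annotation
transferred from co-expression neighbors via one-sided Fisher's exact
(hypergeometric) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexnet import CoexpressionNetwork
from .errors import ValidationError
from .intervals import AnnotationSet, ExpressionMatrix, GeneModel, count_overlaps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS statistic D (sup gap between ECDFs) and its p-value."""

    d: float
    p: float
    n1: int
    n2: int


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], method: str = "asymp"
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute gap between the two empirical CDFs over the
    pooled sample points; the p-value uses the asymptotic Kolmogorov
    distribution with effective size n1*n2/(n1+n2) (``method="exact"``
    switches to the exact small-sample distribution)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if method not in ("asymp", "exact"):
        raise ValidationError(f"unknown KS method {method!r}")
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def feature_ks_table(
    table_values: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    method: str = "asymp",
) -> pd.DataFrame:
    """Per-feature KS comparison of two gene sets (rows of a feature
    matrix); NaNs within a feature column are dropped per group."""
    group_a = [g for g in group_a if g in table_values.index]
    group_b = [g for g in group_b if g in table_values.index]
    rows = []
    for col in table_values.columns:
        a = table_values.loc[group_a, col].dropna().to_numpy()
        b = table_values.loc[group_b, col].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            rows.append({"feature": col, "d": np.nan, "p": np.nan,
                         "n1": a.size, "n2": b.size})
            continue
        r = ks_two_sample(a, b, method=method)
        rows.append({"feature": col, "d": r.d, "p": r.p, "n1": r.n1, "n2": r.n2})
    return pd.DataFrame(rows)


def log2_fold_changes(
    tumor: ExpressionMatrix, normal: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((mean tumor + eps) / (mean normal + eps)) over the
    genes shared by both matrices."""
    shared = [g for g in tumor.gene_ids if g in normal]
    if not shared:
        raise ValidationError("tumor and normal matrices share no genes")
    t = tumor.values.loc[shared].mean(axis=1) + pseudocount
    n = normal.values.loc[shared].mean(axis=1) + pseudocount
    return np.log2(t / n).rename("log2fc")


def de_fraction(log2fc: Sequence[float], cutoff: float = 1.0) -> float:
    """Fraction of genes with |log2 fold change| > cutoff; NAs are dropped
    (count logged)."""
    fc = np.asarray(log2fc, dtype=float)
    n_na = int(np.isnan(fc).sum())
    if n_na:
        logger.info("de_fraction: dropping %d NA fold changes", n_na)
    fc = fc[~np.isnan(fc)]
    if fc.size == 0:
        raise ValidationError("all fold changes are NA")
    if not np.all(np.isfinite(fc)):
        raise ValidationError("fold changes must be finite")
    return float(np.mean(np.abs(fc) > cutoff))


def mutation_burden(
    genes: Iterable[GeneModel], mutations: AnnotationSet
) -> pd.Series:
    """Somatic mutation records overlapping each gene body."""
    out = {g.gene_id: count_overlaps(g.body, mutations) for g in genes}
    return pd.Series(out, dtype=int, name="mutation_count")


def closest_distances(
    query: Sequence[GeneModel],
    anchors: AnnotationSet,
    random_background: int | None = None,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Distance from each query gene to its nearest anchor interval on the
    same chromosome (0 when overlapping), plus a matched random background.

    The background samples uniform positions per chromosome (by default
    ``10 x`` the number of usable queries, proportional to chromosome
    length) and takes the same nearest-anchor statistic.  Queries on
    chromosomes without anchors are excluded with a warning.
    """
    if len(anchors) == 0:
        raise ValidationError("no anchor intervals supplied")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv, _ in anchors:
        by_chrom.setdefault(iv.chrom, ([], []))
        by_chrom[iv.chrom][0].append(iv.start)
        by_chrom[iv.chrom][1].append(iv.end)
    by_chrom = {
        c: (np.asarray(s), np.asarray(e)) for c, (s, e) in by_chrom.items()
    }

    dists = {}
    skipped = 0
    for g in query:
        if g.body.chrom not in by_chrom:
            skipped += 1
            continue
        s, e = by_chrom[g.body.chrom]
        gap = np.maximum(0, np.maximum(s - g.body.end, g.body.start - e))
        dists[g.gene_id] = int(gap.min())
    if skipped:
        logger.warning(
            "closest_distances: %d queries on anchor-free chromosomes skipped",
            skipped,
        )
    if not dists:
        raise ValidationError("no query gene shares a chromosome with an anchor")

    if chrom_lengths is None:
        chrom_lengths = {}
        for c, (s, e) in by_chrom.items():
            chrom_lengths[c] = int(e.max())
        for g in query:
            c = g.body.chrom
            if c in chrom_lengths:
                chrom_lengths[c] = max(chrom_lengths[c], g.body.end)

    n_bg = random_background if random_background is not None else 10 * len(dists)
    rng = np.random.default_rng(seed)
    chroms = sorted(c for c in by_chrom if c in chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    bg = np.empty(n_bg, dtype=int)
    picks = rng.choice(len(chroms), size=n_bg, p=probs)
    for i, ci in enumerate(picks):
        c = chroms[ci]
        pos = int(rng.integers(0, chrom_lengths[c]))
        s, e = by_chrom[c]
        gap = np.maximum(0, np.maximum(s - (pos + 1), pos - e))
        bg[i] = gap.min()
    return pd.Series(dists, name="closest_distance"), bg


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher's exact (hypergeometric upper tail): probability of
    drawing >= k annotated genes when sampling n from a universe of N
    containing K annotated."""
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValidationError(f"inconsistent margins: K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term tested for over-representation among network neighbors."""

    term_id: str
    term_name: str
    counts: tuple[int, int, int, int]  # (k, n-k, K, N-K)
    p: float
    significant: bool


def go_transfer(
    net: CoexpressionNetwork,
    go: Mapping[str, set[str]],
    gene: str,
    alpha: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Guilt-by-association GO annotation of one network gene.

    Every term annotating at least one immediate neighbor is tested by
    :func:`hypergeometric_enrichment` with the gene's annotated
    protein-coding neighbors as the sample and all GO-annotated
    protein-coding network nodes as the background.  Results are returned
    for all tested terms sorted by p, flagged significant at `alpha`
    (assigned terms are the significant ones).  An isolated gene yields an
    empty list."""
    if gene not in net:
        raise ValidationError(f"gene {gene!r} not in network")
    term_names = term_names or {}
    background = [
        g for g in net.nodes
        if net.biotypes.get(g) == "protein_coding" and g in go and go[g]
    ]
    N = len(background)
    bg_with: dict[str, int] = {}
    for g in background:
        for t in go[g]:
            bg_with[t] = bg_with.get(t, 0) + 1

    neighbors = [g for g in net.neighbors(gene) if g in set(background)]
    n = len(neighbors)
    if n == 0:
        return []
    nb_with: dict[str, int] = {}
    for g in neighbors:
        for t in go[g]:
            nb_with[t] = nb_with.get(t, 0) + 1

    results = []
    for term, k in nb_with.items():
        K = bg_with[term]
        p = hypergeometric_enrichment(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=term_names.get(term, ""),
                counts=(k, n - k, K, N - K),
                p=p,
                significant=bool(p < alpha),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "neighbors_with": r.counts[0],
                "neighbors_without": r.counts[1],
                "background_with": r.counts[2],
                "background_without": r.counts[3],
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "neighbors_with", "neighbors_without",
            "background_with", "background_without", "p", "significant",
        ],
    )


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, GO term id); returns gene -> term set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValidationError(f"line {lineno}: expected 2 columns")
            if lineno == 1 and f[0].lower() in {"gene", "gene_id"}:
                continue
            out.setdefault(f[0], set()).add(f[1])
    return out


def write_go_map(go: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for g in sorted(go):
            for t in sorted(go[g]):
                fh.write(f"{g}\t{t}\n")
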