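"""Coding-lncRNA co-expression network and the network feature block.

Edges are called from Spearman's rank correlation across tissues.  For a
pair with correlation Rs over n samples the significance is assessed
through the Fisher variance-stabilizing transform,

    F(Rs) = 1/2 * ln((1 + Rs) / (1 - Rs)),
    Z     = sqrt((n - 3) / 1.06) * F(Rs),

where Z is approximately standard normal under independence (the 1.06
factor is the classical small-sample variance correction for ranked
data).  Two-sided normal p-values are Benjamini-Hochberg adjusted across
all tested pairs; an edge is retained iff Rs >= 0.6 (signed) and the
adjusted p-value is <= 0.01.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConstantInputError, ValidationError
from .intervals import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of one gene pair with its Fisher-z test."""

    rs: float
    f: float
    z: float
    p: float
    p_adj: float
    n: int


def spearman_rs(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's Rs: the Pearson correlation of average-ranked values.

    Ties receive average ranks.  Raises :class:`ConstantInputError` for a
    constant vector (undefined correlation; callers map this to "no edge").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValidationError(f"need n >= 4 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def edge_significance(rs: float, n: int) -> tuple[float, float, float]:
    """Fisher transform, Z statistic and two-sided normal p for one Rs.

    ``|rs| = 1`` returns infinite F and Z with p = 0.
    """
    if n < 4:
        raise ValidationError(f"need n >= 4 samples, got {n}")
    if not -1.0 <= rs <= 1.0:
        raise ValidationError(f"correlation out of range: {rs}")
    if abs(rs) == 1.0:
        inf = math.inf if rs > 0 else -math.inf
        return inf, inf, 0.0
    f = math.atanh(rs)  # = 1/2 ln((1+rs)/(1-rs))
    z = math.sqrt((n - 3) / 1.06) * f
    p = 2.0 * stats.norm.sf(abs(z))
    return f, z, float(p)


class CoexpressionNetwork:
    """Undirected co-expression network with per-edge test statistics."""

    def __init__(
        self,
        biotypes: Mapping[str, str],
        rs_cutoff: float = 0.6,
        p_adj_cutoff: float = 0.01,
    ):
        self.biotypes = dict(biotypes)
        self.rs_cutoff = float(rs_cutoff)
        self.p_adj_cutoff = float(p_adj_cutoff)
        self._adj: dict[str, dict[str, CorrelationResult]] = {
            g: {} for g in self.biotypes
        }

    def add_edge(self, a: str, b: str, result: CorrelationResult) -> None:
        if a == b:
            raise ValidationError("self-edges are not allowed")
        for g in (a, b):
            if g not in self._adj:
                raise ValidationError(f"unknown node {g!r}")
        if result.rs < self.rs_cutoff or result.p_adj > self.p_adj_cutoff:
            raise ValidationError("edge does not satisfy the declared cutoffs")
        self._adj[a][b] = result
        self._adj[b][a] = result

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self._adj:
            raise ValidationError(f"gene {gene!r} not in network")
        return sorted(self._adj[gene])

    def degree(self, gene: str) -> int:
        return len(self._adj[gene])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, {})

    def edge(self, a: str, b: str) -> CorrelationResult:
        return self._adj[a][b]

    def edges(self) -> Iterator[tuple[str, str, CorrelationResult]]:
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield a, b, self._adj[a][b]

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "rs": r.rs,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
            }
            for a, b, r in self.edges()
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rs", "p", "p_adj", "n"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rs_cutoff": self.rs_cutoff,
            "p_adj_cutoff": self.p_adj_cutoff,
            "biotypes": self.biotypes,
            "edges": [
                [a, b, r.rs, r.f, r.z, r.p, r.p_adj, r.n] for a, b, r in self.edges()
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoexpressionNetwork":
        d = json.loads(Path(path).read_text())
        net = cls(d["biotypes"], d["rs_cutoff"], d["p_adj_cutoff"])
        for a, b, rs, f, z, p, p_adj, n in d["edges"]:
            net.add_edge(a, b, CorrelationResult(rs, f, z, p, p_adj, int(n)))
        return net


def build_network(
    m: ExpressionMatrix,
    biotypes: Mapping[str, str],
    rs_cutoff: float = 0.6,
    p_adj_cutoff: float = 0.01,
) -> CoexpressionNetwork:
    """Test every gene pair and keep edges with Rs >= `rs_cutoff` and
    BH-adjusted p <= `p_adj_cutoff`.

    Genes with constant expression cannot be ranked meaningfully and are
    excluded from testing (a count is logged); they remain isolated nodes.
    """
    if not m.normalized:
        raise ValidationError("build_network expects a normalized expression matrix")
    n_samples = m.shape[1]
    if n_samples < 4:
        raise ValidationError(f"need >= 4 samples, got {n_samples}")

    genes = [g for g in m.gene_ids if g in biotypes]
    values = m.values.loc[genes].to_numpy()
    const = np.ptp(values, axis=1) == 0
    if const.any():
        logger.warning(
            "%d constant-expression genes excluded from network testing", const.sum()
        )
    kept = [g for g, c in zip(genes, const) if not c]
    vals = values[~const]

    net = CoexpressionNetwork(
        {g: biotypes[g] for g in genes}, rs_cutoff, p_adj_cutoff
    )
    if len(kept) < 2:
        return net

    # rank each gene across samples once, then one matrix product gives
    # every pairwise Spearman correlation
    ranks = stats.rankdata(vals, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    corr = (ranks @ ranks.T) / np.outer(norms, norms)
    np.clip(corr, -1.0, 1.0, out=corr)

    iu, ju = np.triu_indices(len(kept), k=1)
    rs = corr[iu, ju]
    scale = math.sqrt((n_samples - 3) / 1.06)
    with np.errstate(divide="ignore"):
        f = np.arctanh(rs)
    z = scale * f
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[np.isinf(z)] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]

    keep = (rs >= rs_cutoff) & (p_adj <= p_adj_cutoff)
    for a_i, b_i, rs_v, f_v, z_v, p_v, pa_v in zip(
        iu[keep], ju[keep], rs[keep], f[keep], z[keep], p[keep], p_adj[keep]
    ):
        net.add_edge(
            kept[a_i],
            kept[b_i],
            CorrelationResult(
                float(rs_v), float(f_v), float(z_v), float(p_v), float(pa_v), n_samples
            ),
        )
    return net


#: Mutational-hotspot cancer driver genes used for the driver-correlation
#: feature block (configurable; these are the defaults).
DEFAULT_DRIVER_GENES = (
    "BRAF", "CDKN2A", "CTNNB1", "EGFR", "ERBB2", "FBXW7", "GNAS", "H3F3A",
    "HRAS", "IDH1", "KRAS", "NRAS", "PIK3CA", "PTEN", "RAC1", "SF3B1",
    "TP53", "U2AF1",
)


def network_feature_names(drivers: Sequence[str] = DEFAULT_DRIVER_GENES) -> list[str]:
    return [f"scc_{d}" for d in drivers] + [
        "cancer_protein_neighbors",
        "network_degree",
        "cancer_mirna_interactions",
        "mirna_interactions",
    ]


def network_features(
    gene: str,
    net: CoexpressionNetwork,
    m: ExpressionMatrix,
    drivers: Sequence[str] = DEFAULT_DRIVER_GENES,
    cancer_proteins: Iterable[str] = (),
    mirna_interactions: Iterable[tuple[str, str]] = (),
    cancer_mirnas: Iterable[str] = (),
) -> dict[str, float]:
    """Network feature vector for one lncRNA.

    Per driver gene the raw signed Spearman Rs with that driver (no edge
    cutoff applied); then the number of co-expression neighbors that are
    cancer-related proteins, the total degree, and the counts of
    interacting cancer-related and total miRNAs.
    """
    table = network_features_table(
        [gene], net, m, drivers, cancer_proteins, mirna_interactions, cancer_mirnas
    )
    return table.loc[gene].to_dict()


def network_features_table(
    genes: Sequence[str],
    net: CoexpressionNetwork,
    m: ExpressionMatrix,
    drivers: Sequence[str] = DEFAULT_DRIVER_GENES,
    cancer_proteins: Iterable[str] = (),
    mirna_interactions: Iterable[tuple[str, str]] = (),
    cancer_mirnas: Iterable[str] = (),
) -> pd.DataFrame:
    """Vectorized :func:`network_features` over many lncRNAs."""
    if not m.normalized:
        raise ValidationError("network features expect a normalized expression matrix")
    cancer_proteins = frozenset(cancer_proteins)
    cancer_mirnas = frozenset(cancer_mirnas)
    cols = network_feature_names(drivers)
    out = pd.DataFrame(np.nan, index=list(genes), columns=cols, dtype=float)

    # driver correlations: rank once, correlate lncRNA rows against driver rows
    present = [g for g in genes if g in m]
    ranks = {}
    if present:
        sub = m.values.loc[present].to_numpy()
        r = stats.rankdata(sub, axis=1).astype(float)
        r -= r.mean(axis=1, keepdims=True)
        ranks = {g: r[i] for i, g in enumerate(present)}
    for d in drivers:
        col = f"scc_{d}"
        if d not in m:
            continue  # absent driver: whole column stays missing
        dv = m.row(d)
        if np.ptp(dv) == 0:
            continue
        dr = stats.rankdata(dv)
        dr = dr - dr.mean()
        dnorm = math.sqrt(np.dot(dr, dr))
        for g in present:
            gr = ranks[g]
            gnorm = math.sqrt(np.dot(gr, gr))
            if gnorm == 0:  # constant gene: correlation undefined
                continue
            out.loc[g, col] = float(np.dot(gr, dr) / (gnorm * dnorm))

    # interaction counts; genes absent from the expression matrix keep a
    # fully missing block, genes excluded from the network get zero counts
    inter: dict[str, set[str]] = {}
    for mirna, lnc in mirna_interactions:
        inter.setdefault(lnc, set()).add(mirna)
    for g in genes:
        if g not in m:
            continue
        if g in net:
            nbrs = net.neighbors(g)
            out.loc[g, "network_degree"] = len(nbrs)
            out.loc[g, "cancer_protein_neighbors"] = sum(
                1 for nb in nbrs if nb in cancer_proteins
            )
        else:
            out.loc[g, "network_degree"] = 0.0
            out.loc[g, "cancer_protein_neighbors"] = 0.0
        mirnas = inter.get(g, set())
        out.loc[g, "mirna_interactions"] = len(mirnas)
        out.loc[g, "cancer_mirna_interactions"] = len(mirnas & cancer_mirnas)
    return out


def read_mirna_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (mirna_id, lncRNA_id), optional header."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValidationError(f"line {lineno}: expected 2 columns")
            if lineno == 1 and f[0].lower() in {"mirna", "mirna_id"}:
                continue
            pairs.append((f[0], f[1]))
    return pairs


def write_mirna_interactions(
    pairs: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tlncrna_id\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
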