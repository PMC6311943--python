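"""End-to-end orchestration: a shared run configuration and the staged
pipeline (simulate -> labels -> network -> features -> train /
importance / predict -> evaluate) operating on a workspace directory.

Every stage reads its inputs from the standard on-disk formats and
writes artifacts stamped with the configuration hash and seed, so a
rerun with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as cio
from .classify import (
    ALGORITHMS,
    evaluate_algorithms,
    feature_importance,
    pooled_roc_points,
    predict_candidates,
    predictions_to_dataframe,
)
from .coexnet import (
    CoexpressionNetwork,
    build_network,
    network_features_table,
    read_mirna_interactions,
)
from .errors import DependencyError, ValidationError
from .evaluate import (
    de_fraction,
    enrichment_to_dataframe,
    feature_ks_table,
    go_transfer,
    log2_fold_changes,
    mutation_burden,
    read_go_map,
)
from .features import (
    FeatureTable,
    ResourceBundle,
    assemble_feature_table,
    default_manifest,
    normalize_expression,
)
from .labels import LabelBundle, build_label_bundle, filter_cancer_snps
from .simulate import SimulatedBundle, SimulationConfig, simulate_bundle, write_bundle

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "labels", "network", "features", "train", "importance",
    "predict", "evaluate",
)

#: Which stage produces each artifact (for actionable dependency errors).
_PRODUCERS = {
    "bundle/genes.gtf": "simulate",
    "bundle/expression.tsv": "simulate",
    "labels.json": "labels",
    "network.json": "network",
    "features.tsv": "features",
    "cv_report.json": "train",
    "candidates.tsv": "predict",
}


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline run.

    Defaults are the pipeline's standard operating point: co-expression
    edges at Rs >= 0.6 and BH-adjusted p <= 0.01, a 10 kb SNP exclusion
    window, 100 negative sets of 150 genes, ten-fold cross-validation,
    candidate threshold 0.5, GO transfer at p < 0.05 and a |log2FC| > 1
    differential-expression cutoff.
    """

    outdir: str = "run"
    seed: int = 0
    rs_cutoff: float = 0.6
    p_adj_cutoff: float = 0.01
    window_bp: int = 10_000
    n_sets: int = 100
    set_size: int = 150
    k: int = 10
    candidate_threshold: float = 0.5
    alpha: float = 0.05
    log2fc_cutoff: float = 1.0
    n_trees: int = 500
    algorithms: tuple[str, ...] = ALGORITHMS
    imputation: str = "median"
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self):
        for name in ("rs_cutoff", "p_adj_cutoff", "window_bp", "n_sets",
                     "set_size", "k", "alpha", "log2fc_cutoff", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        # YAML has no tuple type; normalize sequence-valued overrides
        self.algorithms = tuple(self.algorithms)
        self.sim = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.sim.items()
        }

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(d["algorithms"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "algorithms" in d:
            d["algorithms"] = tuple(d["algorithms"])
        return cls(**d)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.sim)


# ---------------------------------------------------------------------------
# in-memory route (used by tests and the acceptance script)


def feature_table_from_bundle(
    bundle: SimulatedBundle,
    rs_cutoff: float = 0.6,
    p_adj_cutoff: float = 0.01,
    imputation: str = "median",
) -> tuple[FeatureTable, CoexpressionNetwork]:
    """Normalize expression, build the co-expression network, and assemble
    the full feature table for every lncRNA in a simulated bundle."""
    manifest = default_manifest(drivers=bundle.drivers)
    normalized = normalize_expression(bundle.expression)
    biotypes = {g.gene_id: g.biotype for g in bundle.genes}
    net = build_network(normalized, biotypes, rs_cutoff, p_adj_cutoff)
    lnc = bundle.lncrnas
    network_block = network_features_table(
        [g.gene_id for g in lnc],
        net,
        normalized,
        drivers=bundle.drivers,
        cancer_proteins=bundle.cancer_proteins,
        mirna_interactions=bundle.mirna_interactions,
        cancer_mirnas=bundle.cancer_mirnas,
    )
    resources = ResourceBundle(
        seqs=bundle.sequences,
        repeats=bundle.repeats,
        conservation=bundle.conservation,
        mirnas=tuple(bundle.mirnas),
        tracks=bundle.tracks,
        expression=normalized,
        provenance={"source": "simulated", "seed": bundle.cfg.seed},
    )
    table = assemble_feature_table(
        lnc, resources, network_block, manifest, imputation=imputation
    )
    return table, net


# ---------------------------------------------------------------------------
# staged on-disk pipeline


def _require(outdir: Path, relpath: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        producer = _PRODUCERS.get(relpath, "an earlier stage")
        raise DependencyError(
            f"missing artifact {relpath!r}; run the {producer!r} stage first"
        )
    return p


def _stamp(outdir: Path, stage: str, cfg: RunConfig, info: Mapping) -> None:
    summary_path = outdir / "run_summary.json"
    summary = (
        json.loads(summary_path.read_text()) if summary_path.exists() else {}
    )
    summary[stage] = {"config_hash": cfg.digest(), "seed": cfg.seed, **info}
    summary_path.write_text(json.dumps(summary, indent=1, default=str))


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> Path:
    """Execute the requested stages in canonical order inside
    ``cfg.outdir``; returns the output directory."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    for stage in stages:
        logger.info("stage %s", stage)
        _RUNNERS[stage](cfg, outdir)
    return outdir


def _stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    bundle = simulate_bundle(cfg.sim_config())
    write_bundle(bundle, outdir / "bundle")
    _stamp(outdir, "simulate", cfg, {
        "n_genes": len(bundle.genes),
        "n_positive": len(bundle.positives),
        "n_pool": len(bundle.pool),
    })


def _load_genes(outdir: Path):
    genes = cio.read_gene_models(_require(outdir, "bundle/genes.gtf"), "gtf")
    lnc = [g for g in genes if g.is_lncrna]
    mirnas = [g for g in genes if g.biotype == "miRNA"]
    return genes, lnc, mirnas


def _stage_labels(cfg: RunConfig, outdir: Path) -> None:
    genes, lnc, _ = _load_genes(outdir)
    snps = cio.read_bed_annotations(_require(outdir, "bundle/snps.bed"), "gwas_snps")
    positives = cio.read_id_list(outdir / "bundle" / "positives.txt")
    unknown_path = outdir / "bundle" / "unknowns.txt"
    exclude = cio.read_id_list(unknown_path) if unknown_path.exists() else ()
    bundle = build_label_bundle(
        lnc,
        filter_cancer_snps(snps),
        positives,
        window_bp=cfg.window_bp,
        n_sets=cfg.n_sets,
        set_size=cfg.set_size,
        seed=cfg.seed,
        exclude=exclude,
    )
    bundle.to_json(outdir / "labels.json")
    _stamp(outdir, "labels", cfg, {
        "n_pool": len(bundle.negative_pool),
        "n_sets": len(bundle.negative_sets),
    })


def _stage_network(cfg: RunConfig, outdir: Path) -> None:
    genes, _, _ = _load_genes(outdir)
    expr = cio.read_expression_matrix(_require(outdir, "bundle/expression.tsv"))
    normalized = normalize_expression(expr)
    biotypes = {g.gene_id: g.biotype for g in genes if g.biotype != "miRNA"}
    net = build_network(normalized, biotypes, cfg.rs_cutoff, cfg.p_adj_cutoff)
    net.to_json(outdir / "network.json")
    net.to_dataframe().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    _stamp(outdir, "network", cfg, {"n_edges": net.n_edges})


def _stage_features(cfg: RunConfig, outdir: Path) -> None:
    genes, lnc, mirnas = _load_genes(outdir)
    bdir = outdir / "bundle"
    expr = cio.read_expression_matrix(_require(outdir, "bundle/expression.tsv"))
    normalized = normalize_expression(expr)
    net = CoexpressionNetwork.from_json(_require(outdir, "network.json"))
    drivers = tuple(cio.read_id_list(bdir / "drivers.txt"))
    manifest = default_manifest(drivers=drivers)
    network_block = network_features_table(
        [g.gene_id for g in lnc],
        net,
        normalized,
        drivers=drivers,
        cancer_proteins=cio.read_id_list(bdir / "cancer_proteins.txt"),
        mirna_interactions=read_mirna_interactions(bdir / "interactions.tsv"),
        cancer_mirnas=cio.read_id_list(bdir / "cancer_mirnas.txt"),
    )
    tracks = {
        p.stem: cio.read_bedgraph(p, p.stem)
        for p in sorted((bdir / "tracks").glob("*.bedgraph"))
    }
    resources = ResourceBundle(
        seqs=cio.open_fasta(bdir / "genome.fa"),
        repeats=cio.read_bed_annotations(bdir / "repeats.bed", "repeats"),
        conservation=cio.read_bedgraph(bdir / "conservation.bedgraph", "phastCons"),
        mirnas=tuple(mirnas),
        tracks=tracks,
        expression=normalized,
        provenance={"config_hash": cfg.digest()},
    )
    table = assemble_feature_table(
        lnc, resources, network_block, manifest, imputation=cfg.imputation
    )
    table.to_tsv(outdir / "features.tsv")
    manifest.to_json(outdir / "manifest.json")
    _stamp(outdir, "features", cfg, {
        "n_genes": len(table.gene_ids), "n_features": len(table.feature_names),
    })


def _stage_train(cfg: RunConfig, outdir: Path) -> None:
    table = FeatureTable.from_tsv(_require(outdir, "features.tsv"))
    labels = LabelBundle.from_json(_require(outdir, "labels.json"))
    reports = evaluate_algorithms(
        table, labels.positives, labels.negative_sets,
        algorithms=cfg.algorithms, k=cfg.k, seed=cfg.seed,
    )
    payload = {
        "config_hash": cfg.digest(),
        "reports": {a: r.to_dict() for a, r in reports.items()},
    }
    (outdir / "cv_report.json").write_text(json.dumps(payload, indent=1))
    if "rf" in reports:
        roc = pooled_roc_points(
            table, labels.positives, labels.negative_sets, algorithm="rf",
            k=cfg.k, seed=cfg.seed,
        )
        roc.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
    _stamp(outdir, "train", cfg, {
        "mean_auc": {a: r.mean_auc for a, r in reports.items()},
    })


def _stage_importance(cfg: RunConfig, outdir: Path) -> None:
    table = FeatureTable.from_tsv(_require(outdir, "features.tsv"))
    labels = LabelBundle.from_json(_require(outdir, "labels.json"))
    report = feature_importance(
        table, labels.positives, labels.negative_sets,
        n_trees=cfg.n_trees, seed=cfg.seed,
    )
    report.to_tsv(outdir / "importance.tsv")
    _stamp(outdir, "importance", cfg, {
        "top10_categories": report.top_category_counts(10),
    })


def _stage_predict(cfg: RunConfig, outdir: Path) -> None:
    table = FeatureTable.from_tsv(_require(outdir, "features.tsv"))
    labels = LabelBundle.from_json(_require(outdir, "labels.json"))
    unknowns = cio.read_id_list(outdir / "bundle" / "unknowns.txt")
    results = predict_candidates(
        table, labels.positives, labels.negative_sets, unknowns,
        threshold=cfg.candidate_threshold, seed=cfg.seed,
    )
    predictions_to_dataframe(results).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False
    )
    _stamp(outdir, "predict", cfg, {
        "n_unknowns": len(unknowns),
        "n_candidates": int(sum(r.is_candidate for r in results)),
    })


def _stage_evaluate(cfg: RunConfig, outdir: Path) -> None:
    genes, lnc, _ = _load_genes(outdir)
    bdir = outdir / "bundle"
    table = FeatureTable.from_tsv(_require(outdir, "features.tsv"))
    labels = LabelBundle.from_json(_require(outdir, "labels.json"))
    candidates = pd.read_csv(_require(outdir, "candidates.tsv"), sep="\t")
    candidate_ids = candidates.loc[candidates["is_candidate"], "gene_id"].tolist()

    values = table.values.mask(table.mask)
    ks = feature_ks_table(values, labels.positives, labels.negative_pool)
    ks.to_csv(outdir / "feature_ks.tsv", sep="\t", index=False)

    mutations = cio.read_bed_annotations(bdir / "mutations.bed", "somatic_mutations")
    burden = mutation_burden(lnc, mutations)
    burden.to_csv(outdir / "mutation_burden.tsv", sep="\t")

    tumor = cio.read_expression_matrix(bdir / "tumor.tsv")
    normal = cio.read_expression_matrix(bdir / "normal.tsv")
    lfc = log2_fold_changes(tumor, normal)
    de = {
        group: de_fraction(lfc.reindex(list(ids)).dropna(), cfg.log2fc_cutoff)
        for group, ids in (
            ("positive", labels.positives),
            ("negative", labels.negative_pool),
            ("predicted", candidate_ids),
        )
        if len(set(ids) & set(lfc.index)) > 0
    }

    net = CoexpressionNetwork.from_json(_require(outdir, "network.json"))
    go = read_go_map(bdir / "go_map.tsv")
    rows = []
    for gid in candidate_ids:
        if gid not in net:
            continue
        for r in go_transfer(net, go, gid, alpha=cfg.alpha):
            if r.significant:
                d = enrichment_to_dataframe([r]).iloc[0].to_dict()
                d["gene_id"] = gid
                rows.append(d)
    pd.DataFrame(rows).to_csv(outdir / "candidate_go.tsv", sep="\t", index=False)

    _stamp(outdir, "evaluate", cfg, {
        "de_fraction": de,
        "n_candidates": len(candidate_ids),
        "median_burden_positive": float(
            burden.reindex(list(labels.positives)).median()
        ),
    })


_RUNNERS = {
    "simulate": _stage_simulate,
    "labels": _stage_labels,
    "network": _stage_network,
    "features": _stage_features,
    "train": _stage_train,
    "importance": _stage_importance,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}
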