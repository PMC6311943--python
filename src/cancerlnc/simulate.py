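"""Synthetic resource bundle with planted positive-vs-negative signal.

The generator emulates, at toy scale, every external resource the
pipeline consumes: gene models, genome sequence, repeat annotations,
conservation and histone signal tracks, a 16-tissue expression
compendium, GWAS SNPs, miRNA interactions, somatic mutations,
tumor/normal expression and a GO map.  Cancer-like ("positive")
lncRNAs differ from background lncRNAs only in a declared set of
planted effects that mirror the contrasts reported for real
cancer-related lncRNAs: more SINE/LINE elements in the gene body,
higher H3K4me1/H3K4me3 signal (H1hesc), stronger co-expression with a
few cancer driver genes, higher exon conservation, higher intron GC,
and more cancer-miRNA interactions.  Setting every effect to its null
value makes the two classes exchangeable, which is the basis of the
null-behavior checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from . import io as cio
from .coexnet import DEFAULT_DRIVER_GENES, write_mirna_interactions
from .errors import ValidationError
from .evaluate import write_go_map
from .features import (
    DEFAULT_TISSUES,
    DEFAULT_TRACKS,
)
from .intervals import (
    AnnotationSet,
    DictSequences,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SignalTrack,
)

#: Driver genes carrying the planted co-expression signal.
PLANTED_DRIVERS = ("ERBB2", "CTNNB1", "CDKN2A")

CANCER_GO_TERM = "GO:0000001"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Effect-size fields come in pos/neg (rates) or shift (location) pairs;
    the positive and negative generative distributions differ only where
    these differ.  :meth:`null` returns the no-signal counterpart.
    """

    seed: int = 0
    # cohort sizes
    n_positive: int = 150
    n_negative_pool: int = 600
    n_unknown: int = 200
    n_coding: int = 120
    n_mirna: int = 60
    # genome geometry
    n_chroms: int = 4
    chrom_lengths: tuple[tuple[str, int], ...] | None = None
    gene_length_range: tuple[int, int] = (2000, 6000)
    n_exons_range: tuple[int, int] = (2, 4)
    flank: int = 5000
    gap: int = 2000
    # sequence composition
    gc_base: float = 0.40
    intron_gc_shift: float = 0.02
    # repeats (Poisson rates per gene body)
    sine_rate_pos: float = 4.5
    sine_rate_neg: float = 2.0
    line_rate_pos: float = 3.25
    line_rate_neg: float = 1.5
    ltr_rate: float = 1.0
    satellite_rate: float = 0.8
    flank_repeat_rate: float = 1.0
    # conservation track
    exon_cons_base: float = 0.25
    exon_cons_shift: float = 0.08
    intron_cons: float = 0.20
    flank_cons: float = 0.15
    cons_sd: float = 0.08
    cons_gene_sd: float = 0.05
    cons_bin: int = 100
    # histone tracks
    histone_base: float = 1.0
    histone_sd: float = 0.4
    histone_gene_sd: float = 0.3
    histone_bin: int = 200
    h3k4me1_shift: float = 0.5
    h3k4me3_shift: float = 0.5
    # expression / network
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    driver_rho: float = 0.45
    driver_coupling: float = 0.95
    expr_noise_sd: float = 0.3
    n_cancer_proteins: int = 40
    n_coupled_cancer_proteins: int = 30
    expr_tissue_shift: float = 0.2
    n_shifted_tissues: int = 4
    # miRNA interactions
    n_cancer_mirnas: int = 30
    cancer_mirna_rate_pos: float = 2.5
    cancer_mirna_rate_neg: float = 1.0
    mirna_rate: float = 2.0
    # SNPs, mutations, differential expression
    snp_taint_fraction: float = 0.3
    snp_window: int = 10_000
    mutation_rate_pos: float = 5.0
    mutation_rate_neg: float = 1.0
    de_prob_pos: float = 0.4
    de_prob_neg: float = 0.2
    de_lfc_sd: float = 0.2
    tumor_reps: int = 3
    normal_reps: int = 3
    unknown_pos_fraction: float = 0.5

    def __post_init__(self):
        for name in (
            "sine_rate_pos", "sine_rate_neg", "line_rate_pos", "line_rate_neg",
            "ltr_rate", "satellite_rate", "flank_repeat_rate",
            "cancer_mirna_rate_pos", "cancer_mirna_rate_neg", "mirna_rate",
            "mutation_rate_pos", "mutation_rate_neg",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.driver_rho < 1:
            raise ValidationError("driver_rho must be in [0, 1)")
        if not 0 < self.gc_base + self.intron_gc_shift < 1:
            raise ValidationError("intron GC out of (0, 1)")
        if self.n_positive < 1 or self.n_negative_pool < 1:
            raise ValidationError("need at least one positive and one pool gene")

    def null(self) -> "SimulationConfig":
        """The same conditions with every planted contrast removed."""
        return replace(
            self,
            intron_gc_shift=0.0,
            sine_rate_pos=self.sine_rate_neg,
            line_rate_pos=self.line_rate_neg,
            exon_cons_shift=0.0,
            h3k4me1_shift=0.0,
            h3k4me3_shift=0.0,
            driver_rho=0.0,
            expr_tissue_shift=0.0,
            cancer_mirna_rate_pos=self.cancer_mirna_rate_neg,
            mutation_rate_pos=self.mutation_rate_neg,
            de_prob_pos=self.de_prob_neg,
        )

    def planted_features(self) -> list[str]:
        """The ten primary planted feature names, by design the strongest
        class contrasts in the default bundle."""
        return [
            "SINE_gene_body",
            "H1hescH3k4me1_gene_body",
            f"scc_{PLANTED_DRIVERS[0]}",
            "gc_intron",
            f"scc_{PLANTED_DRIVERS[1]}",
            "H1hescH3k4me3_gene_body",
            "cons_exon",
            "LINE_gene_body",
            f"scc_{PLANTED_DRIVERS[2]}",
            "cancer_mirna_interactions",
        ]


@dataclass
class SimulatedBundle:
    """In-memory resource bundle plus ground truth."""

    cfg: SimulationConfig
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]  # lncRNAs + coding (placement order)
    mirnas: list[GeneModel]
    positives: list[str]
    pool: list[str]
    unknown: list[str]
    unknown_truth: dict[str, int]
    coding: list[str]
    drivers: tuple[str, ...]
    cancer_proteins: list[str]
    cancer_mirnas: list[str]
    sequences: DictSequences
    repeats: AnnotationSet
    conservation: SignalTrack
    tracks: dict[str, SignalTrack]
    expression: ExpressionMatrix  # raw counts
    mirna_interactions: list[tuple[str, str]]
    snps: AnnotationSet
    mutations: AnnotationSet
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    go_map: dict[str, set[str]]
    go_term_names: dict[str, str]
    truth: pd.DataFrame

    @property
    def lncrnas(self) -> list[GeneModel]:
        coding = set(self.coding)
        return [g for g in self.genes if g.gene_id not in coding]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes + self.mirnas:
            if g.gene_id == gene_id:
                return g
        raise ValidationError(f"unknown gene {gene_id!r}")

    def positive_like(self, gene_id: str) -> bool:
        if gene_id in set(self.positives):
            return True
        return self.unknown_truth.get(gene_id, 0) == 1


def _segment_lengths(rng, total: int, k: int, minimum: int = 100) -> np.ndarray:
    """k random segment lengths >= minimum summing to total."""
    if total < k * minimum:
        raise ValidationError("gene too short for its exon structure")
    extra = total - k * minimum
    props = rng.dirichlet(np.ones(k))
    lens = minimum + np.floor(props * extra).astype(int)
    lens[-1] += total - lens.sum()
    return lens


def _random_bases(rng, n: int, gc: float) -> np.ndarray:
    """n random bases as a uint8 array over the ACGT alphabet."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cuts = np.cumsum(probs)[:-1]
    idx = np.searchsorted(cuts, rng.random(n), side="right")
    return alphabet[idx]


def simulate_bundle(cfg: SimulationConfig) -> SimulatedBundle:
    """Generate the full bundle for one configuration (deterministic in
    ``cfg.seed``)."""
    streams = np.random.SeedSequence(cfg.seed).spawn(10)
    (rng_genes, rng_seq, rng_rep, rng_trk, rng_expr, rng_int, rng_snp,
     rng_mut, rng_de, rng_go) = [np.random.default_rng(s) for s in streams]

    # ------------------------------------------------------------------ roles
    roles = (
        ["positive"] * cfg.n_positive
        + ["pool"] * cfg.n_negative_pool
        + ["unknown"] * cfg.n_unknown
        + ["coding"] * cfg.n_coding
    )
    rng_genes.shuffle(roles)

    drivers = tuple(DEFAULT_DRIVER_GENES)
    if cfg.n_coding < len(drivers) + cfg.n_cancer_proteins:
        raise ValidationError(
            "n_coding must cover the driver list plus n_cancer_proteins"
        )
    coding_names = list(drivers)
    coding_names += [f"CP{i:03d}" for i in range(cfg.n_cancer_proteins)]
    coding_names += [
        f"PCG{i:03d}" for i in range(cfg.n_coding - len(coding_names))
    ]
    cancer_proteins = [n for n in coding_names if n.startswith("CP")]
    coupled_coding = set(PLANTED_DRIVERS) | set(
        cancer_proteins[: cfg.n_coupled_cancer_proteins]
    )

    counters = {"positive": 0, "pool": 0, "unknown": 0, "coding": 0}
    ids, biotypes, truth_label = [], [], []
    unknown_truth: dict[str, int] = {}
    lnc_biotype_choices = ("lncRNA-antisense", "lncRNA-intergenic", "lncRNA-overlapping")
    for role in roles:
        i = counters[role]
        counters[role] += 1
        if role == "positive":
            gid = f"POSLNC{i:04d}"
            bt = lnc_biotype_choices[
                rng_genes.choice(3, p=[0.45, 0.47, 0.08])
            ]
            truth_label.append(1)
        elif role == "pool":
            gid = f"NEGLNC{i:04d}"
            bt = "lncRNA-intergenic"
            truth_label.append(0)
        elif role == "unknown":
            gid = f"UNKLNC{i:04d}"
            bt = lnc_biotype_choices[
                rng_genes.choice(3, p=[0.45, 0.47, 0.08])
            ]
            lab = int(rng_genes.random() < cfg.unknown_pos_fraction)
            unknown_truth[gid] = lab
            truth_label.append(lab)
        else:
            gid = coding_names[i]
            bt = "protein_coding"
            truth_label.append(-1)
        ids.append(gid)
        biotypes.append(bt)

    positive_like = {
        g for g, r, t in zip(ids, roles, truth_label)
        if (r == "positive") or (r == "unknown" and t == 1)
    }

    # ------------------------------------------------------------- placement
    lo, hi = cfg.gene_length_range
    body_lens = rng_genes.integers(lo, hi + 1, size=len(ids))
    strands = np.where(rng_genes.random(len(ids)) < 0.5, "+", "-")
    exon_counts = rng_genes.integers(
        cfg.n_exons_range[0], cfg.n_exons_range[1] + 1, size=len(ids)
    )

    slots = body_lens + 2 * cfg.flank + cfg.gap
    if cfg.chrom_lengths is None:
        total = int(slots.sum())
        target = total // cfg.n_chroms + int(slots.max()) + 1
        chrom_lengths: dict[str, int] = {}
        assignments = []
        c, cursor = 0, 0
        for s in slots:
            if cursor + s > target and c < cfg.n_chroms - 1:
                chrom_lengths[f"chr{c + 1}"] = cursor + 1000
                c, cursor = c + 1, 0
            assignments.append((f"chr{c + 1}", cursor))
            cursor += int(s)
        chrom_lengths[f"chr{c + 1}"] = cursor + 1000
    else:
        chrom_lengths = dict(cfg.chrom_lengths)
        order = sorted(chrom_lengths)
        assignments = []
        cursors = {ch: 0 for ch in order}
        for s in slots:
            for ch in order:
                if cursors[ch] + s <= chrom_lengths[ch]:
                    assignments.append((ch, cursors[ch]))
                    cursors[ch] += int(s)
                    break
            else:
                raise ValidationError(
                    "chromosomes too short for the requested gene count"
                )

    genes: list[GeneModel] = []
    for gid, bt, (ch, slot_start), blen, strand, n_ex in zip(
        ids, biotypes, assignments, body_lens, strands, exon_counts
    ):
        start = slot_start + cfg.flank
        segs = _segment_lengths(rng_genes, int(blen), 2 * int(n_ex) - 1)
        exons = []
        pos = start
        for j, seg in enumerate(segs):
            if j % 2 == 0:
                exons.append(GenomicInterval(ch, pos, pos + int(seg), strand))
            pos += int(seg)
        body = GenomicInterval(ch, start, start + int(blen), strand)
        genes.append(GeneModel(gid, bt, body, tuple(exons)))

    by_id = {g.gene_id: g for g in genes}
    lnc_ids = [g for g, r in zip(ids, roles) if r != "coding"]
    coding_ids = [g for g, r in zip(ids, roles) if r == "coding"]
    positives = [g for g, r in zip(ids, roles) if r == "positive"]
    pool = [g for g, r in zip(ids, roles) if r == "pool"]
    unknown = [g for g, r in zip(ids, roles) if r == "unknown"]

    # miRNA genes hosted inside random lncRNA bodies
    mirnas = []
    host_idx = rng_genes.choice(len(lnc_ids), size=cfg.n_mirna)
    for i, hi_ in enumerate(host_idx):
        host = by_id[lnc_ids[int(hi_)]]
        mlen = 80
        off = int(rng_genes.integers(0, host.body.length - mlen))
        iv = GenomicInterval(
            host.body.chrom, host.body.start + off, host.body.start + off + mlen,
            host.strand,
        )
        mirnas.append(GeneModel(f"MIR{i:03d}", "miRNA", iv, (iv,)))
    mirna_ids = [m.gene_id for m in mirnas]
    cancer_mirnas = sorted(
        rng_genes.choice(mirna_ids, size=min(cfg.n_cancer_mirnas, len(mirna_ids)),
                         replace=False)
    )

    # ------------------------------------------------------------- sequences
    seqs = {}
    for ch in sorted(chrom_lengths):
        seqs[ch] = _random_bases(rng_seq, chrom_lengths[ch], cfg.gc_base)
    for g in genes:
        if g.gene_id in positive_like:
            # regenerate intron bases with the class GC (a no-op in
            # distribution when the shift is zero)
            for intr in g.introns:
                seqs[g.body.chrom][intr.start : intr.end] = _random_bases(
                    rng_seq, intr.length, cfg.gc_base + cfg.intron_gc_shift
                )
    sequences = DictSequences(
        {ch: arr.tobytes().decode("ascii") for ch, arr in seqs.items()}
    )

    # --------------------------------------------------------------- repeats
    repeat_records = []

    def _add_repeats(region: GenomicInterval, cls: str, rate: float,
                     size_range: tuple[int, int]):
        for _ in range(rng_rep.poisson(rate)):
            size = int(rng_rep.integers(*size_range))
            size = min(size, region.length)
            off = int(rng_rep.integers(0, region.length - size + 1))
            repeat_records.append(
                (GenomicInterval(region.chrom, region.start + off,
                                 region.start + off + size), cls)
            )

    for gid in lnc_ids:
        g = by_id[gid]
        pos_like = gid in positive_like
        _add_repeats(g.body, "SINE",
                     cfg.sine_rate_pos if pos_like else cfg.sine_rate_neg,
                     (150, 400))
        _add_repeats(g.body, "LINE",
                     cfg.line_rate_pos if pos_like else cfg.line_rate_neg,
                     (300, 700))
        _add_repeats(g.body, "LTR", cfg.ltr_rate, (200, 500))
        _add_repeats(g.body, "Satellite", cfg.satellite_rate, (150, 400))
        tss = g.tss
        flank1k = GenomicInterval(g.body.chrom, max(0, tss - 1000), tss + 1000)
        for cls in ("SINE", "LINE", "LTR", "Satellite"):
            _add_repeats(flank1k, cls, cfg.flank_repeat_rate, (150, 400))
    repeats = AnnotationSet(
        "repeats", repeat_records, vocabulary=("SINE", "LINE", "LTR", "Satellite")
    )

    # ---------------------------------------------------------------- tracks
    def _binned(region_start: int, region_end: int, bin_size: int):
        edges = list(range(region_start, region_end, bin_size)) + [region_end]
        return zip(edges[:-1], edges[1:])

    cons_per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    track_per_chrom: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        t: {} for t in DEFAULT_TRACKS
    }
    planted_tracks = {
        "H1hescH3k4me1": cfg.h3k4me1_shift,
        "H1hescH3k4me3": cfg.h3k4me3_shift,
    }
    for gid in lnc_ids:
        g = by_id[gid]
        ch = g.body.chrom
        pos_like = gid in positive_like
        gene_cons_eff = rng_trk.normal(0.0, cfg.cons_gene_sd)

        def _cons_bins(iv_start, iv_end, mu):
            rows = cons_per_chrom.setdefault(ch, [])
            for b0, b1 in _binned(iv_start, iv_end, cfg.cons_bin):
                v = float(np.clip(
                    rng_trk.normal(mu + gene_cons_eff, cfg.cons_sd), 0.0, 1.0
                ))
                rows.append((b0, b1, v))

        exon_mu = cfg.exon_cons_base + (cfg.exon_cons_shift if pos_like else 0.0)
        left = max(0, g.body.start - cfg.flank)
        _cons_bins(left, g.body.start, cfg.flank_cons)
        for ex in g.exons:
            _cons_bins(ex.start, ex.end, exon_mu)
        for intr in g.introns:
            _cons_bins(intr.start, intr.end, cfg.intron_cons)
        _cons_bins(g.body.end, g.body.end + cfg.flank, cfg.flank_cons)

        for tname in DEFAULT_TRACKS:
            shift = planted_tracks.get(tname, 0.0) if pos_like else 0.0
            gene_eff = rng_trk.normal(0.0, cfg.histone_gene_sd)
            rows = track_per_chrom[tname].setdefault(ch, [])
            for b0, b1 in _binned(left, g.body.end + cfg.flank, cfg.histone_bin):
                in_body = b0 >= g.body.start and b1 <= g.body.end
                mu = cfg.histone_base + gene_eff + (shift if in_body else 0.0)
                rows.append(
                    (b0, b1, float(max(0.0, rng_trk.normal(mu, cfg.histone_sd))))
                )

    def _track_from_rows(name, per_chrom):
        arrays = {}
        for ch, rows in per_chrom.items():
            rows.sort()
            arrays[ch] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows], dtype=float),
            )
        return SignalTrack.from_arrays(name, arrays)

    conservation = _track_from_rows("phastCons", cons_per_chrom)
    tracks = {
        t: _track_from_rows(t, track_per_chrom[t]) for t in DEFAULT_TRACKS
    }

    # ------------------------------------------------------------ expression
    tissues = list(cfg.tissues)
    n_t = len(tissues)
    latent = rng_expr.normal(0.0, 1.0, size=n_t)
    lib = 2.0 ** rng_expr.uniform(-1.0, 1.0, size=n_t)
    expr_ids = coding_ids + lnc_ids
    mu = np.where(
        [g in set(coding_ids) for g in expr_ids],
        rng_expr.normal(6.0, 1.0, size=len(expr_ids)),
        rng_expr.normal(4.0, 1.0, size=len(expr_ids)),
    )
    counts = np.zeros((len(expr_ids), n_t))
    shifted = np.zeros(n_t)
    shifted[: cfg.n_shifted_tissues] = cfg.expr_tissue_shift
    # basis spanned by the latent tissue factor and the shift pattern;
    # uncoupled genes are built orthogonal to it so that only the declared
    # couplings separate the classes (otherwise chance correlation between
    # the latent factor and an arbitrary gene profile would leak class
    # signal into every undeclared co-expression feature)
    basis = np.column_stack([np.ones(n_t), latent, shifted])
    q, _ = np.linalg.qr(basis)
    for i, gid in enumerate(expr_ids):
        if gid in coupled_coding:
            c = cfg.driver_coupling
            shift_vec = 0.0
        elif gid in positive_like:
            c = cfg.driver_rho
            shift_vec = shifted
        else:
            c = 0.0
            shift_vec = 0.0
        noise = rng_expr.normal(0.0, cfg.expr_noise_sd, size=n_t)
        unshifted = np.ndim(shift_vec) == 0 or not np.any(shift_vec)
        if c == 0.0 and unshifted:
            resid = noise - q @ (q.T @ noise)
            scale = np.std(noise) / max(np.std(resid), 1e-12)
            noise = resid * scale
        log2v = mu[i] + c * latent + shift_vec + noise
        counts[i] = rng_expr.poisson(lib * 2.0 ** log2v)
    expression = ExpressionMatrix(
        pd.DataFrame(counts, index=expr_ids, columns=tissues), normalized=False
    )

    # ----------------------------------------------------------- interactions
    noncancer_mirnas = [m for m in mirna_ids if m not in set(cancer_mirnas)]
    interactions: list[tuple[str, str]] = []
    for gid in lnc_ids:
        pos_like = gid in positive_like
        rate_c = cfg.cancer_mirna_rate_pos if pos_like else cfg.cancer_mirna_rate_neg
        k_c = min(rng_int.poisson(rate_c), len(cancer_mirnas))
        k_o = min(rng_int.poisson(cfg.mirna_rate), len(noncancer_mirnas))
        for m in rng_int.choice(cancer_mirnas, size=k_c, replace=False):
            interactions.append((str(m), gid))
        for m in rng_int.choice(noncancer_mirnas, size=k_o, replace=False):
            interactions.append((str(m), gid))

    # ------------------------------------------------------------------ SNPs
    snp_records = []
    n_taint = int(round(cfg.snp_taint_fraction * len(pool)))
    tainted = set(
        rng_snp.choice(pool, size=n_taint, replace=False)
    ) if n_taint else set()
    # taint SNPs stay within 1.5 kb of the gene body: well inside this
    # gene's exclusion window and outside every neighboring gene's window
    # (bodies are >= flank + gap + flank apart), so the truth table exactly
    # predicts the pool filter
    for gid in sorted(tainted):
        g = by_id[gid]
        off = int(rng_snp.integers(-1500, g.body.length + 1500))
        pos = max(0, g.body.start + off)
        snp_records.append(
            (GenomicInterval(g.body.chrom, pos, pos + 1), "breast carcinoma")
        )
    # positives commonly carry nearby cancer SNPs too
    for gid in positives:
        if rng_snp.random() < 0.5:
            g = by_id[gid]
            pos = int(rng_snp.integers(g.body.start, g.body.end))
            snp_records.append(
                (GenomicInterval(g.body.chrom, pos, pos + 1), "melanoma")
            )
    # non-cancer traits that a keyword filter must discard
    for gid in rng_snp.choice(lnc_ids, size=len(lnc_ids) // 10, replace=False):
        g = by_id[str(gid)]
        pos = int(rng_snp.integers(g.body.start, g.body.end))
        snp_records.append((GenomicInterval(g.body.chrom, pos, pos + 1), "height"))
    snps = AnnotationSet("gwas_snps", snp_records)

    # ------------------------------------------------------------- mutations
    mut_records = []
    for gid in lnc_ids:
        g = by_id[gid]
        rate = cfg.mutation_rate_pos if gid in positive_like else cfg.mutation_rate_neg
        for _ in range(rng_mut.poisson(rate)):
            pos = int(rng_mut.integers(g.body.start, g.body.end))
            mut_records.append(
                (GenomicInterval(g.body.chrom, pos, pos + 1), "somatic")
            )
    mutations = AnnotationSet("somatic_mutations", mut_records)

    # ---------------------------------------------------------- tumor/normal
    base_mean = 2.0 ** rng_de.normal(4.0, 1.0, size=len(lnc_ids))
    lfc = np.empty(len(lnc_ids))
    for i, gid in enumerate(lnc_ids):
        p_de = cfg.de_prob_pos if gid in positive_like else cfg.de_prob_neg
        if rng_de.random() < p_de:
            lfc[i] = rng_de.choice([-1.0, 1.0]) * (1.2 + rng_de.exponential(0.8))
        else:
            lfc[i] = rng_de.normal(0.0, cfg.de_lfc_sd)
    normal_counts = rng_de.poisson(
        base_mean[:, None], size=(len(lnc_ids), cfg.normal_reps)
    )
    tumor_counts = rng_de.poisson(
        (base_mean * 2.0 ** lfc)[:, None], size=(len(lnc_ids), cfg.tumor_reps)
    )
    normal = ExpressionMatrix(
        pd.DataFrame(normal_counts, index=lnc_ids,
                     columns=[f"normal{i + 1}" for i in range(cfg.normal_reps)])
    )
    tumor = ExpressionMatrix(
        pd.DataFrame(tumor_counts, index=lnc_ids,
                     columns=[f"tumor{i + 1}" for i in range(cfg.tumor_reps)])
    )

    # --------------------------------------------------------------------- GO
    other_terms = [f"GO:{i:07d}" for i in range(2, 22)]
    go_map: dict[str, set[str]] = {}
    for gid in coding_ids:
        terms = set(rng_go.choice(other_terms, size=2, replace=False))
        if gid in coupled_coding:
            terms.add(CANCER_GO_TERM)
        go_map[gid] = terms
    go_term_names = {CANCER_GO_TERM: "synthetic cancer-associated process"}
    for i, t in enumerate(other_terms):
        go_term_names[t] = f"synthetic background process {i + 1}"

    # ------------------------------------------------------------------ truth
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "role": roles,
            "truth_label": truth_label,
            "snp_tainted": [g in tainted for g in ids],
        }
    ).set_index("gene_id")

    return SimulatedBundle(
        cfg=cfg,
        chrom_lengths=chrom_lengths,
        genes=genes,
        mirnas=mirnas,
        positives=positives,
        pool=pool,
        unknown=unknown,
        unknown_truth=unknown_truth,
        coding=coding_ids,
        drivers=drivers,
        cancer_proteins=cancer_proteins,
        cancer_mirnas=[str(m) for m in cancer_mirnas],
        sequences=sequences,
        repeats=repeats,
        conservation=conservation,
        tracks=tracks,
        expression=expression,
        mirna_interactions=interactions,
        snps=snps,
        mutations=mutations,
        tumor=tumor,
        normal=normal,
        go_map=go_map,
        go_term_names=go_term_names,
        truth=truth,
    )


def truth_auc_bound(cfg: SimulationConfig) -> dict[str, float]:
    """Analytic AUC of the Bayes-optimal univariate classifier for each
    Gaussian planted feature: Phi(delta / (sigma * sqrt(2))).

    Sigma combines the per-gene random effect with the averaged bin noise
    at the mean gene geometry; Poisson-count features have no Gaussian
    closed form and are reported as NaN."""
    mean_body = sum(cfg.gene_length_range) / 2
    mean_exons = sum(cfg.n_exons_range) / 2
    exon_frac = mean_exons / (2 * mean_exons - 1)

    def _phi(delta, sigma):
        return float(stats.norm.cdf(delta / (sigma * np.sqrt(2.0))))

    n_hist_bins = max(1.0, mean_body / cfg.histone_bin)
    sigma_hist = float(
        np.sqrt(cfg.histone_gene_sd**2 + cfg.histone_sd**2 / n_hist_bins)
    )
    n_cons_bins = max(1.0, mean_body * exon_frac / cfg.cons_bin)
    sigma_cons = float(
        np.sqrt(cfg.cons_gene_sd**2 + cfg.cons_sd**2 / n_cons_bins)
    )
    intron_len = max(1.0, mean_body * (1 - exon_frac))
    p_mid = cfg.gc_base + cfg.intron_gc_shift / 2
    sigma_gc = float(np.sqrt(p_mid * (1 - p_mid) / intron_len))

    bounds = {
        "H1hescH3k4me1_gene_body": _phi(cfg.h3k4me1_shift, sigma_hist),
        "H1hescH3k4me3_gene_body": _phi(cfg.h3k4me3_shift, sigma_hist),
        "cons_exon": _phi(cfg.exon_cons_shift, sigma_cons),
        "gc_intron": _phi(cfg.intron_gc_shift, sigma_gc),
    }
    for name in cfg.planted_features():
        bounds.setdefault(name, float("nan"))
    return bounds


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, str]:
    """Serialize every resource to its standard plain-text format and
    return the MANIFEST (relative path -> sha256)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)

    cio.write_gene_models_gtf(bundle.genes + bundle.mirnas, outdir / "genes.gtf")
    cio.write_fasta(bundle.sequences, outdir / "genome.fa")
    cio.write_bed_annotations(bundle.repeats, outdir / "repeats.bed")
    cio.write_bedgraph(bundle.conservation, outdir / "conservation.bedgraph")
    for name, tr in bundle.tracks.items():
        cio.write_bedgraph(tr, outdir / "tracks" / f"{name}.bedgraph")
    cio.write_expression_matrix(bundle.expression, outdir / "expression.tsv")
    write_mirna_interactions(bundle.mirna_interactions, outdir / "interactions.tsv")
    cio.write_bed_annotations(bundle.snps, outdir / "snps.bed")
    cio.write_bed_annotations(bundle.mutations, outdir / "mutations.bed")
    cio.write_expression_matrix(bundle.tumor, outdir / "tumor.tsv")
    cio.write_expression_matrix(bundle.normal, outdir / "normal.tsv")
    cio.write_id_list(bundle.positives, outdir / "positives.txt")
    cio.write_id_list(bundle.unknown, outdir / "unknowns.txt")
    cio.write_id_list(list(bundle.drivers), outdir / "drivers.txt")
    cio.write_id_list(bundle.cancer_proteins, outdir / "cancer_proteins.txt")
    cio.write_id_list(bundle.cancer_mirnas, outdir / "cancer_mirnas.txt")
    write_go_map(bundle.go_map, outdir / "go_map.tsv")
    with open(outdir / "go_terms.tsv", "w") as fh:
        fh.write("go_id\tname\n")
        for t in sorted(bundle.go_term_names):
            fh.write(f"{t}\t{bundle.go_term_names[t]}\n")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t")

    manifest: dict[str, str] = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "MANIFEST.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(outdir))] = digest
    payload = {
        "config": dataclasses.asdict(bundle.cfg),
        "files": manifest,
        "truth_counts": bundle.truth["role"].value_counts().to_dict(),
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(payload, indent=1, default=str))
    return manifest
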