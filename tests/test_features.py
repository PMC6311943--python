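"""Feature extraction blocks and table assembly."""

import numpy as np
import pandas as pd
import pytest

import cancerlnc as cl
from cancerlnc import (
    AnnotationSet,
    DictSequences,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    ValidationError,
)
from cancerlnc.features import (
    FeatureManifest,
    FeatureSpec,
    ResourceBundle,
    assemble_feature_table,
    default_manifest,
    epigenetic_features,
    expression_features,
    gc_content,
    genomic_features,
    longest_orf_peptide_length,
    normalize_expression,
    size_factors,
)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_missing(self):
        assert np.isnan(gc_content("NNNN"))
        assert np.isnan(gc_content(""))


class TestLongestOrf:
    def test_simple_orf(self):
        assert longest_orf_peptide_length("ATGAAATAA") == 2

    def test_no_atg(self):
        assert longest_orf_peptide_length("CCCCCC") == 0

    def test_orf_without_stop_does_not_count(self):
        assert longest_orf_peptide_length("ATGAAAAAA") == 0

    def test_matches_exhaustive_three_frame_scan(self, rng):
        stops = {"TAA", "TAG", "TGA"}

        def oracle(seq):
            best = 0
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                for j in range(i + 3, len(seq) - 2, 3):
                    if seq[j : j + 3] in stops:
                        best = max(best, (j - i) // 3)
                        break
            return best

        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert longest_orf_peptide_length(seq) == oracle(seq)


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        m = ExpressionMatrix(
            pd.DataFrame([[10, 20], [30, 60]], index=["g1", "g2"],
                         columns=["s1", "s2"])
        )
        f = size_factors(m)
        # geometric means sqrt(200) and sqrt(1800)
        assert f.to_numpy() == pytest.approx([0.70710678, 1.41421356], abs=1e-4)

    def test_identical_samples_give_unit_factors(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5, 5], [9, 9]], index=["a", "b"], columns=["s1", "s2"])
        )
        assert size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_scale_equivariance_of_factor_ratios(self, rng):
        # scaling one sample by c rescales every size factor by a common
        # geometric-mean constant, so factor *ratios* shift by exactly c
        counts = rng.integers(1, 100, size=(20, 4)).astype(float)
        m = ExpressionMatrix(pd.DataFrame(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 3.0
        m2 = ExpressionMatrix(pd.DataFrame(scaled))
        f1, f2 = size_factors(m), size_factors(m2)
        assert f2.iloc[2] / f2.iloc[0] == pytest.approx(
            3.0 * f1.iloc[2] / f1.iloc[0]
        )

    def test_all_zero_reference_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0, 5], [3, 0]], index=["a", "b"], columns=["s1", "s2"])
        )
        with pytest.raises(ValidationError, match="pseudocount"):
            size_factors(m)

    def test_depth_changes_cancel_up_to_global_constant(self, rng):
        # per-sample depth scaling is removed by normalization except for
        # one global constant (the rescaled reference geometric mean):
        # the normalized matrices are exactly proportional
        counts = rng.integers(1, 200, size=(30, 6)).astype(float)
        depth = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 0.25])
        m1 = normalize_expression(ExpressionMatrix(pd.DataFrame(counts)))
        m2 = normalize_expression(ExpressionMatrix(pd.DataFrame(counts * depth)))
        ratio = m2.values.to_numpy() / m1.values.to_numpy()
        assert np.allclose(ratio, ratio[0, 0])


def _toy_gene_resources():
    """A hand-laid single-gene fixture where every genomic feature value
    is computable by inspection."""
    # plus-strand gene [2000, 2300), exons [2000,2100) and [2200,2300)
    chrom = ["A"] * 12000
    # gene body: exon1 all G, intron all C, exon2 all T
    chrom[2000:2100] = ["G"] * 100
    chrom[2100:2200] = ["C"] * 100
    chrom[2200:2300] = ["T"] * 100
    # 1 kb flank [1000, 3000): make the left kb all A, rest left as laid
    seqs = DictSequences({"chr1": "".join(chrom)})
    body = GenomicInterval("chr1", 2000, 2300, "+")
    gene = GeneModel(
        "toy", "lncRNA-intergenic", body,
        (GenomicInterval("chr1", 2000, 2100, "+"),
         GenomicInterval("chr1", 2200, 2300, "+")),
    )
    repeats = AnnotationSet(
        "repeats",
        [(GenomicInterval("chr1", 2010, 2020), "SINE"),
         (GenomicInterval("chr1", 2150, 2160), "SINE"),
         (GenomicInterval("chr1", 2290, 2310), "SINE"),   # straddles the end
         (GenomicInterval("chr1", 5000, 5010), "SINE"),   # far away
         (GenomicInterval("chr1", 1500, 1510), "LINE"),   # flank only
         (GenomicInterval("chr1", 2050, 2060), "LTR")],
        vocabulary=["SINE", "LINE", "LTR", "Satellite"],
    )
    conservation = SignalTrack(
        "cons",
        [(GenomicInterval("chr1", 2000, 2100), 0.8),   # exon1
         (GenomicInterval("chr1", 2100, 2200), 0.2),   # intron
         (GenomicInterval("chr1", 2200, 2300), 0.4)],  # exon2
    )
    mirna_body = GenomicInterval("chr1", 2120, 2180, "+")
    mirnas = [GeneModel("MIR1", "miRNA", mirna_body, (mirna_body,))]
    return gene, seqs, repeats, conservation, mirnas


class TestGenomicFeatures:
    def test_toy_gene_matches_hand_computation(self):
        gene, seqs, repeats, conservation, mirnas = _toy_gene_resources()
        out = genomic_features(gene, seqs, repeats, conservation, mirnas)
        # gene body: 100 G + 100 C + 100 T -> GC 200/300
        assert out["gc_gene_body"] == pytest.approx(2 / 3)
        # exon union: 100 G + 100 T
        assert out["gc_exon"] == pytest.approx(0.5)
        assert out["gc_intron"] == pytest.approx(1.0)  # all C
        # 1 kb flank [1000, 3000): A's except GCT block of 300 -> 200/2000
        assert out["gc_flank1k"] == pytest.approx(200 / 2000)
        # 5 kb flank [0, 7000) clipped at 0: same 200 GC bases
        assert out["gc_flank5k"] == pytest.approx(200 / 7000)
        assert out["cons_exon"] == pytest.approx(0.6)    # (0.8 + 0.4) / 2
        assert out["cons_intron"] == pytest.approx(0.2)
        # flank 1 kb [1000, 3000): covered 300 bases of mean (80+20+40)/300
        assert out["cons_flank1k"] == pytest.approx(140 / 2000)
        assert out["SINE_gene_body"] == 3   # includes the straddler
        assert out["SINE_flank1k"] == 3
        assert out["LINE_gene_body"] == 0
        assert out["LINE_flank1k"] == 1
        assert out["LTR_gene_body"] == 1
        assert out["Satellite_gene_body"] == 0
        assert out["mirna_host_count"] == 1
        # transcript GGG...TTT contains no ATG
        assert out["micropeptide_length"] == 0
        assert len(out) == 18

    def test_intronless_gene_has_missing_intron_features(self):
        body = GenomicInterval("chr1", 100, 200, "+")
        gene = GeneModel("g", "lncRNA-intergenic", body, (body,))
        seqs = DictSequences({"chr1": "ACGT" * 100})
        repeats = AnnotationSet("r", [], vocabulary=["SINE", "LINE", "LTR", "Satellite"])
        cons = SignalTrack("c", [])
        out = genomic_features(gene, seqs, repeats, cons, [])
        assert np.isnan(out["gc_intron"])
        assert np.isnan(out["cons_intron"])
        assert not np.isnan(out["gc_exon"])


class TestExpressionFeatures:
    def test_normalized_value_is_raw_over_size_factor(self):
        tissues = list(cl.DEFAULT_TISSUES)
        raw = pd.DataFrame(
            np.arange(1, 33, dtype=float).reshape(2, 16),
            index=["g1", "g2"], columns=tissues,
        )
        m = ExpressionMatrix(raw)
        f = size_factors(m)
        norm = normalize_expression(m)
        out = expression_features("g1", norm)
        for t in tissues:
            assert out[f"expr_{t}"] == pytest.approx(raw.loc["g1", t] / f[t])
        assert len(out) == 16

    def test_absent_gene_is_missing_row(self):
        tissues = list(cl.DEFAULT_TISSUES)
        m = ExpressionMatrix(
            pd.DataFrame([[1.0] * 16], index=["g1"], columns=tissues),
            normalized=True,
        )
        out = expression_features("missing", m)
        assert all(np.isnan(v) for v in out.values())

    def test_requires_normalized_matrix(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0] * 16], index=["g1"], columns=list(cl.DEFAULT_TISSUES))
        )
        with pytest.raises(ValidationError, match="normalized"):
            expression_features("g1", m)


class TestEpigeneticFeatures:
    def _gene(self):
        body = GenomicInterval("chr1", 20000, 24000, "+")
        return GeneModel("g", "lncRNA-intergenic", body, (body,))

    def test_constant_track_gives_constant_means(self):
        gene = self._gene()
        cover = GenomicInterval("chr1", 0, 40000)
        tracks = {n: SignalTrack(n, [(cover, 2.5)]) for n in cl.DEFAULT_TRACKS}
        out = epigenetic_features(gene, tracks)
        assert len(out) == 27
        assert all(v == pytest.approx(2.5) for v in out.values())

    def test_all_zero_tracks_give_zeros(self):
        gene = self._gene()
        tracks = {n: SignalTrack(n, []) for n in cl.DEFAULT_TRACKS}
        out = epigenetic_features(gene, tracks)
        assert all(v == 0.0 for v in out.values())

    def test_missing_track_named_in_error(self):
        gene = self._gene()
        tracks = {n: SignalTrack(n, []) for n in cl.DEFAULT_TRACKS[1:]}
        with pytest.raises(ValidationError, match=cl.DEFAULT_TRACKS[0]):
            epigenetic_features(gene, tracks)

    def test_step_signal_matches_per_base_oracle(self):
        gene = self._gene()
        base = np.zeros(40000)
        records = []
        for s in range(18000, 30000, 500):
            v = (s // 500) % 4 * 0.5
            records.append((GenomicInterval("chr1", s, s + 500), v))
            base[s : s + 500] = v
        tracks = {n: SignalTrack(n, records) for n in cl.DEFAULT_TRACKS}
        out = epigenetic_features(gene, tracks)
        assert out[f"{cl.DEFAULT_TRACKS[0]}_gene_body"] == pytest.approx(
            base[20000:24000].mean()
        )
        assert out[f"{cl.DEFAULT_TRACKS[0]}_flank1k"] == pytest.approx(
            base[19000:21000].mean()
        )
        assert out[f"{cl.DEFAULT_TRACKS[0]}_flank5k"] == pytest.approx(
            base[15000:25000].mean()
        )


class TestManifestAndAssembly:
    def test_default_manifest_block_sizes(self):
        m = default_manifest()
        assert len(m.names_in("genomic")) == 18
        assert len(m.names_in("expression")) == 16
        assert len(m.names_in("epigenetic")) == 27
        assert len(m.names_in("network")) == len(m.drivers) + 4
        assert len(m.names) == 18 + 16 + 27 + len(m.drivers) + 4

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            FeatureManifest((FeatureSpec("a", "genomic"), FeatureSpec("a", "network")))

    def test_imputation_policies(self, small_bundle):
        b = small_bundle
        norm = normalize_expression(b.expression)
        resources = ResourceBundle(
            seqs=b.sequences, repeats=b.repeats, conservation=b.conservation,
            mirnas=tuple(b.mirnas), tracks=b.tracks, expression=norm,
        )
        manifest = default_manifest(drivers=b.drivers)
        lnc = b.lncrnas[:40]
        empty_net = pd.DataFrame(
            np.nan, index=[g.gene_id for g in lnc],
            columns=manifest.names_in("network"),
        )
        t_median = assemble_feature_table(lnc, resources, empty_net, manifest, "median")
        t_none = assemble_feature_table(lnc, resources, empty_net, manifest, "none")
        t_zero = assemble_feature_table(lnc, resources, empty_net, manifest, "zero")
        # mask identical across policies; median fills exactly the masked cells
        assert t_median.mask.equals(t_none.mask)
        assert t_none.values.isna().equals(t_none.mask)
        assert not t_median.values.isna().any().any()
        assert (t_zero.values.to_numpy()[t_zero.mask.to_numpy()] == 0).all()
        # unmasked cells agree between policies
        unmasked = ~t_median.mask.to_numpy()
        assert np.array_equal(
            t_median.values.to_numpy()[unmasked], t_none.values.to_numpy()[unmasked]
        )
        with pytest.raises(ValidationError):
            t_none.matrix([lnc[0].gene_id])

    def test_feature_table_round_trip(self, tmp_path, small_table):
        p = tmp_path / "features.tsv"
        small_table.to_tsv(p)
        back = cl.FeatureTable.from_tsv(p)
        assert np.allclose(back.values.to_numpy(), small_table.values.to_numpy())
        assert back.mask.to_numpy().sum() == small_table.mask.to_numpy().sum()
        assert back.categories == small_table.categories

    def test_extraction_order_independent(self, small_bundle, small_table):
        b = small_bundle
        norm = normalize_expression(b.expression)
        resources = ResourceBundle(
            seqs=b.sequences, repeats=b.repeats, conservation=b.conservation,
            mirnas=tuple(b.mirnas), tracks=b.tracks, expression=norm,
        )
        manifest = default_manifest(drivers=b.drivers)
        lnc = b.lncrnas[:10]
        block = pd.DataFrame(
            0.0, index=[g.gene_id for g in lnc], columns=manifest.names_in("network")
        )
        fwd = assemble_feature_table(lnc, resources, block, manifest, "none")
        rev = assemble_feature_table(
            list(reversed(lnc)), resources, block, manifest, "none"
        )
        ids = [g.gene_id for g in lnc]
        assert np.allclose(
            fwd.values.loc[ids].to_numpy(), rev.values.loc[ids].to_numpy(),
            equal_nan=True,
        )

    def test_bounded_feature_ranges(self, small_table):
        vals = small_table.values.mask(small_table.mask)
        for col in [c for c in vals.columns if c.startswith(("gc_", "cons_"))]:
            v = vals[col].dropna()
            assert ((v >= 0) & (v <= 1)).all()
        for col in [c for c in vals.columns
                    if c.startswith(("SINE", "LINE", "LTR", "Satellite"))]:
            v = vals[col].dropna()
            assert (v >= 0).all() and (v == v.astype(int)).all()
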