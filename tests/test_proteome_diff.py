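import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aneuadapt import proteome_diff as pdiff, synthetic_data as sd
from aneuadapt import copy_number as cn


def annotations(samples, batches=None, lines=None):
    batches = batches or ["B0"] * len(samples)
    lines = lines or ["L"] * len(samples)
    return pd.DataFrame({"batch": batches, "line": lines},
                        index=pd.Index(samples, name="sample"))


class TestPreprocessIntensities:
    def test_contaminant_rows_removed(self):
        raw = pd.DataFrame(np.full((3, 4), 8.0),
                           index=["a", "b", "c"], columns=list("wxyz"))
        flags = pd.DataFrame({"contaminant": [True, False, False]},
                             index=["a", "b", "c"])
        out = pdiff.preprocess_intensities(raw, annotations(list("wxyz")),
                                           flags=flags)
        assert "a" not in out.index and {"b", "c"} <= set(out.index)

    def test_incomplete_rows_removed(self):
        raw = pd.DataFrame([[4.0, np.nan], [4.0, 8.0]], index=["a", "b"],
                           columns=["s1", "s2"])
        out = pdiff.preprocess_intensities(raw, annotations(["s1", "s2"]))
        assert list(out.index) == ["b"]

    def test_planted_batch_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20, 1, size=(50, 1))
        mat = np.repeat(base, 6, axis=1) + rng.normal(0, 0.1, (50, 6))
        delta = 0.7
        mat[:, 3:] += delta  # batch 2 offset
        raw = pd.DataFrame(2.0 ** mat, columns=[f"s{i}" for i in range(6)])
        ann = annotations(raw.columns, batches=["B1"] * 3 + ["B2"] * 3)
        out = pdiff.preprocess_intensities(raw, ann)
        batch_means = out.T.groupby(ann["batch"]).mean().T
        np.testing.assert_allclose(batch_means["B1"], batch_means["B2"],
                                   atol=1e-10)

    def test_all_rows_filtered_is_an_error(self):
        raw = pd.DataFrame([[np.nan, 1.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="no protein"):
            pdiff.preprocess_intensities(raw, annotations(["s1", "s2"]))

    def test_samples_without_annotation_rejected(self):
        raw = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="annotations"):
            pdiff.preprocess_intensities(raw, annotations(["s1"]))


class TestModeratedDiffAbundance:
    @staticmethod
    def two_group_matrix(rng, n_proteins=200, n=3, delta=0.0, sigma=0.3):
        mat = rng.normal(0, sigma, size=(n_proteins, 2 * n))
        mat[:, :n] += delta
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        matrix = pd.DataFrame(mat, columns=cols,
                              index=[f"p{i}" for i in range(n_proteins)])
        groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
        return matrix, groups

    def test_identical_groups_give_zero_fc(self):
        matrix = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["p"],
                              columns=["a1", "a2", "b1", "b2"])
        groups = pd.Series(["A", "A", "B", "B"], index=matrix.columns)
        out = pdiff.moderated_diff_abundance(matrix, groups, ("A", "B"))
        assert out.loc["p", "log2fc"] == 0.0
        assert out.loc["p", "p"] == pytest.approx(1.0)

    def test_d0_zero_recovers_ordinary_t(self, rng):
        matrix, groups = self.two_group_matrix(rng, n_proteins=50)
        out = pdiff.moderated_diff_abundance(matrix, groups, ("A", "B"),
                                             d0_override=0.0)
        a = matrix.iloc[:, :3].to_numpy()
        b = matrix.iloc[:, 3:].to_numpy()
        t_ref, p_ref = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_moderation_shrinks_extreme_variances(self, rng):
        matrix, groups = self.two_group_matrix(rng, n_proteins=500)
        out = pdiff.moderated_diff_abundance(matrix, groups, ("A", "B"))
        d0 = out["df_prior"].iloc[0]
        assert 0 < d0
        # moderated t never exceeds the ordinary t for the smallest-variance
        # proteins (their variances are pulled up toward the prior)
        t_ref = sps.ttest_ind(matrix.iloc[:, :3], matrix.iloc[:, 3:],
                              axis=1, equal_var=True).statistic
        small_var = out["s2"] < out["s2"].median()
        assert (np.abs(out["t"][small_var]) <=
                np.abs(t_ref[small_var.to_numpy()]) + 1e-9).all()

    def test_fdr_controlled_on_simulated_effects(self):
        # 5% true effects of 1 log2 unit, sigma 0.25, 3v3, 1000 proteins
        fdps = []
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            mat = r.normal(0, 0.25, size=(1000, 6))
            truth = np.zeros(1000, bool)
            truth[r.choice(1000, 50, replace=False)] = True
            mat[truth, :3] += 1.0
            matrix = pd.DataFrame(mat, columns=list("abcdef"))
            groups = pd.Series(list("AAABBB"), index=matrix.columns)
            out = pdiff.moderated_diff_abundance(matrix, groups, ("A", "B"))
            called = (out["fdr"] < 0.05).to_numpy()
            fdps.append((called & ~truth).sum() / max(called.sum(), 1))
        assert np.mean(fdps) <= 0.10

    def test_single_replicate_side_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a1", "b1", "b2"])
        groups = pd.Series(["A", "B", "B"], index=matrix.columns)
        with pytest.raises(ValueError, match="replicates"):
            pdiff.moderated_diff_abundance(matrix, groups, ("A", "B"))


class TestSegmentFoldChanges:
    def test_uniform_fold_changes_give_single_segment(self, small_catalog):
        fc = pd.Series(0.3, index=small_catalog.genes["gene_id"])
        prof = pdiff.segment_fold_changes(fc, small_catalog, seed=0)
        assert (prof.segments.groupby("chromosome").size() == 1).all()

    def test_planted_arm_shift_breaks_at_arm_boundary(self, small_catalog):
        genes = small_catalog.genes
        fc = pd.Series(0.0, index=genes["gene_id"])
        first_arm = genes[(genes["chromosome"] == "1") & (genes["arm"] == "p")]
        fc.loc[first_arm["gene_id"]] = np.log2(1.5)
        prof = pdiff.segment_fold_changes(fc, small_catalog, seed=1)
        chrom1 = prof.segments[prof.segments["chromosome"] == "1"]
        assert len(chrom1) == 2
        np.testing.assert_allclose(sorted(chrom1["mean_log2"]),
                                   [0.0, np.log2(1.5)])
        assert chrom1.iloc[0]["n_bins"] == len(first_arm)

    def test_noisy_arm_mean_recovered(self, rng):
        cat = sd.make_genome(1, 100, seed=5)
        genes = cat.genes
        fc = pd.Series(rng.normal(0, 0.2, len(genes)),
                       index=genes["gene_id"])
        q_genes = genes[genes["arm"] == "q"]["gene_id"]
        fc.loc[q_genes] += np.log2(1.5)
        prof = pdiff.segment_fold_changes(fc, cat, seed=2)
        q_mean = prof.segments.sort_values("start").iloc[-1]["mean_log2"]
        assert abs(q_mean - np.log2(1.5)) < 0.05

    def test_unmapped_proteins_warned_and_excluded(self, small_catalog):
        fc = pd.Series(0.1, index=list(small_catalog.genes["gene_id"])
                       + ["UNKNOWN"])
        with pytest.warns(UserWarning, match="coordinates"):
            prof = pdiff.segment_fold_changes(fc, small_catalog, seed=0)
        assert prof.segments["n_bins"].sum() == len(small_catalog.genes)


class TestArmDosageCompensation:
    @staticmethod
    def dna_profile(catalog, log2_by_arm):
        rows = []
        for arm_row in catalog.arms.itertuples(index=False):
            q = log2_by_arm.get((arm_row.chromosome, arm_row.arm), 0.0)
            rows.append((arm_row.chromosome, arm_row.start, arm_row.end,
                         q, q, 10))
        return cn.SegmentedProfile(sample_id="s", segments=pd.DataFrame(
            rows, columns=["chromosome", "start", "end", "mean_log2",
                           "median_log2", "n_bins"]))

    def test_full_scaling_gives_zero_compensation(self, small_catalog):
        arm = small_catalog.arm_index[0]
        dna = self.dna_profile(small_catalog, {arm: np.log2(1.5)})
        fc = pd.Series(0.0, index=small_catalog.genes["gene_id"])
        fc.loc[small_catalog.genes_on_arm(*arm)["gene_id"]] = np.log2(1.5)
        out = pdiff.arm_dosage_compensation(dna, fc, small_catalog)
        row = out[(out["chromosome"] == arm[0]) & (out["arm"] == arm[1])]
        assert row["compensation"].iloc[0] == pytest.approx(0.0)

    def test_full_buffering_equals_dna_ratio(self, small_catalog):
        arm = small_catalog.arm_index[0]
        dna = self.dna_profile(small_catalog, {arm: np.log2(1.5)})
        fc = pd.Series(0.0, index=small_catalog.genes["gene_id"])
        out = pdiff.arm_dosage_compensation(dna, fc, small_catalog)
        row = out[(out["chromosome"] == arm[0]) & (out["arm"] == arm[1])]
        assert row["compensation"].iloc[0] == pytest.approx(np.log2(1.5))

    def test_arm_without_proteins_omitted_with_warning(self, small_catalog):
        arm = small_catalog.arm_index[0]
        dna = self.dna_profile(small_catalog, {})
        off_arm = small_catalog.genes[
            ~((small_catalog.genes["chromosome"] == arm[0])
              & (small_catalog.genes["arm"] == arm[1]))]
        fc = pd.Series(0.1, index=off_arm["gene_id"])
        with pytest.warns(UserWarning, match="no quantified proteins"):
            out = pdiff.arm_dosage_compensation(dna, fc, small_catalog)
        assert not ((out["chromosome"] == arm[0])
                    & (out["arm"] == arm[1])).any()

    def test_planted_compensation_factor_recovered(self):
        # end-to-end: c = 0.5 on the trisomic arm recovered within 0.03;
        # genome with realistic arm fractions and no adaptation plant so
        # scale normalization does not absorb the dosage signal
        cat = sd.make_genome(12, 100, seed=17)
        cfg = sd.SimulationConfig(seed=17, compensation_factor=0.5,
                                  replicate_sd=0.1,
                                  planted_gene_fraction=0.0)
        kts, parents = sd.default_cellline_design(cat)
        sim = sd.simulate_cellline_proteomes(cat, kts, cfg, parents)
        proc = pdiff.preprocess_intensities(sim.intensities,
                                            sim.sample_sheet.set_index("sample"),
                                            log_transform=False)
        fct = pdiff.build_fold_change_table(proc, sim.sample_sheet,
                                            sim.comparisons)
        fc = (fct[fct["comparison"] == "TRI_p0_vs_WT"]
              .set_index("protein")["log2fc"])
        bins = sd.simulate_binned_profile(kts[("TRI", "p0")], cat,
                                          1_000_000, 0.05, seed=9)
        prof = cn.segment_profile(bins, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = pdiff.arm_dosage_compensation(prof, fc, cat)
        tri_arm = kts[("TRI", "p0")].altered_arms()[0]
        row = comp[(comp["chromosome"] == tri_arm[0])
                   & (comp["arm"] == tri_arm[1])]
        assert row["compensation"].iloc[0] == pytest.approx(
            0.5 * np.log2(1.5), abs=0.03)


class TestClassifyArmScaling:
    @staticmethod
    def build(rng, true_delta, n_per_side=50, sigma=0.2, n_genes=100):
        cat = sd.make_genome(1, n_genes // 2, seed=2)
        genes = cat.genes["gene_id"]
        patients = [f"T{i}" for i in range(2 * n_per_side)]
        gain = pd.DataFrame(False, index=pd.Index(cat.arm_index),
                            columns=patients)
        gain.iloc[:, :n_per_side] = True
        deltas = pd.DataFrame(
            rng.normal(0, sigma, size=(len(genes), 2 * n_per_side)),
            index=genes.values, columns=patients)
        deltas.iloc[:, :n_per_side] += true_delta
        return cat, deltas, gain

    def test_true_scaling_proteins_called_scaling(self, rng):
        cat, deltas, gain = self.build(rng, np.log2(1.5))
        out = pdiff.classify_arm_scaling(deltas, gain, cat)
        assert (out["classification"] == "scaling").mean() > 0.9

    def test_true_scaling_rarely_called_non_scaling(self, rng):
        cat, deltas, gain = self.build(rng, np.log2(1.5), n_genes=400)
        out = pdiff.classify_arm_scaling(deltas, gain, cat)
        assert (out["classification"] == "non_scaling").mean() <= 0.05

    def test_null_delta_called_non_scaling(self, rng):
        cat, deltas, gain = self.build(rng, 0.0)
        out = pdiff.classify_arm_scaling(deltas, gain, cat)
        assert (out["classification"] == "non_scaling").mean() > 0.9

    def test_tiny_cohort_is_mostly_unclassified(self, rng):
        cat, deltas, gain = self.build(rng, np.log2(1.5), n_per_side=3,
                                       sigma=0.3)
        out = pdiff.classify_arm_scaling(deltas, gain, cat)
        assert (out["classification"] == "unclassified").mean() > 0.5
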