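"""Signature selection, stratification, PCA, and clinical association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ltrcage.signature import (atlas_breadth, clinical_association,
                               cluster_samples, pca_embed, select_signature)
from ltrcage.simulate import simulate_counts
from ltrcage.stats import ContingencyTable

from _oracles import fisher_exact_oracle


def diff_frame(rows):
    return pd.DataFrame(rows, columns=["fdr_bh", "p_exact", "log2_fold"],
                        index=[f"p{i}" for i in range(len(rows))])


class TestSelectSignature:
    def counts(self, ids, n_expressed, n_tumor=40):
        data = np.zeros((len(ids), n_tumor))
        for i, n in enumerate(n_expressed):
            data[i, :n] = 1
        return pd.DataFrame(data, index=ids,
                            columns=[f"T{j}" for j in range(n_tumor)])

    def test_peak_meeting_all_criteria_selected(self):
        diff = diff_frame([[1e-11, 1e-13, np.log2(8.5)]])
        counts = self.counts(["p0"], [35])
        out = select_signature(diff, counts, ["p0"], counts.columns,
                               pd.Series({"p0": True}))
        assert list(out.index) == ["p0"]
        assert out.iloc[0]["name"] == "LTR-001"

    def test_fold_exactly_eight_rejected(self):
        diff = diff_frame([[1e-11, 1e-13, np.log2(8.0)]])
        counts = self.counts(["p0"], [35])
        out = select_signature(diff, counts, ["p0"], counts.columns,
                               pd.Series({"p0": True}))
        assert out.empty

    def test_insufficient_breadth_rejected(self):
        diff = diff_frame([[1e-11, 1e-13, np.log2(9)]])
        counts = self.counts(["p0"], [29])
        out = select_signature(diff, counts, ["p0"], counts.columns,
                               pd.Series({"p0": True}))
        assert out.empty

    def test_names_follow_fdr_order_and_input_order_is_irrelevant(self):
        diff = diff_frame([[1e-12, 1e-14, 4.0], [1e-15, 1e-17, 4.0],
                           [1e-11, 1e-13, 4.0]])
        counts = self.counts(["p0", "p1", "p2"], [40, 40, 40])
        flags = pd.Series(True, index=diff.index)
        out = select_signature(diff, counts, ["p0", "p1", "p2"],
                               counts.columns, flags)
        assert list(out.index) == ["p1", "p0", "p2"]
        out2 = select_signature(diff, counts, ["p2", "p0", "p1"],
                                counts.columns, flags)
        assert list(out2.index) == list(out.index)

    def test_strong_planted_set_recovered_weak_excluded(self, rng):
        mu = np.full(40, 50.0)
        strong, libs = simulate_counts(40, 20, 20, mu=mu, fold=16.0, phi=0.05,
                                       rng=rng)
        weak, _ = simulate_counts(200, 20, 20, mu=20.0, fold=2.0, phi=0.05,
                                  rng=rng)
        counts = pd.concat([strong, weak])
        counts.index = [f"p{i}" for i in range(len(counts))]
        tpm = counts / libs * 1e6
        from ltrcage.diffexp import differential_expression
        res = differential_expression(counts, tpm,
                                      [f"A{i}" for i in range(20)],
                                      [f"B{i}" for i in range(20)], libs)
        flags = pd.Series(True, index=counts.index)
        out = select_signature(res, counts, counts.index,
                               [f"A{i}" for i in range(20)], flags,
                               min_tumor_samples=15)
        strong_ids = {f"p{i}" for i in range(40)}
        assert strong_ids.issubset(set(out.index))
        assert not (set(out.index) - strong_ids)


class TestAtlasBreadth:
    def test_all_below_threshold_counts_zero(self):
        tumor = pd.DataFrame([[10.0] * 5], index=["p0"],
                             columns=[f"T{i}" for i in range(5)])
        atlas = pd.DataFrame([[1.0, 2.0]], index=["p0"], columns=["a", "b"])
        out = atlas_breadth(["p0"], atlas, tumor)
        assert out["per_peak"].loc["p0"] == 0

    def test_strictly_greater_than_median_required(self):
        tumor = pd.DataFrame([[0.0] * 5], index=["p0"],
                             columns=[f"T{i}" for i in range(5)])
        atlas = pd.DataFrame([[0.0, 0.5]], index=["p0"], columns=["a", "b"])
        out = atlas_breadth(["p0"], atlas, tumor)
        assert out["per_peak"].loc["p0"] == 1  # only the 0.5 sample

    def test_testis_like_sample_ranks_first(self, rng):
        ids = [f"p{i}" for i in range(40)]
        tumor = pd.DataFrame(rng.uniform(5, 20, (40, 10)), index=ids,
                             columns=[f"T{i}" for i in range(10)])
        atlas = pd.DataFrame(0.0, index=ids,
                             columns=[f"a{i}" for i in range(8)])
        atlas.loc[ids[:20], "a0"] = 1000.0  # expresses half the signature
        out = atlas_breadth(ids, atlas, tumor)
        assert out["per_sample"].index[0] == "a0"
        assert out["per_sample"].iloc[0] == 20

    def test_missing_peaks_tallied_as_unexpressed(self):
        tumor = pd.DataFrame([[1.0]], index=["p0"], columns=["T0"])
        atlas = pd.DataFrame(index=pd.Index([]), columns=["a"], dtype=float)
        out = atlas_breadth(["p0"], atlas, tumor)
        assert out["missing_peaks"] == 1
        assert out["per_peak"].loc["p0"] == 0


class TestClusterSamples:
    def tier_matrix(self, rng, means=(100.0, 10.0, 0.1), n_per=8, n_peaks=43,
                    library_size=20_000_000):
        # tiers planted at the given mean tpm; counts resampled at a
        # realistic library depth, then renormalized to tpm
        cols, truth = [], []
        blocks = []
        for t, m in enumerate(means):
            counts = rng.poisson(m * library_size / 1e6,
                                 size=(n_peaks, n_per))
            blocks.append(counts / library_size * 1e6)
            cols += [f"s{t}_{i}" for i in range(n_per)]
            truth += [t] * n_per
        tpm = pd.DataFrame(np.hstack(blocks), columns=cols,
                           index=[f"p{i}" for i in range(n_peaks)])
        return tpm, pd.Series(truth, index=cols)

    def test_separated_tiers_recovered_exactly(self, rng):
        tpm, truth = self.tier_matrix(rng)
        out = cluster_samples(tpm, tpm.index, k=3)
        ari = adjusted_rand_score(truth, out["strata"].reindex(truth.index))
        assert ari == 1.0
        # labels ordered by expression
        high = out["strata"][out["strata"] == "high"].index
        assert set(high) == set(truth.index[truth == 0])

    def test_duplicated_samples_share_stratum(self, rng):
        tpm, _ = self.tier_matrix(rng, n_per=4)
        tpm["dup"] = tpm["s0_0"]
        out = cluster_samples(tpm, tpm.index, k=3)
        assert out["strata"]["dup"] == out["strata"]["s0_0"]

    def test_k_one_returns_single_stratum(self, rng):
        tpm, _ = self.tier_matrix(rng, n_per=3)
        out = cluster_samples(tpm, tpm.index, k=1)
        assert out["strata"].nunique() == 1

    def test_k_exceeding_samples_rejected(self, rng):
        tpm, _ = self.tier_matrix(rng, n_per=1)
        with pytest.raises(ValueError):
            cluster_samples(tpm, tpm.index, k=10)

    def test_empty_signature_rejected(self, rng):
        tpm, _ = self.tier_matrix(rng, n_per=2)
        with pytest.raises(ValueError):
            cluster_samples(tpm, [], k=2)


class TestPca:
    def test_rank_one_structure_on_first_component(self, rng):
        loading = rng.uniform(1, 2, size=20)
        score = np.linspace(0, 3, 15)
        tpm = pd.DataFrame(np.outer(loading, 10.0 ** score),
                           index=[f"p{i}" for i in range(20)],
                           columns=[f"s{i}" for i in range(15)])
        out = pca_embed(tpm, tpm.index)
        assert out["explained_variance_ratio"][0] > 0.9

    def test_identical_samples_embed_at_origin(self):
        tpm = pd.DataFrame(5.0, index=[f"p{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(4)])
        out = pca_embed(tpm, tpm.index)
        assert np.allclose(out["coords"].to_numpy(), 0.0)

    def test_pc1_orders_planted_tiers(self, rng):
        from scipy.stats import spearmanr
        means = {0: 100.0, 1: 10.0, 2: 0.1}
        cols, tier = [], []
        data = []
        for t, m in means.items():
            data.append(rng.poisson(m, size=(25, 6)))
            cols += [f"s{t}_{i}" for i in range(6)]
            tier += [t] * 6
        tpm = pd.DataFrame(np.hstack(data), columns=cols,
                           index=[f"p{i}" for i in range(25)])
        out = pca_embed(tpm, tpm.index)
        rho = spearmanr(out["coords"]["PC1"], tier).statistic
        assert abs(rho) > 0.9

    def test_sign_convention_deterministic(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 50, (12, 9)),
                           index=[f"p{i}" for i in range(12)],
                           columns=[f"s{i}" for i in range(9)])
        a = pca_embed(tpm, tpm.index)["coords"]
        b = pca_embed(tpm, tpm.index)["coords"]
        pd.testing.assert_frame_equal(a, b)
        for comp in ("PC1", "PC2"):
            load = pca_embed(tpm, tpm.index)["loadings"][comp]
            assert load.iloc[np.argmax(np.abs(load.to_numpy()))] >= 0


class TestClinicalAssociation:
    def cohort(self):
        strata = pd.Series(["high"] * 16 + ["low"] * 14,
                           index=[f"T{i:02d}" for i in range(30)])
        sheet = pd.DataFrame(index=strata.index)
        # 10/16 recurrent in high, 2/14 in low
        sheet["recurrence"] = [1] * 10 + [0] * 6 + [1] * 2 + [0] * 12
        return strata, sheet

    def test_printed_recurrence_table_reproduced(self):
        strata, sheet = self.cohort()
        out = clinical_association(strata, sheet, ["recurrence"])
        row = out["table"].iloc[0]
        assert row["p_fisher"] == pytest.approx(0.011, abs=5e-4)
        assert round(row["p_fisher"], 3) == 0.011
        assert row["odds_ratio"] == pytest.approx(10.0)

    def test_fisher_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b < 2 or c + d < 2:
                continue
            strata = pd.Series(["high"] * (a + b) + ["low"] * (c + d),
                               index=[f"s{i}" for i in range(a + b + c + d)])
            sheet = pd.DataFrame({
                "cov": [1] * a + [0] * b + [1] * c + [0] * d},
                index=strata.index)
            if sheet["cov"].nunique() < 2:
                continue
            out = clinical_association(strata, sheet, ["cov"])
            assert out["table"].iloc[0]["p_fisher"] == pytest.approx(
                fisher_exact_oracle(a, b, c, d, "two-sided"), rel=1e-9)

    def test_single_level_covariate_skipped(self):
        strata, sheet = self.cohort()
        sheet["constant"] = 1
        out = clinical_association(strata, sheet, ["recurrence", "constant"])
        assert out["skipped"] == ["constant"]
        assert len(out["table"]) == 1

    def test_independent_covariate_rarely_significant(self, rng):
        # calibration under the null: BH-significant in <= 7% of replicates
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            strata = pd.Series(["high"] * 16 + ["low"] * 14,
                               index=[f"T{i}" for i in range(30)])
            sheet = pd.DataFrame(
                {f"c{j}": rng.integers(0, 2, size=30) for j in range(4)},
                index=strata.index)
            out = clinical_association(strata, sheet, list(sheet.columns))
            if (out["table"]["fdr_bh"] < 0.05).any():
                hits += 1
        assert hits / n_rep <= 0.07

    def test_heterogeneity_reported(self):
        strata, sheet = self.cohort()
        sheet["age"] = ([1] * 12 + [0] * 4) + ([1] * 5 + [0] * 9)
        out = clinical_association(strata, sheet, ["recurrence", "age"])
        assert np.isfinite(out["heterogeneity_q"])
        assert 0 <= out["heterogeneity_p"] <= 1

    def test_small_strata_rejected(self):
        strata = pd.Series(["high", "low", "low"], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            clinical_association(strata, pd.DataFrame(index=strata.index),
                                 [])

    def test_zero_cell_gets_continuity_corrected_ci(self):
        t = ContingencyTable(5, 0, 2, 7)
        lo, hi = t.ci95()
        assert 0 < lo < hi < np.inf
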