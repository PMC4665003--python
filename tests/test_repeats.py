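"""Repeat overlap geometry, enrichment contingencies, and profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ltrcage.io_formats import GenomeLayout
from ltrcage.repeats import (assign_repeat_overlap, empirical_p,
                             enrichment_tables, fdr_stratified_fractions,
                             metaelement_profile, randomize_distal_peaks,
                             relative_position, relative_position_profile,
                             subfamily_activation)
from ltrcage.stats import ContingencyTable

from _oracles import fisher_exact_oracle


def repeat_catalog(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "subfamily", "family", "is_internal"])
    df.insert(0, "element_id", np.arange(len(df)))
    return df


def peak(pid, chrom, start, end, strand, summit):
    return dict(peak_id=pid, chrom=chrom, start=start, end=end,
                strand=strand, summit=summit)


class TestOverlapAssignment:
    def test_antisense_overlap_flagged(self):
        cat = repeat_catalog([("c1", 100, 1100, "-", "LTR12C", "LTR", False)])
        peaks = pd.DataFrame([peak("p", "c1", 500, 520, "+", 510)])
        ov = assign_repeat_overlap(peaks, cat)
        assert ov.loc["p", "family"] == "LTR"
        assert not ov.loc["p", "sense_flag"]

    def test_relative_position_70_percent(self):
        cat = repeat_catalog([("c1", 0, 1000, "+", "LTR12C", "LTR", False)])
        peaks = pd.DataFrame([peak("p", "c1", 690, 710, "+", 700)])
        ov = assign_repeat_overlap(peaks, cat)
        assert ov.loc["p", "relative_position"] == pytest.approx(0.70)

    def test_minus_strand_five_prime_is_genomic_end(self):
        cat = repeat_catalog([("c1", 0, 1000, "-", "LTR12C", "LTR", False)])
        peaks = pd.DataFrame([peak("p", "c1", 95, 105, "-", 100)])
        ov = assign_repeat_overlap(peaks, cat)
        assert ov.loc["p", "relative_position"] == pytest.approx(0.90)

    def test_internal_elements_skipped_when_excluded(self):
        cat = repeat_catalog([("c1", 0, 1000, "+", "HERVH-int", "LTR", True)])
        peaks = pd.DataFrame([peak("p", "c1", 10, 20, "+", 15)])
        assert assign_repeat_overlap(peaks, cat).loc["p", "family"] == "none"
        kept = assign_repeat_overlap(peaks, cat, exclude_internal=False)
        assert kept.loc["p", "family"] == "LTR"

    def test_summit_covering_element_wins(self):
        cat = repeat_catalog([
            ("c1", 0, 200, "+", "AluY", "SINE", False),
            ("c1", 150, 1500, "+", "LTR12C", "LTR", False),
        ])
        peaks = pd.DataFrame([peak("p", "c1", 100, 400, "+", 300)])
        assert assign_repeat_overlap(peaks, cat).loc["p", "subfamily"] == "LTR12C"


class TestEnrichment:
    def test_printed_cohort_counts_reach_stated_significance(self):
        # up: 935/4756 LTR-sense; non-up: 6.3% of 16,816 -> 1059
        t = ContingencyTable(935, 4756 - 935, 1059, 16816 - 1059)
        assert t.fisher_p("greater") <= 1.0e-5

    def test_identical_fractions_give_null_result(self):
        t = ContingencyTable(50, 450, 100, 900)
        assert t.odds_ratio == pytest.approx(1.0)
        assert t.fisher_p("greater") >= 0.5

    def test_fisher_agrees_with_enumeration_oracle(self, rng):
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            for alt in ("greater", "two-sided"):
                assert t.fisher_p(alt) == pytest.approx(
                    fisher_exact_oracle(a, b, c, d, alt), rel=1e-9)

    def test_family_fractions_partition_each_group(self, rng):
        cat = repeat_catalog([
            ("c1", i * 3000, i * 3000 + 1000,
             rng.choice(["+", "-"]),
             ["LTR12C", "L1PA", "AluY", "SVA_D"][i % 4],
             ["LTR", "LINE", "SINE", "SVA"][i % 4], False)
            for i in range(40)])
        rows = [peak(f"p{i}", "c1", int(s), int(s) + 20, rng.choice(["+", "-"]),
                     int(s) + 10)
                for i, s in enumerate(rng.integers(0, 121_000, size=200))]
        peaks = pd.DataFrame(rows)
        ov = assign_repeat_overlap(peaks, cat)
        up = [f"p{i}" for i in range(80)]
        non = [f"p{i}" for i in range(80, 200)]
        table = enrichment_tables(ov, up, non)
        for ids, col in ((up, "a"), (non, "c")):
            in_any = table.groupby("family")[col].sum().sum()
            none_count = (ov.loc[ids, "family"] == "none").sum()
            assert in_any + none_count == len(ids)

    def test_empty_partition_rejected(self):
        ov = pd.DataFrame(columns=["family", "sense_flag"])
        with pytest.raises(ValueError):
            enrichment_tables(ov, [], ["p1"])


class TestFdrStratified:
    def test_single_bin_equals_global_fraction(self):
        ov = pd.DataFrame({
            "family": ["LTR", "LTR", "none", "none"],
            "sense_flag": [True, True, False, False],
        }, index=[f"p{i}" for i in range(4)])
        diff = pd.DataFrame({"fdr_bh": [1e-9] * 4}, index=ov.index)
        out = fdr_stratified_fractions(ov, diff, ov.index)
        populated = out.dropna(subset=["fraction"])
        assert len(populated) == 1
        assert populated["fraction"].iloc[0] == pytest.approx(0.5)

    def test_significance_gradient_yields_monotone_fraction(self, rng):
        n = 400
        fdr = np.concatenate([10 ** rng.uniform(-12, -9, n // 2),
                              10 ** rng.uniform(-4, -0.5, n // 2)])
        is_ltr = np.concatenate([rng.random(n // 2) < 0.3,
                                 rng.random(n // 2) < 0.05])
        ov = pd.DataFrame({"family": np.where(is_ltr, "LTR", "none"),
                           "sense_flag": is_ltr},
                          index=[f"p{i}" for i in range(n)])
        diff = pd.DataFrame({"fdr_bh": fdr}, index=ov.index)
        out = fdr_stratified_fractions(ov, diff, ov.index).dropna(
            subset=["fraction"])
        fr = out["fraction"].to_numpy()
        assert fr[-1] >= fr[0]


class TestRandomization:
    def genome(self):
        return GenomeLayout(("c1", "c2"), (1_000_000, 1_000_000))

    def test_no_repeats_gives_zero_null(self):
        cat = repeat_catalog([])
        peaks = pd.DataFrame([peak("p", "c1", 0, 100, "+", 50)])
        out = randomize_distal_peaks(peaks, cat, self.genome(), 10, seed=1)
        assert np.all(out["fractions"] == 0)

    def test_null_fraction_converges_to_coverage_expectation(self):
        # 10% of every chromosome covered by plus-strand LTR elements
        rows = []
        for chrom in ("c1", "c2"):
            rows += [(chrom, i * 100_000, i * 100_000 + 10_000, "+",
                      "LTR12C", "LTR", False) for i in range(10)]
        cat = repeat_catalog(rows)
        peaks = pd.DataFrame([peak(f"p{i}", "c1", 0, 1, "+", 0)
                              for i in range(400)])
        out = randomize_distal_peaks(peaks, cat, self.genome(), 60, seed=7)
        # sense hit needs strand match too: 0.10 coverage x 1/2
        expect = 0.05
        se = out["sd"] / np.sqrt(60)
        assert abs(out["mean"] - expect) <= 3 * max(se, 1e-3)

    def test_fixed_seed_reproduces_null(self):
        cat = repeat_catalog([("c1", 0, 100_000, "+", "LTR12C", "LTR", False)])
        peaks = pd.DataFrame([peak(f"p{i}", "c1", 0, 50, "+", 0)
                              for i in range(50)])
        a = randomize_distal_peaks(peaks, cat, self.genome(), 20, seed=5)
        b = randomize_distal_peaks(peaks, cat, self.genome(), 20, seed=5)
        assert np.array_equal(a["fractions"], b["fractions"])
        assert empirical_p(a["fractions"], 0.9) == pytest.approx(1 / 21)


class TestSubfamilyActivation:
    def catalog(self):
        rows = [("c1", i * 5000, i * 5000 + 1000, "+", "LTR12C", "LTR", False)
                for i in range(20)]
        rows += [("c1", 200_000 + i * 5000, 200_000 + i * 5000 + 300, "+",
                  "AluY", "SINE", False) for i in range(50)]
        return repeat_catalog(rows)

    def test_zero_activation_gives_p_one(self):
        cat = self.catalog()
        ov = pd.DataFrame({"element_id": [20], "subfamily": ["AluY"]},
                          index=["p0"])
        out = subfamily_activation(ov, ["p0"], cat)
        row = out.set_index("subfamily").loc["LTR12C"]
        assert row["p_hyper"] == 1.0

    def test_concentrated_activation_has_smallest_fdr(self):
        cat = self.catalog()
        ov = pd.DataFrame({
            "element_id": list(range(10)) + [25],
            "subfamily": ["LTR12C"] * 10 + ["AluY"],
        }, index=[f"p{i}" for i in range(11)])
        out = subfamily_activation(ov, ov.index, cat)
        assert out.iloc[0]["subfamily"] == "LTR12C"

    def test_elements_counted_once_peaks_separately(self):
        cat = self.catalog()
        ov = pd.DataFrame({"element_id": [0, 0], "subfamily": ["LTR12C"] * 2},
                          index=["p0", "p1"])
        out = subfamily_activation(ov, ["p0", "p1"], cat).set_index("subfamily")
        assert out.loc["LTR12C", "n_activated_elements"] == 1
        assert out.loc["LTR12C", "n_peaks"] == 2

    def test_unknown_subfamily_raises(self):
        cat = self.catalog()
        ov = pd.DataFrame({"element_id": [999], "subfamily": ["Phantom"]},
                          index=["p0"])
        with pytest.raises(KeyError):
            subfamily_activation(ov, ["p0"], cat)


class TestPositionProfile:
    def test_midpoint_summits_land_in_center_bin(self):
        ov = pd.DataFrame({"subfamily": ["LTR12C"] * 5,
                           "relative_position": [0.5] * 5})
        out = relative_position_profile(ov, "LTR12C")
        assert out["mode_bin"] == (0.50, 0.55)

    def test_uniform_positions_have_no_dominant_bin(self, rng):
        ov = pd.DataFrame({"subfamily": ["LTR12C"] * 500,
                           "relative_position": rng.random(500)})
        out = relative_position_profile(ov, "LTR12C")
        expected = 500 / 20
        chi2 = ((out["hist"] - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=19) > 0.01

    def test_strand_aware_formula(self):
        assert relative_position(700, 0, 1000, "+") == pytest.approx(0.70)
        assert relative_position(300, 0, 1000, "-") == pytest.approx(0.70)


class TestMetaelement:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])

    def test_five_prime_sense_tag_in_first_bin(self):
        elements = repeat_catalog([("c1", 1000, 7000, "+", "L1", "LINE",
                                    False)])
        tracks = {"g": {"s1": self.track([("c1", 1000, "+", 4)])}}
        prof = metaelement_profile(tracks, elements,
                                   pd.Series({"s1": 1e6}))
        assert prof["g"]["sense"][0] == pytest.approx(4.0)
        assert prof["g"]["sense"][1:].sum() == 0
        assert prof["g"]["antisense"].sum() == 0

    def test_empty_group_gives_zero_profile(self):
        elements = repeat_catalog([("c1", 0, 6000, "+", "L1", "LINE", False)])
        tracks = {"g": {"s1": self.track([])}}
        prof = metaelement_profile(tracks, elements, pd.Series({"s1": 1e6}))
        assert prof["g"]["sense"].sum() == 0

    def test_short_elements_rejected(self):
        elements = repeat_catalog([("c1", 0, 1000, "+", "L1", "LINE", False)])
        with pytest.raises(ValueError):
            metaelement_profile({}, elements, pd.Series(dtype=float))

    def test_minus_element_five_prime_is_genomic_end(self):
        elements = repeat_catalog([("c1", 1000, 7000, "-", "L1", "LINE",
                                    False)])
        tracks = {"g": {"s1": self.track([("c1", 6999, "-", 2)])}}
        prof = metaelement_profile(tracks, elements, pd.Series({"s1": 1e6}))
        assert prof["g"]["sense"][0] == pytest.approx(2.0)
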