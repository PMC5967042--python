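import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grburden.annotations_io import DosageMatrix, SamplePanel, SampleRecord
from grburden.errors import AnalysisError, ValidationError
from grburden.grb_core import ScoreSet
from grburden.population_stats import (
    classify_rare,
    compare_grb_groups,
    compute_group_raf,
    detect_fixed,
    frequency_spectrum,
    selection_test,
    welch_test,
    within_group_strata_contrast,
)


def panel_for(groups):
    """groups: {label: n} -> panel with population==super_population==label."""
    records = []
    for label, n in groups.items():
        for i in range(n):
            records.append(SampleRecord(f"{label}_{i}", label, label))
    return SamplePanel(records)


def scores_for(values_by_group, label="all", n_variants=10):
    samples, values = [], []
    for group, vals in values_by_group.items():
        for i, v in enumerate(vals):
            samples.append(f"{group}_{i}")
            values.append(v)
    return ScoreSet(label, n_variants, samples, np.array(values, dtype=float))


def welch_oracle(a, b):
    """Textbook Welch formulas, written independently of the implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * (1 - stats.t.cdf(abs(t), df))
    return t, df, p


class TestWelch:
    def test_matches_textbook_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(5, 40)))
            b = rng.normal(0.3, 2, size=int(rng.integers(5, 40)))
            diff, lo, hi, t, df, p = welch_test(a, b)
            t0, df0, p0 = welch_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-8)
            assert df == pytest.approx(df0, abs=1e-8)
            assert p == pytest.approx(p0, abs=1e-8)
            assert lo <= diff <= hi

    def test_textbook_example(self):
        # A={1,2,3}, B={4,5,6}: diff -3 symmetric, var 1 each
        diff, lo, hi, t, df, p = welch_test([4, 5, 6], [1, 2, 3])
        assert diff == pytest.approx(3.0)
        t0, df0, p0 = welch_oracle([4, 5, 6], [1, 2, 3])
        assert t == pytest.approx(t0)
        assert p == pytest.approx(p0)

    def test_identical_groups_null(self):
        diff, lo, hi, t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError):
            welch_test([1.0], [1.0, 2.0])


class TestCompareGrbGroups:
    def test_reference_row_first_and_null(self):
        panel = panel_for({"A": 3, "B": 3})
        scores = scores_for({"A": [1, 2, 3], "B": [4, 5, 6]})
        comps = compare_grb_groups(scores, panel, "population", "A")
        assert comps[0].group == "A" and comps[0].is_reference
        assert comps[0].mean_diff == 0.0

    def test_derived_example_mean_diff(self):
        panel = panel_for({"A": 3, "B": 3})
        scores = scores_for({"A": [1, 2, 3], "B": [4, 5, 6]})
        comp_b = compare_grb_groups(scores, panel, "population", "A")[1]
        assert comp_b.mean_diff == pytest.approx(3.0)
        t0, df0, p0 = welch_oracle([4, 5, 6], [1, 2, 3])
        assert comp_b.p_value == pytest.approx(p0, abs=1e-10)
        half = stats.t.ppf(0.975, df0) * np.sqrt(2 * (1.0 / 3))
        assert comp_b.ci_low == pytest.approx(3 - half, abs=1e-10)
        assert comp_b.ci_high == pytest.approx(3 + half, abs=1e-10)

    def test_identical_multisets_p_one(self):
        panel = panel_for({"A": 4, "B": 4})
        scores = scores_for({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        comp_b = compare_grb_groups(scores, panel, "population", "A")[1]
        assert comp_b.mean_diff == pytest.approx(0.0)
        assert comp_b.p_value == pytest.approx(1.0)

    def test_unknown_reference_errors(self):
        panel = panel_for({"A": 3})
        scores = scores_for({"A": [1, 2, 3]})
        with pytest.raises(AnalysisError):
            compare_grb_groups(scores, panel, "population", "Z")

    def test_tiny_group_excluded(self):
        panel = panel_for({"A": 3, "B": 1})
        scores = scores_for({"A": [1, 2, 3], "B": [9]})
        comps = compare_grb_groups(scores, panel, "population", "A")
        assert [c.group for c in comps] == ["A"]

    def test_sd_uses_n_minus_1(self):
        panel = panel_for({"A": 3, "B": 2})
        scores = scores_for({"A": [1, 2, 3], "B": [5, 7]})
        comps = compare_grb_groups(scores, panel, "population", "A")
        assert comps[0].sd == pytest.approx(1.0)
        assert comps[1].sd == pytest.approx(np.sqrt(2))


def freq_frame(rows):
    return pd.DataFrame(rows, columns=["group", "rsid", "raf", "n_chromosomes"])


class TestGroupRaf:
    def test_fixation(self):
        panel = panel_for({"A": 2})
        dm = DosageMatrix(["A_0", "A_1"], ["rs1"], np.array([[2.0], [2.0]]))
        freqs = compute_group_raf(dm, panel, "population")
        assert freqs["raf"].iloc[0] == 1.0
        assert freqs["n_chromosomes"].iloc[0] == 4

    def test_quarter(self):
        panel = panel_for({"A": 2})
        dm = DosageMatrix(["A_0", "A_1"], ["rs1"], np.array([[0.0], [1.0]]))
        freqs = compute_group_raf(dm, panel, "population")
        assert freqs["raf"].iloc[0] == pytest.approx(0.25)

    def test_missing_cells(self):
        panel = panel_for({"A": 2, "B": 2})
        dm = DosageMatrix(
            ["A_0", "A_1", "B_0", "B_1"],
            ["rs1"],
            np.array([[np.nan], [np.nan], [1.0], [np.nan]]),
        )
        freqs = compute_group_raf(dm, panel, "population").set_index("group")
        assert np.isnan(freqs.loc["A", "raf"])
        assert freqs.loc["A", "n_chromosomes"] == 0
        assert freqs.loc["B", "raf"] == pytest.approx(0.5)
        assert freqs.loc["B", "n_chromosomes"] == 2


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestClassifyRare:
    def test_folding(self):
        freqs = freq_frame(
            [("A", "rs1", 0.01, 100), ("A", "rs2", 0.5, 100), ("A", "rs3", 0.97, 100)]
        )
        out = classify_rare(freqs, maf_cut=0.05)
        assert out["n_rare"].iloc[0] == 2
        assert out["n_total"].iloc[0] == 3

    def test_identical_groups_p_one(self):
        rows = [("A", f"rs{i}", raf, 100) for i, raf in enumerate([0.01, 0.3, 0.8])]
        rows += [("B", f"rs{i}", raf, 100) for i, raf in enumerate([0.01, 0.3, 0.8])]
        out = classify_rare(freq_frame(rows), reference="A")
        p = out.loc[out["group"] == "B", "p_value"].iloc[0]
        assert p == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        # the 16/44 vs 1/59 configuration plus a sweep of other tables
        rows = [("A", f"rs{i}", 0.01 if i < 16 else 0.3, 100) for i in range(60)]
        rows += [("B", f"rs{i}", 0.01 if i < 1 else 0.3, 100) for i in range(60)]
        out = classify_rare(freq_frame(rows), reference="B")
        p = out.loc[out["group"] == "A", "p_value"].iloc[0]
        assert p == pytest.approx(fisher_oracle(16, 44, 1, 59), rel=1e-9)

    def test_flip_invariance(self, rng):
        rafs = rng.uniform(0, 1, size=40)
        rows = [("A", f"rs{i}", r, 50) for i, r in enumerate(rafs)]
        flipped = [("A", f"rs{i}", 1 - r, 50) for i, r in enumerate(rafs)]
        out1 = classify_rare(freq_frame(rows))
        out2 = classify_rare(freq_frame(flipped))
        assert out1["n_rare"].iloc[0] == out2["n_rare"].iloc[0]

    def test_missing_cell_dropped_from_denominator(self):
        freqs = freq_frame([("A", "rs1", 0.01, 100), ("A", "rs2", np.nan, 0)])
        out = classify_rare(freqs)
        assert out["n_total"].iloc[0] == 1

    def test_bad_cut_rejected(self):
        with pytest.raises(ValidationError):
            classify_rare(freq_frame([("A", "rs1", 0.1, 10)]), maf_cut=0.7)


class TestDetectFixed:
    def test_basic_fixed(self):
        freqs = freq_frame(
            [("EAS", "rs1", 1.0, 100), ("EUR", "rs1", 0.74, 100), ("AFR", "rs1", 0.8, 100)]
        )
        out = detect_fixed(freqs, reference="EUR")
        assert out["rsid"].tolist() == ["rs1"]
        assert out["fixed_in"].iloc[0] == "EAS"

    def test_not_polymorphic_in_reference(self):
        freqs = freq_frame([("EAS", "rs1", 0.995, 100), ("EUR", "rs1", 0.995, 100)])
        assert detect_fixed(freqs, reference="EUR").empty

    def test_boundary_cut(self):
        freqs = freq_frame([("EAS", "rs1", 0.99, 100), ("EUR", "rs1", 0.9899, 100)])
        out = detect_fixed(freqs, reference="EUR")
        assert out["rsid"].tolist() == ["rs1"]

    def test_multiple_groups_joined(self):
        freqs = freq_frame(
            [
                ("AFR", "rs1", 0.999, 100),
                ("EAS", "rs1", 1.0, 100),
                ("EUR", "rs1", 0.5, 100),
            ]
        )
        out = detect_fixed(freqs, reference="EUR")
        assert out["fixed_in"].iloc[0] == "AFR,EAS"


class TestSelectionTest:
    def test_symmetric_counts_p_one(self):
        rows = [("A", f"rs{i}", raf, 100) for i, raf in
                enumerate([0.01] * 3 + [0.99] * 3 + [0.5] * 4)]
        res = selection_test(freq_frame(rows))[0]
        assert res.n_rare == 3 and res.n_common_reciprocal == 3
        assert res.p_value == pytest.approx(1.0)
        assert res.conclusion == "no_excess"

    def test_one_sided_extreme_closed_form(self):
        rows = [("A", f"rs{i}", 0.01, 100) for i in range(8)]
        res = selection_test(freq_frame(rows))[0]
        # two-sided exact binomial with all 8 in the rare tail: 2 * (1/2)^8
        assert res.p_value == pytest.approx(2 * 0.5**8)
        assert res.conclusion == "excess_rare"

    def test_half_split_mode(self):
        rows = [("A", f"rs{i}", raf, 100) for i, raf in
                enumerate([0.2, 0.3, 0.5, 0.7])]
        res = selection_test(freq_frame(rows), low=0.5, high=0.5)[0]
        assert res.n_rare == 2  # 0.2, 0.3
        assert res.n_common_reciprocal == 2  # 0.5 counts as common
        assert res.p_value == pytest.approx(1.0)

    def test_empty_tails(self):
        rows = [("A", f"rs{i}", 0.5, 100) for i in range(5)]
        res = selection_test(freq_frame(rows))[0]
        assert res.conclusion == "no_excess"
        assert np.isnan(res.p_value)

    def test_non_reciprocal_cuts_rejected(self):
        with pytest.raises(ValidationError):
            selection_test(freq_frame([("A", "rs1", 0.5, 10)]), low=0.05, high=0.9)

    def test_type_one_error_calibration(self, rng):
        # symmetric raf distribution: rejection of either direction ~ <= 5%
        reps = 2000
        rejections = 0
        for _ in range(reps):
            rafs = rng.uniform(0.0, 1.0, size=59)
            rows = [("A", f"rs{i}", r, 100) for i, r in enumerate(rafs)]
            res = selection_test(freq_frame(rows))[0]
            if not np.isnan(res.p_value) and res.p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        # exact binomial test is conservative; allow 3 binomial sds above 5%
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestWithinGroupContrast:
    def test_identical_scores(self):
        panel = panel_for({"A": 3})
        a = scores_for({"A": [1, 2, 3]}, label="x")
        b = scores_for({"A": [1, 2, 3]}, label="y")
        out = within_group_strata_contrast(a, b, panel, "population")
        assert out["mean_diff"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_constant_offset(self):
        panel = panel_for({"A": 4})
        a = scores_for({"A": [3, 4, 5, 6]}, label="x")
        b = scores_for({"A": [1, 2, 3, 4]}, label="y")
        out = within_group_strata_contrast(a, b, panel, "population")
        assert out["mean_diff"].iloc[0] == pytest.approx(2.0)
        assert out["p_value"].iloc[0] == pytest.approx(0.0)

    def test_matches_scipy_paired(self, rng):
        panel = panel_for({"A": 20})
        x = rng.normal(5, 1, 20)
        y = rng.normal(4, 1, 20)
        a = scores_for({"A": x}, label="x", n_variants=10)
        b = scores_for({"A": y}, label="y", n_variants=10)
        out = within_group_strata_contrast(a, b, panel, "population")
        assert out["p_value"].iloc[0] == pytest.approx(
            stats.ttest_rel(x, y).pvalue, abs=1e-10
        )

    def test_sample_mismatch_errors(self):
        panel = panel_for({"A": 2})
        a = scores_for({"A": [1, 2]})
        b = ScoreSet("y", 10, ["A_1", "A_0"], np.array([1.0, 2.0]))
        with pytest.raises(AnalysisError):
            within_group_strata_contrast(a, b, panel)


class TestFrequencySpectrum:
    def test_single_bin(self):
        freqs = freq_frame([("A", f"rs{i}", 0.35, 10) for i in range(5)])
        spec = frequency_spectrum(freqs)["A"]
        assert spec["counts"][3] == 5
        assert spec["counts"].sum() == 5
        assert spec["modal_bin"] == 3

    def test_counts_conserved(self, rng):
        rafs = rng.uniform(0, 1, size=50)
        rows = [("A", f"rs{i}", r, 10) for i, r in enumerate(rafs)]
        rows.append(("A", "rsX", np.nan, 0))
        spec = frequency_spectrum(freq_frame(rows))["A"]
        assert spec["counts"].sum() == 50

    def test_edge_values_binned(self):
        freqs = freq_frame([("A", "rs1", 0.0, 10), ("A", "rs2", 1.0, 10)])
        spec = frequency_spectrum(freqs)["A"]
        assert spec["counts"][0] == 1 and spec["counts"][-1] == 1

    def test_uniform_approximately_flat(self, rng):
        counts = np.zeros(10)
        for _ in range(50):
            rafs = rng.uniform(0, 1, size=100)
            rows = [("A", f"rs{i}", r, 10) for i, r in enumerate(rafs)]
            counts += frequency_spectrum(freq_frame(rows))["A"]["counts"]
        props = counts / counts.sum()
        assert np.all(np.abs(props - 0.1) < 0.02)

    def test_degenerate_density_is_nan(self):
        freqs = freq_frame([("A", "rs1", 0.4, 10), ("A", "rs2", 0.4, 10)])
        spec = frequency_spectrum(freqs)["A"]
        assert np.isnan(spec["density"]).all()
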