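"""Sex calling, spline time-course DE, dosage report, smoothing."""

import numpy as np
import pandas as pd
import pytest

from embryotime import (
    Clustering,
    call_sex,
    dosage_report,
    smooth_series,
    spline_de,
)
from tests.conftest import make_normalized


class TestCallSex:
    def make_nm(self, female_counts, male_counts):
        f = np.asarray(female_counts, float)
        m = np.asarray(male_counts, float)
        bulk = 200 - f - m
        return make_normalized(
            np.vstack([f, m, bulk]), genes=["sxl", "msl2", "bulk"]
        )

    def test_clear_female_and_male_calls(self):
        sc = call_sex(self.make_nm([50, 0], [0, 50]), "sxl", "msl2")
        assert sc.calls.tolist() == ["female", "male"]

    def test_both_markers_silent_is_undetermined(self):
        sc = call_sex(self.make_nm([0, 50], [0, 0]), "sxl", "msl2")
        assert sc.calls.iloc[0] == "undetermined"

    def test_missing_marker_is_named(self):
        with pytest.raises(ValueError, match="nope"):
            call_sex(self.make_nm([1, 2], [3, 4]), "nope", "msl2")

    def test_scale_invariance_above_floor(self):
        a = call_sex(self.make_nm([40, 4], [4, 40]), "sxl", "msl2")
        b = call_sex(self.make_nm([80, 8], [8, 80]), "sxl", "msl2")
        assert a.calls.tolist() == b.calls.tolist()


def spline_inputs(rng, n_per_cell=6, timepoints=5, n_genes=50, sex_shift=None):
    """Balanced two-sex cohort over `timepoints` with NB-ish noise."""
    cells = []
    sexes = []
    times = []
    for t in range(timepoints):
        for s in ("female", "male"):
            for _ in range(n_per_cell):
                cells.append((t, s))
                sexes.append(s)
                times.append(t)
    n = len(cells)
    base = rng.lognormal(np.log(20), 0.4, n_genes)
    values = np.empty((n_genes, n))
    for j, (t, s) in enumerate(cells):
        mu = base * (1.0 + 0.15 * t)
        if sex_shift is not None and s == "female":
            mu = mu * sex_shift
        values[:, j] = rng.poisson(mu)
    values += 1.0
    nm = make_normalized(values)
    ids = list(nm.embryo_ids)
    return (
        nm,
        pd.Series(times, index=ids, dtype=float),
        pd.Series(sexes, index=ids),
    )


class TestSplineDE:
    def test_identical_trajectories_are_not_significant(self):
        rng = np.random.default_rng(0)
        nm, time, sex = spline_inputs(rng)
        res = spline_de(nm, time, sex)
        assert len(res.significant_genes) == 0
        assert res.table["p_value"].min() > 1e-4

    def test_doubled_female_expression_is_detected(self):
        # shift only 10 of 500 genes: a small library share, so
        # normalization neither absorbs the signal nor spreads a
        # composition shift onto the null genes
        rng = np.random.default_rng(1)
        nm, time, sex = spline_inputs(rng, n_genes=500)
        values = nm.values.to_numpy().copy()
        females = (sex == "female").to_numpy()
        values[:10][:, females] *= 2.0
        nm2 = make_normalized(values)
        res = spline_de(nm2, time, sex)
        shifted = set(list(nm2.gene_ids)[:10])
        assert len(shifted & set(res.significant_genes)) >= 9
        assert len(set(res.significant_genes) - shifted) <= 10

    def test_f_statistic_invariant_to_constant_shift(self):
        # x -> 2x + 1 turns log2(x+1) into log2(x+1) + 1 exactly, a
        # per-gene constant shift the F statistic must ignore
        rng = np.random.default_rng(2)
        nm, time, sex = spline_inputs(rng)
        res1 = spline_de(nm, time, sex)
        shifted = make_normalized(nm.values.to_numpy() * 2.0 + 1.0)
        res2 = spline_de(shifted, time, sex)
        np.testing.assert_allclose(
            res1.table["F_statistic"], res2.table["F_statistic"], rtol=1e-6
        )

    def test_undetermined_embryos_are_excluded(self):
        rng = np.random.default_rng(3)
        nm, time, sex = spline_inputs(rng)
        sex.iloc[:4] = "undetermined"
        res = spline_de(nm, time, sex)
        assert res.df_denom == len(sex) - 4 - (res.table.shape[0] * 0 + 6)

    def test_single_timepoint_errors(self):
        rng = np.random.default_rng(4)
        nm, time, sex = spline_inputs(rng, timepoints=1)
        with pytest.raises(ValueError, match="timepoints"):
            spline_de(nm, time, sex)

    def test_degrees_of_freedom_recorded_and_shared(self):
        rng = np.random.default_rng(5)
        nm, time, sex = spline_inputs(rng)
        res = spline_de(nm, time, sex)
        assert res.df_num >= 1
        assert res.df_denom == len(sex) - 2 * (res.df_num)
        # p in [0, 1] for every gene
        assert ((res.table["p_value"] >= 0) & (res.table["p_value"] <= 1)).all()


class TestDosageReport:
    def build(self, f_x, m_x, f_a, m_a):
        # 2 X genes, 2 autosomal genes; one cluster, one embryo per sex
        values = np.array(
            [[f_x, m_x], [f_x, m_x], [f_a, m_a], [f_a, m_a]], dtype=float
        )
        nm = make_normalized(values, genes=["x1", "x2", "a1", "a2"])
        ids = list(nm.embryo_ids)
        labels = pd.Series([1, 1], index=ids)
        cl = Clustering(labels=labels, medoid_ids=[ids[0]], k=1, total_cost=0.0)
        calls = pd.DataFrame(
            {
                "embryo_id": ids,
                "call": ["female", "male"],
                "female_marker_count": [9.0, 0.0],
                "male_marker_count": [0.0, 9.0],
                "log_ratio": [5.0, -5.0],
            }
        ).set_index("embryo_id", drop=False)
        from embryotime.sexdiff import SexCall

        chrom = pd.Series({"x1": "X", "x2": "X", "a1": "2L", "a2": "3R"})
        return nm, SexCall(table=calls), cl, chrom

    def test_identical_expression_gives_unit_ratios(self):
        nm, sc, cl, chrom = self.build(10, 10, 30, 30)
        report = dosage_report(nm, sc, cl, [], chrom)
        assert report.loc[1, "x_ratio_f_over_m"] == pytest.approx(1.0)
        assert report.loc[1, "autosome_ratio_f_over_m"] == pytest.approx(1.0)

    def test_missing_sex_cell_reports_nan(self):
        nm, sc, cl, chrom = self.build(10, 10, 30, 30)
        table = sc.table.copy()
        table["call"] = ["female", "female"]
        from embryotime.sexdiff import SexCall

        report = dosage_report(nm, SexCall(table=table), cl, [], chrom)
        assert np.isnan(report.loc[1, "x_ratio_f_over_m"])

    def test_maternal_and_excluded_genes_leave_the_sums(self):
        nm, sc, cl, chrom = self.build(10, 10, 30, 30)
        report = dosage_report(nm, sc, cl, ["x1"], chrom, exclude=("a1",))
        # x sum now only x2; autosome sum only a2 (values still symmetric)
        assert report.loc[1, "female_x"] == pytest.approx(
            nm.values.loc["x2"].iloc[0]
        )

    def test_unannotated_zygotic_gene_errors(self):
        nm, sc, cl, chrom = self.build(10, 10, 30, 30)
        with pytest.raises(ValueError, match="annotation missing"):
            dosage_report(nm, sc, cl, [], chrom.drop("a2"))


class TestSmoothSeries:
    def test_constant_series_unchanged(self):
        y = np.full(20, 3.7)
        np.testing.assert_allclose(smooth_series(y), y)

    def test_linear_series_preserved_at_interior(self):
        y = 0.7 * np.arange(30) - 2.0
        out = smooth_series(y, window=5, poly_order=2)
        np.testing.assert_allclose(out[2:-2], y[2:-2], atol=1e-10)

    def test_output_length_preserved(self):
        y = np.sin(np.linspace(0, 3, 41))
        assert len(smooth_series(y)) == 41

    def test_window_validation(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="odd"):
            smooth_series(y, window=4)
        with pytest.raises(ValueError, match="exceed"):
            smooth_series(y, window=3, poly_order=3)
        with pytest.raises(ValueError, match="smaller"):
            smooth_series(np.arange(4.0), window=5)

    def test_noisy_sine_variance_reduction_and_accuracy(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 2 * np.pi, 100)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.5, 100)
        smoothed = smooth_series(noisy, window=5, poly_order=2)
        assert np.var(smoothed - clean) < np.var(noisy - clean)
        # windowed least-squares oracle: direct quadratic fit per window
        oracle = np.empty(100)
        for i in range(100):
            lo, hi = max(0, i - 2), min(100, i + 3)
            coef = np.polynomial.polynomial.polyfit(
                x[lo:hi] - x[i], noisy[lo:hi], min(2, hi - lo - 1)
            )
            oracle[i] = coef[0]
        # the two-stage smoother must not be worse at recovering the
        # clean signal than the single-stage windowed oracle, and must
        # land near the window-5 noise floor (sigma / sqrt(5) ~ 0.22)
        rms = np.sqrt(np.mean((smoothed - clean) ** 2))
        rms_oracle = np.sqrt(np.mean((oracle - clean) ** 2))
        assert rms <= rms_oracle + 0.02
        assert rms < 0.25
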