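import numpy as np
import pandas as pd
import pytest

from halovasc import (
    BinaryVolume,
    SampleMetrics,
    build_significance_table,
    fit_per_sample,
    percent_volume,
    quadratic_fit,
    read_metrics_workbook,
    significance_stars,
    summarize,
    welch_t,
    wilcoxon_rank,
)

from oracles import (
    quadratic_normal_equations,
    ranksum_exact_two_sided_p,
    welch_p_closed_form,
)


class TestPercentVolume:
    def test_extremes(self):
        assert percent_volume(BinaryVolume(np.ones((3, 3, 3), bool))) == 100.0
        assert percent_volume(BinaryVolume(np.zeros((3, 3, 3), bool))) == 0.0

    def test_arithmetic(self):
        v = np.zeros((30, 30, 30), bool)
        v[:3, :3, :3] = True
        assert percent_volume(BinaryVolume(v)) == pytest.approx(0.1)

    def test_tube_phantom_close_to_continuous_area(self):
        from halovasc.phantoms import rasterize_tube

        shape = (40, 21, 21)
        tube = rasterize_tube(shape, (0, 10, 10), (39, 10, 10), 4)
        vpct = percent_volume(BinaryVolume(tube))
        continuous = 100 * np.pi * 16 * 40 / np.prod(shape)
        assert vpct == pytest.approx(continuous, rel=0.05)


class TestSummarize:
    def test_small_sample(self):
        assert summarize([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert summarize([7.5]) == (7.5, 7.5, 7.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_linear_interpolation_convention(self, rng):
        vals = rng.normal(size=11)
        med, q25, q75 = summarize(vals)
        s = np.sort(vals)
        # manual linear interpolation between order statistics
        def pct(q):
            h = q * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert med == pytest.approx(pct(0.5))
        assert q25 == pytest.approx(pct(0.25))
        assert q75 == pytest.approx(pct(0.75))


class TestWelch:
    def test_identical_samples_give_p_one(self):
        assert welch_t([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a = [19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0]
        b = [28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7]
        assert welch_t(a, b) == pytest.approx(welch_p_closed_form(a, b), abs=1e-10)

    def test_separated_samples_highly_significant(self):
        assert welch_t([1, 1.1, 0.9, 1.05], [10, 10.1, 9.9, 10.05]) < 0.001

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([3, 3, 3], [3, 3, 3])

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 8)
        assert welch_t(a, b) == pytest.approx(welch_t(a + 100, b + 100))


class TestWilcoxonRank:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_fully_separated_n4_exact_p(self):
        p = wilcoxon_rank([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70, abs=1e-12)
        assert p == pytest.approx(ranksum_exact_two_sided_p([1, 2, 3, 4], [5, 6, 7, 8]))

    def test_matches_enumeration_oracle_on_interleaved_fixture(self):
        a, b = [1.2, 3.4, 5.1, 7.7], [2.2, 4.9, 6.0, 9.3]
        assert wilcoxon_rank(a, b) == pytest.approx(ranksum_exact_two_sided_p(a, b))

    def test_invariant_under_monotone_transform(self):
        a, b = [1.0, 2.5, 3.0, 8.0], [2.0, 4.0, 6.5, 7.0]
        assert wilcoxon_rank(a, b) == pytest.approx(
            wilcoxon_rank(np.exp(a), np.exp(b))
        )

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank([2, 2, 2, 2], [2, 2, 2, 2])


class TestStars:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.2, "ns"),
            (0.05, "ns"),  # strict "<": boundary is not significant
            (0.049, "*"),
            (0.01, "*"),
            (0.009, "**"),
            (0.001, "**"),
            (0.0009, "***"),
            (float("nan"), "na"),
        ],
    )
    def test_threshold_coding(self, p, stars):
        assert significance_stars(p) == stars


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        x = np.linspace(0, 10, 12)
        y = 0.7 * x**2 - 2.0 * x + 5.0
        a, b, c, r2 = quadratic_fit(x, y)
        assert (a, b, c) == pytest.approx((0.7, -2.0, 5.0), abs=1e-8)
        assert r2 == pytest.approx(1.0)

    def test_three_points_interpolate_exactly(self):
        a, b, c, r2 = quadratic_fit([0, 1, 2], [1, 0, 3])
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.linspace(0.5, 8, 21)
        y = 0.3 * x**2 - 1.1 * x + 2 + rng.normal(0, 0.4, 21)
        got = quadratic_fit(x, y)
        want = quadratic_normal_equations(x, y)
        assert got == pytest.approx(want, rel=1e-8)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            quadratic_fit([1, 1, 1, 1], [1, 2, 3, 4])

    def test_r2_invariant_to_rescaling_x(self, rng):
        x = np.linspace(1, 5, 10)
        y = x**2 + rng.normal(0, 0.3, 10)
        _, _, _, r2a = quadratic_fit(x, y)
        _, _, _, r2b = quadratic_fit(10 * x + 3, y)
        assert r2a == pytest.approx(r2b, abs=1e-9)


def _metrics(sample, treatment, v, h):
    return SampleMetrics(
        sample=sample, treatment=treatment,
        v_pct=np.asarray(v, dtype=float), nhv=np.asarray(h, dtype=float),
    )


class TestSignificanceTable:
    def _cohorts(self, rng, shift=0.0):
        ctrl = [
            _metrics(f"c{i}", "control", rng.normal(5, 0.5, 6), rng.normal(3, 0.3, 6))
            for i in range(5)
        ]
        trt = [
            _metrics(
                f"t{i}", "treated",
                rng.normal(5 - shift, 0.5, 6), rng.normal(3 + shift, 0.3, 6),
            )
            for i in range(5)
        ]
        return {"control": ctrl, "treated": trt}

    def test_identical_cohorts_not_significant(self, rng):
        cohorts = self._cohorts(rng, shift=0.0)
        summary = build_significance_table(cohorts)
        assert (summary.pairwise["p_vpct_welch"] > 0.05).mean() > 0.8
        assert set(summary.pairwise["stars_vpct"]) <= {"ns", "*"}

    def test_planted_effect_detected(self, rng):
        summary = build_significance_table(self._cohorts(rng, shift=3.0))
        assert (summary.pairwise["p_vpct_welch"] < 0.01).all()
        assert (summary.pairwise["p_nhv_wilcoxon"] < 0.05).all()

    def test_medians_and_iqr_shape(self, rng):
        summary = build_significance_table(self._cohorts(rng))
        assert len(summary.medians) == 2 * 6
        assert {"v_pct_median", "v_pct_q25", "nhv_q75"} <= set(summary.medians.columns)

    def test_missing_class_flagged_not_fabricated(self, rng):
        cohorts = self._cohorts(rng)
        for m in cohorts["treated"]:
            m.nhv[5] = np.nan  # class absent after treatment
        summary = build_significance_table(cohorts)
        cell = summary.pairwise[summary.pairwise["class"] == 6].iloc[0]
        assert np.isnan(cell["p_nhv_wilcoxon"]) and cell["stars_nhv"] == "na"

    def test_single_arm_rejected(self, rng):
        with pytest.raises(ValueError):
            build_significance_table({"control": self._cohorts(rng)["control"]})


class TestWorkbook:
    def test_roundtrip_and_per_sample_fits(self, tmp_path, rng):
        # synthetic workbook in the tidy cohort-export layout
        rows = []
        truths = {}
        for s in range(4):
            a, b, c = 0.05 * (s + 1), -0.5, 4 + s
            truths[f"s{s}"] = (a, b, c)
            v = np.linspace(1, 9, 6)
            for klass, (vi, hi) in enumerate(zip(v, a * v**2 + b * v + c), start=1):
                rows.append(
                    {"Sample": f"s{s}", "Treatment": "control", "Class": klass,
                     "Vol %": vi, "nHv 90": hi}
                )
        path = tmp_path / "metrics_synthetic.xlsx"
        pd.DataFrame(rows).to_excel(path, index=False)
        tidy = read_metrics_workbook(path)
        assert list(tidy.columns) == ["sample", "treatment", "class", "v_pct", "nhv"]
        fits = fit_per_sample(tidy)
        assert (fits["r2"] > 1 - 1e-9).all()
        for _, row in fits.iterrows():
            a, b, c = truths[row["sample"]]
            assert (row["a"], row["b"], row["c"]) == pytest.approx((a, b, c), abs=1e-8)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.xlsx"
        pd.DataFrame({"Sample": ["x"], "Class": [1]}).to_excel(path, index=False)
        with pytest.raises(ValueError, match="columns"):
            read_metrics_workbook(path)
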