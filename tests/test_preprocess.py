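"""Pretreatments: autoscale, MSC, Savitzky-Golay derivative, shorthand
parsing, and the pretreatment survey."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import silagescan as ss
from silagescan.preprocess import (FittedPreprocess, default_survey_candidates,
                                   fit_preprocess)


class TestAutoscale:
    def test_hand_computed_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xs, mu, sd = ss.autoscale(X)
        np.testing.assert_allclose(Xs.ravel(), [-1, 0, 1])  # sample SD = 1
        assert mu[0] == 2 and sd[0] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Xs, _, _ = ss.autoscale(X)
        Xss, _, _ = ss.autoscale(Xs)
        np.testing.assert_allclose(Xss, Xs, atol=1e-10)

    def test_constant_column_names_variable(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            ss.autoscale(X)

    def test_train_statistics_apply_to_new_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2, 3, size=(30, 4))
        fp = fit_preprocess(ss.PreprocessSpec("autoscale"), X)
        new = rng.normal(2, 3, size=(5, 4))
        np.testing.assert_allclose(fp.apply(new),
                                   (new - X.mean(0)) / X.std(0, ddof=1))


class TestMSC:
    def test_affine_scatter_removed_exactly(self):
        ref = np.sin(np.linspace(0, 3, 50)) + 2
        row = 2.0 * ref + 3.0
        out = ss.msc(row[None, :], reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_reference_row_unchanged(self):
        ref = np.linspace(1, 2, 30) ** 2
        out = ss.msc(ref[None, :], reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-12)

    def test_corrected_rows_have_unit_slope_zero_intercept(self):
        rng = np.random.default_rng(2)
        ref = np.exp(-np.linspace(-2, 2, 80) ** 2)
        rows = np.array([(1 + 0.3 * rng.normal()) * ref + 0.2 * rng.normal()
                         + 0.01 * rng.normal(size=80) for _ in range(10)])
        corrected = ss.msc(rows, reference=ref)
        for row in corrected:
            slope, intercept = np.polyfit(ref, row, 1)
            assert slope == pytest.approx(1.0, abs=1e-6)
            assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_idempotent_with_fixed_reference(self):
        rng = np.random.default_rng(3)
        ref = np.cumsum(rng.uniform(size=40))
        rows = rng.uniform(size=(6, 40)) + ref
        once = ss.msc(rows, reference=ref)
        twice = ss.msc(once, reference=ref)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            ss.msc(np.ones((2, 5)), reference=np.full(5, 3.0))


class TestSGDerivative:
    def test_exact_second_derivative_of_quadratic(self):
        i = np.arange(60, dtype=float)
        out = ss.sg_derivative((i ** 2)[None, :], window=11, poly_order=2,
                               derivative_order=2)
        np.testing.assert_allclose(out[0, 5:-5], 2.0, atol=1e-8)

    def test_exact_first_derivative_of_line(self):
        i = np.arange(40, dtype=float)
        out = ss.sg_derivative((3 * i + 1)[None, :], window=9, poly_order=2,
                               derivative_order=1)
        np.testing.assert_allclose(out[0, 4:-4], 3.0, atol=1e-8)

    def test_sine_second_derivative_matches_finite_differences(self):
        x = np.linspace(0, 2 * np.pi, 400)
        y = np.sin(x)
        out = ss.sg_derivative(y[None, :], window=9, poly_order=3,
                               derivative_order=2)[0]
        fd = np.zeros_like(y)
        fd[1:-1] = y[2:] - 2 * y[1:-1] + y[:-2]  # index-space second difference
        np.testing.assert_allclose(out[5:-5], fd[5:-5], atol=1e-3)

    def test_zeroth_derivative_smoothing_preserves_constant(self):
        out = ss.sg_derivative(np.full((1, 30), 7.0), window=11, poly_order=2,
                               derivative_order=0)
        np.testing.assert_allclose(out, 7.0, atol=1e-12)

    def test_window_larger_than_row_rejected(self):
        with pytest.raises(ValueError):
            ss.sg_derivative(np.zeros((1, 5)), window=11, poly_order=2,
                             derivative_order=2)

    @pytest.mark.parametrize("window,poly", [(10, 2), (5, 5), (9, 1)])
    def test_invalid_sg_parameters_rejected(self, window, poly):
        with pytest.raises(ValueError):
            ss.PreprocessSpec("sg_derivative", derivative_order=2,
                              window=window, poly_order=poly)


class TestShorthand:
    @pytest.mark.parametrize("text", ["none", "autoscale", "msc", "D-2,2,11",
                                      "D-1,3,27"])
    def test_round_trip(self, text):
        assert ss.PreprocessSpec.from_shorthand(text).shorthand() == text

    def test_unknown_shorthand_rejected(self):
        with pytest.raises(ValueError):
            ss.PreprocessSpec.from_shorthand("SNV")


class TestSurvey:
    def test_default_candidate_grid_has_43_entries(self):
        cands = default_survey_candidates()
        assert len(cands) == 43
        assert len({c.shorthand() for c in cands}) == 43

    def test_noiseless_data_all_candidates_succeed(self):
        rng = np.random.default_rng(4)
        ref = np.exp(-((np.linspace(1300, 2500, 60) - 1950) / 100) ** 2)
        y = rng.uniform(30, 70, 40)
        X = 0.3 + (y[:, None] / 100) * ref
        cands = [ss.PreprocessSpec("none"),
                 ss.PreprocessSpec.from_shorthand("D-2,2,11"),
                 ss.PreprocessSpec.from_shorthand("D-1,2,9")]
        table = ss.optimize_preprocessing(X, y, candidates=cands, max_lv=3)
        assert len(table) == 3
        assert (table["error"] == "").all()
        assert (table["rmsecv"] < 1e-6).all()

    def test_scatter_ranks_msc_or_derivative_above_none(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(1300, 2500, 80)
        ref = np.exp(-((grid - 1950) / 120) ** 2)
        y = rng.uniform(30, 70, 60)
        clean = 0.4 + (y[:, None] / 100) * ref
        mult = 1 + 0.1 * rng.normal(size=(60, 1))     # multiplicative scatter
        X = mult * clean + 0.02 * rng.normal(size=(60, 1))
        cands = [ss.PreprocessSpec("none"), ss.PreprocessSpec("msc"),
                 ss.PreprocessSpec.from_shorthand("D-2,2,11")]
        # at one latent variable a scatter-blind model cannot also span the
        # scatter direction, so the correction has to come from pretreatment
        table = ss.optimize_preprocessing(X, y, candidates=cands, max_lv=1)
        ranked = table["pretreatment"].tolist()
        assert ranked.index("none") > 0  # msc or SGD wins under scatter

    def test_failures_recorded_without_aborting(self):
        X = np.random.default_rng(6).normal(size=(30, 6))
        y = X[:, 0] * 2 + 1
        cands = [ss.PreprocessSpec("none"),
                 ss.PreprocessSpec.from_shorthand("D-2,2,11")]  # window > 6 cols
        table = ss.optimize_preprocessing(X, y, candidates=cands, max_lv=3)
        assert (table["error"] != "").sum() == 1
        assert (table["error"] == "").sum() == 1
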