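"""Replicate assay statistics: induction, expression, autophosphorylation,
in-vitro substrate phosphorylation and pharmacological rescue calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gcn2triage.assays import (
    AssayError,
    AssayPanel,
    ExpressionSummary,
    ReporterMeasurement,
    call_autophos,
    call_induction,
    call_rescue,
    quantify_eif2a_phos,
    quantify_expression,
    quantify_expression_panel,
)


def welch_oracle(a, b):
    """Independent one-sided Welch p for mean(a) > mean(b) on log values,
    from the textbook statistic and Welch-Satterthwaite degrees of freedom."""
    la, lb = np.log(a), np.log(b)
    na, nb = len(la), len(lb)
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    t = (la.mean() - lb.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(stats.t.sf(t, df))


class TestInduction:
    def test_strong_induction_called_yes(self):
        m = ReporterMeasurement((100, 110, 95), (520, 480, 505))
        assert welch_oracle(np.array(m.rlu_treated), np.array(m.rlu_untreated)) < 0.05
        assert np.mean(m.rlu_treated) / np.mean(m.rlu_untreated) > 2
        assert call_induction(m) == "yes"

    def test_flat_response_called_no(self):
        assert call_induction(ReporterMeasurement((100, 100, 100), (100, 100, 100))) == "no"

    def test_subthreshold_fold_called_no(self):
        m = ReporterMeasurement((100, 105, 95), (185, 190, 195))
        assert np.mean(m.rlu_treated) / np.mean(m.rlu_untreated) < 2
        assert call_induction(m) == "no"

    def test_significance_required_even_above_fold(self):
        # high fold but wildly dispersed treated arm: Welch test cannot reject
        m = ReporterMeasurement((100, 101, 99), (20, 30, 2000))
        assert np.mean(m.rlu_treated) / np.mean(m.rlu_untreated) > 2
        assert welch_oracle(np.array(m.rlu_treated), np.array(m.rlu_untreated)) > 0.05
        assert call_induction(m) == "no"

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50)
    def test_scale_invariance(self, scale):
        base_u, base_t = (100.0, 110.0, 95.0), (520.0, 480.0, 505.0)
        scaled = ReporterMeasurement(tuple(v * scale for v in base_u),
                                     tuple(v * scale for v in base_t))
        assert call_induction(scaled) == call_induction(ReporterMeasurement(base_u, base_t))

    @pytest.mark.parametrize("untreated, treated", [((100,), (200, 210)),
                                                    ((100, 110), (0, 210)),
                                                    ((100, -110), (200, 210))])
    def test_invalid_measurements_rejected(self, untreated, treated):
        with pytest.raises(AssayError):
            ReporterMeasurement(untreated, treated)


class TestExpression:
    def test_identical_replicates_not_reduced(self):
        summary = quantify_expression((1.0, 1.1, 0.9, 1.0), (1.0, 1.1, 0.9, 1.0))
        assert summary.ratio_vs_wt == pytest.approx(1.0)
        assert not summary.significantly_reduced and not summary.severe

    def test_strong_loss_is_reduced_and_severe(self):
        summary = quantify_expression((0.09, 0.10, 0.08, 0.09), (1.0, 1.05, 0.95, 1.0))
        assert summary.ratio_vs_wt == pytest.approx(0.09, rel=0.05)
        assert summary.significantly_reduced and summary.severe

    def test_moderate_loss_reduced_but_not_severe(self):
        summary = quantify_expression((0.21, 0.22, 0.20, 0.21), (1.0, 1.02, 0.98, 1.0))
        assert summary.significantly_reduced and not summary.severe

    def test_severe_implies_reduced_by_construction(self):
        with pytest.raises(AssayError):
            ExpressionSummary(ratio_vs_wt=0.1, significantly_reduced=False, severe=True)

    @given(
        ratio=st.floats(min_value=0.01, max_value=1.5),
        cv=st.floats(min_value=0.0, max_value=0.3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=100, deadline=None)
    def test_severe_flag_never_without_significance(self, ratio, cv, seed):
        rng = np.random.default_rng(seed)
        wt = 1.0 * np.exp(cv * rng.standard_normal(4))
        variant = ratio * np.exp(cv * rng.standard_normal(4))
        summary = quantify_expression(variant, wt)
        assert not summary.severe or summary.significantly_reduced

    def test_panel_holm_correction_is_conservative(self):
        rng = np.random.default_rng(1)
        wt = tuple(np.exp(0.1 * rng.standard_normal(4)))
        reps = {f"V{i}": tuple(0.8 * np.exp(0.1 * rng.standard_normal(4))) for i in range(10)}
        corrected = quantify_expression_panel(reps, wt)
        raw = {n: quantify_expression(r, wt) for n, r in reps.items()}
        flagged_corrected = {n for n, s in corrected.items() if s.significantly_reduced}
        flagged_raw = {n for n, s in raw.items() if s.significantly_reduced}
        assert flagged_corrected <= flagged_raw

    def test_non_positive_replicates_rejected(self):
        with pytest.raises(AssayError):
            quantify_expression((0.5, 0.6), (1.0, 0.0))


class TestAutophos:
    def test_tenfold_over_basal_called_yes(self):
        assert call_autophos(0.1, 1.0, 1.0) == "yes"

    def test_absent_signal_called_no(self):
        assert call_autophos(0.1, 0.0, 1.0) == "no"

    def test_subfold_increase_called_no(self):
        assert call_autophos(0.5, 0.8, 1.0) == "no"

    def test_kinase_dead_control_row_is_no(self, tested_panels):
        assert tested_panels["K619R"].autophos_t899 == "no"

    @pytest.mark.parametrize("basal, stressed, total", [(math.nan, 1, 1), (0.1, 1, 0),
                                                        (-0.1, 1, 1), (0.1, math.inf, 1)])
    def test_invalid_signals_rejected(self, basal, stressed, total):
        with pytest.raises(AssayError):
            call_autophos(basal, stressed, total)


class TestEif2aPhos:
    def test_reference_percentage(self):
        assert quantify_eif2a_phos(0.326, 1.0) == pytest.approx(32.6)

    def test_identity_and_zero(self):
        assert quantify_eif2a_phos(1.7, 1.7) == pytest.approx(100.0)
        assert quantify_eif2a_phos(0.0, 2.0) == 0.0

    @given(v=st.floats(min_value=0, max_value=10), k=st.floats(min_value=0.1, max_value=5))
    @settings(max_examples=50)
    def test_linear_in_variant_signal(self, v, k):
        assert quantify_eif2a_phos(k * v, 1.0) == pytest.approx(k * quantify_eif2a_phos(v, 1.0) if v else 0.0)

    def test_non_positive_wildtype_rejected(self):
        with pytest.raises(AssayError):
            quantify_eif2a_phos(0.5, 0.0)


class TestRescue:
    def test_hypomorph_like_arms_rescued(self):
        m = ReporterMeasurement((100, 108, 96), (420, 390, 405), treatment="gcn2ib")
        assert call_rescue(m) == "rescued"

    def test_identical_arms_not_rescued(self):
        m = ReporterMeasurement((100, 100, 100), (100, 100, 100), treatment="gcn2ib")
        assert call_rescue(m) == "not-rescued"

    def test_fixture_control_not_rescued(self, tested_panels):
        assert tested_panels["K619R"].rescue_gcn2ib == "not-rescued"
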