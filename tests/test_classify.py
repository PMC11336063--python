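"""The five-way decision tree and its truth-table equivalence."""

import itertools

import pytest

from gcn2triage.assays import AssayPanel, ExpressionSummary
from gcn2triage.classify import (
    ClassificationError,
    classify_cohort,
    classify_variant,
    predict_rescuable,
)


def make_panel(induction, reduced, severe, autophos, eif2a, context):
    return AssayPanel(
        induction=induction,
        expression=ExpressionSummary(
            ratio_vs_wt=0.1 if severe else (0.5 if reduced else 1.0),
            significantly_reduced=reduced,
            severe=severe,
        ),
        autophos_t899=autophos,
        eif2a_phos_pct=eif2a,
        context_null_second_allele=context,
    )


def truth_table(induction, reduced, severe, autophos, eif2a, context):
    """Independent statement of the classification scheme, written as a
    flat truth table rather than the ordered rule cascade."""
    if induction == "yes" and reduced and context:
        return "Destabilised"
    if induction == "yes":
        return "Benign"
    if severe:
        return "Misfolded"
    if autophos == "no":
        return "Kinase-dead"
    if eif2a is not None and eif2a >= 5.0:
        return "Hypomorphic"
    if eif2a is not None:
        return "Kinase-dead"
    return None  # unreachable without the in-vitro kinase readout


def full_grid():
    for induction, autophos, context in itertools.product(("yes", "no"), ("yes", "no"), (False, True)):
        for reduced, severe in ((False, False), (True, False), (True, True)):
            for eif2a in (None, 0.0, 4.9, 5.0, 32.6, 120.0):
                yield induction, reduced, severe, autophos, eif2a, context


class TestDecisionTree:
    def test_equivalent_to_truth_table_over_full_grid(self):
        """Brute-force enumeration of the discretised input grid."""
        checked = 0
        for args in full_grid():
            expected = truth_table(*args)
            panel = make_panel(*args)
            if expected is None:
                with pytest.raises(ClassificationError, match="eif2a_phos_pct"):
                    classify_variant(panel)
            else:
                assert classify_variant(panel).functional_class == expected, args
            checked += 1
        assert checked == 144

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("R585Q", "Hypomorphic"),   # no induction, preserved expression, weak in-vitro activity
            ("A870V", "Kinase-dead"),   # no induction, no autophosphorylation
            ("R989W", "Misfolded"),     # severe expression loss dominates
            ("Y34C", "Destabilised"),   # ISR-competent, reduced, null second allele
            ("H1202Y", "Benign"),       # ISR-competent, reduced, classical PAH context
            ("H1202L", "Misfolded"),    # autophos-competent but barely expressed
        ],
    )
    def test_reference_panels(self, tested_panels, name, expected):
        assert classify_variant(tested_panels[name]).functional_class == expected

    def test_trace_is_deterministic_and_nonempty(self, tested_panels):
        a = classify_variant(tested_panels["R585Q"])
        b = classify_variant(tested_panels["R585Q"])
        assert a == b
        assert a.rule_path and a.rule_path[0] == "induction-lost"
        assert a.inputs_used["eif2a_phos_pct"] == 32.6

    def test_missing_required_field_names_field_and_rule(self):
        panel = make_panel("no", False, False, "yes", None, False)
        with pytest.raises(ClassificationError, match="eif2a_phos_pct.*autophosphorylation-competent"):
            classify_variant(panel)


class TestCohort:
    def test_fixture_reproduces_published_classification(self, catalog, tested_panels):
        table = classify_cohort(tested_panels)
        printed = {e.name: e.classification_printed for e in catalog.assayed}
        assert len(table) == 17
        for row in table.itertuples():
            assert row.functional_class == printed[row.variant], row.variant
        counts = table["functional_class"].value_counts()
        assert counts["Hypomorphic"] == 4
        assert counts["Kinase-dead"] == 4  # includes the engineered control

    def test_order_independence(self, tested_panels):
        forward = classify_cohort(tested_panels)
        backward = classify_cohort(dict(reversed(list(tested_panels.items()))))
        merged = forward.set_index("variant")["functional_class"]
        assert all(backward.set_index("variant")["functional_class"] == merged[backward["variant"]].values)

    def test_empty_cohort(self):
        table = classify_cohort({})
        assert len(table) == 0 and "functional_class" in table.columns

    def test_errors_collected_not_raised(self):
        panels = {
            "OK": make_panel("yes", False, False, "yes", None, False),
            "BAD": make_panel("no", False, False, "yes", None, False),
        }
        table = classify_cohort(panels).set_index("variant")
        assert table.loc["OK", "functional_class"] == "Benign"
        assert table.loc["BAD", "functional_class"] is None
        assert "eif2a_phos_pct" in table.loc["BAD", "error"]

    def test_benign_variants_all_autophosphorylate(self, catalog, tested_panels):
        """Autophosphorylation is necessary (not sufficient) for function."""
        table = classify_cohort(tested_panels).set_index("variant")
        for name, panel in tested_panels.items():
            if table.loc[name, "functional_class"] == "Benign":
                assert panel.autophos_t899 == "yes"


class TestRescue:
    def test_only_hypomorphs_predicted_rescuable(self):
        assert predict_rescuable("Hypomorphic")
        for cls in ("Benign", "Destabilised", "Misfolded", "Kinase-dead"):
            assert not predict_rescuable(cls)
        with pytest.raises(ClassificationError):
            predict_rescuable("Gain-of-function")

    def test_predictions_match_observed_drug_response(self, catalog, tested_panels):
        """Seven variants were tested with the inhibitor: the four
        hypomorphs were rescued, the other three were not."""
        table = classify_cohort(tested_panels).set_index("variant")
        observed = {
            name: panel.rescue_gcn2ib
            for name, panel in tested_panels.items()
            if panel.rescue_gcn2ib != "untested"
        }
        assert len(observed) == 7
        assert sum(v == "rescued" for v in observed.values()) == 4
        for name, outcome in observed.items():
            predicted = predict_rescuable(table.loc[name, "functional_class"])
            assert predicted == (outcome == "rescued"), name
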