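"""Predictor benchmarking: gold standards, confusion counts, metrics."""

import pandas as pd
import pytest

from gcn2triage.benchmark import (
    BenchmarkError,
    ConfusionSummary,
    GoldStandard,
    benchmark_panel,
    evaluate_tool,
    gold_from_catalog,
    make_gold,
)
from gcn2triage.insilico import PredictionCall, binarise_predictor


class TestMakeGold:
    def test_modes_disagree_exactly_at_isr_competent_deficient_variants(self, catalog):
        isr = gold_from_catalog(catalog, "isr_reporter")
        final = gold_from_catalog(catalog, "final_class")
        assert set(isr.labels) == set(final.labels) and len(isr.labels) == 16
        differing = {v for v in isr.labels if isr.labels[v] != final.labels[v]}
        assert differing == {"Y34C"}  # reporter-competent but destabilised
        assert isr.labels["Y34C"] == "functional"
        assert final.labels["Y34C"] == "deficient"

    def test_all_benign_input_is_all_functional(self):
        table = pd.DataFrame(
            {"variant": ["A", "B"], "induction": ["yes", "yes"], "functional_class": ["Benign", "Benign"]}
        )
        for mode in ("isr_reporter", "final_class"):
            assert set(make_gold(table, mode).labels.values()) == {"functional"}

    def test_unknown_mode_and_missing_columns_rejected(self):
        table = pd.DataFrame({"variant": ["A"], "induction": ["yes"], "functional_class": ["Benign"]})
        with pytest.raises(BenchmarkError):
            make_gold(table, "clinvar")
        with pytest.raises(BenchmarkError, match="missing columns"):
            make_gold(table.drop(columns=["induction"]), "isr_reporter")


def brute_force_counts(calls, gold, policy="exclude"):
    tp = fp = tn = fn = excluded = 0
    for v, label in gold.labels.items():
        call = calls[v].call
        if call == "ambiguous" and policy == "exclude":
            excluded += 1
        elif label == "deficient":
            if call == "pathogenic":
                tp += 1
            else:
                fn += 1
        else:
            if call == "pathogenic" or call == "ambiguous":
                fp += 1
            else:
                tn += 1
    return tp, fp, tn, fn, excluded


class TestEvaluate:
    @pytest.mark.parametrize("tool", ["sift", "polyphen2", "cadd", "revel", "alphamissense", "foldx"])
    @pytest.mark.parametrize("mode", ["isr_reporter", "final_class"])
    def test_counts_agree_with_brute_force_recount(self, catalog, tool, mode):
        gold = gold_from_catalog(catalog, mode)
        calls = {e.name: binarise_predictor(tool, e.profile.score(tool)) for e in catalog.tested}
        summary = evaluate_tool(calls, gold)
        assert (summary.tp, summary.fp, summary.tn, summary.fn, summary.n_excluded) == \
            brute_force_counts(calls, gold)
        # conservation of n
        assert summary.n_evaluated + summary.n_excluded == len(gold.labels)
        assert summary.errors == summary.fp + summary.fn

    def test_perfect_calls_give_perfect_metrics(self):
        gold = GoldStandard("isr_reporter", {"A": "deficient", "B": "functional"})
        calls = {"A": PredictionCall("revel", "pathogenic", (0.5,)),
                 "B": PredictionCall("revel", "benign", (0.5,))}
        summary = evaluate_tool(calls, gold)
        assert summary.accuracy == 1.0 and summary.errors == 0

    def test_polarity_swap_exchanges_sensitivity_specificity_and_ppv_npv(self, catalog):
        gold = gold_from_catalog(catalog, "isr_reporter")
        flipped = GoldStandard(
            gold.mode,
            {v: ("functional" if l == "deficient" else "deficient") for v, l in gold.labels.items()},
        )
        calls = {
            e.name: PredictionCall(
                "revel",
                "benign" if binarise_predictor("revel", e.profile.revel).call == "pathogenic" else "pathogenic",
                (0.5,),
            )
            for e in catalog.tested
        }
        straight = evaluate_tool(
            {e.name: binarise_predictor("revel", e.profile.revel) for e in catalog.tested}, gold
        )
        swapped = evaluate_tool(calls, flipped)
        assert swapped.sensitivity == straight.specificity
        assert swapped.specificity == straight.sensitivity
        assert swapped.ppv == straight.npv
        assert swapped.npv == straight.ppv

    def test_strict_policy_counts_ambiguous_as_errors(self, catalog):
        gold = gold_from_catalog(catalog, "isr_reporter")
        calls = {e.name: binarise_predictor("alphamissense", e.profile.alphamissense)
                 for e in catalog.tested}
        excl = evaluate_tool(calls, gold, "exclude")
        strict = evaluate_tool(calls, gold, "strict")
        assert excl.n_excluded == 1 and strict.n_excluded == 0
        assert strict.errors == excl.errors + 1

    def test_coverage_gap_rejected(self, catalog):
        gold = gold_from_catalog(catalog, "isr_reporter")
        calls = {e.name: binarise_predictor("revel", e.profile.revel) for e in catalog.tested}
        calls.pop("Y34C")
        with pytest.raises(BenchmarkError, match="Y34C"):
            evaluate_tool(calls, gold)


class TestPanel:
    def test_report_shape_six_tools_times_modes(self, catalog):
        table = benchmark_panel(catalog)
        assert len(table) == 12
        assert set(table["tool"]) == {"sift", "polyphen2", "cadd", "revel", "alphamissense", "foldx"}

    def test_headline_numbers(self, catalog):
        """The reported benchmark figures: integrative tools miss deficient
        GCN2 variants that the reporter assay catches."""
        table = benchmark_panel(catalog).set_index(["tool", "gold_mode"])
        assert table.loc[("polyphen2", "isr_reporter"), "errors"] == 5
        assert table.loc[("cadd", "isr_reporter"), "errors"] == 6
        assert table.loc[("revel", "isr_reporter"), "accuracy"] == pytest.approx(0.75)
        assert table.loc[("alphamissense", "isr_reporter"), "errors"] == 3
        assert table.loc[("alphamissense", "isr_reporter"), "n_excluded"] == 1
        # positive predictive value of the integrative tools is near 60%
        assert table.loc[("polyphen2", "isr_reporter"), "ppv"] == pytest.approx(10 / 15)
        assert table.loc[("cadd", "isr_reporter"), "ppv"] == pytest.approx(10 / 16)
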