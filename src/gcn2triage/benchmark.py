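"""Benchmarking computational predictors against the experimental calls.

The experimental gold standard comes in two flavours:

* ``isr_reporter`` — a variant is *functional* iff the ATF4::NanoLuc ISR
  reporter is induced by stress (the cell-based readout);
* ``final_class`` — a variant is *functional* iff its five-way functional
  classification is Benign (so an ISR-competent but destabilised variant
  counts as deficient).

The two modes differ only at variants where reporter induction and the
final class disagree (in the packaged panel: Y34C).  "Deficient" is the
positive class throughout, matching the clinical question (detecting loss
of kinase function).  An "error" is any variant whose binarised call
disagrees with the gold label; ambiguous AlphaMissense calls are excluded
from evaluation by default, or counted as errors under the ``strict``
policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds
from .insilico import TOOLS, PredictionCall, binarise_predictor

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .catalog import Catalog

__all__ = [
    "GOLD_MODES",
    "BenchmarkError",
    "GoldStandard",
    "ConfusionSummary",
    "make_gold",
    "gold_from_catalog",
    "evaluate_tool",
    "benchmark_panel",
]

GOLD_MODES = ("isr_reporter", "final_class")


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class GoldStandard:
    """Binary experimental labels (functional / deficient) for the tested
    natural variants, under one gold mode."""

    mode: str
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.mode not in GOLD_MODES:
            raise BenchmarkError(f"unknown gold mode {self.mode!r}")
        bad = {v for v in self.labels.values()} - {"functional", "deficient"}
        if bad:
            raise BenchmarkError(f"bad gold labels: {sorted(bad)}")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts and derived metrics for one tool vs one gold.

    Positive = deficient/pathogenic.  Ambiguous calls sit in
    ``n_excluded`` (policy ``exclude``) so ``tp+fp+tn+fn+n_excluded``
    equals the number of gold variants.
    """

    tool: str
    gold_mode: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_excluded) < 0:
            raise BenchmarkError("confusion counts must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        """Variants whose call disagrees with gold (fp + fn)."""
        return self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_evaluated if self.n_evaluated else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def to_dict(self) -> dict:
        return {
            "tool": self.tool,
            "gold_mode": self.gold_mode,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "errors": self.errors,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def make_gold(classifications: pd.DataFrame, mode: str) -> GoldStandard:
    """Build a gold standard from a classification table.

    ``classifications`` needs columns ``variant``, ``induction`` and
    ``functional_class`` covering the tested natural variants (the
    engineered control must already be excluded).
    """
    if mode not in GOLD_MODES:
        raise BenchmarkError(f"unknown gold mode {mode!r}")
    required = {"variant", "induction", "functional_class"}
    missing = required - set(classifications.columns)
    if missing:
        raise BenchmarkError(f"classification table missing columns: {sorted(missing)}")
    labels = {}
    for _, row in classifications.iterrows():
        if mode == "isr_reporter":
            functional = row["induction"] == "yes"
        else:
            functional = row["functional_class"] == "Benign"
        labels[row["variant"]] = "functional" if functional else "deficient"
    return GoldStandard(mode=mode, labels=labels)


def gold_from_catalog(
    catalog: "Catalog", mode: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> GoldStandard:
    """Gold standard over the catalog's tested natural variants, with the
    final class recomputed through the decision tree."""
    from .classify import classify_variant

    rows = [
        {
            "variant": e.name,
            "induction": e.panel.induction,
            "functional_class": classify_variant(e.panel, thresholds).functional_class,
        }
        for e in catalog.tested
    ]
    if not rows:
        raise BenchmarkError("catalog has no tested natural variants")
    return make_gold(pd.DataFrame(rows), mode)


def evaluate_tool(
    calls: Mapping[str, PredictionCall],
    gold: GoldStandard,
    ambiguous_policy: str = "exclude",
) -> ConfusionSummary:
    """Score one tool's binarised calls against a gold standard."""
    if ambiguous_policy not in {"exclude", "strict"}:
        raise BenchmarkError(f"unknown ambiguous policy {ambiguous_policy!r}")
    missing = set(gold.labels) - set(calls)
    if missing:
        raise BenchmarkError(f"calls missing for gold variants: {sorted(missing)}")
    tools = {c.tool for c in calls.values()}
    if len(tools) > 1:
        raise BenchmarkError(f"calls mix tools: {sorted(tools)}")
    tp = fp = tn = fn = excluded = 0
    for variant, label in gold.labels.items():
        call = calls[variant].call
        if call == "ambiguous":
            if ambiguous_policy == "exclude":
                excluded += 1
                continue
            # strict: an ambiguous call can never match the gold label
            call = "pathogenic" if label == "functional" else "benign"
        deficient = label == "deficient"
        pathogenic = call == "pathogenic"
        if pathogenic and deficient:
            tp += 1
        elif pathogenic and not deficient:
            fp += 1
        elif not pathogenic and deficient:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(
        tool=tools.pop(), gold_mode=gold.mode, tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=excluded
    )


def benchmark_panel(
    catalog: "Catalog",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    modes: tuple[str, ...] = GOLD_MODES,
    ambiguous_policy: str = "exclude",
) -> pd.DataFrame:
    """Score every predictor against every requested gold mode.

    Returns one row per tool per gold mode (6 tools x modes) with the
    confusion counts and the derived metrics.
    """
    rows = []
    for mode in modes:
        gold = gold_from_catalog(catalog, mode, thresholds)
        for tool in TOOLS:
            calls = {
                e.name: binarise_predictor(tool, e.profile.score(tool), thresholds)
                for e in catalog.tested
            }
            rows.append(evaluate_tool(calls, gold, ambiguous_policy).to_dict())
    return pd.DataFrame(rows)
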