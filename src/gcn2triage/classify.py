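"""Five-way functional classification of GCN2 variants.

The classifier is an ordered decision tree over the assay panel:

1. ISR reporter induction preserved -> **Benign**, except **Destabilised**
   when expression is significantly reduced *and* the patient carries a
   null second allele (the clinical-context flag).  The context flag is an
   explicit input because expression alone cannot separate an
   ISR-competent but under-expressed variant found with a high-impact
   second allele from one found in classical PAH.
2. No induction, severe expression loss -> **Misfolded** (abundance
   dominates: a weakly autophosphorylation-competent but barely expressed
   variant is still misfolded).
3. No induction, no T899 autophosphorylation -> **Kinase-dead**.
4. No induction, autophosphorylation present, in-vitro eIF2a-S51
   phosphorylation at or above the detection floor -> **Hypomorphic**
   (target engagement preserved but cellular signalling insufficient).
5. Autophosphorylation present but substrate phosphorylation below the
   floor -> **Kinase-dead**.

Only hypomorphic variants are predicted rescuable by the ATP-competitive
type-1 1/2 inhibitor Gcn2iB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .assays import AssayPanel
from .config import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "FUNCTIONAL_CLASSES",
    "ClassificationError",
    "ClassificationTrace",
    "classify_variant",
    "classify_cohort",
    "predict_rescuable",
]

FUNCTIONAL_CLASSES = ("Benign", "Destabilised", "Misfolded", "Kinase-dead", "Hypomorphic")

#: Rescue by Gcn2iB is expected for hypomorphs only.
_RESCUABLE = {"Hypomorphic"}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationTrace:
    """A classification together with the ordered rule path that fired and
    the panel fields each rule consulted."""

    functional_class: str
    rule_path: tuple[str, ...]
    inputs_used: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ClassificationError(f"unknown class {self.functional_class!r}")
        if not self.rule_path:
            raise ClassificationError("rule path must be non-empty")


def classify_variant(panel: AssayPanel, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> ClassificationTrace:
    """Classify one assay panel; returns the class plus its rule trace."""
    used: dict[str, object] = {"induction": panel.induction}
    path: list[str] = []

    if panel.induction == "yes":
        path.append("induction-preserved")
        used["expression_reduced"] = panel.expression.significantly_reduced
        used["context_null_second_allele"] = panel.context_null_second_allele
        if panel.expression.significantly_reduced and panel.context_null_second_allele:
            path.append("reduced-with-null-second-allele")
            return ClassificationTrace("Destabilised", tuple(path), used)
        path.append("isr-competent")
        return ClassificationTrace("Benign", tuple(path), used)

    path.append("induction-lost")
    used["expression_severe"] = panel.expression.severe
    if panel.expression.severe:
        path.append("severe-expression-loss")
        return ClassificationTrace("Misfolded", tuple(path), used)

    used["autophos_t899"] = panel.autophos_t899
    if panel.autophos_t899 == "no":
        path.append("no-autophosphorylation")
        return ClassificationTrace("Kinase-dead", tuple(path), used)

    path.append("autophosphorylation-competent")
    if panel.eif2a_phos_pct is None:
        raise ClassificationError(
            "eif2a_phos_pct is required to separate hypomorphic from kinase-dead "
            "(rule: autophosphorylation-competent, induction lost, expression preserved)"
        )
    used["eif2a_phos_pct"] = panel.eif2a_phos_pct
    if panel.eif2a_phos_pct >= thresholds.eif2a_floor:
        path.append("substrate-engagement-preserved")
        return ClassificationTrace("Hypomorphic", tuple(path), used)
    path.append("substrate-engagement-absent")
    return ClassificationTrace("Kinase-dead", tuple(path), used)


def classify_cohort(
    panels: Mapping[str, AssayPanel],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify a keyed collection of panels.

    Per-variant errors are collected, not fail-fast: failed rows carry the
    error message and a null class.  Returns one row per variant with the
    class, the rule path and a rescue prediction, in input order.
    """
    rows = []
    for name, panel in panels.items():
        try:
            trace = classify_variant(panel, thresholds)
            rows.append(
                {
                    "variant": name,
                    "functional_class": trace.functional_class,
                    "rule_path": ";".join(trace.rule_path),
                    "rescuable": predict_rescuable(trace.functional_class),
                    "error": None,
                }
            )
        except (ClassificationError, ValueError) as err:
            rows.append(
                {
                    "variant": name,
                    "functional_class": None,
                    "rule_path": None,
                    "rescuable": None,
                    "error": str(err),
                }
            )
    columns = ["variant", "functional_class", "rule_path", "rescuable", "error"]
    return pd.DataFrame(rows, columns=columns)


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Summary counts by functional class for a classification table."""
    counts = table["functional_class"].value_counts()
    return {c: int(counts.get(c, 0)) for c in FUNCTIONAL_CLASSES}


def predict_rescuable(functional_class: str) -> bool:
    """True iff the class is expected to respond to Gcn2iB (hypomorphs)."""
    if functional_class not in FUNCTIONAL_CLASSES:
        raise ClassificationError(f"unknown class {functional_class!r}")
    return functional_class in _RESCUABLE
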