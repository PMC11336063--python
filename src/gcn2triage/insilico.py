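"""In-silico predictor panel: binarisation and the integrative prediction.

Six computational predictors are consumed as scores (the tools themselves
are never run here): SIFT (tolerated / not-tolerated call), PolyPhen2,
CADD (PHRED), REVEL, AlphaMissense and FoldX folding free-energy change
(ddG, kcal/mol).  Each is binarised against configurable thresholds;
AlphaMissense alone has a two-threshold band and may return ``ambiguous``.

``integrative_predict`` reconstructs a deterministic version of the
catalog's integrative functional prediction (Benign / Misfolded /
Kinase-deficient / Uncertain).  The printed column is expert-curated and
not fully reproducible by any single threshold rule; per-variant agreement
is therefore measured and reported (``compare_integrative``), never
asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .catalog import Catalog, DomainLabel

__all__ = [
    "SEQUENCE_TOOLS",
    "TOOLS",
    "PredictorProfile",
    "PredictionCall",
    "InSilicoError",
    "binarise_predictor",
    "stability_call",
    "integrative_predict",
    "compare_integrative",
]

#: Sequence/conservation-based tools (everything but FoldX).
SEQUENCE_TOOLS = ("sift", "polyphen2", "cadd", "revel", "alphamissense")
TOOLS = SEQUENCE_TOOLS + ("foldx",)


class InSilicoError(ValueError):
    pass


@dataclass(frozen=True)
class PredictorProfile:
    """The six in-silico scores for one variant."""

    sift_call: str  # "T" tolerated / "NT" not tolerated
    polyphen2: float
    cadd_phred: float
    revel: float
    alphamissense: float
    foldx_ddg: float

    def __post_init__(self) -> None:
        if self.sift_call not in {"T", "NT"}:
            raise InSilicoError(f"SIFT call must be T or NT, got {self.sift_call!r}")
        for tool, score in (("polyphen2", self.polyphen2), ("revel", self.revel),
                            ("alphamissense", self.alphamissense)):
            if not 0.0 <= score <= 1.0:
                raise InSilicoError(f"{tool} score {score} outside [0, 1]")
        if self.cadd_phred < 0:
            raise InSilicoError(f"CADD score {self.cadd_phred} must be non-negative")
        if not math.isfinite(self.foldx_ddg):
            raise InSilicoError("FoldX ddG must be finite")

    def score(self, tool: str):
        return {
            "sift": self.sift_call,
            "polyphen2": self.polyphen2,
            "cadd": self.cadd_phred,
            "revel": self.revel,
            "alphamissense": self.alphamissense,
            "foldx": self.foldx_ddg,
        }[tool]


@dataclass(frozen=True)
class PredictionCall:
    """One tool's binarised verdict for one variant."""

    tool: str
    call: str  # pathogenic / benign / ambiguous
    threshold_used: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.call == "ambiguous" and self.tool != "alphamissense":
            raise InSilicoError(f"{self.tool} cannot return an ambiguous call")


def binarise_predictor(tool: str, score, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> PredictionCall:
    """Binarise one predictor score into pathogenic/benign (or ambiguous).

    The pathogenic side is ``>=`` the cutoff for the score-based tools;
    FoldX uses the strictly-greater destabilisation cutoff.  AlphaMissense
    uses its two-threshold band and is the only tool that may return
    ``ambiguous``.
    """
    if tool == "sift":
        if score not in {"T", "NT"}:
            raise InSilicoError(f"SIFT score must be T or NT, got {score!r}")
        return PredictionCall("sift", "pathogenic" if score == "NT" else "benign", ())
    if tool not in TOOLS:
        raise InSilicoError(f"unknown predictor {tool!r}")
    score = float(score)
    if not math.isfinite(score):
        raise InSilicoError(f"{tool} score must be finite")
    if tool in {"polyphen2", "revel", "alphamissense"} and not 0 <= score <= 1:
        raise InSilicoError(f"{tool} score {score} outside [0, 1]")
    if tool == "cadd" and score < 0:
        raise InSilicoError(f"CADD score {score} must be non-negative")

    if tool == "polyphen2":
        cut = thresholds.polyphen2
    elif tool == "cadd":
        cut = thresholds.cadd
    elif tool == "revel":
        cut = thresholds.revel
    elif tool == "alphamissense":
        hi, lo = thresholds.alphamissense_pathogenic, thresholds.alphamissense_benign
        if score >= hi:
            call = "pathogenic"
        elif score <= lo:
            call = "benign"
        else:
            call = "ambiguous"
        return PredictionCall("alphamissense", call, (lo, hi))
    else:  # foldx
        call = "pathogenic" if stability_call(score, thresholds) == "destabilised" else "benign"
        return PredictionCall("foldx", call, (thresholds.foldx_ddg,))
    return PredictionCall(tool, "pathogenic" if score >= cut else "benign", (cut,))


def stability_call(foldx_ddg: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """``destabilised`` iff ddG strictly exceeds the cutoff (1.5 kcal/mol)."""
    if not math.isfinite(foldx_ddg):
        raise InSilicoError("FoldX ddG must be finite")
    return "destabilised" if foldx_ddg > thresholds.foldx_ddg else "stable"


def profile_calls(profile: PredictorProfile, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> dict[str, PredictionCall]:
    """Binarised calls for every tool in the profile."""
    return {tool: binarise_predictor(tool, profile.score(tool), thresholds) for tool in TOOLS}


def integrative_predict(
    profile: PredictorProfile,
    domain: "DomainLabel | str",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Integrate the six predictors into a four-way functional prediction.

    Rules, evaluated in order:

    1. **Benign** — predicted stable and the benign gate passes
       (``benign_gate``: ``any``/``all`` of REVEL and AlphaMissense on
       the benign side).
    2. **Misfolded** — predicted destabilised (ddG strictly above the
       cutoff) and AlphaMissense is not benign-side.
    3. **Kinase-deficient** — residue in the kinase domain, predicted
       stable, and at least ``kinase_votes`` of the five sequence-based
       tools are pathogenic-side (ambiguous AlphaMissense casts no vote).
    4. **Uncertain** otherwise.
    """
    domain_name = getattr(domain, "name", domain)
    calls = profile_calls(profile, thresholds)
    stable = stability_call(profile.foldx_ddg, thresholds) == "stable"

    modern_benign = [calls["revel"].call == "benign", calls["alphamissense"].call == "benign"]
    gate = any if thresholds.benign_gate == "any" else all
    if thresholds.benign_gate not in {"any", "all"}:
        raise InSilicoError(f"benign_gate must be 'any' or 'all', got {thresholds.benign_gate!r}")
    if stable and gate(modern_benign):
        return "Benign"
    if not stable and calls["alphamissense"].call != "benign":
        return "Misfolded"
    votes = sum(calls[t].call == "pathogenic" for t in SEQUENCE_TOOLS)
    if domain_name == "kinase" and stable and votes >= thresholds.kinase_votes:
        return "Kinase-deficient"
    return "Uncertain"


def compare_integrative(catalog: "Catalog", thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-variant agreement of the default rule with the catalog's printed
    integrative prediction (reported, never asserted: the printed column is
    expert-curated)."""
    rows = []
    for entry in catalog:
        predicted = integrative_predict(entry.profile, entry.record.domain, thresholds)
        rows.append(
            {
                "variant": entry.name,
                "domain": entry.record.domain.name,
                "predicted": predicted,
                "printed": entry.insilico_printed,
                "agree": predicted == entry.insilico_printed,
            }
        )
    return pd.DataFrame(rows)
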