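"""Shared threshold configuration for every pipeline stage.

All decision points of the pipeline are collected in one dataclass so the
CLI, the analysis scripts and the tests share a single source of defaults.
Values are plain numbers/strings and round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["Thresholds", "DEFAULT_THRESHOLDS"]


@dataclass(frozen=True)
class Thresholds:
    """Tunable decision thresholds.

    Predictor binarisation (pathogenic side is ``>=`` except FoldX,
    which is strictly ``>``):

    * ``polyphen2`` — probability-of-damage cutoff, default 0.85
      (PolyPhen2's "possibly/probably damaging" territory).
    * ``cadd`` — PHRED-scaled cutoff, default 20 (top 1% of substitutions).
    * ``revel`` — ensemble-score cutoff, default 0.5.
    * ``alphamissense_pathogenic`` / ``alphamissense_benign`` — the tool's
      published two-threshold band (>=0.564 likely pathogenic, <=0.34
      likely benign, ambiguous between).
    * ``foldx_ddg`` — kcal/mol; strictly above 1.5 is destabilising.

    Assay calling:

    * ``induction_fold`` — minimum treated/untreated reporter fold change
      (relative light units) to call ISR induction, default 2.
    * ``alpha`` — significance level for the per-variant Welch contrasts
      on log-transformed replicates, default 0.05.
    * ``severe_expression`` — actin-normalised expression ratio below
      which a significantly reduced variant is "severe" (misfolded-by-
      abundance territory), default 0.13: strictly between the highest
      misfolded-class ratio (0.12) and the lowest ratio of any other
      class (0.14) in the packaged panel.
    * ``autophos_fold`` — stressed/basal pT899 ratio required to call
      autophosphorylation, default 2.
    * ``autophos_floor`` — minimum stressed pT899/total-GCN2 signal,
      default 0.05 (densitometry detection floor).

    Classification:

    * ``eif2a_floor`` — percent of wild-type eIF2a-S51 phosphorylation
      below which in-vitro substrate engagement is treated as absent,
      default 5 (below the smallest printed positive value, 12.9).
    * ``benign_gate`` — whether the integrative in-silico Benign call
      requires ``any`` or ``all`` of REVEL/AlphaMissense on the benign
      side, default ``any``.
    * ``kinase_votes`` — pathogenic votes (of the five sequence-based
      tools) required for the integrative Kinase-deficient call, default 3.
    """

    polyphen2: float = 0.85
    cadd: float = 20.0
    revel: float = 0.5
    alphamissense_pathogenic: float = 0.564
    alphamissense_benign: float = 0.34
    foldx_ddg: float = 1.5

    induction_fold: float = 2.0
    alpha: float = 0.05
    severe_expression: float = 0.13
    autophos_fold: float = 2.0
    autophos_floor: float = 0.05

    eif2a_floor: float = 5.0
    benign_gate: str = "any"
    kinase_votes: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return replace(cls(), **data)


DEFAULT_THRESHOLDS = Thresholds()
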