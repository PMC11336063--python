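"""Functional-assay calling: replicate measurements to categorical readouts.

Four cell-biological readouts feed the functional classification of a GCN2
variant:

* **ISR reporter induction** — ATF4-5'UTR::NanoLuc luminescence (relative
  light units, RLU) without vs with a stressor (histidinol or amino-acid
  starvation).  Induction is called when the mean fold change reaches the
  configured threshold *and* a one-sided Welch test on log-RLU rejects.
* **Expression level** — actin-normalised immunoblot densitometry relative
  to wild-type GCN2 (wild type = 1).  A one-sided contrast flags
  significantly reduced expression; ratios below the severe threshold mark
  misfolded-by-abundance variants.
* **T899 autophosphorylation** — stress-induced activation-loop
  self-phosphorylation, normalised to total GCN2 signal.
* **eIF2a-S51 phosphorylation** — in-vitro kinase activity on the eIF2a
  N-terminal domain substrate, as percent of the wild-type signal.

Replicate arms with zero variance (the synthetic generator's zero-noise
limit) degenerate to exact mean comparison, since a t statistic is then
undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "AssayError",
    "ReporterMeasurement",
    "ExpressionSummary",
    "AssayPanel",
    "call_induction",
    "quantify_expression",
    "quantify_expression_panel",
    "call_autophos",
    "quantify_eif2a_phos",
    "call_rescue",
]


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class ReporterMeasurement:
    """Replicate reporter luminescence for one variant, two arms."""

    rlu_untreated: tuple[float, ...]
    rlu_treated: tuple[float, ...]
    treatment: str = "histidinol"  # histidinol / starvation / gcn2ib

    def __post_init__(self) -> None:
        for arm, values in (("untreated", self.rlu_untreated), ("treated", self.rlu_treated)):
            if len(values) < 2:
                raise AssayError(f"{arm} arm needs >=2 replicates, got {len(values)}")
            if not all(math.isfinite(v) and v > 0 for v in values):
                raise AssayError(f"{arm} arm RLU values must be finite and positive")


@dataclass(frozen=True)
class ExpressionSummary:
    """Summarised expression of one variant relative to wild type."""

    ratio_vs_wt: float
    significantly_reduced: bool
    severe: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.ratio_vs_wt) or self.ratio_vs_wt < 0:
            raise AssayError(f"expression ratio {self.ratio_vs_wt!r} must be finite and >=0")
        if self.severe and not self.significantly_reduced:
            raise AssayError("severe expression loss implies significantly reduced")


@dataclass(frozen=True)
class AssayPanel:
    """All functional readouts for one variant (one summary-table row)."""

    induction: str  # yes / no
    expression: ExpressionSummary
    autophos_t899: str  # yes / no
    dimerisation: str = "untested"  # yes / no / untested (metadata only)
    eif2a_phos_pct: Optional[float] = None
    rescue_gcn2ib: str = "untested"  # rescued / not-rescued / untested
    context_null_second_allele: bool = False

    def __post_init__(self) -> None:
        if self.induction not in {"yes", "no"}:
            raise AssayError(f"induction must be yes/no, got {self.induction!r}")
        if self.autophos_t899 not in {"yes", "no"}:
            raise AssayError(f"autophos must be yes/no, got {self.autophos_t899!r}")
        if self.dimerisation not in {"yes", "no", "untested"}:
            raise AssayError(f"bad dimerisation value {self.dimerisation!r}")
        if self.rescue_gcn2ib not in {"rescued", "not-rescued", "untested"}:
            raise AssayError(f"bad rescue value {self.rescue_gcn2ib!r}")
        if self.eif2a_phos_pct is not None and (
            not math.isfinite(self.eif2a_phos_pct) or self.eif2a_phos_pct < 0
        ):
            raise AssayError(f"eIF2a phosphorylation percent {self.eif2a_phos_pct!r} must be >=0")


def _one_sided_welch_p(a: Sequence[float], b: Sequence[float], alternative: str) -> float:
    """One-sided Welch p-value for mean(a) vs mean(b) on log-transformed
    values; degenerates to exact mean comparison when both arms are
    constant."""
    la, lb = np.log(np.asarray(a, float)), np.log(np.asarray(b, float))
    # arms constant up to float noise: the t statistic is undefined, so the
    # decision degenerates to exact mean comparison
    tol = 1e-12 * (1 + max(abs(la).max(), abs(lb).max()))
    if np.ptp(la) <= tol and np.ptp(lb) <= tol:
        if alternative == "greater":
            return 0.0 if la.mean() > lb.mean() else 1.0
        return 0.0 if la.mean() < lb.mean() else 1.0
    return float(stats.ttest_ind(la, lb, equal_var=False, alternative=alternative).pvalue)


def call_induction(
    m: ReporterMeasurement,
    fold_threshold: float | None = None,
    alpha: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Call ISR-reporter induction (``yes``/``no``).

    ``yes`` iff mean(treated)/mean(untreated) >= ``fold_threshold`` and the
    one-sided Welch test on log-RLU rejects at ``alpha``.  The call is
    scale-invariant: rescaling every RLU by a positive constant changes
    neither the fold nor the log-domain contrast.
    """
    fold_threshold = thresholds.induction_fold if fold_threshold is None else fold_threshold
    alpha = thresholds.alpha if alpha is None else alpha
    fold = float(np.mean(m.rlu_treated) / np.mean(m.rlu_untreated))
    p = _one_sided_welch_p(m.rlu_treated, m.rlu_untreated, "greater")
    return "yes" if fold >= fold_threshold and p < alpha else "no"


def quantify_expression(
    variant_reps: Sequence[float],
    wt_reps: Sequence[float],
    severe_threshold: float | None = None,
    alpha: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    p_value: float | None = None,
) -> ExpressionSummary:
    """Summarise actin-normalised variant expression against wild type.

    ``ratio = mean(variant)/mean(wt)``; reduction is a one-sided Welch
    contrast on the log replicates at ``alpha`` (pass ``p_value`` to reuse
    a multiplicity-corrected p from :func:`quantify_expression_panel`);
    ``severe`` requires significance plus a ratio below the severe
    threshold.
    """
    severe_threshold = thresholds.severe_expression if severe_threshold is None else severe_threshold
    alpha = thresholds.alpha if alpha is None else alpha
    v = np.asarray(variant_reps, float)
    w = np.asarray(wt_reps, float)
    if len(v) < 2 or len(w) < 2:
        raise AssayError("expression quantification needs >=2 replicates per arm")
    if not (np.isfinite(v).all() and np.isfinite(w).all()) or (v <= 0).any() or (w <= 0).any():
        raise AssayError("densitometry replicates must be finite and positive")
    ratio = float(v.mean() / w.mean())
    if p_value is None:
        p_value = _one_sided_welch_p(v, w, "less")
    reduced = p_value < alpha and ratio < 1
    return ExpressionSummary(
        ratio_vs_wt=ratio,
        significantly_reduced=reduced,
        severe=reduced and ratio < severe_threshold,
    )


def quantify_expression_panel(
    variant_reps: Mapping[str, Sequence[float]],
    wt_reps: Sequence[float],
    severe_threshold: float | None = None,
    alpha: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict[str, ExpressionSummary]:
    """Panel-wide expression calls with Holm correction across variants."""
    alpha = thresholds.alpha if alpha is None else alpha
    names = list(variant_reps)
    raw_p = [_one_sided_welch_p(variant_reps[n], wt_reps, "less") for n in names]
    if names:
        _, corrected, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    else:
        corrected = []
    return {
        n: quantify_expression(
            variant_reps[n], wt_reps, severe_threshold, alpha, thresholds, p_value=float(p)
        )
        for n, p in zip(names, corrected)
    }


def call_autophos(
    basal_signal: float,
    stressed_signal: float,
    total_gcn2: float,
    fold: float | None = None,
    floor: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Call stress-induced T899 autophosphorylation (``yes``/``no``).

    ``yes`` iff the stressed pT899/total-GCN2 signal clears the detection
    floor and exceeds the basal signal by the configured factor.  Weak but
    reproducible induction still counts as ``yes``.
    """
    fold = thresholds.autophos_fold if fold is None else fold
    floor = thresholds.autophos_floor if floor is None else floor
    for name, x in (("basal", basal_signal), ("stressed", stressed_signal), ("total", total_gcn2)):
        if not math.isfinite(x) or x < 0:
            raise AssayError(f"{name} signal must be finite and >=0")
    if total_gcn2 <= 0:
        raise AssayError("total GCN2 signal must be positive")
    stressed = stressed_signal / total_gcn2
    basal = basal_signal / total_gcn2
    return "yes" if stressed > floor and stressed >= fold * basal else "no"


def quantify_eif2a_phos(variant_signal: float, wt_signal: float) -> float:
    """In-vitro eIF2a-S51 phosphorylation as percent of the wild-type
    signal (linear in the variant signal; 100 at identity)."""
    if not math.isfinite(wt_signal) or wt_signal <= 0:
        raise AssayError("wild-type eIF2a-P signal must be positive")
    if not math.isfinite(variant_signal) or variant_signal < 0:
        raise AssayError("variant eIF2a-P signal must be finite and >=0")
    return 100.0 * variant_signal / wt_signal


def call_rescue(
    m: ReporterMeasurement,
    fold_threshold: float | None = None,
    alpha: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Call pharmacological rescue by the type-1 1/2 inhibitor Gcn2iB.

    The decision rule is the induction rule applied to the vehicle vs
    25 nM Gcn2iB reporter arms: ``rescued``/``not-rescued``.
    """
    call = call_induction(m, fold_threshold, alpha, thresholds)
    return "rescued" if call == "yes" else "not-rescued"
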