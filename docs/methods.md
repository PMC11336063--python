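# Methods

## Scope and data model

The pipeline operates on a catalog of GCN2 (EIF2AK4) missense variants.
Each record pairs the printed cDNA and protein notation (1-based coding
and residue coordinates; splice-region entries like `145-2A>G` carry a
signed intron offset and skip the `ceil(pos/3) == residue` codon check),
clinical annotations (diagnosis, ClinVar class, population rarity with
strict cutoffs: rare < 0.01, common > 0.1, intermediate between), the six
predictor scores, and — for the experimental panel — summarised assay
readouts. The engineered kinase-dead control K619R is a first-class
catalog row flagged `control=true` (it has no cDNA notation and no
ClinVar class) so every stage can include or exclude it explicitly.
Domain spans (RWD 20–137, pseudokinase 276–539, kinase 585–1016,
HisRS-like 1058–1490, CTD 1533–1649) are closed intervals; residues
outside them are `interdomain`.

## In-silico panel

Scores are consumed, never computed. Binarisation defaults (all
configurable, `Thresholds`): SIFT not-tolerated → pathogenic-side;
PolyPhen2 ≥ 0.85; CADD ≥ 20; REVEL ≥ 0.5; AlphaMissense two-threshold
band (≥ 0.564 pathogenic, ≤ 0.34 benign, ambiguous between — the only
tool allowed an ambiguous call); FoldX ΔΔG strictly > 1.5 kcal/mol →
destabilised. Pathogenic-side comparisons are `≥` except FoldX's strict
`>`. These are the tools' widely used operating points and the settings
under which the benchmark reproduces the reference figures.

The integrative four-way prediction is an ordered rule:

1. *Benign* if predicted stable and the benign gate passes. The gate
   defaults to **any** of REVEL/AlphaMissense benign-side
   (`benign_gate: any`); requiring both (`all`) is stricter than the
   curated reference column warrants (it calls stable variants with a
   single mildly elevated score Uncertain).
2. *Misfolded* if destabilised **and** AlphaMissense is not benign-side.
   The guard keeps variants that the deep-learning model confidently
   calls benign (e.g. a ΔΔG of 1.68 with AlphaMissense 0.083) out of the
   Misfolded bin.
3. *Kinase-deficient* if the residue lies in the kinase domain, the
   protein is predicted stable, and ≥ 3 of the five sequence-based tools
   vote pathogenic (an ambiguous AlphaMissense call casts no vote).
4. *Uncertain* otherwise.

The reference integrative column is expert-curated and provably not
reproducible by any single threshold rule (it contains pairs with
near-identical profiles and different labels); the default rule agrees
for 28/35 variants and the disagreement list is part of the reported
output, never silently overwritten.

## Assay calling

All replicate contrasts are Welch tests on log-transformed values —
reporter luminescence and densitometry errors are multiplicative — with
one-sided alternatives (induction: treated > untreated; expression:
variant < wild type).

* **ISR induction**: `yes` iff mean fold change ≥ 2 *and* the test
  rejects at α = 0.05. The summary table the classifier consumes does not
  state the criteria behind its yes/no column, so both knobs are config
  keys. The call is scale-invariant by construction.
* **Expression**: ratio of means vs wild type; panel-wide calls apply
  Holm correction across variants (the per-variant operation accepts a
  pre-corrected p). `severe` requires significance plus ratio below the
  severe threshold. The default severe threshold is **0.13**: the
  misfolded-by-abundance variants sit at 0.09–0.12 while the lowest
  ratio of any other class is 0.14, so any cutoff in (0.12, 0.14] gives
  the same partition and 0.13 is the midpoint choice.
* **Autophosphorylation (T899)**: `yes` iff stressed pT899/total-GCN2
  clears a detection floor (0.05) and exceeds basal by ≥ 2-fold. Weak
  but reproducible induction counts as `yes` (the reference panel calls
  weakly autophosphorylating variants "Yes").
* **eIF2α-S51 phosphorylation**: 100 × variant/wild-type signal, defined
  per paired signal (whether the reference percentages were pooled
  across experiments is not stated).
* **Gcn2iB rescue**: the induction rule applied to vehicle vs 25 nM
  drug arms.

Degenerate inputs: when both replicate arms have zero variance (the
synthetic generator's zero-noise limit) the t statistic is undefined and
significance degenerates to exact mean comparison.

## Functional classification

Ordered decision tree over the panel:

1. Induction preserved → **Benign**, except **Destabilised** when
   expression is significantly reduced *and* the patient carries a null
   second allele. The context flag is an explicit input: expression
   alone cannot separate an ISR-competent, under-expressed variant found
   in trans with a high-impact allele (Y34C, ratio 0.21 → Destabilised)
   from one found in classical PAH (H1202Y, ratio 0.14 → Benign). This
   formalisation of the clinical reasoning is the one genuinely open
   design point of the tree and is flagged as such.
2. No induction + severe expression loss → **Misfolded**. The severity
   check precedes autophosphorylation because a barely expressed variant
   is misfolded regardless of residual autophosphorylation (H1202L:
   autophos yes, ratio 0.12, Misfolded).
3. No induction + no autophosphorylation → **Kinase-dead**.
4. No induction + autophosphorylation + in-vitro eIF2α phosphorylation at
   or above the detection floor (default 5%, below the smallest observed
   positive value of 12.9% and above densitometry noise) →
   **Hypomorphic**.
5. Autophosphorylation present but substrate phosphorylation below the
   floor → **Kinase-dead**. No real panel row reaches this branch; its
   assignment extrapolates the scheme to autophosphorylation-competent,
   engagement-free kinases.

Dimerisation is carried as metadata but never consulted: loss of
dimerisation does not explain the non-functional variants (mixed dimers
form even for kinase-domain mutants). Only hypomorphs are predicted
rescuable by Gcn2iB. Every classification returns its fired rule path
and the fields it consulted; cohort classification collects per-variant
errors instead of failing fast.

## Predictor benchmark

Two gold-standard modes, both first-class: `isr_reporter` (functional iff
the reporter is induced) and `final_class` (functional iff classified
Benign). They differ only at variants where the two disagree — in the
packaged panel, Y34C. "Deficient" is the positive class; an *error* is
any disagreement with gold (FP + FN). Ambiguous AlphaMissense calls are
excluded from evaluation by default (policy `strict` counts them as
errors). Counts always conserve: tp+fp+tn+fn+n_excluded equals the number
of gold variants (the 16 tested natural variants; the control is
excluded). The headline figures — PolyPhen2 5 errors, CADD 6 errors
(PPV 66.7% / 62.5%), REVEL 75% accuracy, AlphaMissense 3 of 16 — all
arise under the ISR-reporter gold; under the final-class gold REVEL
scores 81.25%. Reports always state the gold used.

## Synthetic cohorts

The generator emulates the statistical structure of the real panel, not
its biology (no translation, kinase-kinetic or drug-binding mechanism):

* **Scores**: class-conditional distributions whose per-class means and
  variances are fitted from the packaged catalog at run time (Beta by
  moment matching for the [0,1] tools, Bernoulli for the SIFT call,
  Normal for CADD and ΔΔG). Single-member classes get degenerate
  distributions; infeasible Beta moments are clamped to 95% of the
  maximal variance.
* **Assays**: raw replicates around class-typical centres — reporter
  fold ≈ 5 for ISR-competent classes vs ≈ 1 for deficient ones,
  expression ratio ≈ 0.10 for misfolded, ≈ 0.21 for destabilised,
  hypomorph eIF2α ≈ 30% with rescue fold ≈ 4 — with multiplicative
  log-normal noise. Defaults: 4 replicates per arm (matching the real
  panel's n = 4), log-RLU σ = 0.15 and expression CV = 0.15 (typical
  biological-replicate spread for these readouts), flag-flip probability
  0 (applied post-hoc to the categorical autophosphorylation call).
  The null-second-allele context rate for Destabilised truth defaults
  to 1 so the zero-noise cohort is fully identifiable.
* **Streams**: one seed sequence per cohort with a spawned substream per
  variant; adding variants never perturbs earlier draws, and noise draws
  are consumed in a fixed order so sweeps over noise levels see the same
  perturbations scaled rather than resampled (which is what makes the
  degradation curves cleanly monotone with paired seeds).

Recovery analyses classify each synthetic variant from its raw assays
using per-variant significance (no Holm across the cohort: synthetic
cohorts are arbitrarily large and the analyses probe the per-variant
rule; panel-wide correction is exercised on the real-panel workflow).
What passing recovery tests show is that the pipeline inverts its own
generative assumptions — they do not certify performance on real data,
whose noise is not log-normal, whose classes are not balanced and whose
assay centres vary between variants of the same class.

## Problem sizes and determinism

Everything on the real catalog is exact and sub-second (35 rows). The
synthetic analyses use 100 variants for the zero-noise check and 200 per
level for the four-level noise sweep — large enough that the reported
rates are stable to a few percent, small enough to keep the whole suite
in seconds. All randomness flows from explicit integer seeds through
NumPy's PCG64.

## Known limitations

* The integrative in-silico rule is a reconstruction of a curated
  column; 7/35 disagreements are expected output, not a defect.
* The Benign/Destabilised split depends on a clinical-context flag that
  is an input, not an inference.
* Decision-tree branch 5 is unpopulated in the real panel; its
  assignment is an extrapolation.
* The assay-summary fixture stores the published yes/no flags verbatim;
  raw-replicate calling is exercised only through the synthetic module.
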