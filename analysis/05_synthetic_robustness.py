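#!/usr/bin/env python
"""Robustness of the pipeline on synthetic cohorts with known truth.

Generates cohorts whose class-conditional scores and raw assay replicates
mirror the real panel's structure, then measures how well the full
assay-calling + classification pipeline recovers the generator's truth
labels: perfectly at zero noise, degrading monotonically as replicate
noise grows.

Writes results/synthetic_recovery.tsv.
"""

import argparse
from pathlib import Path

from gcn2triage.synthetic import AssayNoise, CohortSpec, generate_cohort, noise_sweep, recovery_rate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n", type=int, default=200)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    zero = CohortSpec(n_variants=100, seed=args.seed,
                      assay_noise=AssayNoise(log_rlu_sd=0.0, expression_cv=0.0))
    rate = recovery_rate(generate_cohort(zero))
    print(f"Zero-noise recovery: {100 * rate:.1f}% over {zero.n_variants} variants.")

    sweep = noise_sweep(args.n, log_rlu_sds=(0.0, 0.2, 0.5, 1.0), seed=args.seed)
    sweep.to_csv(OUT / "synthetic_recovery.tsv", sep="\t", index=False)
    print(f"\nRecovery vs replicate noise (n={args.n} per level, paired seeds):")
    for row in sweep.itertuples():
        print(f"  sigma={row.log_rlu_sd:.1f}  recovery={100 * row.recovery:.1f}%")
    monotone = all(a >= b for a, b in
                   zip(sweep["recovery"], sweep["recovery"][1:]))
    print(f"Monotone degradation: {monotone}")


if __name__ == "__main__":
    main()
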