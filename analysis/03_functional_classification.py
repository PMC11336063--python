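#!/usr/bin/env python
"""Functional classification of the experimental panel.

Runs the five-way decision tree (Benign / Destabilised / Misfolded /
Kinase-dead / Hypomorphic) over the 17 assayed rows and checks every
classification against the published reference column, then compares
the rescue prediction (hypomorphs only) with the observed Gcn2iB
response of the seven drug-tested variants.

Writes results/classification.tsv.
"""

from pathlib import Path

from gcn2triage import classify_cohort, load_catalog, predict_rescuable
from gcn2triage.classify import class_counts

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    catalog = load_catalog()
    panels = {e.name: e.panel for e in catalog.assayed}
    table = classify_cohort(panels)
    table.to_csv(OUT / "classification.tsv", sep="\t", index=False)

    printed = {e.name: e.classification_printed for e in catalog.assayed}
    concordant = sum(
        row.functional_class == printed[row.variant] for row in table.itertuples()
    )
    print(f"Classification concordant with the reference for {concordant}/17 rows.")
    print("Class counts:", class_counts(table))

    indexed = table.set_index("variant")
    drug = {n: p.rescue_gcn2ib for n, p in panels.items() if p.rescue_gcn2ib != "untested"}
    print(f"\nGcn2iB response observed for {len(drug)} variants:")
    for name, outcome in sorted(drug.items()):
        predicted = predict_rescuable(indexed.loc[name, "functional_class"])
        ok = "OK" if predicted == (outcome == "rescued") else "MISS"
        print(f"  {name:8s} predicted {'rescuable' if predicted else 'refractory':10s} "
              f"observed {outcome:12s} [{ok}]")


if __name__ == "__main__":
    main()
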