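#!/usr/bin/env python
"""Catalog overview: what is known about the published GCN2 variants.

Loads the packaged catalog of 34 PAH-associated EIF2AK4 missense variants
(plus the engineered K619R kinase-dead control), annotates each with its
protein domain, and summarises ClinVar status, population rarity and
membership of the 16-variant experimental panel.

Writes results/catalog_annotated.tsv and results/catalog_summary.tsv.
"""

import json
from pathlib import Path

from gcn2triage import load_catalog

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    catalog = load_catalog()
    frame = catalog.to_frame()
    frame.to_csv(OUT / "catalog_annotated.tsv", sep="\t", index=False)

    summary = catalog.summary()
    print("Catalog:", json.dumps(summary, indent=2))
    by_domain = frame[~frame["control"]].groupby("domain")["variant"].count()
    print("\nNatural variants per domain:")
    print(by_domain.to_string())
    by_domain.rename("n_variants").to_frame().to_csv(OUT / "catalog_summary.tsv", sep="\t")

    print(
        f"\n{summary['n_natural']} natural missense variants: "
        f"{summary['n_pathogenic']} pathogenic/likely-pathogenic, "
        f"{summary['n_benign']} benign/likely-benign, {summary['n_vus']} VUS; "
        f"{summary['n_common']} common polymorphisms; "
        f"{summary['n_tested']} in the experimental panel."
    )


if __name__ == "__main__":
    main()
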