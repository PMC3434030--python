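#!/usr/bin/env python
"""Category overrepresentation of the among-strain DE list (EASE score).

Builds a synthetic annotation (40 categories over the array, one of them
deliberately concentrated in the planted strain-DE genes so the screen
has a positive control), then scores each category against the expressed
background with the EASE-adjusted one-tailed Fisher test.  Writes
results/enrichment/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strainarray.enrichment import run_enrichment
from strainarray.io import AnnotationTable, write_result_table

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20120720


def synthetic_annotation(background, de_genes, rng) -> AnnotationTable:
    """40 random categories plus one enriched in the DE list (synthetic
    stand-in for a curated category database)."""
    membership: dict[str, set[str]] = {}
    labels = {}
    bg = list(background)
    for j in range(40):
        cat = f"cat{j:02d}"
        labels[cat] = f"random category {j}"
        for g in rng.choice(bg, size=25, replace=False):
            membership.setdefault(g, set()).add(cat)
    labels["cat_de"] = "planted DE-enriched category"
    de = list(de_genes)
    picks = list(rng.choice(de, size=min(20, len(de)), replace=False))
    picks += list(rng.choice(bg, size=10, replace=False))
    for g in picks:
        membership.setdefault(g, set()).add("cat_de")
    return AnnotationTable(membership=membership, labels=labels)


def main() -> None:
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    background = list(
        pd.read_csv(ROOT / "expression" / "expr_filtered.tsv", sep="\t")["probeset_id"]
    )
    de_strain = pd.read_csv(ROOT / "de" / "de_strain.tsv", sep="\t")
    gene_list = sorted(de_strain.loc[de_strain["significant"], "probeset_id"])
    rng = np.random.default_rng(SEED)
    annotation = synthetic_annotation(background, gene_list, rng)
    result = run_enrichment(gene_list, background, annotation, alpha=0.05)
    write_result_table(result, out / "enrichment.tsv", id_column="category_id",
                       p_column="ease_p")
    n_sig = int(result["overrepresented"].sum())
    print(f"{len(gene_list)} DE genes vs background of {len(background)}")
    print(f"{n_sig} of {len(result)} categories overrepresented at EASE < 0.05")
    top = result.iloc[0]
    print(f"top category: {top['category_id']} ({top['label']}), "
          f"EASE p = {top['ease_p']:.3g}")


if __name__ == "__main__":
    main()
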