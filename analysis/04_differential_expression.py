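#!/usr/bin/env python
"""Moderated differential expression: strain, domestication, sex.

Fits per-probe-set linear models on the filtered, SFP-free expression
matrix with empirical-Bayes variance moderation, tests the among-strain
omnibus F, the wild-vs-domesticated contrast and the sex main effect
(factorial model), applies Benjamini-Hochberg at 5%, computes pairwise
fold changes, and tightens the domestication list with the range-overlap
filter (at most one overlapping sample).  Writes results/de/.
"""

from pathlib import Path

import pandas as pd

from strainarray import diffexpr
from strainarray.io import ExpressionMatrix, load_probe_level_dataset, write_result_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_probe_level_dataset(
        ROOT / "synthetic" / "pm.tsv",
        ROOT / "synthetic" / "mm.tsv",
        ROOT / "synthetic" / "samples.tsv",
    )
    expr_df = pd.read_csv(
        ROOT / "expression" / "expr_filtered.tsv", sep="\t"
    ).set_index("probeset_id")
    flagged = pd.read_csv(ROOT / "sfp" / "flagged.tsv", sep="\t")
    sfp_ids = set(flagged.loc[flagged["flagged"], "probeset_id"])
    analyzed = ExpressionMatrix(expr_df.loc[[i for i in expr_df.index if i not in sfp_ids]])
    print(f"{len(expr_df)} expressed - {len(sfp_ids)} SFP = "
          f"{len(analyzed.probeset_ids)} probe sets analyzed")

    wild = tuple(sorted({s.strain for s in dataset.samples if s.domestication == "wild"}))
    design = diffexpr.make_design(dataset.samples, "strain")
    mfit = diffexpr.moderate_variances(
        diffexpr.fit_gene_linear_models(analyzed, design)
    )
    de_strain = diffexpr.test_contrasts(mfit, "among_strain", wild_strains=wild)
    de_dom = diffexpr.test_contrasts(mfit, "wild_vs_domesticated", wild_strains=wild)
    design_f = diffexpr.make_design(dataset.samples, "strain_sex")
    mfit_f = diffexpr.moderate_variances(
        diffexpr.fit_gene_linear_models(analyzed, design_f)
    )
    de_sex = diffexpr.test_contrasts(mfit_f, "sex", wild_strains=wild)

    strain_groups = {
        st: [s.sample_id for s in dataset.samples if s.strain == st]
        for st in design.strains
    }
    fc_strain = diffexpr.fold_changes(analyzed, strain_groups)
    wild_ids = [s.sample_id for s in dataset.samples if s.domestication == "wild"]
    dom_ids = [s.sample_id for s in dataset.samples if s.domestication == "domesticated"]
    fc_dom = diffexpr.fold_changes(analyzed, {"domesticated": dom_ids, "wild": wild_ids})

    sig_dom = list(de_dom.loc[de_dom["significant"], "probeset_id"])
    dom_final = diffexpr.range_overlap_filter(analyzed, wild_ids, dom_ids, sig_dom)

    write_result_table(de_strain, out / "de_strain.tsv", id_column="probeset_id")
    write_result_table(de_dom, out / "de_domestication.tsv", id_column="probeset_id")
    write_result_table(de_sex, out / "de_sex.tsv", id_column="probeset_id")
    fc_strain.to_csv(out / "fold_changes_strain.tsv", sep="\t", index=False,
                     float_format="%.12g")
    fc_dom.to_csv(out / "fold_changes_domestication.tsv", sep="\t", index=False,
                  float_format="%.12g")
    pd.Series(dom_final, name="probeset_id").to_csv(
        out / "de_domestication_final.tsv", sep="\t", index=False
    )

    n_strain = int(de_strain["significant"].sum())
    fc_map = fc_strain.set_index("probeset_id")["fold_change"]
    sig_strain = de_strain.loc[de_strain["significant"], "probeset_id"]
    n_strain_2fold = int((fc_map.loc[sig_strain] >= 2).sum())
    fc_dom_map = fc_dom.set_index("probeset_id")["fold_change"]
    print(f"among strains: {n_strain} significant at BH 5% "
          f"({n_strain_2fold} with >= 2-fold pairwise difference)")
    print(f"wild vs domesticated: {len(sig_dom)} initial -> {len(dom_final)} after "
          f"range-overlap filter ({int((fc_dom_map.loc[dom_final] >= 2).sum())} >= 2-fold)")
    print(f"sex: {int(de_sex['significant'].sum())} significant")


if __name__ == "__main__":
    main()
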