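#!/usr/bin/env python
"""Behavior scoring + nested ANOVA, and qPCR ANCOVA with Tukey pairs.

Scores each fish's Vertical Depth (mean zone, 1 = surface) and Horizontal
Position (proportion of recordings near the front), fits the
Sex + Domestication + Strain(Domestication) fixed-effects model with
partial sums of squares, and analyzes the qPCR cycle thresholds by
ANCOVA with the reference-gene C_T as covariate, following up the strain
effect with Tukey studentized-range comparisons and compact letters.
Writes results/behavior/.
"""

from pathlib import Path

import pandas as pd

from strainarray.behavior import (
    fixed_effects_anova,
    qpcr_ancova,
    score_behavior,
    tukey_hsd,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "behavior"
    out.mkdir(parents=True, exist_ok=True)
    obs = pd.read_csv(ROOT / "synthetic" / "behavior.tsv", sep="\t")
    scores = score_behavior(obs)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.12g")

    terms = ["sex", "domestication", "strain(domestication)"]
    tables = []
    for response in ("vertical_depth", "horizontal_position"):
        table, diag = fixed_effects_anova(scores, response, terms)
        table.insert(0, "response", response)
        tables.append(table)
        dom = table.loc[table["term"] == "domestication"].iloc[0]
        print(f"{response}: Domestication F = {dom['F']:.2f} "
              f"(df {int(dom['df'])}, {int(table.iloc[-1]['df'])}), p = {dom['p']:.2e}; "
              f"residual skew {diag['residual_skew']:.2f}")
    pd.concat(tables).to_csv(out / "behavior_anova.tsv", sep="\t", index=False,
                             float_format="%.12g")

    qpcr = pd.read_csv(ROOT / "synthetic" / "qpcr.tsv", sep="\t")
    res = qpcr_ancova(qpcr)
    res.table.to_csv(out / "qpcr_ancova.tsv", sep="\t", index=False,
                     float_format="%.12g")
    strain_row = res.table.loc[res.table["term"] == "strain"].iloc[0]
    print(f"qPCR strain F = {strain_row['F']:.2f}, p = {strain_row['p']:.2e}")
    print("covariate-adjusted strain means (C_T):")
    print(res.adjusted_means.round(3).to_string())
    pairs = tukey_hsd(res.adjusted_means.to_dict(), res.mse, res.df_resid,
                      res.group_sizes)
    pairs.to_csv(out / "qpcr_tukey.tsv", sep="\t", index=False,
                 float_format="%.12g")
    letters = pairs.attrs["letters"]
    print("Tukey letters:", " ".join(f"{k}:{v}" for k, v in sorted(letters.items())))


if __name__ == "__main__":
    main()
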