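#!/usr/bin/env python
"""Generate the synthetic study: probe-level arrays, behavior assays, qPCR.

Emulates the 4-strain (2 wild, 2 domesticated) x 2-sex x 2-pool design:
1000 probe sets x 11 PM/MM probe pairs on 16 arrays with planted
strain/domestication/sex expression effects and single-feature
polymorphisms; 64 fish x 30 observation periods x 3 recordings; and one
qPCR target gene with a reference-gene covariate.  Writes the datasets
and their planted truth under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from strainarray.io import write_probe_level_dataset
from strainarray.simulate import (
    SimulationConfig,
    generate_behavior_data,
    generate_probe_level_dataset,
    generate_qpcr_data,
)

SEED = 20120720  # study-wide base seed
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_probesets=1000, seed=SEED)
    dataset, truth = generate_probe_level_dataset(cfg)
    write_probe_level_dataset(dataset, OUT)
    (OUT / "truth").mkdir(exist_ok=True)
    truth.probesets.to_csv(OUT / "truth" / "probesets.tsv", sep="\t", index=False,
                           float_format="%.12g")
    truth.probes.to_csv(OUT / "truth" / "probes.tsv", sep="\t", index=False,
                        float_format="%.12g")

    obs, fish_truth = generate_behavior_data(n_fish_per_strain=16, seed=SEED + 1)
    obs.to_csv(OUT / "behavior.tsv", sep="\t", index=False)
    fish_truth.to_csv(OUT / "truth" / "fish.tsv", sep="\t", index=False,
                      float_format="%.12g")

    qpcr, qpcr_truth = generate_qpcr_data(
        {"Gaighatta": 21.0, "Nadia": 22.0, "SH": 20.0, "TM1": 20.5},
        noise_sd=0.2,
        seed=SEED + 2,
    )
    qpcr.to_csv(OUT / "qpcr.tsv", sep="\t", index=False, float_format="%.12g")
    qpcr_truth.to_csv(OUT / "truth" / "qpcr.tsv", sep="\t", index=False,
                      float_format="%.12g")

    tt = truth.probesets
    print(f"wrote {cfg.n_probesets} probe sets x {cfg.n_samples} samples to {OUT}")
    print(
        f"planted: {(~tt['expressed']).sum()} unexpressed, "
        f"{(tt['de_category'] == 'strain').sum()} strain-DE, "
        f"{(tt['de_category'] == 'domestication').sum()} domestication-DE, "
        f"{(tt['de_category'] == 'sex').sum()} sex-DE, "
        f"{tt['has_sfp'].sum()} SFP probe sets"
    )
    print(f"behavior: {obs['fish_id'].nunique()} fish, {len(obs)} recordings")
    print(f"qPCR: {len(qpcr)} pools")


if __name__ == "__main__":
    main()
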