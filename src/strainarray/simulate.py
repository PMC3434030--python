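"""Synthetic probe-level, behavior and qPCR data with planted ground truth.

The probe-level generator emulates the study design the pipeline assumes:
4 strains (2 wild, 2 domesticated) x 2 sexes x 2 replicate pools = 16
samples on an oligonucleotide array where every transcript is measured by
a set of perfect-match / mismatch (PM/MM) probe pairs.  The generative
model is additive on the log2 scale — per-probe-set expression (baseline
plus planted strain / domestication / sex effects), per-probe affinity,
probe- and strain-specific single-feature-polymorphism (SFP) shifts, and
Gaussian measurement noise — exponentiated and summed with an additive
optical background, which is the model RMA-style preprocessing assumes:

    PM_ij = 2**(mu_gs + phi_j + sfp_js + eps_ij) + background
    MM_ij = 2**(phi_j + eps'_ij)                 + background

MM carries no true-signal term (cross-hybridization only), which keeps the
PM-MM discrimination score informative for detection calls.  Unexpressed
probe sets have no signal term at all and sit at background.  SFPs are
probe-affinity shifts shared by every sample of the affected strain(s) —
the genetic reading of probe-level polymorphism — so they are invisible at
the probe-set level after robust summarization but leave a strain-
associated footprint in probe residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ProbeLevelDataset, SampleInfo

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_probe_level_dataset",
    "generate_behavior_data",
    "generate_qpcr_data",
    "DEFAULT_DEPTH_MEANS",
    "DEFAULT_FRONT_PROBS",
]


class ConfigError(ValueError):
    """Simulation configuration is infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and effect-scale parameters of the generator.

    Fractions are of all probe sets; differential-expression categories
    are disjoint and drawn from the expressed pool, so
    ``fraction_unexpressed`` plus the three DE fractions must not exceed 1.
    Effect sizes are log2 fold changes; the defaults span the ~0.9-2.5
    log2 (1.85x-5.59x) range the downstream fold-change filters target.
    """

    strains: tuple[str, ...] = ("Gaighatta", "Nadia", "SH", "TM1")
    wild_strains: tuple[str, ...] = ("Gaighatta", "Nadia")
    n_sex: int = 2
    pools_per_cell: int = 2
    pool_size: int = 4
    n_probesets: int = 1000
    probes_per_probeset: int = 11
    fraction_unexpressed: float = 0.45
    fraction_strain_de: float = 0.20
    fraction_domestication_de: float = 0.05
    fraction_sex_de: float = 0.01
    effect_size_log2_mean: float = 1.2
    effect_size_log2_sd: float = 0.4
    effect_size_log2_min: float = 0.8
    fraction_sfp_probesets: float = 0.05
    sfp_affinity_shift_log2: float = 1.5
    sfp_probes_per_probeset: int = 2
    sfp_affected_strains: tuple[str, ...] | None = None  # None -> one random strain
    probe_affinity_sd: float = 1.0
    measurement_noise_sd: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (
            self.fraction_unexpressed,
            self.fraction_strain_de,
            self.fraction_domestication_de,
            self.fraction_sex_de,
            self.fraction_sfp_probesets,
        )
        if any(f < 0 or f > 1 for f in fr):
            raise ConfigError("all fractions must lie in [0, 1]")
        if (
            self.fraction_unexpressed
            + self.fraction_strain_de
            + self.fraction_domestication_de
            + self.fraction_sex_de
            > 1
        ):
            raise ConfigError("unexpressed + DE fractions exceed 1: infeasible")
        if self.fraction_sfp_probesets > 1 - self.fraction_unexpressed:
            raise ConfigError("more SFP probe sets requested than expressed probe sets")
        for name in ("effect_size_log2_sd", "probe_affinity_sd",
                     "measurement_noise_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sfp_probes_per_probeset > self.probes_per_probeset:
            raise ConfigError("sfp_probes_per_probeset exceeds probes_per_probeset")
        if self.sfp_affected_strains is not None:
            unknown = set(self.sfp_affected_strains) - set(self.strains)
            if unknown:
                raise ConfigError(f"unknown SFP strains: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.strains) * self.n_sex * self.pools_per_cell

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to score any downstream detector.

    ``probesets`` has one row per probe set: expressed flag, baseline log2
    expression, per-strain offsets, domestication and sex effects, DE
    category, and whether any member probe carries an SFP.  ``probes`` has
    one row per probe: affinity, SFP flag, shift and the affected strains.
    """

    probesets: pd.DataFrame
    probes: pd.DataFrame
    fish: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None

    def de_probesets(self, category: str) -> set[str]:
        m = self.probesets
        return set(m.loc[m["de_category"] == category, "probeset_id"])

    def sfp_probesets(self) -> set[str]:
        m = self.probesets
        return set(m.loc[m["has_sfp"], "probeset_id"])

    def expressed_probesets(self) -> set[str]:
        m = self.probesets
        return set(m.loc[m["expressed"], "probeset_id"])


def _make_samples(config: SimulationConfig) -> list[SampleInfo]:
    wild = set(config.wild_strains)
    samples = []
    for strain in config.strains:
        dom = "wild" if strain in wild else "domesticated"
        for sex in ("F", "M")[: config.n_sex]:
            for pool in range(1, config.pools_per_cell + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{strain}_{sex}{pool}",
                        strain=strain,
                        domestication=dom,
                        sex=sex,
                        pool_size=config.pool_size,
                    )
                )
    return samples


def generate_probe_level_dataset(
    config: SimulationConfig,
) -> tuple[ProbeLevelDataset, SyntheticTruth]:
    """Draw one probe-level dataset plus its planted truth.

    The same seed yields a bit-identical dataset.  Planted counts follow
    the configured fractions exactly (rounded): e.g. 1000 probe sets at
    ``fraction_sfp_probesets = 0.05`` carry exactly 50 SFP probe sets.
    """
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config)
    n_s = len(samples)
    n_ps = config.n_probesets
    n_pp = config.probes_per_probeset
    n_probes = n_ps * n_pp
    strains = list(config.strains)
    strain_idx = np.array([strains.index(s.strain) for s in samples])
    is_dom = np.array([s.domestication == "domesticated" for s in samples])
    is_male = np.array([s.sex == "M" for s in samples])

    probeset_ids = np.array([f"ps{k:05d}" for k in range(n_ps)])

    # --- assign probe-set categories (exact counts, disjoint) ------------
    n_unexpr = round(config.fraction_unexpressed * n_ps)
    n_strain = round(config.fraction_strain_de * n_ps)
    n_dom = round(config.fraction_domestication_de * n_ps)
    n_sex = round(config.fraction_sex_de * n_ps)
    perm = rng.permutation(n_ps)
    unexpr = perm[:n_unexpr]
    de_strain = perm[n_unexpr : n_unexpr + n_strain]
    de_dom = perm[n_unexpr + n_strain : n_unexpr + n_strain + n_dom]
    de_sex = perm[n_unexpr + n_strain + n_dom : n_unexpr + n_strain + n_dom + n_sex]
    expressed = np.ones(n_ps, bool)
    expressed[unexpr] = False
    de_category = np.full(n_ps, "none", dtype=object)
    de_category[de_strain] = "strain"
    de_category[de_dom] = "domestication"
    de_category[de_sex] = "sex"
    de_category[unexpr] = "unexpressed"

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_ps)

    # strain offsets: for strain-DE probe sets, a random 2/2 split of the
    # four strains at +-effect/2; for domestication-DE, the domesticated
    # pair shifted by a signed effect; sex-DE shifts males.
    strain_offsets = np.zeros((n_ps, len(strains)))
    # planted effect magnitudes floored so fold changes span the ~1.85x-5.6x
    # band the downstream filters target
    eff = rng.normal(config.effect_size_log2_mean, config.effect_size_log2_sd, n_ps)
    eff = np.sign(eff) * np.maximum(np.abs(eff), config.effect_size_log2_min)
    sign = rng.choice([-1.0, 1.0], n_ps)
    for k in de_strain:
        up = rng.choice(len(strains), size=len(strains) // 2, replace=False)
        strain_offsets[k, up] = abs(eff[k]) / 2.0
        strain_offsets[k, [j for j in range(len(strains)) if j not in up]] = (
            -abs(eff[k]) / 2.0
        )
    dom_effect = np.zeros(n_ps)
    dom_effect[de_dom] = sign[de_dom] * np.abs(eff[de_dom])
    sex_effect = np.zeros(n_ps)
    sex_effect[de_sex] = sign[de_sex] * np.abs(eff[de_sex])

    # --- SFPs: planted on expressed probe sets only ----------------------
    n_sfp = round(config.fraction_sfp_probesets * n_ps)
    expressed_idx = np.flatnonzero(expressed)
    sfp_sets = rng.choice(expressed_idx, size=n_sfp, replace=False)
    has_sfp = np.zeros(n_ps, bool)
    has_sfp[sfp_sets] = True

    probe_affinity = rng.normal(0.0, config.probe_affinity_sd, n_probes)
    probe_probeset = np.repeat(np.arange(n_ps), n_pp)
    probe_index = np.tile(np.arange(1, n_pp + 1), n_ps)

    sfp_flag = np.zeros(n_probes, bool)
    sfp_shift = np.zeros(n_probes)
    sfp_strains: list[str] = [""] * n_probes
    # probe x strain shift matrix applied in the PM exponent
    shift_by_strain = np.zeros((n_probes, len(strains)))
    for k in sfp_sets:
        members = np.flatnonzero(probe_probeset == k)
        hit = rng.choice(members, size=config.sfp_probes_per_probeset, replace=False)
        if config.sfp_affected_strains is None:
            affected = [strains[rng.integers(len(strains))]]
        else:
            affected = list(config.sfp_affected_strains)
        cols = [strains.index(s) for s in affected]
        sfp_flag[hit] = True
        sfp_shift[hit] = -config.sfp_affinity_shift_log2  # polymorphism lowers binding
        for j in hit:
            sfp_strains[j] = ",".join(affected)
            shift_by_strain[j, cols] = -config.sfp_affinity_shift_log2

    # --- compose intensities ---------------------------------------------
    mu = (
        baseline[:, None]
        + strain_offsets[:, strain_idx]
        + dom_effect[:, None] * is_dom[None, :]
        + sex_effect[:, None] * is_male[None, :]
    )  # probe-set x sample log2 expression
    mu_probe = mu[probe_probeset]  # probes x samples
    shift = shift_by_strain[:, strain_idx]  # probes x samples
    eps_pm = rng.normal(0.0, config.measurement_noise_sd, (n_probes, n_s))
    eps_mm = rng.normal(0.0, config.measurement_noise_sd, (n_probes, n_s))
    signal = np.where(
        expressed[probe_probeset][:, None],
        np.exp2(mu_probe + probe_affinity[:, None] + shift + eps_pm),
        0.0,
    )
    cross_hyb = np.exp2(probe_affinity[:, None] + eps_mm)
    bg_pm = rng.normal(config.background_mean, config.background_sd, (n_probes, n_s))
    bg_mm = rng.normal(config.background_mean, config.background_sd, (n_probes, n_s))
    pm = signal + np.maximum(bg_pm, 1e-3)
    mm = cross_hyb + np.maximum(bg_mm, 1e-3)

    probe_map = pd.DataFrame(
        {"probeset_id": probeset_ids[probe_probeset], "probe_index": probe_index}
    )
    dataset = ProbeLevelDataset(
        pm=pm, mm=mm, probe_map=probe_map, samples=samples
    )

    probeset_truth = pd.DataFrame(
        {
            "probeset_id": probeset_ids,
            "expressed": expressed,
            "baseline_log2": baseline,
            "de_category": de_category,
            "dom_effect_log2": dom_effect,
            "sex_effect_log2": sex_effect,
            "has_sfp": has_sfp,
        }
    )
    for j, s in enumerate(strains):
        probeset_truth[f"offset_{s}"] = strain_offsets[:, j]
    probe_truth = pd.DataFrame(
        {
            "probe_id": [
                f"{probeset_ids[g]}:{i}" for g, i in zip(probe_probeset, probe_index)
            ],
            "probeset_id": probeset_ids[probe_probeset],
            "probe_index": probe_index,
            "affinity_log2": probe_affinity,
            "is_sfp": sfp_flag,
            "sfp_shift_log2": sfp_shift,
            "sfp_strains": sfp_strains,
        }
    )
    return dataset, SyntheticTruth(probesets=probeset_truth, probes=probe_truth)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

# Paper-directional defaults: wild strains sit deeper (zones toward 6) and
# approach the front less than domesticated strains.
DEFAULT_DEPTH_MEANS = {"Gaighatta": 5.0, "Nadia": 4.8, "SH": 2.5, "TM1": 2.8}
DEFAULT_FRONT_PROBS = {"Gaighatta": 0.10, "Nadia": 0.15, "SH": 0.50, "TM1": 0.45}
WILD_STRAINS = ("Gaighatta", "Nadia")


def generate_behavior_data(
    n_fish_per_strain: int = 16,
    n_periods: int = 30,
    recordings_per_period: int = 3,
    strain_depth_means: dict[str, float] | None = None,
    strain_front_probs: dict[str, float] | None = None,
    between_fish_sd: float = 0.6,
    within_fish_sd: float = 0.6,
    front_between_fish_sd: float = 0.12,
    wild_strains: Sequence[str] = WILD_STRAINS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the tank-observation assay.

    Each fish has a latent depth preference (strain mean + N(0,
    between_fish_sd)) and a latent front-approach probability; every
    recording discretizes latent depth + N(0, within_fish_sd) into a
    vertical zone 1..6 (1 = top) and draws a Bernoulli front flag.  With
    the default variance split the intraclass correlation of the zone
    scores is 0.5, inside the 0.4-0.6 repeatability band the assay is
    designed to reproduce.

    Returns (observations, per-fish truth).
    """
    if n_periods < 1:
        raise ConfigError("n_periods must be >= 1")
    depth_means = dict(DEFAULT_DEPTH_MEANS if strain_depth_means is None else strain_depth_means)
    front_probs = dict(DEFAULT_FRONT_PROBS if strain_front_probs is None else strain_front_probs)
    for s, m in depth_means.items():
        if not (1.0 <= m <= 6.0):
            raise ConfigError(f"latent depth mean for {s} outside [1, 6]")
    for s, p in front_probs.items():
        if not (0.0 <= p <= 1.0):
            raise ConfigError(f"front probability for {s} outside [0, 1]")

    rng = np.random.default_rng(seed)
    wild = set(wild_strains)
    obs_rows = []
    fish_rows = []
    for strain in depth_means:
        for f in range(n_fish_per_strain):
            fish_id = f"{strain}_f{f:02d}"
            sex = "M" if f % 2 == 0 else "F"
            latent_depth = np.clip(
                depth_means[strain] + rng.normal(0.0, between_fish_sd), 1.0, 6.0
            )
            latent_front = float(
                np.clip(front_probs[strain] + rng.normal(0.0, front_between_fish_sd), 0.0, 1.0)
            )
            fish_rows.append(
                {
                    "fish_id": fish_id,
                    "strain": strain,
                    "sex": sex,
                    "domestication": "wild" if strain in wild else "domesticated",
                    "latent_depth": latent_depth,
                    "latent_front_prob": latent_front,
                }
            )
            n_rec = n_periods * recordings_per_period
            zones = np.clip(
                np.rint(latent_depth + rng.normal(0.0, within_fish_sd, n_rec)), 1, 6
            ).astype(int)
            fronts = (rng.random(n_rec) < latent_front).astype(int)
            r = 0
            for period in range(1, n_periods + 1):
                for rec in range(1, recordings_per_period + 1):
                    obs_rows.append(
                        {
                            "fish_id": fish_id,
                            "strain": strain,
                            "domestication": "wild" if strain in wild else "domesticated",
                            "sex": sex,
                            "period": period,
                            "recording": rec,
                            "vertical_zone": zones[r],
                            "front_flag": fronts[r],
                        }
                    )
                    r += 1
    return pd.DataFrame(obs_rows), pd.DataFrame(fish_rows)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr_data(
    strain_means_ct: dict[str, float],
    reference_mean_ct: float = 20.0,
    noise_sd: float = 0.2,
    beta: float = 1.0,
    pools_per_cell: int = 2,
    wild_strains: Sequence[str] = WILD_STRAINS,
    gene: str = "target",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-pool qRT-PCR cycle-threshold (C_T) measurements.

    The reference gene C_T is N(reference_mean, noise_sd); the target
    C_T is the strain mean plus ``beta`` times the centered reference C_T
    (shared loading variation) plus independent noise — the structure the
    reference-gene ANCOVA assumes.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wild = set(wild_strains)
    rows = []
    for strain, mean_ct in strain_means_ct.items():
        for sex in ("F", "M"):
            for pool in range(1, pools_per_cell + 1):
                ct_ref = reference_mean_ct + rng.normal(0.0, noise_sd)
                ct_tgt = (
                    mean_ct
                    + beta * (ct_ref - reference_mean_ct)
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "sample_id": f"{strain}_{sex}{pool}",
                        "strain": strain,
                        "domestication": "wild" if strain in wild else "domesticated",
                        "sex": sex,
                        "gene": gene,
                        "ct_target": ct_tgt,
                        "ct_reference": ct_ref,
                    }
                )
    truth = pd.DataFrame(
        {"strain": list(strain_means_ct), "true_mean_ct": list(strain_means_ct.values())}
    )
    return pd.DataFrame(rows), truth
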