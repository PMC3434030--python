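"""Single-feature-polymorphism (SFP) screening from probe-level residuals.

A sequence polymorphism under a probe changes that probe's hybridization
affinity for every sample of the carrier strain, without changing the
transcript's abundance.  After robust probe-set summarization such a probe
leaves a strain-associated footprint in its residuals: the probe-set
expression estimate is subtracted from the normalized log2 value at each
probe, and the residuals are screened for a strain effect with a
permutation-calibrated multiclass statistic (SAM-style).  Probe sets with
at least one significant probe are flagged and removed from differential
expression, since their summarized values confound genotype with
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SFPReport",
    "compute_probe_residuals",
    "sam_multiclass",
    "flag_sfp_probesets",
]


@dataclass
class SFPReport:
    """Per-probe permutation statistics and the flagged probe sets."""

    probes: pd.DataFrame  # probe_id, probeset_id, d, q
    flagged: pd.DataFrame  # probeset_id, n_significant_probes, flagged
    alpha: float

    def flagged_probesets(self) -> set[str]:
        return set(self.flagged.loc[self.flagged["flagged"], "probeset_id"])


def compute_probe_residuals(
    normalized_log2_probes: np.ndarray,
    expr: ExpressionMatrix,
    probe_map: pd.DataFrame,
) -> np.ndarray:
    """Subtract each probe set's expression estimate from its probes.

    ``normalized_log2_probes`` must be the background-corrected,
    quantile-normalized log2 probe matrix the expression estimates were
    summarized from; the residual r_{j,i} for probe j in sample i is the
    probe value minus the probe-set expression in that sample.  A constant
    probe affinity survives in the residual row but carries no
    between-strain signal.
    """
    x = np.asarray(normalized_log2_probes, dtype=float)
    if len(probe_map) != x.shape[0]:
        raise ValueError("probe_map rows must match probe matrix rows")
    missing = set(probe_map["probeset_id"]) - set(expr.probeset_ids)
    if missing:
        raise ValueError(
            f"probe sets missing from expression matrix: {sorted(missing)[:5]}"
        )
    per_probe_expr = expr.values.loc[probe_map["probeset_id"]].to_numpy()
    return x - per_probe_expr


def _class_stat(
    x: np.ndarray, indicator: np.ndarray, n_per_class: np.ndarray, s0: float
) -> np.ndarray:
    """F-like multiclass score per row of x given a class-indicator matrix."""
    n = x.shape[1]
    k = indicator.shape[1]
    class_sums = x @ indicator
    class_means = class_sums / n_per_class
    grand = x.mean(axis=1, keepdims=True)
    between = ((class_means - grand) ** 2 * n_per_class).sum(axis=1)
    ssw = (x**2).sum(axis=1) - (class_sums**2 / n_per_class).sum(axis=1)
    ssw = np.maximum(ssw, 0.0)
    s = np.sqrt(ssw / (n - k))
    return np.sqrt(between) / (s + s0)


def sam_multiclass(
    residuals: np.ndarray,
    strain_labels: np.ndarray | list[str],
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | str = "auto",
) -> pd.DataFrame:
    """Permutation-calibrated multiclass statistic per probe.

    The score is d = sqrt(sum_k n_k (xbar_k - xbar)^2) / (s + s0) with s
    the pooled within-class standard deviation and s0 a small-denominator
    guard ("auto" = 5th percentile of the s distribution).  The null is
    built from ``n_permutations`` random permutations of the strain labels;
    the q-value of probe j is the median permutation count of scores >=
    d_j divided by the observed count, clipped to [0, 1] and monotone
    nonincreasing in d.

    Returns a DataFrame with columns ``d`` and ``q`` in probe order.
    """
    x = np.asarray(residuals, dtype=float)
    labels = np.asarray(strain_labels)
    if x.shape[1] != labels.size:
        raise ValueError("one strain label per sample column required")
    classes, class_idx = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 strains")
    counts = np.bincount(class_idx)
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per strain (design not invertible)")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give a coarse null; >= 100 recommended",
            stacklevel=2,
        )
    n = labels.size
    k = classes.size
    indicator = np.zeros((n, k))
    indicator[np.arange(n), class_idx] = 1.0
    n_per_class = counts.astype(float)

    ssw = (x**2).sum(axis=1) - ((x @ indicator) ** 2 / n_per_class).sum(axis=1)
    s = np.sqrt(np.maximum(ssw, 0.0) / (n - k))
    s0_val = float(np.percentile(s, 5.0)) if s0 == "auto" else float(s0)

    d_obs = _class_stat(x, indicator, n_per_class, s0_val)

    rng = np.random.default_rng(seed)
    order = np.argsort(d_obs)[::-1]
    d_sorted = d_obs[order]
    n_probes = d_obs.size
    # counts of permuted scores >= each observed (descending) d
    perm_counts = np.empty((n_permutations, n_probes), dtype=np.int64)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        d_perm = _class_stat(x[:, perm], indicator, n_per_class, s0_val)
        # number of permuted d >= threshold t, for t = each d_sorted
        d_perm_sorted = np.sort(d_perm)
        perm_counts[b] = n_probes - np.searchsorted(
            d_perm_sorted, d_sorted, side="left"
        )
    median_false = np.median(perm_counts, axis=0)
    # observed count of d >= d_j; members of a tie share the largest count
    _, first_idx, inv = np.unique(-d_sorted, return_index=True, return_inverse=True)
    group_last = np.maximum.reduceat(np.arange(n_probes), first_idx)
    observed_count = (group_last[inv] + 1).astype(float)
    fdr = np.clip(median_false / observed_count, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_probes)
    q[order] = q_sorted
    return pd.DataFrame({"d": d_obs, "q": q})


def flag_sfp_probesets(
    probe_stats: pd.DataFrame,
    probe_map: pd.DataFrame,
    alpha: float = 0.01,
    min_probes: int = 1,
) -> SFPReport:
    """Flag probe sets with >= ``min_probes`` member probes at q < alpha."""
    if not {"d", "q"}.issubset(probe_stats.columns):
        raise ValueError("probe_stats must have columns 'd' and 'q'")
    if len(probe_stats) != len(probe_map):
        raise ValueError("probe_stats and probe_map must be row-aligned")
    probes = probe_map[["probeset_id", "probe_index"]].copy()
    probes["probe_id"] = [
        f"{ps}:{ix}" for ps, ix in zip(probes["probeset_id"], probes["probe_index"])
    ]
    probes["d"] = probe_stats["d"].to_numpy()
    probes["q"] = probe_stats["q"].to_numpy()
    sig = probes.assign(significant=probes["q"] < alpha)
    counts = (
        sig.groupby("probeset_id", sort=False)["significant"].sum().rename(
            "n_significant_probes"
        )
    )
    flagged = counts.reset_index()
    flagged["flagged"] = flagged["n_significant_probes"] >= min_probes
    return SFPReport(
        probes=probes[["probe_id", "probeset_id", "d", "q"]],
        flagged=flagged,
        alpha=alpha,
    )
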