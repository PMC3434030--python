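"""RMA-style preprocessing: background correction, quantile normalization,
median-polish summarization, detection calls, and expression/variability
filters.

Background correction uses the exponential-signal + normal-background
convolution model: per sample, observed intensity o = s + b with
s ~ Exp(alpha) and b ~ N(mu, sigma^2).  Parameters are estimated from the
intensity density (mode-based) and each intensity is replaced by the
posterior mean E[s | o], which has the closed form

    a = o - mu - sigma^2 * alpha
    E[s | o] = a + sigma * (phi(a/sigma) - phi((o - a)/sigma))
                   / (Phi(a/sigma) + Phi((o - a)/sigma) - 1)

with phi/Phi the standard normal pdf/cdf.  The transform is strictly
positive and monotone in o within a sample.

Detection calls follow the standard present/marginal/absent construction:
per probe set and sample the discrimination scores
R_j = (PM_j - MM_j)/(PM_j + MM_j) are tested against H0: median(R) = tau
(one-sided, greater) with a Wilcoxon signed-rank test — exact null
enumeration for small probe sets, normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ProbeLevelDataset

__all__ = [
    "BackgroundModel",
    "DetectionCalls",
    "background_correct",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "detection_calls",
    "expression_threshold_filter",
    "iqr_filter",
    "rma",
    "signed_rank_pvalue",
]

EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class BackgroundModel:
    """Per-sample convolution parameters: b ~ N(mu, sigma^2), s ~ Exp(alpha)."""

    mu: float
    sigma: float
    alpha: float


@dataclass
class DetectionCalls:
    """Present/Marginal/Absent calls with their signed-rank p-values."""

    call: pd.DataFrame  # probe-set x sample, values in {"P", "M", "A"}
    pvalue: pd.DataFrame

    def absent_in_all_samples(self) -> pd.Index:
        """Probe sets never called Present (marginal counts as absent)."""
        return self.call.index[(self.call != "P").all(axis=1)]


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def estimate_background_parameters(x: np.ndarray, n_grid: int = 512) -> BackgroundModel:
    """Mode-based estimate of (mu, sigma, alpha) from one sample's intensities.

    mu is the mode of a kernel density estimate; sigma is the RMS spread of
    the sub-mode intensities (the left half of the background normal);
    alpha is the reciprocal mean excess of supra-mode intensities
    (exponential fit to the signal tail).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate sample: constant intensities")
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    mu = float(grid[np.argmax(kde(grid))])
    below = x[x < mu]
    if below.size == 0:
        below = x[x <= mu]
    sigma = float(np.sqrt(np.mean((below - mu) ** 2)))
    sigma = max(sigma, 1e-8)
    above = x[x > mu]
    mean_excess = float(np.mean(above - mu)) if above.size else 1.0
    alpha = 1.0 / max(mean_excess, 1e-8)
    return BackgroundModel(mu=mu, sigma=sigma, alpha=alpha)


def posterior_signal_mean(
    o: np.ndarray, model: BackgroundModel
) -> np.ndarray:
    """Closed-form E[signal | observed] under the exponential+normal model."""
    o = np.asarray(o, dtype=float)
    a = o - model.mu - model.sigma**2 * model.alpha
    b = model.sigma
    num = stats.norm.pdf(a / b) - stats.norm.pdf((o - a) / b)
    den = stats.norm.cdf(a / b) + stats.norm.cdf((o - a) / b) - 1.0
    den = np.maximum(den, 1e-300)
    corrected = a + b * num / den
    return np.maximum(corrected, 1e-10)


def background_correct(
    pm: np.ndarray, return_models: bool = False
) -> np.ndarray | tuple[np.ndarray, list[BackgroundModel]]:
    """Background-correct each sample (column) of a PM matrix."""
    pm = np.asarray(pm, dtype=float)
    if (pm <= 0).any():
        raise ValueError("intensities must be strictly positive")
    out = np.empty_like(pm)
    models = []
    for j in range(pm.shape[1]):
        model = estimate_background_parameters(pm[:, j])
        out[:, j] = posterior_signal_mean(pm[:, j], model)
        models.append(model)
    return (out, models) if return_models else out


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the identical empirical distribution.

    The value at rank r becomes the mean over columns of each column's
    r-th order statistic; ties within a column receive the mean of the
    values their tied ranks would get.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 1 column")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    order_stat_mean = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(col)
        ranked[order] = order_stat_mean
        # average would-be rank values over ties
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=ranked)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked
    return out


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def median_polish(
    x: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Additive fit overall + row + column by alternating median sweeps.

    Rows are swept before columns.  Iteration stops when the total
    absolute residual changes by less than ``tol`` (relative to its
    magnitude) or after ``max_iter`` iterations.

    Returns (overall, row_effects, col_effects, residuals).
    """
    z = np.asarray(x, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("need a non-empty 2-D matrix")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    prev_sum = np.abs(z).sum()
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cmed = np.median(row)
        overall += cmed
        row -= cmed
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rmed = np.median(col)
        overall += rmed
        col -= rmed
        cur_sum = np.abs(z).sum()
        if cur_sum == 0 or abs(cur_sum - prev_sum) < tol * max(cur_sum, 1e-12):
            break
        prev_sum = cur_sum
    return overall, row, col, z


def median_polish_summarize(
    log2_probes: np.ndarray,
    probe_map: pd.DataFrame,
    sample_ids: list[str] | pd.Index,
    tol: float = 0.01,
    max_iter: int = 10,
) -> ExpressionMatrix:
    """Summarize log2 probe intensities per probe set.

    expression(sample) = overall + sample effect of the per-probe-set
    median-polish fit; probe (row) effects absorb probe affinities.
    """
    x = np.asarray(log2_probes, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("log2 probe matrix must be finite")
    groups = probe_map.groupby("probeset_id", sort=False).indices
    values = np.empty((len(groups), x.shape[1]))
    ids = []
    for k, (probeset, rows) in enumerate(groups.items()):
        overall, _, col, _ = median_polish(x[rows], tol=tol, max_iter=max_iter)
        values[k] = overall + col
        ids.append(probeset)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(ids, name="probeset_id"),
                            columns=list(sample_ids))
    )


# ---------------------------------------------------------------------------
# detection calls
# ---------------------------------------------------------------------------

def signed_rank_pvalue(x: np.ndarray, exact_max_n: int = EXACT_WILCOXON_MAX_N) -> float:
    """One-sided (greater) Wilcoxon signed-rank p-value of H0: median(x)=0.

    Zeros are dropped; tied absolute values receive average ranks.  For
    n <= ``exact_max_n`` the null is enumerated exactly over all 2^n sign
    assignments (valid under ties); larger n uses the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    n = x.size
    if n == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(x))
    w = float(ranks[x > 0].sum())
    if n <= exact_max_n:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        sums = signs @ ranks
        return float(np.mean(sums >= w - 1e-9))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def detection_calls(
    dataset: ProbeLevelDataset,
    tau: float = 0.015,
    p_present: float = 0.04,
    p_absent: float = 0.04,
) -> DetectionCalls:
    """Present/Marginal/Absent calls from raw PM/MM discrimination scores.

    call = P iff p < ``p_present``; A iff p > ``p_absent``; else M.
    Downstream filters treat marginal as absent.
    """
    r = (dataset.pm - dataset.mm) / (dataset.pm + dataset.mm)
    groups = dataset.probe_map.groupby("probeset_id", sort=False).indices
    pvals = np.empty((len(groups), r.shape[1]))
    ids = []
    for k, (probeset, rows) in enumerate(groups.items()):
        sub = r[rows] - tau
        pvals[k] = [signed_rank_pvalue(sub[:, j]) for j in range(sub.shape[1])]
        ids.append(probeset)
    call = np.where(pvals < p_present, "P", np.where(pvals > p_absent, "A", "M"))
    index = pd.Index(ids, name="probeset_id")
    cols = dataset.sample_ids
    return DetectionCalls(
        call=pd.DataFrame(call, index=index, columns=cols),
        pvalue=pd.DataFrame(pvals, index=index, columns=cols),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def expression_threshold_filter(
    expr: ExpressionMatrix,
    calls: DetectionCalls,
    percentile: float = 0.99,
    pooled: bool = True,
    threshold: float | None = None,
) -> tuple[ExpressionMatrix, float]:
    """Remove probe sets whose expression never clears the absent background.

    The threshold T is the ``percentile`` quantile (linear interpolation)
    of the expression values of probe sets called absent (A or M) in every
    sample — pooled over samples by default, or the max of per-sample
    quantiles with ``pooled=False``.  A probe set is removed when its
    maximum expression across samples is below T.  Passing ``threshold``
    reuses a previously derived T (re-applying the filter with its own T
    is the identity; recomputing T from an already-filtered matrix would
    shift the absent pool).
    """
    if threshold is None:
        common = expr.probeset_ids.intersection(calls.call.index)
        absent = calls.absent_in_all_samples().intersection(common)
        if len(absent) == 0:
            warnings.warn(
                "no probe set absent in all samples; expression filter is vacuous",
                stacklevel=2,
            )
            return expr, float("-inf")
        absent_values = expr.values.loc[absent]
        if pooled:
            threshold = float(
                np.quantile(absent_values.to_numpy().ravel(), percentile)
            )
        else:
            threshold = float(
                np.quantile(absent_values.to_numpy(), percentile, axis=0).max()
            )
    keep = expr.values.max(axis=1) >= threshold
    return ExpressionMatrix(expr.values.loc[keep]), threshold


def iqr_filter(expr: ExpressionMatrix, min_iqr: float = 0.5) -> ExpressionMatrix:
    """Drop probe sets whose interquartile range across all samples is
    strictly below ``min_iqr`` (linear-interpolation quantiles)."""
    x = expr.values.to_numpy()
    q75, q25 = np.quantile(x, [0.75, 0.25], axis=1)
    keep = (q75 - q25) >= min_iqr
    return ExpressionMatrix(expr.values.loc[keep])


# ---------------------------------------------------------------------------
# full RMA path
# ---------------------------------------------------------------------------

def rma(
    dataset: ProbeLevelDataset,
    background: bool = True,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Background correction -> quantile normalization -> log2 -> median
    polish.

    Returns the probe-set expression matrix and the background-corrected,
    quantile-normalized log2 probe matrix (needed for single-feature-
    polymorphism residuals).
    """
    x = background_correct(dataset.pm) if background else dataset.pm.copy()
    x = quantile_normalize(x)
    log2_probes = np.log2(x)
    expr = median_polish_summarize(
        log2_probes, dataset.probe_map, dataset.sample_ids
    )
    return expr, log2_probes
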