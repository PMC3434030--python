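"""Gene-wise linear models with empirical-Bayes variance moderation.

Each probe set's log2 expression is fit by ordinary least squares against
a design built from the sample metadata (strain-only, or a fully crossed
strain x sex factorial).  Residual variances are shrunk toward a global
prior estimated by matching the moments of log s^2 to a scaled-F model
(the standard limma construction): with per-gene residual variance s_g^2
on d_g degrees of freedom and prior (d0, s0^2), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and moderated t/F statistics use d0 + d_g denominator degrees of freedom.
Contrasts of interest: the omnibus among-strain F, the wild-vs-
domesticated contrast 1/2(SH + TM1) - 1/2(Nadia + Gaighatta) (positive =
higher in domesticated), and the sex main effect from the factorial model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, SampleInfo

__all__ = [
    "DesignMatrix",
    "GeneFits",
    "ModeratedFit",
    "make_design",
    "fit_gene_linear_models",
    "moderate_variances",
    "test_contrasts",
    "bh_adjust",
    "fold_changes",
    "range_overlap_filter",
]


@dataclass
class DesignMatrix:
    """Samples x coefficients encoding with factor metadata."""

    X: np.ndarray
    coef_names: list[str]
    strains: list[str]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            # name aliased columns by checking rank without each column
            aliased = []
            full = np.linalg.matrix_rank(self.X)
            for j, name in enumerate(self.coef_names):
                reduced = np.delete(self.X, j, axis=1)
                if np.linalg.matrix_rank(reduced) == full:
                    aliased.append(name)
            raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
        if self.X.shape[0] - self.X.shape[1] <= 0:
            raise ValueError("no residual degrees of freedom")


def make_design(
    samples: list[SampleInfo], model: str = "strain"
) -> DesignMatrix:
    """Build a cell-means-style design.

    model = "strain": one indicator per strain (no intercept).
    model = "strain_sex": strain indicators plus a male main effect and
    strain x male interaction terms (fully crossed factorial).
    """
    strains = sorted({s.strain for s in samples})
    n = len(samples)
    cols = []
    names = []
    for st in strains:
        cols.append([1.0 if s.strain == st else 0.0 for s in samples])
        names.append(f"strain[{st}]")
    if model == "strain_sex":
        male = [1.0 if s.sex == "M" else 0.0 for s in samples]
        cols.append(male)
        names.append("sex[M]")
        for st in strains[1:]:
            cols.append(
                [m * c for m, c in zip(male, cols[strains.index(st)])]
            )
            names.append(f"strain[{st}]:sex[M]")
    elif model != "strain":
        raise ValueError(f"unknown model {model!r}")
    X = np.array(cols, dtype=float).T
    return DesignMatrix(X=X, coef_names=names, strains=strains, samples=list(samples))


@dataclass
class GeneFits:
    """Per-gene ordinary-least-squares results."""

    coef: np.ndarray  # genes x p
    sigma2: np.ndarray  # genes, residual variance (0 if df 0 impossible here)
    df_resid: int
    xtx_inv: np.ndarray  # p x p
    design: DesignMatrix
    probeset_ids: pd.Index


def fit_gene_linear_models(expr: ExpressionMatrix, design: DesignMatrix) -> GeneFits:
    """OLS per probe set: coefficients, residual variance, normal equations."""
    Y = expr.values.to_numpy()  # genes x samples
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise ValueError("expression columns and design rows must align")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - coef @ X.T
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / df
    return GeneFits(
        coef=coef,
        sigma2=sigma2,
        df_resid=df,
        xtx_inv=xtx_inv,
        design=design,
        probeset_ids=expr.probeset_ids,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class ModeratedFit:
    """Empirical-Bayes moderated fits."""

    fits: GeneFits
    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    posterior_s2: np.ndarray

    @property
    def df_total(self) -> float:
        return self.d0 + self.fits.df_resid


def moderate_variances(fits: GeneFits, d0: float | None = None) -> ModeratedFit:
    """Estimate (d0, s0^2) from the spread of log residual variances.

    If all variances are identical the spread is zero and d0 = inf (full
    shrinkage to the common value).  ``d0`` may be forced (0 disables
    moderation and reproduces classical t exactly).
    """
    s2 = np.asarray(fits.sigma2, dtype=float)
    d = fits.df_resid
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need >= 2 genes with positive residual variance")
    z = np.log(positive)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    tri_d = float(special.polygamma(1, d / 2.0))
    if d0 is None:
        excess = e_var - tri_d
        if excess <= 0:
            d0_est = np.inf
        else:
            d0_est = 2.0 * _trigamma_inverse(excess)
    else:
        d0_est = float(d0)
    if np.isinf(d0_est):
        s0_2 = float(np.exp(e_mean))
        posterior = np.full_like(s2, s0_2)
    elif d0_est == 0:
        s0_2 = float(np.exp(e_mean))
        posterior = s2.copy()
    else:
        s0_2 = float(
            np.exp(e_mean + special.digamma(d0_est / 2.0) - np.log(d0_est / 2.0))
        )
        posterior = (d0_est * s0_2 + d * s2) / (d0_est + d)
    return ModeratedFit(fits=fits, d0=d0_est, s0_2=s0_2, posterior_s2=posterior)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

WILD_DEFAULT = ("Gaighatta", "Nadia")


def _strain_coef_index(design: DesignMatrix) -> dict[str, int]:
    return {
        st: design.coef_names.index(f"strain[{st}]") for st in design.strains
    }


def _moderated_t(
    mfit: ModeratedFit, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fits = mfit.fits
    est = fits.coef @ contrast
    u2 = float(contrast @ fits.xtx_inv @ contrast)
    se = np.sqrt(u2 * mfit.posterior_s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf * np.sign(est)))
    df = mfit.df_total
    p = 2.0 * stats.t.sf(np.abs(t), df) if np.isfinite(df) else 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(se > 0, p, np.where(est == 0, 1.0, 0.0))
    return est, t, p


def _moderated_f(
    mfit: ModeratedFit, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated F for H0: C beta = 0 (C is q x p)."""
    fits = mfit.fits
    q = C.shape[0]
    mid = np.linalg.inv(C @ fits.xtx_inv @ C.T)
    cb = fits.coef @ C.T  # genes x q
    quad = np.einsum("gi,ij,gj->g", cb, mid, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mfit.posterior_s2 > 0, quad / (q * mfit.posterior_s2), np.inf)
    f = np.where((mfit.posterior_s2 <= 0) & (quad <= 1e-300), 0.0, f)
    df2 = mfit.df_total
    if np.isfinite(df2):
        p = stats.f.sf(f, q, df2)
    else:
        p = stats.chi2.sf(q * f, q)
    p = np.where(np.isinf(f), 0.0, np.where(f == 0, 1.0, p))
    return f, p


def test_contrasts(
    mfit: ModeratedFit,
    contrast: str,
    wild_strains: tuple[str, ...] = WILD_DEFAULT,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test one of the study's contrasts on a moderated fit.

    contrast = "among_strain": moderated F on the three strain-difference
    coefficients.  "wild_vs_domesticated": moderated t on the average-
    domesticated minus average-wild contrast.  "sex": moderated t on the
    sex main effect (requires the factorial design).
    """
    design = mfit.fits.design
    p_coef = design.X.shape[1]
    idx = _strain_coef_index(design)
    if contrast == "among_strain":
        strains = design.strains
        C = np.zeros((len(strains) - 1, p_coef))
        for r, st in enumerate(strains[1:]):
            C[r, idx[strains[0]]] = 1.0
            C[r, idx[st]] = -1.0
        f, p = _moderated_f(mfit, C)
        out = pd.DataFrame(
            {"probeset_id": mfit.fits.probeset_ids, "F": f, "p": p}
        )
    elif contrast == "wild_vs_domesticated":
        missing = set(wild_strains) - set(design.strains)
        if missing:
            raise ValueError(f"wild strains absent from design: {sorted(missing)}")
        dom = [s for s in design.strains if s not in wild_strains]
        if not dom:
            raise ValueError("no domesticated strains in design")
        c = np.zeros(p_coef)
        for st in dom:
            c[idx[st]] = 1.0 / len(dom)
        for st in wild_strains:
            c[idx[st]] = -1.0 / len(wild_strains)
        est, t, p = _moderated_t(mfit, c)
        out = pd.DataFrame(
            {
                "probeset_id": mfit.fits.probeset_ids,
                "estimate_log2": est,
                "t": t,
                "p": p,
            }
        )
    elif contrast == "sex":
        if "sex[M]" not in design.coef_names:
            raise ValueError("sex contrast requires the strain_sex factorial design")
        # sex main effect averaged over strains: male effect + mean interaction
        c = np.zeros(p_coef)
        c[design.coef_names.index("sex[M]")] = 1.0
        inter = [n for n in design.coef_names if n.endswith(":sex[M]")]
        for n in inter:
            c[design.coef_names.index(n)] = 1.0 / len(design.strains)
        est, t, p = _moderated_t(mfit, c)
        out = pd.DataFrame(
            {
                "probeset_id": mfit.fits.probeset_ids,
                "estimate_log2": est,
                "t": t,
                "p": p,
            }
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < fdr
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# fold changes and range-overlap filter
# ---------------------------------------------------------------------------

def fold_changes(
    expr: ExpressionMatrix, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-gene linear-scale fold change over group means.

    Two groups: FC = 2**|mean_A - mean_B| with a signed direction column.
    More than two: the maximum pairwise fold change over all group pairs
    (the convention behind the "2-fold or greater in pairwise comparisons"
    among-strain rule).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    means = {}
    for g, cols in groups.items():
        if len(cols) == 0:
            raise ValueError(f"group {g!r} is empty")
        means[g] = expr.values[cols].mean(axis=1)
    if len(names) == 2:
        diff = means[names[0]] - means[names[1]]
        return pd.DataFrame(
            {
                "probeset_id": expr.probeset_ids,
                "log2_diff": diff.to_numpy(),
                "fold_change": np.exp2(np.abs(diff.to_numpy())),
                "direction": np.where(
                    diff.to_numpy() >= 0, f"up_in_{names[0]}", f"up_in_{names[1]}"
                ),
            }
        )
    mean_mat = pd.DataFrame(means)
    max_abs = np.zeros(len(mean_mat))
    pair = np.empty(len(mean_mat), dtype=object)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = np.abs(mean_mat[names[i]] - mean_mat[names[j]]).to_numpy()
            upd = d > max_abs
            pair[upd] = f"{names[i]}|{names[j]}"
            max_abs = np.maximum(max_abs, d)
    return pd.DataFrame(
        {
            "probeset_id": expr.probeset_ids,
            "max_log2_diff": max_abs,
            "fold_change": np.exp2(max_abs),
            "max_pair": pair,
        }
    )


def range_overlap_filter(
    expr: ExpressionMatrix,
    wild_samples: list[str],
    domesticated_samples: list[str],
    candidates: list[str] | pd.Index,
    max_overlap: int = 1,
) -> list[str]:
    """Keep candidates whose wild and domesticated expression ranges
    overlap by at most ``max_overlap`` samples.

    The overlap count is the number of wild samples inside the
    [min, max] range of the domesticated group plus the number of
    domesticated samples inside the wild range; values equal to a group
    extreme count as inside.
    """
    if not wild_samples or not domesticated_samples:
        raise ValueError("both groups must be non-empty")
    unknown = set(candidates) - set(expr.probeset_ids)
    if unknown:
        raise ValueError(f"candidates absent from expression: {sorted(unknown)[:5]}")
    w = expr.values[wild_samples]
    d = expr.values[domesticated_samples]
    retained = []
    for ps in candidates:
        wv = w.loc[ps].to_numpy()
        dv = d.loc[ps].to_numpy()
        overlap = int(
            ((wv >= dv.min()) & (wv <= dv.max())).sum()
            + ((dv >= wv.min()) & (dv <= wv.max())).sum()
        )
        if overlap <= max_overlap:
            retained.append(ps)
    return retained
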