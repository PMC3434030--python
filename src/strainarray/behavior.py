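"""Behavior scoring, fixed-effects ANOVA, qPCR ANCOVA and Tukey comparisons.

Raw tank observations (vertical zone 1..6, 1 = top; binary front flag) are
scored per fish into Vertical Depth (mean zone over observation periods)
and Horizontal Position (proportion of recordings within one body length
of the front of the tank).  Scores are analyzed with fixed-effects linear
models — Sex + Domestication + Strain nested within Domestication, or
one-way Strain — using partial (Type-III-style) sums of squares on a
sum-to-zero encoding.  qPCR cycle thresholds are analyzed by ANCOVA with
the reference-gene C_T as covariate; pairwise strain comparisons use the
Tukey studentized-range test with the Tukey-Kramer convention for
unbalanced group sizes and compact-letter-display grouping.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "score_behavior",
    "fixed_effects_anova",
    "qpcr_ancova",
    "tukey_hsd",
    "anova_repeatability",
    "AncovaResult",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_behavior(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-fish Vertical Depth and Horizontal Position.

    Vertical Depth is the mean over observation periods of the within-
    period mean zone (incomplete periods contribute their available
    recordings); Horizontal Position is the overall proportion of front
    flags.  Fish with zero recordings are dropped with a warning.
    """
    required = {"fish_id", "strain", "sex", "period", "recording",
                "vertical_zone", "front_flag"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = observations.dropna(subset=["vertical_zone", "front_flag"])
    dropped = set(observations["fish_id"]) - set(obs["fish_id"])
    if dropped:
        warnings.warn(
            f"fish with zero usable recordings excluded: {sorted(dropped)}",
            stacklevel=2,
        )
    if not obs["vertical_zone"].between(1, 6).all():
        raise ValueError("vertical_zone outside 1..6")
    period_means = (
        obs.groupby(["fish_id", "period"])["vertical_zone"].mean().rename("zone")
    )
    depth = period_means.groupby("fish_id").mean().rename("vertical_depth")
    front = obs.groupby("fish_id")["front_flag"].mean().rename("horizontal_position")
    counts = obs.groupby("fish_id").agg(
        n_periods=("period", "nunique"), n_recordings=("recording", "size")
    )
    meta_cols = ["strain", "sex"] + (
        ["domestication"] if "domestication" in obs.columns else []
    )
    meta = obs.groupby("fish_id")[meta_cols].first()
    scores = pd.concat([meta, depth, front, counts], axis=1).reset_index()
    return scores


# ---------------------------------------------------------------------------
# sum-coded designs and partial-SS ANOVA
# ---------------------------------------------------------------------------

def _sum_coded(values: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {prefix!r} needs >= 2 levels")
    ref = levels[-1]
    cols = {}
    for lev in levels[:-1]:
        col = np.where(values == lev, 1.0, np.where(values == ref, -1.0, 0.0))
        cols[f"{prefix}[{lev}]"] = col
    return pd.DataFrame(cols, index=values.index)


def _nested_sum_coded(
    inner: pd.Series, outer: pd.Series, prefix: str
) -> pd.DataFrame:
    cols = {}
    for outer_level in sorted(outer.unique()):
        mask = outer == outer_level
        levels = sorted(inner[mask].unique())
        if len(levels) < 2:
            continue
        ref = levels[-1]
        for lev in levels[:-1]:
            col = np.zeros(len(inner))
            col[(inner == lev) & mask] = 1.0
            col[(inner == ref) & mask] = -1.0
            cols[f"{prefix}[{lev}|{outer_level}]"] = col
    if not cols:
        raise ValueError(f"nested factor {prefix!r} has no estimable contrasts")
    return pd.DataFrame(cols, index=inner.index)


def _term_columns(data: pd.DataFrame, term: str) -> pd.DataFrame:
    """Columns for one model term.

    Supported: a numeric column name (covariate), a categorical column
    name (sum-coded factor), ``inner(outer)`` nesting, and ``a:b``
    interactions of factors.
    """
    if "(" in term and term.endswith(")"):
        inner_name, outer_name = term[:-1].split("(")
        return _nested_sum_coded(data[inner_name], data[outer_name], inner_name)
    if ":" in term:
        parts = term.split(":")
        blocks = [_term_columns(data, p) for p in parts]
        out = blocks[0]
        for blk in blocks[1:]:
            cols = {}
            for a in out.columns:
                for b in blk.columns:
                    cols[f"{a}:{b}"] = out[a].to_numpy() * blk[b].to_numpy()
            out = pd.DataFrame(cols, index=data.index)
        return out
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        return pd.DataFrame({term: col.to_numpy(dtype=float)}, index=data.index)
    return _sum_coded(col, term)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fixed_effects_anova(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    ss_type: str = "partial",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fixed-effects linear model with per-term F tests.

    ``terms`` name columns of ``data`` (factors are sum-coded), nested
    terms as ``"strain(domestication)"`` and interactions as ``"a:b"``.
    ``ss_type="partial"`` (default) drops each term from the full model
    (Type-III-style); ``"sequential"`` adds terms in order (Type I).

    Returns the ANOVA table and residual diagnostics (skew, kurtosis and
    a D'Agostino-Pearson normality p, reported for inspection only).
    """
    y = data[response].to_numpy(dtype=float)
    n = y.size
    blocks = {t: _term_columns(data, t) for t in terms}
    X_full = np.column_stack(
        [np.ones(n)] + [blocks[t].to_numpy() for t in terms]
    )
    rank_full = np.linalg.matrix_rank(X_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    rss_full = _rss(y, X_full)
    ms_resid = rss_full / df_resid

    rows = []
    if ss_type == "partial":
        for t in terms:
            others = [np.ones((n, 1))] + [
                blocks[u].to_numpy() for u in terms if u != t
            ]
            X_red = np.column_stack(others)
            rank_red = np.linalg.matrix_rank(X_red)
            df_t = rank_full - rank_red
            if df_t == 0:
                raise ValueError(
                    f"term {t!r} is confounded with the remaining terms"
                )
            ss_t = _rss(y, X_red) - rss_full
            rows.append((t, df_t, max(ss_t, 0.0)))
    elif ss_type == "sequential":
        X_cur = np.ones((n, 1))
        rss_cur = _rss(y, X_cur)
        rank_cur = 1
        for t in terms:
            X_next = np.column_stack([X_cur, blocks[t].to_numpy()])
            rank_next = np.linalg.matrix_rank(X_next)
            rss_next = _rss(y, X_next)
            rows.append((t, rank_next - rank_cur, max(rss_cur - rss_next, 0.0)))
            X_cur, rss_cur, rank_cur = X_next, rss_next, rank_next
    else:
        raise ValueError(f"unknown ss_type {ss_type!r}")

    table_rows = []
    for t, df_t, ss_t in rows:
        ms_t = ss_t / df_t if df_t else np.nan
        if ms_resid > 0:
            f = ms_t / ms_resid
            p = float(stats.f.sf(f, df_t, df_resid))
        else:
            f = np.inf if ss_t > 1e-12 else 0.0
            p = 0.0 if ss_t > 1e-12 else 1.0
        table_rows.append(
            {"term": t, "df": df_t, "sum_sq": ss_t, "mean_sq": ms_t, "F": f, "p": p}
        )
    table_rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "sum_sq": rss_full,
            "mean_sq": ms_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(table_rows)

    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    if n >= 8 and np.ptp(resid) > 0:
        normality_p = float(stats.normaltest(resid).pvalue)
    else:
        normality_p = np.nan
    diagnostics = {
        "residual_skew": float(stats.skew(resid)),
        "residual_kurtosis": float(stats.kurtosis(resid)),
        "normality_p": normality_p,
    }
    return table, diagnostics


# ---------------------------------------------------------------------------
# qPCR ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    table: pd.DataFrame
    adjusted_means: pd.Series  # per strain, at the mean reference C_T
    mse: float
    df_resid: int
    group_sizes: dict[str, int]


def qpcr_ancova(qpcr: pd.DataFrame) -> AncovaResult:
    """ANCOVA of target C_T with the reference-gene C_T as covariate.

    Model: ct_target ~ ct_reference + Strain + Sex + Strain:Sex.  A
    constant reference C_T carries no information and is dropped with a
    warning (the model degenerates to the two-way ANOVA).  Adjusted strain
    means are predictions at the mean reference C_T averaged over sexes.
    """
    required = {"strain", "sex", "ct_target", "ct_reference"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    sizes = qpcr.groupby("strain").size()
    if (sizes < 2).any():
        raise ValueError(
            f"strains with < 2 samples: {list(sizes.index[sizes < 2])}"
        )
    data = qpcr.reset_index(drop=True).copy()
    terms = ["ct_reference", "strain", "sex", "strain:sex"]
    if np.ptp(data["ct_reference"].to_numpy(dtype=float)) == 0:
        warnings.warn(
            "constant reference C_T: covariate dropped", stacklevel=2
        )
        terms = ["strain", "sex", "strain:sex"]
    table, _ = fixed_effects_anova(data, "ct_target", terms)

    # adjusted means from the full fit
    y = data["ct_target"].to_numpy(dtype=float)
    blocks = {t: _term_columns(data, t) for t in terms}
    X = np.column_stack([np.ones(len(data))] + [blocks[t].to_numpy() for t in terms])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    strains = sorted(data["strain"].unique())
    sexes = sorted(data["sex"].unique())
    ref_mean = float(data["ct_reference"].mean())
    adj = {}
    for st in strains:
        preds = []
        for sx in sexes:
            cell = pd.DataFrame(
                {
                    "strain": pd.Series([st]),
                    "sex": pd.Series([sx]),
                    "ct_reference": [ref_mean],
                }
            )
            # rebuild the design row with the training-level encodings
            row = [1.0]
            for t in terms:
                cols = _term_columns(
                    pd.concat([data[["strain", "sex", "ct_reference"]], cell],
                              ignore_index=True),
                    t,
                ).iloc[-1]
                row.extend(cols.to_numpy())
            preds.append(float(np.array(row) @ beta))
        adj[st] = float(np.mean(preds))
    resid_row = table.loc[table["term"] == "Residual"].iloc[0]
    return AncovaResult(
        table=table,
        adjusted_means=pd.Series(adj),
        mse=float(resid_row["mean_sq"]),
        df_resid=int(resid_row["df"]),
        group_sizes=sizes.to_dict(),
    )


# ---------------------------------------------------------------------------
# Tukey studentized-range comparisons
# ---------------------------------------------------------------------------

def _compact_letters(
    groups: list[str], means: dict[str, float], significant: dict[frozenset, bool]
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ."""
    ordered = sorted(groups, key=lambda g: means[g])
    runs = []
    for i in range(len(ordered)):
        j = i
        while j + 1 < len(ordered) and not any(
            significant[frozenset((ordered[a], ordered[b]))]
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append(tuple(ordered[i : j + 1]))
    # drop runs contained in another run
    maximal = [
        r for r in runs if not any(set(r) < set(o) for o in runs if o != r)
    ]
    seen = []
    for r in maximal:
        if r not in seen:
            seen.append(r)
    letters = {g: "" for g in groups}
    for letter, run in zip("abcdefghijklmnopqrstuvwxyz", seen):
        for g in run:
            letters[g] += letter
    return letters


def tukey_hsd(
    group_means: dict[str, float],
    mse: float,
    df_resid: int,
    group_sizes: dict[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons by the Tukey studentized-range test.

    Unbalanced sizes use the Tukey-Kramer standard error
    sqrt(mse/2 * (1/n_i + 1/n_j)).  Returns one row per pair; the
    compact-letter-display grouping is attached as
    ``result.attrs["letters"]`` (groups sharing a letter do not differ at
    ``alpha``).
    """
    groups = list(group_means)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    sig: dict[frozenset, bool] = {}
    for a, b in itertools.combinations(groups, 2):
        diff = group_means[a] - group_means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / group_sizes[a] + 1.0 / group_sizes[b]))
        if se > 0:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
        else:
            q = np.inf if abs(diff) > 1e-12 else 0.0
            p = 0.0 if abs(diff) > 1e-12 else 1.0
        sig[frozenset((a, b))] = p < alpha
        rows.append(
            {"group_a": a, "group_b": b, "diff": diff, "q": q, "p": p,
             "significant": p < alpha}
        )
    result = pd.DataFrame(rows)
    result.attrs["letters"] = _compact_letters(groups, group_means, sig)
    return result


# ---------------------------------------------------------------------------
# ANOVA-based repeatability (intraclass correlation)
# ---------------------------------------------------------------------------

def anova_repeatability(values: pd.Series, group: pd.Series) -> float:
    """One-way-ANOVA intraclass correlation of repeated scores per fish.

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW) with n0 the effective group
    size; this is the repeatability estimator the behavior simulator is
    calibrated against.
    """
    df = pd.DataFrame({"y": values.to_numpy(dtype=float), "g": group.to_numpy()})
    sizes = df.groupby("g").size()
    a = len(sizes)
    n_total = len(df)
    if a < 2:
        raise ValueError("need >= 2 groups")
    grand = df["y"].mean()
    group_means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (group_means - grand) ** 2).sum())
    ssw = float(((df["y"] - group_means.loc[df["g"]].to_numpy()) ** 2).sum())
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    n0 = (n_total - (sizes**2).sum() / n_total) / (a - 1)
    return float((msb - msw) / (msb + (n0 - 1) * msw))
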