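import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from strainarray import preprocess
from strainarray.io import ExpressionMatrix
from strainarray.preprocess import (
    BackgroundModel,
    DetectionCalls,
    background_correct,
    detection_calls,
    expression_threshold_filter,
    iqr_filter,
    median_polish,
    median_polish_summarize,
    posterior_signal_mean,
    quantile_normalize,
    signed_rank_pvalue,
)
from strainarray.simulate import SimulationConfig, generate_probe_level_dataset

from conftest import make_expression


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def quadrature_posterior_mean(o, mu, sigma, alpha):
    """Numerical E[s | o, 0 <= s <= o] for s ~ Exp(alpha), b ~ N(mu, sigma)
    (the convolution model constrains the signal to [0, o])."""
    def num(s):
        return s * alpha * np.exp(-alpha * s) * stats.norm.pdf(o - s, mu, sigma)

    def den(s):
        return alpha * np.exp(-alpha * s) * stats.norm.pdf(o - s, mu, sigma)

    a, _ = integrate.quad(num, 0, o, limit=200)
    b, _ = integrate.quad(den, 0, o, limit=200)
    return a / b


def test_background_closed_form_matches_quadrature():
    """The closed-form posterior signal mean agrees with numerical
    integration of the convolution posterior to 1e-6 relative error."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        mu = rng.uniform(50, 200)
        sigma = rng.uniform(5, 40)
        alpha = 1.0 / rng.uniform(50, 500)
        o = mu + rng.uniform(-1.5 * sigma, 8 * sigma)
        model = BackgroundModel(mu=mu, sigma=sigma, alpha=alpha)
        closed = float(posterior_signal_mean(np.array([o]), model)[0])
        numeric = quadrature_posterior_mean(o, mu, sigma, alpha)
        assert closed == pytest.approx(numeric, rel=1e-6)


def test_background_correction_is_monotone_per_sample(small_dataset):
    dataset, _ = small_dataset
    corrected = background_correct(dataset.pm)
    for j in range(corrected.shape[1]):
        order_raw = np.argsort(dataset.pm[:, j], kind="mergesort")
        assert (np.diff(corrected[order_raw, j]) >= -1e-12).all()
    assert (corrected > 0).all()


def test_background_small_sigma_limit():
    """For observed >> mu and sigma -> 0 the correction approaches
    observed - mu - sigma^2 * alpha."""
    model = BackgroundModel(mu=100.0, sigma=1e-3, alpha=0.01)
    o = np.array([5000.0])
    expected = 5000.0 - 100.0 - model.sigma**2 * model.alpha
    assert posterior_signal_mean(o, model)[0] == pytest.approx(expected, rel=1e-9)


def test_background_degenerate_sample_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        preprocess.estimate_background_parameters(np.full(100, 7.0))


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_hand_example():
    """Columns [2,4,6] and [1,3,5] both become [1.5, 3.5, 5.5] in original
    rank order; a single column is unchanged."""
    out = quantile_normalize(np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]))
    np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])
    single = np.array([[3.0], [1.0], [2.0]])
    np.testing.assert_allclose(quantile_normalize(single), single)


def test_quantile_normalize_ties_get_mean_rank_value():
    x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
    out = quantile_normalize(x)
    # tied values in column 0 share the mean of their would-be rank values
    assert out[0, 0] == out[1, 0] == pytest.approx((5.5 + 10.5) / 2)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.integers(2, 30),
    st.integers(1, 6),
    st.integers(0, 2**31 - 1),
)
def test_quantile_normalize_equalizes_distributions(n_rows, n_cols, seed):
    """After normalization every column has the identical sorted vector."""
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 50.0, (n_rows, n_cols))
    out = quantile_normalize(x)
    ref = np.sort(out[:, 0])
    for j in range(n_cols):
        np.testing.assert_array_equal(np.sort(out[:, j]), ref)


def test_quantile_normalize_rejects_missing():
    with pytest.raises(ValueError, match="missing"):
        quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def brute_force_median_polish(x, max_iter=10, tol=0.01):
    """Straightforward loop-based median polish (row sweep then column)."""
    z = [list(row) for row in x]
    nr, nc = len(z), len(z[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    import statistics

    prev = sum(abs(v) for r in z for v in r)
    for _ in range(max_iter):
        for i in range(nr):
            m = statistics.median(z[i])
            for j in range(nc):
                z[i][j] -= m
            row[i] += m
        m = statistics.median(row)
        overall += m
        row = [r - m for r in row]
        for j in range(nc):
            m = statistics.median([z[i][j] for i in range(nr)])
            for i in range(nr):
                z[i][j] -= m
            col[j] += m
        m = statistics.median(col)
        overall += m
        col = [c - m for c in col]
        cur = sum(abs(v) for r in z for v in r)
        if cur == 0 or abs(cur - prev) < tol * max(cur, 1e-12):
            break
        prev = cur
    return overall, row, col


def test_median_polish_exact_on_additive_data():
    """Exactly additive input is recovered with zero residuals, up to the
    shared offset between sample effects and the overall term."""
    e = np.array([1.0, 3.0, -2.0, 0.5])
    phi = np.array([0.2, -0.4, 1.0])
    x = e[None, :] + phi[:, None]
    overall, row, col, resid = median_polish(x)
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)
    np.testing.assert_allclose((overall + col) - e, (overall + col[0]) - e[0], atol=1e-12)

    const = np.full((5, 4), 3.25)
    overall, _, col, _ = median_polish(const)
    np.testing.assert_allclose(overall + col, 3.25)


def test_median_polish_matches_oracle_and_resists_outlier():
    """On a 3x3 matrix with one gross +10 outlier the fit equals the
    brute-force oracle exactly and differs from column means."""
    x = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [0.5, 1.5, 2.5]])
    x[0, 1] += 10.0
    overall, row, col, _ = median_polish(x)
    o_overall, o_row, o_col = brute_force_median_polish(x)
    assert overall == pytest.approx(o_overall, abs=1e-12)
    np.testing.assert_allclose(col, o_col, atol=1e-12)
    np.testing.assert_allclose(row, o_row, atol=1e-12)
    assert not np.allclose(overall + np.array(col), x.mean(axis=0))


def test_median_polish_summarize_groups_by_probe_set():
    x = np.vstack([np.full((3, 2), 1.0), np.full((4, 2), 5.0)])
    pm = pd.DataFrame(
        {"probeset_id": ["a"] * 3 + ["b"] * 4, "probe_index": [1, 2, 3, 1, 2, 3, 4]}
    )
    expr = median_polish_summarize(x, pm, ["s1", "s2"])
    np.testing.assert_allclose(expr.values.loc["a"], 1.0)
    np.testing.assert_allclose(expr.values.loc["b"], 5.0)


# ---------------------------------------------------------------------------
# detection calls
# ---------------------------------------------------------------------------

def test_signed_rank_exact_maximum_statistic():
    """Eleven identical positive discrimination scores put the signed-rank
    statistic at its maximum: exact one-sided p = 1/2^11."""
    p = signed_rank_pvalue(np.full(11, 0.5 - 0.015))
    assert p == pytest.approx(1.0 / 2048.0)


def test_signed_rank_wrong_direction_is_nonsignificant():
    p = signed_rank_pvalue(-np.abs(np.random.default_rng(0).normal(0.2, 0.05, 9)))
    assert p >= 0.5


def test_signed_rank_normal_approximation_close_to_exact():
    rng = np.random.default_rng(1)
    x = rng.normal(0.1, 0.2, 12)
    exact = signed_rank_pvalue(x, exact_max_n=12)
    approx = signed_rank_pvalue(x, exact_max_n=0)
    assert approx == pytest.approx(exact, abs=0.02)


def test_detection_calls_on_constructed_probesets(samples16):
    """A probe set with strong PM excess is Present; one with PM ~ MM is
    Absent; p-values at the cutoff yield Marginal which counts as absent."""
    from strainarray.io import ProbeLevelDataset

    n = len(samples16)
    pm = np.vstack([np.full((11, n), 300.0), np.full((11, n), 100.0)])
    mm = np.vstack([np.full((11, n), 100.0), np.full((11, n), 100.0)])
    mm[11:] += np.random.default_rng(0).normal(0, 1e-3, (11, n))  # break ties at 0
    probe_map = pd.DataFrame(
        {"probeset_id": ["hi"] * 11 + ["lo"] * 11, "probe_index": list(range(1, 12)) * 2}
    )
    ds = ProbeLevelDataset(pm=pm, mm=mm, probe_map=probe_map, samples=samples16)
    calls = detection_calls(ds)
    assert (calls.call.loc["hi"] == "P").all()
    assert (calls.call.loc["lo"] != "P").all()
    assert list(calls.absent_in_all_samples()) == ["lo"]

    # boundary: p exactly at the cutoff is Marginal, and marginal counts
    # as absent downstream
    pv = pd.DataFrame([[0.04], [0.01]], index=["m", "p"], columns=["s"])
    call = pd.DataFrame(
        np.where(pv < 0.04, "P", np.where(pv > 0.04, "A", "M")),
        index=pv.index,
        columns=pv.columns,
    )
    dc = DetectionCalls(call=call, pvalue=pv)
    assert call.loc["m", "s"] == "M"
    assert list(dc.absent_in_all_samples()) == ["m"]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_expression_filter_vacuous_without_all_absent_sets():
    expr = make_expression(np.array([[1.0, 2.0], [3.0, 4.0]]))
    call = pd.DataFrame(
        [["P", "A"], ["A", "P"]], index=expr.probeset_ids, columns=expr.sample_ids
    )
    pv = pd.DataFrame(
        np.where(call == "P", 0.01, 0.5), index=call.index, columns=call.columns
    )
    calls = DetectionCalls(call=call, pvalue=pv)
    with pytest.warns(UserWarning, match="vacuous"):
        out, t = expression_threshold_filter(expr, calls)
    assert t == float("-inf")
    pd.testing.assert_frame_equal(out.values, expr.values)


def test_expression_filter_quantile_oracle_and_idempotence():
    """With absent expression values 1..100 pooled, T is their 99th
    percentile; a probe set peaking below T is removed, one sample above T
    keeps the probe set; the filter is idempotent."""
    absent_vals = np.arange(1.0, 101.0).reshape(50, 2)
    expr_vals = np.vstack([absent_vals, [[2.0, 1.9], [1.0, 99.9]]])
    expr = make_expression(expr_vals)
    ids = list(expr.probeset_ids)
    call = pd.DataFrame("A", index=ids, columns=expr.sample_ids)
    call.loc[ids[50]] = ["P", "P"]  # low expressed probe set
    call.loc[ids[51]] = ["P", "P"]  # one sample above threshold
    pv = pd.DataFrame(
        np.where(call == "P", 0.01, 0.5), index=call.index, columns=call.columns
    )
    calls = DetectionCalls(call=call, pvalue=pv)
    out, t = expression_threshold_filter(expr, calls)
    assert t == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.99))
    assert ids[50] not in out.probeset_ids  # max 2.0 < T
    assert ids[51] in out.probeset_ids  # 99.9 >= T
    out2, _ = expression_threshold_filter(out, calls, threshold=t)
    pd.testing.assert_frame_equal(out2.values, out.values)


def test_iqr_filter_conventions():
    """Constant rows go; a 16-sample half-and-half 0/1 row has IQR exactly
    1.0 and stays; IQR exactly at the 0.5 cutoff is retained (strictly
    'less than' removes)."""
    rows = np.array(
        [
            np.zeros(16),
            np.r_[np.zeros(8), np.ones(8)],
            np.r_[np.zeros(8), np.full(8, 0.5)],
        ]
    )
    expr = make_expression(rows)
    out = iqr_filter(expr)
    assert list(out.probeset_ids) == ["g1", "g2"]


def test_full_rma_recovers_noiseless_group_difference(samples16):
    """Background -> quantile -> median polish on a noiseless additive
    dataset recovers planted 1-log2 group differences within +-0.05.

    Effects are planted as mirrored pairs (one probe set up in
    domesticated, its partner up in wild, sharing baseline and affinities)
    so every sample has the identical intensity distribution and quantile
    normalization is exact; unexpressed probe sets anchor the background
    mode.
    """
    from strainarray.io import ProbeLevelDataset

    rng = np.random.default_rng(3)
    is_dom = np.array([s.domestication == "domesticated" for s in samples16])
    n_pairs, n_unexpr, npp = 30, 60, 11
    baselines = rng.normal(9.0, 0.5, n_pairs)
    affinities = rng.normal(0, 0.5, (n_pairs, npp))
    blocks, ids = [], []
    for i in range(n_pairs):
        for up in (is_dom, ~is_dom):
            mu = baselines[i] + up.astype(float)
            blocks.append(np.exp2(mu[None, :] + affinities[i][:, None]))
            ids.append(f"ps{len(ids):04d}")
    for _ in range(n_unexpr):
        blocks.append(np.zeros((npp, 16)))
        ids.append(f"ps{len(ids):04d}")
    signal = np.vstack(blocks)
    bg = 100.0
    pm = signal + bg
    mm = np.exp2(rng.normal(0, 0.5, signal.shape[0]))[:, None] + bg + np.zeros((1, 16))
    probe_map = pd.DataFrame(
        {
            "probeset_id": np.repeat(ids, npp),
            "probe_index": np.tile(np.arange(1, npp + 1), len(ids)),
        }
    )
    dataset = ProbeLevelDataset(pm=pm, mm=mm, probe_map=probe_map, samples=samples16)
    expr, _ = preprocess.rma(dataset)
    v = expr.values.to_numpy()
    diff = v[:, is_dom].mean(axis=1) - v[:, ~is_dom].mean(axis=1)
    np.testing.assert_allclose(diff[0 : 2 * n_pairs : 2], 1.0, atol=0.05)
    np.testing.assert_allclose(diff[1 : 2 * n_pairs : 2], -1.0, atol=0.05)


def test_filters_keep_de_and_drop_unexpressed():
    """On default synthetic data the expression + IQR filters retain >=95%
    of expressed-and-DE probe sets and remove >=90% of unexpressed ones."""
    cfg = SimulationConfig(n_probesets=600, seed=21)
    dataset, truth = generate_probe_level_dataset(cfg)
    expr, _ = preprocess.rma(dataset)
    calls = detection_calls(dataset)
    filtered, _ = expression_threshold_filter(expr, calls)
    filtered = iqr_filter(filtered)
    kept = set(filtered.probeset_ids)
    tt = truth.probesets
    de = tt[tt["de_category"].isin(["strain", "domestication", "sex"])]
    unexpr = tt[~tt["expressed"]]
    assert de["probeset_id"].isin(kept).mean() >= 0.95
    assert (~unexpr["probeset_id"].isin(kept)).mean() >= 0.90
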