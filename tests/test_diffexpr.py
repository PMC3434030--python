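import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainarray import diffexpr
from strainarray.diffexpr import (
    DesignMatrix,
    bh_adjust,
    fit_gene_linear_models,
    fold_changes,
    make_design,
    moderate_variances,
    range_overlap_filter,
)
from strainarray.diffexpr import test_contrasts as contrast_test
from strainarray.io import SampleInfo

from conftest import make_expression

WILD = ("Gaighatta", "Nadia")


def _expr_for(samples, values):
    return make_expression(values, sample_ids=[s.sample_id for s in samples])


# ---------------------------------------------------------------------------
# gene-wise fits
# ---------------------------------------------------------------------------

def test_ols_matches_normal_equations_oracle(samples16):
    """Per-gene fits equal an independent normal-equations solve to 1e-10."""
    rng = np.random.default_rng(0)
    design = make_design(samples16, "strain_sex")
    Y = rng.normal(7, 1, (10, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    X = design.X
    for g in range(10):
        beta = np.linalg.solve(X.T @ X, X.T @ Y[g])
        np.testing.assert_allclose(fits.coef[g], beta, atol=1e-10)
        resid = Y[g] - X @ beta
        s2 = resid @ resid / (16 - X.shape[1])
        assert fits.sigma2[g] == pytest.approx(s2, abs=1e-10)


def test_noiseless_group_difference_and_intercept_only(samples16):
    is_dom = np.array([s.domestication == "domesticated" for s in samples16])
    y = np.where(is_dom, 2.0, 1.0)[None, :]
    design = make_design(samples16, "strain")
    fits = fit_gene_linear_models(_expr_for(samples16, y), design)
    coef = dict(zip(design.coef_names, fits.coef[0]))
    assert coef["strain[SH]"] - coef["strain[Nadia]"] == pytest.approx(1.0)
    assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-20)

    intercept = DesignMatrix(
        X=np.ones((16, 1)), coef_names=["const"], strains=[], samples=list(samples16)
    )
    fits2 = fit_gene_linear_models(_expr_for(samples16, y), intercept)
    assert fits2.coef[0, 0] == pytest.approx(y.mean())


def test_rank_deficient_design_names_aliased_columns(samples16):
    X = make_design(samples16, "strain").X
    X2 = np.column_stack([X, X[:, 0]])
    with pytest.raises(ValueError, match="aliased"):
        DesignMatrix(
            X=X2,
            coef_names=["a", "b", "c", "d", "dup"],
            strains=[],
            samples=list(samples16),
        )


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

def test_moderated_t_with_zero_prior_df_equals_classical_t(samples16):
    rng = np.random.default_rng(1)
    design = make_design(samples16, "strain")
    Y = rng.normal(7, 1, (200, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits, d0=0)
    res = contrast_test(mfit, "wild_vs_domesticated", wild_strains=WILD)
    c = np.zeros(4)
    for i, st in enumerate(design.strains):
        c[i] = 0.5 if st in ("SH", "TM1") else -0.5
    t_classical = (fits.coef @ c) / np.sqrt((c @ fits.xtx_inv @ c) * fits.sigma2)
    p_classical = 2 * stats.t.sf(np.abs(t_classical), fits.df_resid)
    np.testing.assert_allclose(res["t"], t_classical, atol=1e-10)
    np.testing.assert_allclose(res["p"], p_classical, atol=1e-10)


def test_infinite_prior_df_pools_variances(samples16):
    """d0 = inf shrinks every posterior variance to the common prior; equal
    residual variances estimate d0 = inf without error."""
    rng = np.random.default_rng(2)
    design = make_design(samples16, "strain")
    Y = rng.normal(0, 1, (50, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits, d0=np.inf)
    assert np.ptp(mfit.posterior_s2) == 0.0

    fits.sigma2 = np.full(50, 0.3)
    mfit2 = moderate_variances(fits)
    assert np.isinf(mfit2.d0)
    # all posteriors collapse onto the moment-matched prior, which carries
    # the log-chi-square bias correction relative to the raw 0.3
    assert np.ptp(mfit2.posterior_s2) == 0.0
    assert mfit2.s0_2 == pytest.approx(0.3, rel=0.15)


def test_posterior_variance_between_prior_and_sample(samples16):
    rng = np.random.default_rng(3)
    design = make_design(samples16, "strain")
    Y = rng.normal(0, 1, (300, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits)
    lo = np.minimum(fits.sigma2, mfit.s0_2)
    hi = np.maximum(fits.sigma2, mfit.s0_2)
    assert ((mfit.posterior_s2 >= lo - 1e-12) & (mfit.posterior_s2 <= hi + 1e-12)).all()


def test_prior_recovery_on_simulated_variances():
    """(d0, s0^2) estimated within 25% of truth on 2000 scaled-F variances."""
    d0_true, s0_true, d = 4.0, 0.05, 12

    class Stub:
        pass

    stub = Stub()
    chi_num = stats.chi2.rvs(d, size=2000, random_state=1)
    chi_den = stats.chi2.rvs(d0_true, size=2000, random_state=2)
    stub.sigma2 = s0_true * d0_true / chi_den * chi_num / d
    stub.df_resid = d
    mfit = moderate_variances(stub)
    assert mfit.d0 == pytest.approx(d0_true, rel=0.25)
    assert mfit.s0_2 == pytest.approx(s0_true, rel=0.25)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_equal_strain_means_give_zero_f(samples16):
    design = make_design(samples16, "strain")
    y = np.full((1, 16), 5.0)
    rng = np.random.default_rng(4)
    noise = rng.normal(0, 1, (30, 16))  # companions so moderation works
    Y = np.vstack([y, noise + 5.0])
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits)
    res = contrast_test(mfit, "among_strain")
    assert res.loc[0, "F"] == pytest.approx(0.0, abs=1e-20)
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_domestication_contrast_recovers_planted_effect(samples16):
    """A planted -2.483 log2 domestication effect (5.59-fold down in
    domesticated fish) is estimated within +-0.1 on average at noise 0.2."""
    rng = np.random.default_rng(5)
    effect = -2.4829
    is_dom = np.array([s.domestication == "domesticated" for s in samples16])
    Y = effect * is_dom[None, :] + rng.normal(0, 0.2, (100, 16)) + 8.0
    design = make_design(samples16, "strain")
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits)
    res = contrast_test(mfit, "wild_vs_domesticated", wild_strains=WILD)
    assert res["estimate_log2"].mean() == pytest.approx(effect, abs=0.1)
    assert res["significant"].all()


def test_swapping_group_labels_flips_contrast_sign(samples16):
    rng = np.random.default_rng(6)
    design = make_design(samples16, "strain")
    Y = rng.normal(0, 1, (50, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits)
    a = contrast_test(mfit, "wild_vs_domesticated", wild_strains=("Gaighatta", "Nadia"))
    b = contrast_test(mfit, "wild_vs_domesticated", wild_strains=("SH", "TM1"))
    np.testing.assert_allclose(a["estimate_log2"], -b["estimate_log2"], atol=1e-12)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)


def test_sex_contrast_requires_factorial(samples16):
    design = make_design(samples16, "strain")
    Y = np.random.default_rng(7).normal(0, 1, (20, 16))
    fits = fit_gene_linear_models(_expr_for(samples16, Y), design)
    mfit = moderate_variances(fits)
    with pytest.raises(ValueError, match="factorial"):
        contrast_test(mfit, "sex")


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_hand_example_and_properties():
    """(0.01, 0.02, 0.03, 0.04) all adjust to 0.04; a single p is
    unchanged; adjusted >= raw and monotone in ranks."""
    np.testing.assert_allclose(
        bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
    )
    assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 500)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    # agreement with the statsmodels implementation
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))


# ---------------------------------------------------------------------------
# fold changes and range-overlap filter
# ---------------------------------------------------------------------------

def test_fold_change_conventions():
    expr = make_expression(
        np.array([[5.0, 5.0, 5.0, 5.0], [6.0, 6.0, 5.0, 5.0], [5.0, 5.0, 7.4829, 7.4829]])
    )
    groups = {"A": ["s0", "s1"], "B": ["s2", "s3"]}
    fc = fold_changes(expr, groups)
    assert fc.loc[0, "fold_change"] == pytest.approx(1.0)
    assert fc.loc[1, "fold_change"] == pytest.approx(2.0)  # boundary: counts as 2-fold
    assert fc.loc[1, "direction"] == "up_in_A"
    assert fc.loc[2, "fold_change"] == pytest.approx(5.59, abs=0.005)
    assert fc.loc[2, "direction"] == "up_in_B"


def test_pairwise_max_fold_change_over_strains():
    expr = make_expression(np.array([[1.0, 1.0, 2.0, 4.0]]))
    groups = {k: [f"s{i}"] for i, k in enumerate("abcd")}
    with pytest.raises(ValueError, match="empty"):
        fold_changes(expr, {"a": [], "b": ["s0"]})
    fc = fold_changes(expr, groups)
    assert fc.loc[0, "max_log2_diff"] == pytest.approx(3.0)
    assert fc.loc[0, "fold_change"] == pytest.approx(8.0)


def test_range_overlap_filter_cases():
    """Disjoint ranges pass; identical ranges fail; the boundary-inclusive
    hand example {1,2,3,4} vs {3.5,5,6,7} counts overlap 2 and is
    rejected at max_overlap 1."""
    vals = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0],  # disjoint
            [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],  # identical
            [1.0, 2.0, 3.0, 4.0, 3.5, 5.0, 6.0, 7.0],  # overlap 2
        ]
    )
    expr = make_expression(vals)
    wild = ["s0", "s1", "s2", "s3"]
    dom = ["s4", "s5", "s6", "s7"]
    kept = range_overlap_filter(expr, wild, dom, list(expr.probeset_ids))
    assert kept == ["g0"]
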