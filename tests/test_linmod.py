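"""Designs, weighted fits, moderation, BH -- with independent oracles.

The reference values in ``tests/data/limma_oracle_expected.tsv`` were
precomputed with Bioconductor limma (voom + lmFit + eBayes + contrasts.fit)
by ``tests/data/make_limma_oracle.R`` on the frozen count fixture.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from oncostage.datatypes import STAGES, OncostageError
from oncostage.linmod import (
    StageLinearModel,
    adjust_bh,
    build_design,
    ebayes_moderate,
    fit_gene_models,
    summarize_linear_top,
)
from oncostage.salience import apply_contrasts, make_contrast_matrix
from oncostage.voom import voom_transform

from conftest import make_groups


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def test_baseline_design_rows():
    X = build_design(["control", "I"], "baseline")
    assert list(X.columns) == ["intercept", "I", "II", "III", "IV"]
    assert X.iloc[0].tolist() == [1, 0, 0, 0, 0]
    assert X.iloc[1].tolist() == [1, 1, 0, 0, 0]


def test_cellmeans_design_rows():
    X = build_design(["control", "I"], "cellmeans")
    assert list(X.columns) == ["control", "I", "II", "III", "IV"]
    assert X.iloc[0].tolist() == [1, 0, 0, 0, 0]
    assert X.iloc[1].tolist() == [0, 1, 0, 0, 0]
    assert (X.sum(axis=1) == 1).all()


def test_unknown_stage_label_rejected():
    with pytest.raises(OncostageError, match="unknown stage"):
        build_design(["control", "V"], "baseline")


def test_rank_deficient_design_names_columns():
    stages = ["control"] * 6  # all-control: stage columns are all zero
    X = build_design(stages, "cellmeans")
    Y = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)))
    Y.columns = range(6)
    with pytest.raises(OncostageError, match="collinear"):
        fit_gene_models((Y, None), X)


# ---------------------------------------------------------------------------
# weighted least squares
# ---------------------------------------------------------------------------

def _group_matrix(group_means, n_per_group, noise=0.0, rng=None):
    stages = make_groups(n_per_group)
    means = {g: m for g, m in zip(["control", *STAGES], group_means)}
    row = np.array([means[s] for s in stages], dtype=float)
    Y = np.tile(row, (1, 1))
    if noise and rng is not None:
        Y = Y + rng.normal(0, noise, size=Y.shape)
    df = pd.DataFrame(Y, index=["g0"], columns=range(len(stages)))
    return df, stages


def test_noiseless_baseline_fit_interpolates_exactly():
    Y, stages = _group_matrix([0, 2, 2, 2, 2], 4)
    Y = pd.concat([Y, Y + 1.0])  # second gene to satisfy >= 2 genes downstream
    Y.index = ["g0", "g1"]
    fits = fit_gene_models((Y, None), build_design(stages, "baseline"))
    assert np.allclose(fits.coefficients.loc["g0"], [0, 2, 2, 2, 2], atol=1e-12)
    assert fits.sigma2["g0"] == pytest.approx(0.0, abs=1e-20)


def test_equal_weights_reduce_to_ols(rng):
    """Against a statsmodels OLS oracle, gene by gene."""
    stages = make_groups(4)
    X = build_design(stages, "baseline")
    Y = pd.DataFrame(
        rng.normal(size=(20, len(stages))), index=[f"g{i}" for i in range(20)]
    )
    Y.columns = range(len(stages))
    W = pd.DataFrame(np.full(Y.shape, 3.7), index=Y.index, columns=Y.columns)
    fits = fit_gene_models((Y, W), X)
    for g in Y.index:
        ols = sm.OLS(Y.loc[g].to_numpy(), X.to_numpy()).fit()
        assert np.allclose(fits.coefficients.loc[g], ols.params, atol=1e-10)
        # precision-weight convention: var(y_i) = sigma^2 / w_i
        assert fits.sigma2[g] == pytest.approx(ols.mse_resid * 3.7, rel=1e-10)


def test_cellmeans_coefficients_are_group_means(rng):
    stages = make_groups(5)
    X = build_design(stages, "cellmeans")
    Y = pd.DataFrame(
        rng.normal(size=(10, len(stages))), index=[f"g{i}" for i in range(10)]
    )
    Y.columns = range(len(stages))
    fits = fit_gene_models((Y, None), X)
    stages_s = pd.Series(stages)
    for g in ["control", *STAGES]:
        grp_mean = Y.loc[:, (stages_s == g).to_numpy()].mean(axis=1)
        assert np.allclose(fits.coefficients[g], grp_mean, atol=1e-12)


def test_baseline_equals_cellmeans_difference(rng):
    """Contrast identity: baseline beta_i == cellmeans beta_i - beta_0."""
    stages = make_groups(6)
    Y = pd.DataFrame(
        rng.normal(size=(15, len(stages))), index=[f"g{i}" for i in range(15)]
    )
    Y.columns = range(len(stages))
    fb = fit_gene_models((Y, None), build_design(stages, "baseline"))
    fc = fit_gene_models((Y, None), build_design(stages, "cellmeans"))
    for s in STAGES:
        assert np.allclose(
            fb.coefficients[s],
            fc.coefficients[s] - fc.coefficients["control"],
            atol=1e-10,
        )


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def test_identical_variances_posterior_unchanged(rng):
    stages = make_groups(4)
    X = build_design(stages, "baseline")
    # construct genes with exactly equal residual variance by scaling residuals
    base = rng.normal(size=len(stages))
    Y = pd.DataFrame(
        [base + i for i in range(12)], index=[f"g{i}" for i in range(12)]
    )
    Y.columns = range(len(stages))
    fits = fit_gene_models((Y, None), X)
    mf = ebayes_moderate(fits)
    # no spread in the variances: the prior df is infinite and every
    # posterior variance collapses onto the common prior variance, which the
    # log-scale moments estimator places at s^2 * exp(log(df/2) - digamma(df/2))
    assert np.isinf(mf.d0)
    from scipy.special import digamma

    df = fits.df_residual
    factor = np.exp(np.log(df / 2.0) - digamma(df / 2.0))
    assert np.allclose(mf.s2_post, fits.sigma2 * factor, rtol=1e-8)
    assert mf.s2_post.nunique() == 1


def test_moderated_t_reduces_to_ordinary_t_when_d0_zero(rng):
    stages = make_groups(4)
    X = build_design(stages, "baseline")
    Y = pd.DataFrame(
        rng.normal(size=(30, len(stages))), index=[f"g{i}" for i in range(30)]
    )
    Y.columns = range(len(stages))
    fits = fit_gene_models((Y, None), X)
    mf = ebayes_moderate(fits)
    # d0 -> 0 limit computed directly from the definitions
    ord_t = fits.coefficients["I"] / (
        fits.stdev_unscaled["I"] * np.sqrt(fits.sigma2)
    )
    lim_t = fits.coefficients["I"] / (
        fits.stdev_unscaled["I"]
        * np.sqrt((0 * mf.s02 + fits.df_residual * fits.sigma2) / (0 + fits.df_residual))
    )
    assert np.allclose(ord_t, lim_t, rtol=1e-12)


def test_null_moderated_f_pvalues_uniform(rng):
    """1,000 null genes: moderated-F p-values pass a KS uniformity check."""
    stages = make_groups(8)
    X = build_design(stages, "baseline")
    Y = pd.DataFrame(
        rng.normal(size=(1000, len(stages))), index=[f"g{i}" for i in range(1000)]
    )
    Y.columns = range(len(stages))
    mf = ebayes_moderate(fit_gene_models((Y, None), X))
    ks = stats.kstest(mf.p_F.to_numpy(), "uniform")
    assert ks.pvalue > 0.01


def test_all_zero_variances_warns_and_uses_prior():
    stages = make_groups(3)
    X = build_design(stages, "baseline")
    row = np.array([{"control": 0.0, "I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}[s]
                    for s in stages])
    Y = pd.DataFrame([row, row * 2], index=["g0", "g1"])
    Y.columns = range(len(stages))
    fits = fit_gene_models((Y, None), X)
    with pytest.warns(UserWarning, match="zero"):
        mf = ebayes_moderate(fits)
    assert np.isinf(mf.d0)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def test_bh_hand_example():
    got = adjust_bh([0.002, 0.01, 0.03, 0.04])
    assert np.allclose(got, [0.008, 0.02, 0.04, 0.04])


def test_bh_degenerate_cases():
    assert adjust_bh([0.37])[0] == pytest.approx(0.37)
    assert np.allclose(adjust_bh([0.2, 0.2, 0.2]), 0.2)


def test_bh_matches_brute_force_and_na_propagation(rng):
    p = rng.uniform(size=200)
    assert np.allclose(adjust_bh(p), brute_force_bh(p), atol=1e-12)
    with_na = p.copy()
    with_na[::7] = np.nan
    got = adjust_bh(with_na)
    mask = ~np.isnan(with_na)
    assert np.isnan(got[::7]).all()
    assert np.allclose(got[mask], brute_force_bh(p[mask]), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(OncostageError):
        adjust_bh([0.5, 1.2])


def test_bh_permutation_invariant(rng):
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))


# ---------------------------------------------------------------------------
# ranked summary
# ---------------------------------------------------------------------------

def test_summarize_recovers_planted_global_gene(mixed_dataset):
    from oncostage.pipeline import run_stagewise_analysis

    expr, truth = mixed_dataset
    res = run_stagewise_analysis(expr)
    tab = res.linear_table
    planted = truth.index[truth["planted_class"] == "global_de"]
    kept = [g for g in planted if g in tab.index]
    assert len(kept) == len(planted)
    # all planted global genes are significant and consistently signed
    assert tab.loc[kept, "significant"].all()
    for g in kept:
        expected = "UP" if truth.loc[g, "lfc_I"] > 0 else "DOWN"
        assert tab.loc[g, "status"] == expected
    # nulls dominate the bottom of the ranking
    nulls = truth.index[truth["planted_class"] == "null"]
    null_in = [g for g in nulls if g in tab.index]
    assert tab.loc[null_in, "p_F_adj"].min() > 1e-5 or \
        (tab.loc[null_in, "p_F_adj"] < 1e-5).mean() < 0.02


# ---------------------------------------------------------------------------
# limma cross-check (frozen oracle)
# ---------------------------------------------------------------------------

class TestLimmaOracle:
    """Agreement with the Bioconductor reference on the frozen fixture.

    logCPM must agree to float precision; weights and moderated statistics
    to a small relative tolerance (the lowess smoothers differ slightly);
    the joint stage F is compared loosely because the reference approximates
    all genes' coefficient correlation by a single matrix whereas this
    implementation uses each gene's exact weighted covariance.
    """

    @pytest.fixture(autouse=True)
    def _fit(self, limma_oracle):
        counts, stages, expected, meta = limma_oracle
        self.expected, self.meta = expected, meta
        X = build_design(stages, "baseline")
        self.vr = voom_transform(counts, X)
        self.mf = ebayes_moderate(fit_gene_models(self.vr, X))
        X2 = build_design(stages, "cellmeans")
        vr2 = voom_transform(counts, X2)
        mf2 = ebayes_moderate(fit_gene_models(vr2, X2))
        self.csc = apply_contrasts(mf2, make_contrast_matrix("stage_vs_control"))
        self.cbs = apply_contrasts(mf2, make_contrast_matrix("between_stages"))

    def test_logcpm_exact(self):
        assert np.allclose(
            self.vr.logcpm.iloc[:, 0], self.expected["logcpm_s00"], atol=1e-10
        )

    def test_weights_close(self):
        for col, idx in (("weight_s00", 0), ("weight_s19", 19)):
            rel = np.abs(self.vr.weights.iloc[:, idx] / self.expected[col] - 1)
            assert rel.max() < 0.01

    def test_prior_parameters(self):
        assert self.mf.d0 == pytest.approx(self.meta["d0"], rel=1e-3)
        assert self.mf.s02 == pytest.approx(self.meta["s02"], rel=1e-3)

    def test_coefficients_and_moderated_t(self):
        assert np.allclose(
            self.mf.coefficients["I"], self.expected["coef_I"], atol=5e-4
        )
        rel = np.abs(self.mf.t["I"] / self.expected["t_I"] - 1)
        assert rel.max() < 0.01
        rel_p = np.abs(self.mf.p_t["I"] / self.expected["p_I"] - 1)
        assert rel_p.max() < 0.01

    def test_stage_f(self):
        rel = np.abs(self.mf.F / self.expected["F_stage"] - 1)
        assert np.median(rel) < 0.02
        assert rel.max() < 0.2

    def test_contrast_statistics(self):
        assert np.allclose(
            self.csc.lfc["I"], self.expected["sc_lfc_I"], atol=5e-4
        )
        rel = np.abs(self.csc.p["I"] / self.expected["sc_p_I"] - 1)
        assert rel.max() < 0.01
        rel_b = np.abs(self.cbs.p["I_vs_II"] / self.expected["bs_p_I_vs_II"] - 1)
        assert rel_b.max() < 0.01
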