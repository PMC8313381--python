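import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpattern.io import FeatureMatrix
from methpattern.limma_lite import (
    LinearFit,
    VariancePrior,
    bh_adjust,
    estimate_variance_prior,
    fit_linear_models,
    moderated_statistics,
    run_moderated_analysis,
    sex_within_tissue_contrasts,
    squeeze_variances,
    tissue_sex_design,
)


def _random_matrix(layout, n_probes, seed):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(size=(n_probes, len(layout))),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=layout["sample_id"],
    )
    return FeatureMatrix(values, layout)


class TestLinearFit:
    def test_exact_fit_zero_variance(self, layout):
        X, names = tissue_sex_design(layout)
        alpha = np.arange(1.0, 7.0)
        values = pd.DataFrame(
            (X @ alpha)[None, :], index=["f0"], columns=layout["sample_id"]
        )
        fit = fit_linear_models(FeatureMatrix(values, layout), X, names)
        np.testing.assert_allclose(fit.coef[0], alpha, atol=1e-10)
        assert fit.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_two_group_difference(self):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "tissue": ["ATM"] * 3 + ["CAM"] * 3,
                "sex": ["male"] * 6,
            }
        )
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], index=["f0"],
            columns=samples["sample_id"],
        )
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        with pytest.warns(UserWarning):
            fm = FeatureMatrix(values, samples)
        fit = fit_linear_models(fm, X)
        assert fit.coef[0, 1] == pytest.approx(2.0)

    def test_df_bookkeeping(self, layout):
        X, names = tissue_sex_design(layout)
        fit = fit_linear_models(_random_matrix(layout, 5, 0), X, names)
        assert fit.df_resid == len(layout) - np.linalg.matrix_rank(X)

    def test_rank_deficient_rejected(self, layout):
        X, _ = tissue_sex_design(layout)
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            fit_linear_models(_random_matrix(layout, 2, 0), X)


class TestContrasts:
    def test_columns_sum_to_zero(self, layout):
        _, names = tissue_sex_design(layout)
        C = sex_within_tissue_contrasts(names)
        np.testing.assert_allclose(C.sum(axis=0), 0.0)

    def test_detects_cam_only_difference(self, layout):
        _, names = tissue_sex_design(layout)
        C = sex_within_tissue_contrasts(names)
        alpha = np.zeros(6)
        alpha[names.index("CAM.male")] = 1.0  # male-female gap of +1 in CAM only
        np.testing.assert_allclose(alpha @ C, [0.0, 1.0, 0.0])

    def test_equal_sexes_give_zero(self, layout):
        _, names = tissue_sex_design(layout)
        C = sex_within_tissue_contrasts(names)
        alpha = np.array([5.0, 5.0, 2.0, 2.0, -1.0, -1.0])
        np.testing.assert_allclose(alpha @ C, 0.0)

    def test_empty_cell_rejected(self):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "tissue": ["ATM", "ATM", "CAM", "CAM", "NTM", "NTM"],
                "sex": ["male"] * 6,
            }
        )
        with pytest.raises(ValueError, match="no samples"):
            tissue_sex_design(samples)


class TestVariancePrior:
    def test_simulation_recovery(self):
        rng = np.random.default_rng(4)
        d0, s0_2, d = 4.0, 1.0, 6.0
        true_var = s0_2 * d0 / rng.chisquare(d0, size=10_000)
        s2 = true_var * rng.chisquare(d, size=10_000) / d
        prior = estimate_variance_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_2 == pytest.approx(s0_2, rel=0.1)

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_variance_prior(np.full(50, 2.0), 6.0)
        assert np.isinf(prior.d0)
        assert prior.s0_2 == pytest.approx(2.0)

    def test_tight_variances_recover_scale_with_infinite_d0(self):
        # true d0 = inf: every probe shares s0^2 = 2, spread is pure chi-square
        rng = np.random.default_rng(15)
        s2 = 2.0 * rng.chisquare(6, size=20_000) / 6
        prior = estimate_variance_prior(s2, 6.0)
        assert prior.d0 > 50 or np.isinf(prior.d0)
        assert prior.s0_2 == pytest.approx(2.0, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(5, size=500)
        p1 = estimate_variance_prior(s2, 5.0)
        p2 = estimate_variance_prior(7.0 * s2, 5.0)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-6)
        assert p2.s0_2 == pytest.approx(7.0 * p1.s0_2, rel=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_variance_prior(np.zeros(10), 4.0)

    def test_shrinkage_bounds(self):
        s2 = np.array([0.1, 1.0, 10.0])
        prior = VariancePrior(d0=4.0, s0_2=1.0)
        post = squeeze_variances(s2, 4.0, prior)
        assert (post >= np.minimum(s2, 1.0)).all()
        assert (post <= np.maximum(s2, 1.0)).all()


def _toy_fit(coef, s2, df, v):
    return LinearFit(
        coef=np.atleast_2d(coef).astype(float),
        s2=np.atleast_1d(s2).astype(float),
        df_resid=float(df),
        design=np.eye(1),
        design_names=["x0"],
        xtx_inv=np.array([[v]]),
        probe_ids=pd.Index(["f0"]),
    )


class TestModeratedStatistics:
    def test_hand_worked_single_probe(self):
        # s~^2 = (4*1 + 4*1)/8 = 1, t = 2 / sqrt(0.5) = 2.828...
        fit = _toy_fit([[2.0]], [1.0], 4, 0.5)
        mod = moderated_statistics(fit, np.eye(1), VariancePrior(4.0, 1.0))
        assert mod.t[0, 0] == pytest.approx(2.0 / np.sqrt(0.5), abs=1e-12)
        assert mod.df_total == 8.0

    def test_d0_zero_equals_classical_tests(self, layout):
        matrix = _random_matrix(layout, 50, 3)
        X, names = tissue_sex_design(layout)
        fit = fit_linear_models(matrix, X, names)
        C = sex_within_tissue_contrasts(names)
        mod = moderated_statistics(fit, C, VariancePrior(d0=0.0, s0_2=1.0))
        # classical t computed independently per probe
        V = C.T @ fit.xtx_inv @ C
        t_classic = (fit.coef @ C) / np.sqrt(fit.s2[:, None] * np.diag(V)[None, :])
        p_classic = 2 * stats.t.sf(np.abs(t_classic), fit.df_resid)
        np.testing.assert_allclose(mod.t, t_classic, atol=1e-10)
        np.testing.assert_allclose(mod.p_t, p_classic, atol=1e-10)

    def test_infinite_d0_uses_normal_reference(self):
        fit = _toy_fit([[1.0]], [4.0], 4, 1.0)
        mod = moderated_statistics(fit, np.eye(1), VariancePrior(np.inf, 1.0))
        assert mod.t[0, 0] == pytest.approx(1.0)
        assert mod.p_t[0, 0] == pytest.approx(2 * stats.norm.sf(1.0))

    def test_scale_invariance_of_p_values(self, layout):
        matrix = _random_matrix(layout, 30, 6)
        mod1 = run_moderated_analysis(matrix)
        scaled = FeatureMatrix(matrix.values * 3.7, matrix.samples)
        mod2 = run_moderated_analysis(scaled)
        np.testing.assert_allclose(mod1.p_F, mod2.p_F, atol=1e-10)
        np.testing.assert_allclose(mod1.t, mod2.t, atol=1e-8)

    def test_matches_bioconductor_limma(self, layout, tmp_path):
        """Cross-check moderated t/F and the prior fit against R limma."""
        matrix = _random_matrix(layout, 40, 12)
        mod = run_moderated_analysis(matrix)
        matrix.values.to_csv(tmp_path / "y.tsv", sep="\t")
        layout.to_csv(tmp_path / "samples.csv", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("y.tsv", row.names = 1, check.names = FALSE))
            s <- read.csv("samples.csv")
            cell <- factor(paste(s$tissue, s$sex, sep = "."),
                           levels = c("ATM.male","ATM.female","CAM.male",
                                      "CAM.female","NTM.male","NTM.female"))
            X <- model.matrix(~0 + cell)
            colnames(X) <- levels(cell)
            fit <- lmFit(y, X)
            C <- makeContrasts(ATM.male - ATM.female, CAM.male - CAM.female,
                               NTM.male - NTM.female, levels = X)
            fit2 <- eBayes(contrasts.fit(fit, C))
            out <- cbind(fit2$t, F = fit2$F, p.F = fit2$F.p.value,
                         d0 = fit2$df.prior, s02 = fit2$s2.prior)
            write.csv(out, "limma_out.csv")
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        np.testing.assert_allclose(mod.prior.d0, ref["d0"].iloc[0], rtol=1e-4)
        np.testing.assert_allclose(mod.prior.s0_2, ref["s02"].iloc[0], rtol=1e-4)
        np.testing.assert_allclose(mod.t, ref.iloc[:, :3].to_numpy(), rtol=1e-5)
        np.testing.assert_allclose(mod.F, ref["F"].to_numpy(), rtol=1e-5)
        np.testing.assert_allclose(mod.p_F, ref["p.F"].to_numpy(), rtol=1e-5)


def _bh_bruteforce(p):
    """Literal step-up definition: p~_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.array(
        [min(min(1.0, m * sorted_p[j] / (j + 1)) for j in range(i, m))
         for i in range(m)]
    )
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
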