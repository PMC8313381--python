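"""Moderated t/F linear-model stage with empirical-Bayes variance shrinkage.

Per probe j an ordinary least-squares fit of the tissue-by-sex cell-means
model gives coefficients, a residual variance s_j^2 and residual degrees of
freedom d_j.  The residual variances are shrunk toward a common prior value
s0^2 with prior degrees of freedom d0, both estimated by moment matching on
log s^2 (digamma/trigamma inversion):

    s~_j^2 = (d0 * s0^2 + d_j * s_j^2) / (d0 + d_j)

The moderated t-statistic for contrast t is b_jt / (s~_j * sqrt(v_jt)),
referred to a t distribution on d_j + d0 degrees of freedom; the joint
moderated F over the three male-minus-female contrasts uses an F(3, d_j+d0)
reference.  Multiplicity is handled by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix, SEXES, TISSUES


@dataclass
class LinearFit:
    """Per-probe OLS results under a shared design matrix."""

    coef: np.ndarray          # probes x q
    s2: np.ndarray            # residual variances
    df_resid: float
    design: np.ndarray        # n x q
    design_names: list[str]
    xtx_inv: np.ndarray
    probe_ids: pd.Index


@dataclass
class VariancePrior:
    """Scaled inverse-chi-square prior for residual variances."""

    d0: float                 # prior degrees of freedom; may be inf
    s0_2: float               # prior variance


@dataclass
class ModeratedStats:
    """Moderated t/F statistics with raw and BH-adjusted p-values."""

    contrast_names: list[str]
    coef: np.ndarray          # contrast estimates, probes x 3
    s2_post: np.ndarray       # shrunken variances
    t: np.ndarray             # moderated t, probes x 3
    p_t: np.ndarray
    F: np.ndarray
    p_F: np.ndarray
    p_BH: np.ndarray
    df_total: float
    prior: VariancePrior
    probe_ids: pd.Index

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for i, name in enumerate(self.contrast_names):
            data[f"t_{name}"] = self.t[:, i]
            data[f"p_{name}"] = self.p_t[:, i]
        data["F"] = self.F
        data["p_F"] = self.p_F
        data["p_BH"] = self.p_BH
        return pd.DataFrame(data, index=self.probe_ids)


def tissue_sex_design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cell-means design matrix with one column per tissue-by-sex cell.

    Errors on an empty cell (the sex contrasts would be inestimable) and
    warns on singleton cells, which contribute no residual degrees of
    freedom of their own.
    """
    names, cols = [], []
    for tissue in TISSUES:
        for sex in SEXES:
            ind = ((samples["tissue"] == tissue) & (samples["sex"] == sex)).to_numpy()
            n_cell = int(ind.sum())
            if n_cell == 0:
                raise ValueError(f"design cell {tissue}:{sex} has no samples")
            if n_cell == 1:
                warnings.warn(
                    f"design cell {tissue}:{sex} has a single sample", stacklevel=2
                )
            names.append(f"{tissue}.{sex}")
            cols.append(ind.astype(float))
    return np.column_stack(cols), names


def sex_within_tissue_contrasts(design_names: list[str]) -> np.ndarray:
    """Contrast matrix with one male-minus-female column per tissue."""
    C = np.zeros((len(design_names), len(TISSUES)))
    for t, tissue in enumerate(TISSUES):
        C[design_names.index(f"{tissue}.male"), t] = 1.0
        C[design_names.index(f"{tissue}.female"), t] = -1.0
    return C


def fit_linear_models(matrix: FeatureMatrix, design: np.ndarray,
                      design_names: list[str] | None = None) -> LinearFit:
    """Ordinary least squares of every probe on a shared design matrix."""
    X = np.asarray(design, dtype=float)
    n, q = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {q} columns)"
        )
    if n <= rank:
        raise ValueError("need more samples than design columns")
    Y = matrix.values.to_numpy(dtype=float)
    xtx = X.T @ X
    xtx_inv = linalg.inv(xtx)
    coef = Y @ X @ xtx_inv.T        # (p, q); OLS via normal equations
    resid = Y - coef @ X.T
    df_resid = n - rank
    s2 = (resid**2).sum(axis=1) / df_resid
    if design_names is None:
        design_names = [f"x{i}" for i in range(q)]
    return LinearFit(
        coef=coef,
        s2=s2,
        df_resid=float(df_resid),
        design=X,
        design_names=list(design_names),
        xtx_inv=xtx_inv,
        probe_ids=matrix.feature_ids,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(s2, df) -> VariancePrior:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Matches the mean and spread of log s^2 against the sampling moments of a
    scaled chi-square on df degrees of freedom using digamma/trigamma
    identities.  When the observed spread is at or below the pure sampling
    floor the prior degrees of freedom are infinite (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero")
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero residual variance(s) excluded from the "
            "prior fit",
            stacklevel=2,
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        # no excess spread beyond chi-square sampling: a single common
        # variance, best estimated by the plain mean
        return VariancePrior(d0=np.inf, s0_2=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_2=s0_2)


def squeeze_variances(s2, df, prior: VariancePrior) -> np.ndarray:
    """Posterior (shrunken) residual variances under the fitted prior."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_2)
    return (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)


def moderated_statistics(
    fit: LinearFit,
    contrasts: np.ndarray,
    prior: VariancePrior | None = None,
    contrast_names: list[str] | None = None,
) -> ModeratedStats:
    """Moderated t per contrast and joint moderated F across all contrasts.

    With ``prior.d0 = 0`` the statistics reduce to the classical per-probe
    tests; with infinite d0 the t reference becomes standard normal (the
    chi-square limit of the F).
    """
    C = np.asarray(contrasts, dtype=float)
    if prior is None:
        prior = estimate_variance_prior(fit.s2, fit.df_resid)
    if prior.d0 < 0 or prior.s0_2 < 0:
        raise ValueError("variance prior must be nonnegative")
    df_total = fit.df_resid + prior.d0
    if df_total <= 0:
        raise ValueError("total degrees of freedom d_j + d0 must be positive")
    B = fit.coef @ C                                   # (p, r)
    V = C.T @ fit.xtx_inv @ C                          # (r, r) unscaled covariance
    v_diag = np.diag(V)
    if np.any(v_diag <= 0):
        raise ValueError("contrast variances must be positive")
    s2_post = squeeze_variances(fit.s2, fit.df_resid, prior)
    t = B / np.sqrt(s2_post[:, None] * v_diag[None, :])
    r = C.shape[1]
    # quadratic form B V^{-1} B' per probe via a Cholesky solve
    solve = linalg.cho_solve(linalg.cho_factor(V), B.T)  # (r, p)
    quad = np.einsum("pr,rp->p", B, solve)
    F = quad / (r * s2_post)
    if np.isinf(df_total):
        p_t = 2.0 * stats.norm.sf(np.abs(t))
        p_F = stats.chi2.sf(r * F, r)
    else:
        p_t = 2.0 * stats.t.sf(np.abs(t), df_total)
        p_F = stats.f.sf(F, r, df_total)
    names = contrast_names or [f"c{i}" for i in range(r)]
    return ModeratedStats(
        contrast_names=list(names),
        coef=B,
        s2_post=s2_post,
        t=t,
        p_t=p_t,
        F=F,
        p_F=p_F,
        p_BH=bh_adjust(p_F),
        df_total=float(df_total),
        prior=prior,
        probe_ids=fit.probe_ids,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_moderated_analysis(matrix: FeatureMatrix) -> ModeratedStats:
    """Full small-sample pipeline: cell-means fit, prior estimate, moderation."""
    X, names = tissue_sex_design(matrix.samples)
    fit = fit_linear_models(matrix, X, names)
    prior = estimate_variance_prior(fit.s2, fit.df_resid)
    C = sex_within_tissue_contrasts(names)
    return moderated_statistics(
        fit, C, prior, contrast_names=[f"{t}.male-female" for t in TISSUES]
    )
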