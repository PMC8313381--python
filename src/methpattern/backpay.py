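"""Sign-constrained Bayesian mixture clustering of methylation trajectories.

Each probe's M-values in a sex stratum s follow, given membership in
trajectory cluster h,

    y_jsi = a_js + x_si1 * b_sh1 + x_si2 * b_sh2 + e_jsih,
    e_jsih ~ Normal(0, sigma_h^2),

where x_si1 / x_si2 indicate ATM / NTM samples (CAM is the reference).  The
nine clusters are defined by the *signs* of the slope pair (b_js1, b_js2):
a coordinate whose sign is zero carries a point mass at 0 ("flat"), a
nonzero-sign coordinate carries a probe-level half-normal prior with
cluster-level precision tau_sh, truncated to that sign.  Because the
components are identified by fixed sign constraints, the mixture has no
label-switching problem and posterior summaries need no relabelling.

Inference is by Gibbs sampling with a blocked membership update: the
membership z_js is drawn from the component likelihood with the probe's own
slopes integrated out in closed form (a truncated-normal integral), then
the slopes are redrawn conditional on the new membership.  Marginalising
the slopes is what separates a flat coordinate from a sign-constrained one
near zero — the integral carries the Occam factor that a conditional
likelihood at a near-zero slope would miss.  The per-probe pair of cluster
memberships across the two strata defines one of 81 patterns; posterior
pattern probabilities are empirical frequencies over retained draws.
Probes are ranked by their posterior probability of the null
FlatFlat-FlatFlat pattern, converted to Bayesian q-values (estimated
Bayesian FDR), and selected when the q-value is small and a non-null
pattern has high posterior probability.

Priors
------
b_jsk | tau_sh ~ half-Normal(precision tau_sh), sign-truncated (0 if flat)
tau_sh ~ Gamma(shape=7, rate=5)        slope precision (prior mean 1.4)
sigma_h^2 ~ Inverse-Gamma(2, b0)       cluster noise variance
b0 ~ Gamma(2, 2)                       hierarchical variance scale
a_js ~ Normal(stratum probe mean, 10)  probe-specific intercept
pi_s ~ Dirichlet(1, ..., 1)            per-stratum mixture weights

The hierarchical rate b0 keeps momentarily empty clusters' noise variances
on the scale of the data rather than a fixed prior scale, which would
otherwise create one-way traps for membership moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

from .io import FeatureMatrix, SEXES
from .patterns import (
    CLUSTER_SIGNS,
    FLAT_FLAT,
    N_CLUSTERS,
    PATTERN_NAMES,
    DesignEncoding,
    Pattern,
    encode_design,
)

_SIGNS = np.array(CLUSTER_SIGNS)          # (9, 2) slope signs per cluster
_FREE = _SIGNS != 0                       # coordinates with a sampled slope
NULL_INDEX = FLAT_FLAT * N_CLUSTERS + FLAT_FLAT


@dataclass(frozen=True)
class BackpayConfig:
    """Sampler configuration.

    ``n_iter`` Gibbs sweeps are run and the first ``burn_in`` discarded.
    ``a_tau``/``b_tau`` are the shape/rate of the Gamma prior on the slope
    precisions (default mean 7/5 = 1.4).  ``pb`` is the minimum posterior
    pattern probability and ``q_cut`` the Bayesian q-value cutoff used by
    :func:`select_differential`.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    a_tau: float = 7.0
    b_tau: float = 5.0
    pb: float = 0.5
    q_cut: float = 0.05
    seed: int = 0
    intercept_prior_var: float = 10.0
    sigma2_shape: float = 2.0
    sigma2_rate: float = 1.0          # initial value of the hierarchical rate b0
    b0_prior_shape: float = 2.0
    b0_prior_rate: float = 2.0
    init_threshold: float = 0.3
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_iter <= self.burn_in:
            raise ValueError("need 0 <= burn_in < n_iter")
        if not 0 < self.pb < 1:
            raise ValueError("pb must be in (0, 1)")
        if not 0 < self.q_cut <= 1:
            raise ValueError("q_cut must be in (0, 1]")
        for name in ("a_tau", "b_tau", "intercept_prior_var", "sigma2_shape",
                     "sigma2_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_prior_mean(self) -> float:
        return self.a_tau / self.b_tau


@dataclass
class BackpayPosterior:
    """Posterior summaries of a Gibbs run.

    ``pattern_probs`` is probes x 81 (columns in the canonical pattern
    enumeration, male cluster major).  ``p0`` is the posterior probability of
    the null pattern, ``q_values`` the derived Bayesian q-values,
    ``map_pattern``/``pma`` the modal pattern and its probability.
    """

    probe_ids: pd.Index
    pattern_probs: pd.DataFrame
    p0: pd.Series
    q_values: pd.Series
    map_pattern: pd.Series
    pma: pd.Series
    n_retained: int
    config: BackpayConfig
    summaries: dict = field(default_factory=dict, repr=False)
    z_draws: np.ndarray | None = field(default=None, repr=False)


def log_component_likelihood(y, design, intercept, beta, sigma2) -> float:
    """Gaussian log-likelihood of one probe-stratum vector under one cluster.

    ``design`` is the n x 2 ATM/NTM indicator matrix; ``beta`` the cluster's
    slope pair (flat coordinates are zero).
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    y = np.asarray(y, dtype=float)
    mu = intercept + np.asarray(design, dtype=float) @ np.asarray(beta, dtype=float)
    resid = y - mu
    n = y.shape[0]
    return float(-0.5 * np.sum(resid**2) / sigma2 - 0.5 * n * np.log(2 * np.pi * sigma2))


def _sample_truncated_normal(rng, mean, sd, sign):
    """Vectorised draw from Normal(mean, sd^2) truncated to the given signs."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    sign = np.asarray(sign)
    lo = np.where(sign > 0, (0.0 - mean) / sd, -np.inf)
    hi = np.where(sign > 0, np.inf, (0.0 - mean) / sd)
    return stats.truncnorm.rvs(lo, hi, loc=mean, scale=sd, random_state=rng)


def _initial_state(Y, X, config):
    """Deterministic data-driven starting point for one stratum.

    Memberships start at the sign pattern of the observed segment estimates
    thresholded at ``init_threshold``; probe slopes start at the sign-clipped
    estimates themselves.
    """
    p = Y.shape[0]
    atm = X[:, 0] == 1
    ntm = X[:, 1] == 1
    cam = ~(atm | ntm)
    a0 = Y[:, cam].mean(axis=1) if cam.any() else Y.mean(axis=1)
    b1 = Y[:, atm].mean(axis=1) - a0 if atm.any() else np.zeros(p)
    b2 = Y[:, ntm].mean(axis=1) - a0 if ntm.any() else np.zeros(p)
    t = config.init_threshold
    g1 = np.where(b1 > t, 1, np.where(b1 < -t, -1, 0))
    g2 = np.where(b2 > t, 1, np.where(b2 < -t, -1, 0))
    sign_to_idx = {s: i for i, s in enumerate(CLUSTER_SIGNS)}
    z = np.array([sign_to_idx[(s1, s2)] for s1, s2 in zip(g1, g2)])
    beta = np.zeros((p, 2))
    for k, bhat in enumerate((b1, b2)):
        sign = _SIGNS[z, k]
        beta[:, k] = np.where(sign != 0, sign * np.maximum(sign * bhat, 0.05), 0.0)
    return z, a0.copy(), beta


def run_mcmc(
    matrix: FeatureMatrix,
    config: BackpayConfig,
    design: DesignEncoding | None = None,
) -> BackpayPosterior:
    """Run the Gibbs sampler and summarise the posterior.

    Identical data, configuration and seed yield an identical posterior.
    """
    if design is None:
        design = encode_design(matrix.samples)
    data = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("input matrix contains non-finite values")
    p = data.shape[0]
    if p == 0:
        raise ValueError("input matrix has no features")

    rng = np.random.default_rng(config.seed)
    strata = list(design.strata)
    Y = {s: data[:, design.columns[s]] for s in strata}
    X = {s: design.design[s] for s in strata}
    n_s = {s: Y[s].shape[1] for s in strata}
    # per-coordinate sample masks (a sample informs slope k iff x_k = 1)
    coord_cols = {s: [X[s][:, k] == 1 for k in range(2)] for s in strata}
    n_coord = {s: np.array([m.sum() for m in coord_cols[s]]) for s in strata}

    z: dict[str, np.ndarray] = {}
    a: dict[str, np.ndarray] = {}
    beta: dict[str, np.ndarray] = {}          # per-probe slopes, (p, 2)
    m0: dict[str, np.ndarray] = {}
    resid_init = []
    for s in strata:
        z[s], a[s], beta[s] = _initial_state(Y[s], X[s], config)
        m0[s] = Y[s].mean(axis=1)
        mu = beta[s] @ X[s].T
        resid_init.append((Y[s] - a[s][:, None] - mu).ravel())
    tau = {s: np.full(N_CLUSTERS, config.tau_prior_mean) for s in strata}
    pi = {s: np.full(N_CLUSTERS, 1.0 / N_CLUSTERS) for s in strata}
    sigma2 = np.full(
        N_CLUSTERS, max(float(np.var(np.concatenate(resid_init))), 1e-3)
    )
    b0 = config.sigma2_rate

    v_a = config.intercept_prior_var
    a_sig = config.sigma2_shape
    n_retained = config.n_iter - config.burn_in
    pattern_counts = np.zeros((p, N_CLUSTERS**2), dtype=np.int64)
    rows = np.arange(p)
    draws = (
        np.empty((n_retained, p, 2), dtype=np.int8) if config.keep_draws else None
    )
    # running posterior-mean accumulators for diagnostics
    acc = {
        "beta": {s: np.zeros((p, 2)) for s in strata},
        "tau": {s: np.zeros(N_CLUSTERS) for s in strata},
        "sigma2": np.zeros(N_CLUSTERS),
        "b0": 0.0,
    }

    log2pi = np.log(2 * np.pi)
    for it in range(config.n_iter):
        # --- mixture weights ---
        for s in strata:
            counts = np.bincount(z[s], minlength=N_CLUSTERS)
            pi[s] = rng.dirichlet(1.0 + counts)

        # --- blocked membership + slope update (slopes integrated out) ---
        for s in strata:
            resid = Y[s] - a[s][:, None]               # (p, n_s)
            ss_total = (resid**2).sum(axis=1)
            S = np.column_stack(
                [resid[:, coord_cols[s][k]].sum(axis=1) for k in range(2)]
            )                                          # (p, 2)
            # base: all observations at their flat means
            loglik = (
                -0.5 * ss_total[:, None] / sigma2[None, :]
                - 0.5 * n_s[s] * (log2pi + np.log(sigma2))[None, :]
            )
            prec = {}
            mu_star = {}
            for k in range(2):
                prec_k = n_coord[s][k] / sigma2 + tau[s]          # (9,)
                mu_k = (S[:, k][:, None] / sigma2[None, :]) / prec_k[None, :]
                # marginal correction for a sign-constrained coordinate:
                # Gaussian integral over the half-normal slope prior
                corr = (
                    0.5 * mu_k**2 * prec_k[None, :]
                    + 0.5 * (np.log(tau[s]) - np.log(prec_k))[None, :]
                    + np.log(2.0)
                    + log_ndtr(_SIGNS[:, k][None, :] * mu_k * np.sqrt(prec_k)[None, :])
                )
                loglik += np.where(_FREE[:, k][None, :], corr, 0.0)
                prec[k], mu_star[k] = prec_k, mu_k
            logw = np.log(pi[s])[None, :] + loglik
            z[s] = np.argmax(logw + rng.gumbel(size=logw.shape), axis=1)
            # redraw the probe slopes conditional on the new memberships
            new_beta = np.zeros((p, 2))
            for k in range(2):
                sign_k = _SIGNS[z[s], k]
                free = sign_k != 0
                if free.any():
                    prec_p = prec[k][z[s][free]]
                    mu_p = mu_star[k][free, z[s][free]]
                    new_beta[free, k] = _sample_truncated_normal(
                        rng, mu_p, 1.0 / np.sqrt(prec_p), sign_k[free]
                    )
            beta[s] = new_beta

        # --- intercepts ---
        for s in strata:
            mu_z = beta[s] @ X[s].T                    # (p, n_s)
            sig_z = sigma2[z[s]]
            prec_a = n_s[s] / sig_z + 1.0 / v_a
            mean_a = ((Y[s] - mu_z).sum(axis=1) / sig_z + m0[s] / v_a) / prec_a
            a[s] = mean_a + rng.standard_normal(p) / np.sqrt(prec_a)

        # --- slope precisions ---
        for s in strata:
            member_counts = np.bincount(z[s], minlength=N_CLUSTERS)
            for h in range(N_CLUSTERS):
                n_free = int(_FREE[h].sum())
                if member_counts[h] == 0 or n_free == 0:
                    tau[s][h] = rng.gamma(config.a_tau, 1.0 / config.b_tau)
                    continue
                members = z[s] == h
                ssq = float(np.sum(beta[s][members][:, _FREE[h]] ** 2))
                tau[s][h] = rng.gamma(
                    config.a_tau + 0.5 * n_free * member_counts[h],
                    1.0 / (config.b_tau + 0.5 * ssq),
                )

        # --- cluster noise variances (pooled over strata) ---
        ssr_h = np.zeros(N_CLUSTERS)
        n_h = np.zeros(N_CLUSTERS)
        for s in strata:
            mu_z = beta[s] @ X[s].T
            row_ssr = ((Y[s] - a[s][:, None] - mu_z) ** 2).sum(axis=1)
            ssr_h += np.bincount(z[s], weights=row_ssr, minlength=N_CLUSTERS)
            n_h += np.bincount(z[s], minlength=N_CLUSTERS) * n_s[s]
        sigma2 = 1.0 / rng.gamma(a_sig + 0.5 * n_h, 1.0 / (b0 + 0.5 * ssr_h))
        # hierarchical rate keeps empty clusters on the data's variance scale
        b0 = rng.gamma(
            config.b0_prior_shape + N_CLUSTERS * a_sig,
            1.0 / (config.b0_prior_rate + np.sum(1.0 / sigma2)),
        )

        # --- accumulate retained draws ---
        if it >= config.burn_in:
            pair = z[strata[0]] * N_CLUSTERS + z[strata[1]]
            np.add.at(pattern_counts, (rows, pair), 1)
            if draws is not None:
                idx = it - config.burn_in
                draws[idx, :, 0] = z[strata[0]]
                draws[idx, :, 1] = z[strata[1]]
            for s in strata:
                acc["beta"][s] += beta[s]
                acc["tau"][s] += tau[s]
            acc["sigma2"] += sigma2
            acc["b0"] += b0

    probs = pattern_counts / float(n_retained)
    probe_ids = matrix.feature_ids
    probs_df = pd.DataFrame(probs, index=probe_ids, columns=list(PATTERN_NAMES))
    p0 = pd.Series(probs[:, NULL_INDEX], index=probe_ids, name="p0")
    q = pd.Series(bayesian_qvalues(p0.to_numpy()), index=probe_ids, name="q_value")
    map_idx = probs.argmax(axis=1)
    map_pattern = pd.Series(
        [PATTERN_NAMES[i] for i in map_idx], index=probe_ids, name="pattern"
    )
    pma = pd.Series(probs[rows, map_idx], index=probe_ids, name="probability")
    summaries = {
        "beta_mean": {s: acc["beta"][s] / n_retained for s in strata},
        "tau_mean": {s: acc["tau"][s] / n_retained for s in strata},
        "sigma2_mean": acc["sigma2"] / n_retained,
        "b0_mean": acc["b0"] / n_retained,
    }
    return BackpayPosterior(
        probe_ids=probe_ids,
        pattern_probs=probs_df,
        p0=p0,
        q_values=q,
        map_pattern=map_pattern,
        pma=pma,
        n_retained=n_retained,
        config=config,
        summaries=summaries,
        z_draws=draws,
    )


def pattern_probabilities(z_draws: np.ndarray):
    """Empirical pattern frequencies from retained membership draws.

    ``z_draws`` has shape (n_draws, n_probes, 2) with cluster indices for the
    (male, female) strata.  Returns ``(probs, pma, map_index)`` where
    ``probs`` is probes x 81, each row summing to one, ``pma`` the per-probe
    maximum probability and ``map_index`` its pattern index (ties resolved to
    the lowest index).
    """
    z_draws = np.asarray(z_draws)
    if z_draws.ndim != 3 or z_draws.shape[0] == 0 or z_draws.shape[2] != 2:
        raise ValueError("z_draws must be a non-empty (n_draws, n_probes, 2) array")
    n_draws, p, _ = z_draws.shape
    pair = z_draws[:, :, 0].astype(np.int64) * N_CLUSTERS + z_draws[:, :, 1]
    probs = np.zeros((p, N_CLUSTERS**2))
    for j in range(p):
        probs[j] = np.bincount(pair[:, j], minlength=N_CLUSTERS**2)
    probs /= n_draws
    map_index = probs.argmax(axis=1)
    pma = probs[np.arange(p), map_index]
    return probs, pma, map_index


def marginal_cluster_probabilities(probs: np.ndarray, stratum: str) -> np.ndarray:
    """Per-probe marginal cluster probabilities for one stratum.

    Sums the 81-pattern probabilities over the other stratum's cluster.
    """
    arr = np.asarray(probs).reshape(-1, N_CLUSTERS, N_CLUSTERS)
    if stratum == SEXES[0]:
        return arr.sum(axis=2)
    if stratum == SEXES[1]:
        return arr.sum(axis=1)
    raise ValueError(f"unknown stratum {stratum!r}")


def bayesian_qvalues(p0) -> np.ndarray:
    """Bayesian q-values from posterior null probabilities.

    Sort the null probabilities ascending; the q-value at rank r is the mean
    of the r smallest values — the estimated Bayesian FDR incurred by calling
    every probe up to that rank.  Tied null probabilities share the
    cumulative mean at the last tied rank.  Values are mapped back to the
    input order.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.size == 0:
        return p0.copy()
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("null probabilities must lie in [0, 1]")
    order = np.argsort(p0, kind="stable")
    sorted_p0 = p0[order]
    cum = np.cumsum(sorted_p0) / np.arange(1, p0.size + 1)
    last_tied = np.searchsorted(sorted_p0, sorted_p0, side="right") - 1
    q_sorted = cum[last_tied]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def select_differential(
    posterior: BackpayPosterior,
    pb: float | None = None,
    q_cut: float | None = None,
) -> pd.DataFrame:
    """Per-probe assignment table with the differential-call flag.

    A probe is selected when its q-value is below ``q_cut``, its modal
    pattern is not the null FlatFlat-FlatFlat pattern and that pattern's
    posterior probability exceeds ``pb``.
    """
    pb = posterior.config.pb if pb is None else pb
    q_cut = posterior.config.q_cut if q_cut is None else q_cut
    table = pd.DataFrame(
        {
            "probe_id": posterior.probe_ids,
            "pattern": posterior.map_pattern.to_numpy(),
            "probability": posterior.pma.to_numpy(),
            "q_value": posterior.q_values.to_numpy(),
            "p0": posterior.p0.to_numpy(),
        }
    )
    non_null = table["pattern"] != str(Pattern("FlatFlat", "FlatFlat"))
    table["selected"] = (
        (table["q_value"] < q_cut) & non_null & (table["probability"] > pb)
    )
    return table


def per_pattern_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and maximum membership probability per pattern among selected probes."""
    sel = table.loc[table["selected"]]
    if sel.empty:
        return pd.DataFrame(columns=["pattern", "n_probes", "pma"])
    grouped = sel.groupby("pattern", sort=True)["probability"]
    out = grouped.agg(n_probes="size", pma="max").reset_index()
    return out.sort_values("n_probes", ascending=False, ignore_index=True)
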