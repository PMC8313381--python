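"""Univariate Cox proportional-hazards screening and Kaplan-Meier summaries.

Candidate genes from the pattern analysis are screened one at a time against
overall survival with the hazard model h(t) = h0(t) * exp(b1 * X1), X1 being
the gene's (continuous) expression.  The Breslow partial likelihood is
maximised by Newton-Raphson; Wald p-values are adjusted across genes by
Benjamini-Hochberg.  For presentation, expression can be dichotomised at a
user-chosen threshold and per-group Kaplan-Meier curves exported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .limma_lite import bh_adjust

#: cap on |b1| used to flag monotone (perfectly separating) likelihoods
_B_CAP = 20.0


@dataclass
class CoxFit:
    """Univariate Cox fit: log hazard ratio, its SE and Wald p-value."""

    b1: float
    se: float
    wald_p: float
    converged: bool
    n_events: int
    n: int
    degenerate: bool = False


def _breslow_loglik_parts(b: float, time, event, x):
    """Breslow partial log-likelihood with gradient and negative Hessian.

    Each event contributes b*x_i - log(sum over the risk set of exp(b*x_j));
    tied event times share one risk set but contribute one log-denominator
    per event.
    """
    order = np.argsort(-time, kind="stable")
    t_s, e_s, x_s = time[order], event[order], x[order]
    eta = b * x_s
    eta -= eta.max()  # stabilise; constant cancels in all three quantities
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x_s)
    cwx2 = np.cumsum(w * x_s**2)
    # risk set for an event at time t = all subjects with time >= t; with the
    # descending sort that is the prefix up to the last index sharing time t
    last = np.searchsorted(-t_s, -t_s, side="right") - 1
    ev = e_s == 1
    s0 = cw[last][ev]
    s1 = cwx[last][ev]
    s2m = cwx2[last][ev]
    loglik = float(np.sum(eta[ev] - np.log(s0)))
    grad = float(np.sum(x_s[ev] - s1 / s0))
    info = float(np.sum(s2m / s0 - (s1 / s0) ** 2))
    return loglik, grad, info


def cox_fit_univariate(
    time, event, x, tol: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Fit h(t) = h0(t) exp(b1 x) by Newton-Raphson on the Breslow partial
    likelihood.

    Raises when there are no events.  A covariate that is constant within
    every risk set yields a degenerate fit (b1 = 0, infinite SE, p = 1).  A
    monotone likelihood (perfect separation) is flagged non-converged with
    the estimate capped at +/-20.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    x = np.asarray(x, dtype=float)
    if time.shape != event.shape or time.shape != x.shape:
        raise ValueError("time, event and x must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    n_events = int(np.sum(event == 1))
    if n_events == 0:
        raise ValueError("no events observed; b1 is not estimable")
    _, _, info0 = _breslow_loglik_parts(0.0, time, event, x)
    if info0 <= 0:
        return CoxFit(
            b1=0.0, se=np.inf, wald_p=1.0, converged=False,
            n_events=n_events, n=time.size, degenerate=True,
        )
    b = 0.0
    converged = False
    for _ in range(max_iter):
        _, grad, info = _breslow_loglik_parts(b, time, event, x)
        if info <= 0:
            break
        step = grad / info
        # damp huge steps early on; the likelihood is concave so this is safe
        step = float(np.clip(step, -5.0, 5.0))
        b += step
        if abs(b) > _B_CAP:
            b = float(np.sign(b) * _B_CAP)
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _breslow_loglik_parts(b, time, event, x)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = b / se if np.isfinite(se) and se > 0 else 0.0
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(
        b1=float(b), se=float(se), wald_p=wald_p, converged=converged,
        n_events=n_events, n=time.size,
    )


def screen_genes(
    expression: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Univariate Cox screen of every gene against overall survival.

    ``expression`` is gene-by-subject; ``survival`` needs columns
    ``subject_id``, ``time`` and ``event`` covering exactly the expression
    columns.  Returns one row per gene with b1, SE, Wald p, BH-adjusted p and
    a sign column: "+" means higher expression is associated with *longer*
    survival (negative log hazard ratio), "-" the opposite.
    """
    surv = survival.set_index("subject_id")
    if set(expression.columns) != set(surv.index):
        raise ValueError("expression columns and survival subject_ids differ")
    surv = surv.loc[list(expression.columns)]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    rows = []
    for gene, values in expression.iterrows():
        fit = cox_fit_univariate(time, event, values.to_numpy(dtype=float))
        rows.append(
            {
                "gene": gene,
                "b1": fit.b1,
                "se": fit.se,
                "p": fit.wald_p,
                "converged": fit.converged,
                "sign": "+" if fit.b1 < 0 else "-",
            }
        )
    table = pd.DataFrame(rows)
    table["p_BH"] = bh_adjust(table["p"].to_numpy())
    return table.loc[:, ["gene", "b1", "se", "p", "p_BH", "sign", "converged"]]


def dichotomize(values, threshold: float) -> np.ndarray:
    """Split expression at a threshold: <= threshold -> "low", else "high"."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = np.asarray(values, dtype=float)
    labels = np.where(values <= threshold, "low", "high")
    if len(np.unique(labels)) < 2:
        warnings.warn(
            f"threshold {threshold} puts all subjects in one group", stacklevel=2
        )
    return labels


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival, at_risk) table.

    One row per distinct event time; the curve starts at 1 and drops only at
    event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    event_times = np.unique(time[np.asarray(event) == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(time >= t).sum() for t in event_times])
    return pd.DataFrame({"time": event_times, "survival": surv, "at_risk": at_risk})


def km_by_group(time, event, groups) -> pd.DataFrame:
    """Per-group Kaplan-Meier curves stacked in long format."""
    groups = np.asarray(groups)
    out = []
    for g in np.unique(groups):
        mask = groups == g
        curve = km_estimate(np.asarray(time)[mask], np.asarray(event)[mask])
        curve.insert(0, "group", g)
        out.append(curve)
    return pd.concat(out, ignore_index=True)
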