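"""Methylation quantification scales.

Illumina arrays report per-probe intensities for the methylated (M) and
unmethylated (U) alleles.  The beta-value

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + offset)

is the proportion-scale methylation level (offset 100 stabilises low-intensity
probes and keeps beta strictly below 1).  The M-value is its log2-odds
transform, M = log2(beta / (1 - beta)), the statistically better-behaved scale
for differential analysis: 0 means half-methylated, positive values mean a
methylation rate above 50%.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

#: clipping bound applied to beta-values of exactly 0 or 1 before the logit
BETA_EPS = 1e-6

#: conventional beta thresholds for hypo- and hypermethylation calls
HYPO_THRESHOLD = 0.2
HYPER_THRESHOLD = 0.8


def _maybe_scalar(x, arr):
    return arr.item() if np.ndim(x) == 0 else arr


def beta_from_intensities(meth, unmeth, offset: float = 100.0):
    """Beta-value from allele intensities; intensities are clamped at zero.

    Parameters
    ----------
    meth, unmeth
        Methylated / unmethylated signal intensities (scalar or array).
    offset
        Positive stabilising constant added to the denominator.
    """
    if not np.isscalar(offset) or offset <= 0:
        raise ValueError(f"offset must be a positive scalar, got {offset!r}")
    m = np.maximum(np.asarray(meth, dtype=float), 0.0)
    u = np.maximum(np.asarray(unmeth, dtype=float), 0.0)
    beta = m / (m + u + offset)
    return _maybe_scalar(meth, beta)


def m_from_beta(beta, clip: bool = True):
    """Logit (base 2) transform of beta-values.

    Beta-values of exactly 0 or 1 cannot be mapped to a finite M-value; with
    ``clip=True`` (default) they are clipped to ``[BETA_EPS, 1 - BETA_EPS]``
    with a warning, otherwise a :class:`ValueError` is raised.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(b < 0) or np.any(b > 1):
        raise ValueError("beta-values must lie in [0, 1]")
    at_bound = (b == 0) | (b == 1)
    if np.any(at_bound):
        if not clip:
            raise ValueError("beta-values of exactly 0 or 1 have no finite M-value")
        warnings.warn(
            f"{int(np.sum(at_bound))} beta-value(s) at 0 or 1 clipped to "
            f"[{BETA_EPS}, {1 - BETA_EPS}] before the logit transform",
            stacklevel=2,
        )
        b = np.clip(b, BETA_EPS, 1 - BETA_EPS)
    m = np.log2(b / (1.0 - b))
    return _maybe_scalar(beta, m)


def beta_from_m(m):
    """Inverse logit: beta = 2**M / (1 + 2**M), strictly inside (0, 1)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("M-values must be finite")
    # expit formulation avoids overflow for large |M|
    beta = expit(np.log(2.0) * arr)
    return _maybe_scalar(m, beta)


def classify_methylation(beta, lo: float = HYPO_THRESHOLD, hi: float = HYPER_THRESHOLD):
    """Classify beta-values as ``hypo`` (< lo), ``hyper`` (> hi) or ``intermediate``.

    Boundary values are intermediate (strict inequalities).
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    b = np.asarray(beta, dtype=float)
    out = np.full(b.shape, "intermediate", dtype=object)
    out[b < lo] = "hypo"
    out[b > hi] = "hyper"
    return _maybe_scalar(beta, out)
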