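"""Missing-value removal and per-feature one-way ANOVA filtering.

The pre-screen keeps features whose mean level differs among the three
tissue types (classical one-way F-test, p < alpha, sexes pooled).  It is the
step that reduces a genome-wide matrix to the working set handed to the
pattern model and the moderated linear-model stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureMatrix

DEFAULT_ALPHA = 0.05


def drop_missing_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Remove features with any missing value; row order is preserved."""
    keep = matrix.values.notna().all(axis=1)
    if not keep.any():
        warnings.warn("all features contain missing values; result is empty",
                      stacklevel=2)
    return FeatureMatrix(matrix.values.loc[keep], matrix.samples)


@dataclass
class AnovaResult:
    F: float
    p: float
    degenerate: bool = False


def _anova_arrays(values: np.ndarray, groups: np.ndarray):
    """Vectorised one-way ANOVA across the rows of ``values``.

    Returns (F, p, degenerate) arrays.  Degenerate rows are those with zero
    within-group variance: p = 0 if the between-group sum of squares is
    positive (perfect separation), p = 1 if all values are identical.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    labels = np.unique(groups)
    k = len(labels)
    n = values.shape[1]
    if k < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if n - k < 1:
        raise ValueError("not enough residual degrees of freedom")
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in labels:
        cols = values[:, groups == g]
        gmean = cols.mean(axis=1, keepdims=True)
        ssb += cols.shape[1] * (gmean - grand)[:, 0] ** 2
        ssw += ((cols - gmean) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / (ssw / (n - k))
    p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0),
                                            k - 1, n - k), np.nan)
    degenerate = ssw == 0
    # zero within-group variance: separation if between-SS > 0, else constant
    p = np.where(degenerate & (ssb > 0), 0.0, p)
    p = np.where(degenerate & (ssb == 0), 1.0, p)
    F = np.where(degenerate & (ssb == 0), np.nan, F)
    return F, p, degenerate


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA of a single feature across group labels."""
    F, p, degenerate = _anova_arrays(np.asarray(values, dtype=float),
                                     np.asarray(groups))
    return AnovaResult(F=float(F[0]), p=float(p[0]), degenerate=bool(degenerate[0]))


def anova_table(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-feature tissue-type ANOVA table with columns F, p, degenerate."""
    groups = matrix.tissue_labels().to_numpy()
    F, p, degenerate = _anova_arrays(matrix.values.to_numpy(), groups)
    return pd.DataFrame(
        {"F": F, "p": p, "degenerate": degenerate}, index=matrix.feature_ids
    )


def anova_filter(
    matrix: FeatureMatrix, alpha: float = DEFAULT_ALPHA
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Keep features with tissue-type ANOVA p strictly below ``alpha``.

    Returns the filtered matrix and the full per-feature (F, p) table.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    table = anova_table(matrix)
    keep = table.index[table["p"] < alpha]
    return matrix.subset(keep), table
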