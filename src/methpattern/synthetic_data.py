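"""Ground-truth simulators for every pipeline stage.

The methylation generator runs the trajectory mixture model forward: each
probe draws a (male, female) pattern, per-stratum slopes with magnitudes
``effect_size + Uniform(0, effect_jitter)`` and signs dictated by the
cluster, a probe-specific intercept, and Gaussian noise on the M-value
scale.  The default sample layout mirrors a three-tissue design with three
samples per tissue and mixed sexes within each tissue group.

The survival generator draws per-gene standard-normal expression and
exponential event times whose rate is the baseline hazard times
exp(sum_g b1_g * X_g), with independent uniform censoring calibrated to a
target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quantify
from .io import FeatureMatrix, SEXES
from .patterns import (
    ALL_PATTERNS,
    N_CLUSTERS,
    NULL_PATTERN,
    PATTERN_NAMES,
    differential_pattern_catalog,
    signs_from_label,
)


def nine_sample_layout() -> pd.DataFrame:
    """Nine-sample layout: 3 tissues x 3 samples with mixed sexes.

    ATM and NTM carry two males and one female, CAM one male and two
    females, so both sex strata cover every tissue.
    """
    rows = []
    sex_split = {"ATM": ("male", "male", "female"),
                 "CAM": ("male", "female", "female"),
                 "NTM": ("male", "male", "female")}
    for tissue, sexes in sex_split.items():
        for i, sex in enumerate(sexes, start=1):
            rows.append({"sample_id": f"{tissue}_{i}", "tissue": tissue, "sex": sex})
    return pd.DataFrame(rows)


def default_pattern_weights(null_fraction: float = 0.25) -> np.ndarray:
    """81-pattern weights: mass on the null plus the eight discordant families."""
    if not 0 <= null_fraction < 1:
        raise ValueError("null_fraction must be in [0, 1)")
    weights = np.zeros(N_CLUSTERS**2)
    weights[NULL_PATTERN.index] = null_fraction
    catalog = differential_pattern_catalog()
    for pat in catalog:
        weights[pat.index] = (1.0 - null_fraction) / len(catalog)
    return weights


@dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    ``effect_size`` is the minimum slope magnitude on the M-value scale for
    non-flat coordinates; actual magnitudes are ``effect_size +
    Uniform(0, effect_jitter)``.  ``noise_sd`` is the residual SD.  Survival
    settings cover a 238-subject cohort with exponential event times and a
    30% target censoring fraction.
    """

    n_probes: int = 200
    samples: pd.DataFrame = field(default_factory=nine_sample_layout)
    pattern_weights: np.ndarray = field(default_factory=default_pattern_weights)
    effect_size: float = 2.0
    effect_jitter: float = 0.5
    intercept_mean: float = 0.0
    intercept_sd: float = 1.5
    noise_sd: float = 0.3
    n_subjects: int = 238
    n_genes: int = 181
    b1: np.ndarray | None = None
    censoring_rate: float = 0.3
    baseline_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be at least 1")
        weights = np.asarray(self.pattern_weights, dtype=float)
        if weights.shape != (N_CLUSTERS**2,):
            raise ValueError(f"pattern_weights must have {N_CLUSTERS**2} entries")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("pattern_weights must be a probability vector")
        self.pattern_weights = weights
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.effect_jitter < 0:
            raise ValueError("effect_jitter must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class SimulatedStudy:
    """A simulated methylation study with its generating truth."""

    matrix: FeatureMatrix                 # M-values
    beta_values: pd.DataFrame
    truth: pd.DataFrame                   # per-probe pattern and parameters
    config: SimulationConfig


def simulate_methylation(config: SimulationConfig) -> SimulatedStudy:
    """Draw a probe-by-sample M-value matrix from the trajectory model."""
    rng = np.random.default_rng(config.seed)
    samples = config.samples.reset_index(drop=True)
    n = len(samples)
    probe_ids = pd.Index(
        [f"cg{j:08d}" for j in range(config.n_probes)], name="probe_id"
    )
    pattern_idx = rng.choice(N_CLUSTERS**2, size=config.n_probes,
                             p=config.pattern_weights)
    tissues = samples["tissue"].to_numpy()
    sexes = samples["sex"].to_numpy()
    x1 = (tissues == "ATM").astype(float)
    x2 = (tissues == "NTM").astype(float)

    values = np.zeros((config.n_probes, n))
    truth_rows = []
    for j in range(config.n_probes):
        pat = ALL_PATTERNS[pattern_idx[j]]
        row = {"probe_id": probe_ids[j], "pattern": str(pat),
               "male_cluster": pat.male_cluster, "female_cluster": pat.female_cluster,
               "noise_sd": config.noise_sd}
        mean = np.zeros(n)
        for sex, cluster in ((SEXES[0], pat.male_cluster),
                             (SEXES[1], pat.female_cluster)):
            g1, g2 = signs_from_label(cluster)
            a = rng.normal(config.intercept_mean, config.intercept_sd)
            mags = config.effect_size + rng.uniform(0, config.effect_jitter, size=2)
            b1 = g1 * mags[0]
            b2 = g2 * mags[1]
            in_stratum = sexes == sex
            mean[in_stratum] = (
                a + x1[in_stratum] * b1 + x2[in_stratum] * b2
            )
            row[f"a_{sex}"] = a
            row[f"b1_{sex}"] = b1
            row[f"b2_{sex}"] = b2
        values[j] = mean
        truth_rows.append(row)
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    m_df = pd.DataFrame(values, index=probe_ids, columns=samples["sample_id"])
    beta_df = pd.DataFrame(
        quantify.beta_from_m(values), index=probe_ids, columns=samples["sample_id"]
    )
    truth = pd.DataFrame(truth_rows).set_index("probe_id")
    return SimulatedStudy(
        matrix=FeatureMatrix(m_df, samples),
        beta_values=beta_df,
        truth=truth,
        config=config,
    )


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Upper bound of the Uniform(0, c) censoring law hitting the target rate.

    The censoring fraction under C ~ Uniform(0, c) is
    P(C < T) = E[min(T, c)] / c, monotone decreasing in c; solve by bisection
    on the empirical event times.
    """
    if target <= 0:
        return np.inf

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(event_times, c)) / c)

    lo, hi = 1e-9, float(np.max(event_times))
    if frac(hi) > target:
        # even censoring spread over the full range censors too much: widen
        while frac(hi) > target:
            hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(config: SimulationConfig):
    """Draw an expression matrix and a matching survival table.

    Returns ``(survival, expression, b1)``: a subject-level table with
    columns subject_id/time/event, a gene-by-subject expression DataFrame,
    and the per-gene true log hazard ratios.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, g = config.n_subjects, config.n_genes
    b1 = (
        np.zeros(g)
        if config.b1 is None
        else np.broadcast_to(np.asarray(config.b1, dtype=float), (g,)).copy()
    )
    X = rng.standard_normal((g, n))
    eta = b1 @ X
    rate = config.baseline_rate * np.exp(eta)
    T = rng.exponential(1.0 / rate)
    u = rng.uniform(size=n)
    c_max = _calibrate_censoring(T, config.censoring_rate)
    C = u * c_max if np.isfinite(c_max) else np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    subjects = [f"s{i:04d}" for i in range(n)]
    survival = pd.DataFrame({"subject_id": subjects, "time": time, "event": event})
    expression = pd.DataFrame(
        X, index=pd.Index([f"gene{i:04d}" for i in range(g)], name="gene"),
        columns=subjects,
    )
    return survival, expression, b1


def evaluate_assignments(assignments: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare an assignment table with the generating truth.

    ``assignments`` needs columns probe_id, pattern, selected (as produced by
    the pattern model); ``truth`` is indexed by probe_id with a ``pattern``
    column.  Returns modal accuracy over all probes, accuracy and empirical
    FDR over selected probes, and an 81x81 confusion table
    (rows = truth, columns = assigned).
    """
    table = assignments.set_index("probe_id")
    if set(table.index) != set(truth.index):
        raise ValueError("assignment and truth probe sets differ")
    table = table.loc[truth.index]
    assigned = table["pattern"].to_numpy()
    true_pat = truth["pattern"].to_numpy()
    modal_accuracy = float(np.mean(assigned == true_pat))
    selected = table["selected"].to_numpy(dtype=bool)
    n_selected = int(selected.sum())
    if n_selected:
        sel_acc = float(np.mean(assigned[selected] == true_pat[selected]))
        fdr = float(np.mean(true_pat[selected] == str(NULL_PATTERN)))
    else:
        sel_acc = np.nan
        fdr = 0.0
    confusion = pd.crosstab(
        pd.Categorical(true_pat, categories=list(PATTERN_NAMES)),
        pd.Categorical(assigned, categories=list(PATTERN_NAMES)),
        dropna=False,
    )
    return {
        "modal_accuracy": modal_accuracy,
        "selected_accuracy": sel_acc,
        "empirical_fdr": fdr,
        "n_selected": n_selected,
        "confusion": confusion,
    }
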