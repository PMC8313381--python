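"""End-to-end orchestration, reporting exports and run manifests.

A pipeline run executes prefilter -> pattern model and/or moderated linear
model -> optional survival screen, writing every stage output as TSV plus a
JSON manifest with parameters, seed and SHA-256 checksums of all artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .backpay import BackpayConfig, per_pattern_summary, run_mcmc, select_differential
from .io import (
    FeatureMatrix,
    TISSUES,
    read_feature_matrix,
    read_matrix,
    write_matrix,
)
from .limma_lite import run_moderated_analysis
from .prefilter import anova_filter, drop_missing_features
from .survival import screen_genes

logger = logging.getLogger("methpattern")

TISSUE_ORDER = TISSUES  # trajectory convention: ATM, CAM, NTM everywhere


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters for one run."""

    matrix_path: str
    sample_sheet_path: str
    out_dir: str
    alpha: float = 0.05
    run_backpay: bool = True
    run_limma: bool = True
    run_survival: bool = False
    expression_path: str | None = None
    survival_path: str | None = None
    n_iter: int = 30_000
    burn_in: int = 10_000
    pb: float = 0.5
    q_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        for path in (self.matrix_path, self.sample_sheet_path):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if self.run_survival:
            for path in (self.expression_path, self.survival_path):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"survival stage enabled but input missing: {path}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            "matrix": _sha256(Path(config.matrix_path)),
            "sample_sheet": _sha256(Path(config.sample_sheet_path)),
        },
        "stages": {},
        "outputs": {},
        "complete": False,
    }
    try:
        matrix = read_feature_matrix(config.matrix_path, config.sample_sheet_path)
        logger.info("loaded %d features x %d samples", matrix.n_features,
                    matrix.n_samples)

        matrix = drop_missing_features(matrix)
        filtered, table = anova_filter(matrix, alpha=config.alpha)
        write_matrix(filtered.values, out / "filtered_matrix.tsv")
        table.to_csv(out / "anova_table.tsv", sep="\t", index_label="feature_id")
        manifest["stages"]["prefilter"] = {
            "n_input": matrix.n_features,
            "n_kept": filtered.n_features,
            "alpha": config.alpha,
        }
        logger.info("prefilter kept %d / %d features", filtered.n_features,
                    matrix.n_features)

        if config.run_backpay:
            bp_config = BackpayConfig(
                n_iter=config.n_iter, burn_in=config.burn_in, pb=config.pb,
                q_cut=config.q_cut, seed=config.seed,
            )
            posterior = run_mcmc(filtered, bp_config)
            assignments = select_differential(posterior)
            assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
            posterior.pattern_probs.to_csv(
                out / "pattern_probabilities.tsv", sep="\t", index_label="probe_id"
            )
            per_pattern_summary(assignments).to_csv(
                out / "pattern_summary.tsv", sep="\t", index=False
            )
            export_pattern_trajectories(assignments, filtered).to_csv(
                out / "pattern_trajectories.tsv", sep="\t", index=False
            )
            manifest["stages"]["backpay"] = {
                "n_iter": config.n_iter,
                "burn_in": config.burn_in,
                "n_selected": int(assignments["selected"].sum()),
            }
            logger.info("pattern model selected %d probes",
                        int(assignments["selected"].sum()))

        if config.run_limma:
            mod = run_moderated_analysis(filtered)
            mod.to_frame().to_csv(out / "moderated_stats.tsv", sep="\t",
                                  index_label="probe_id")
            manifest["stages"]["limma"] = {
                "d0": mod.prior.d0 if np.isfinite(mod.prior.d0) else "inf",
                "s0_2": mod.prior.s0_2,
                "n_bh_significant": int((mod.p_BH < config.alpha).sum()),
            }

        if config.run_survival:
            expr = read_matrix(config.expression_path)
            surv = pd.read_csv(config.survival_path)
            screen = screen_genes(expr, surv)
            screen.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
            manifest["inputs"]["expression"] = _sha256(Path(config.expression_path))
            manifest["inputs"]["survival"] = _sha256(Path(config.survival_path))
            manifest["stages"]["survival"] = {
                "n_genes": len(screen),
                "n_bh_significant": int((screen["p_BH"] < config.alpha).sum()),
            }
        else:
            manifest["stages"]["survival"] = "skipped"
        manifest["complete"] = True
    finally:
        for artifact in sorted(out.glob("*.tsv")):
            manifest["outputs"][artifact.name] = _sha256(artifact)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def group_summary(matrix: FeatureMatrix, feature_ids) -> pd.DataFrame:
    """Per-feature tissue-group means with two-sided 95% t-intervals.

    Groups with a single sample get an undefined (NaN) interval; zero-variance
    groups collapse the interval to the mean.
    """
    missing = [f for f in feature_ids if f not in matrix.feature_ids]
    if missing:
        raise KeyError(f"unknown feature(s): {missing}")
    tissues = matrix.tissue_labels().to_numpy()
    rows = []
    for feature in feature_ids:
        values = matrix.values.loc[feature].to_numpy(dtype=float)
        for tissue in TISSUE_ORDER:
            group = values[tissues == tissue]
            n = group.size
            if n == 0:
                continue
            mean = float(np.mean(group))
            if n == 1:
                lo = hi = np.nan
                defined = False
            else:
                half = stats.t.ppf(0.975, n - 1) * np.std(group, ddof=1) / np.sqrt(n)
                lo, hi = mean - half, mean + half
                defined = True
            rows.append(
                {"feature": feature, "group": tissue, "mean": mean,
                 "ci_low": lo, "ci_high": hi, "n": n, "ci_defined": defined}
            )
    return pd.DataFrame(rows)


def export_pattern_trajectories(
    assignments: pd.DataFrame, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Long-format tissue-mean trajectories of the selected probes.

    One row per selected probe, sex stratum and tissue (ordered ATM, CAM,
    NTM), carrying the stratum's mean M-value and the assigned pattern.
    """
    sel = (
        assignments.loc[assignments["selected"]]
        .reset_index(drop=True)
        .sort_values("probe_id")
    )
    tissues = matrix.tissue_labels().to_numpy()
    sexes = matrix.samples.set_index("sample_id")["sex"].loc[
        matrix.values.columns
    ].to_numpy()
    rows = []
    for _, record in sel.iterrows():
        probe = record["probe_id"]
        values = matrix.values.loc[probe].to_numpy(dtype=float)
        for sex in ("male", "female"):
            for tissue in TISSUE_ORDER:
                mask = (sexes == sex) & (tissues == tissue)
                rows.append(
                    {
                        "probe_id": probe,
                        "stratum": sex,
                        "tissue": tissue,
                        "mean_m_value": float(values[mask].mean())
                        if mask.any()
                        else np.nan,
                        "pattern": record["pattern"],
                        "probability": record["probability"],
                    }
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "stratum", "tissue", "mean_m_value",
                       "pattern", "probability"],
    )
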