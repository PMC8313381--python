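"""File formats and the core probe-by-sample container.

Matrices are tab-separated text with a header row of sample IDs and a first
column of feature identifiers (Illumina cg-probes or gene symbols).  Sample
annotations travel in a CSV sample sheet with columns ``sample_id``,
``tissue`` and ``sex``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

TISSUES = ("ATM", "CAM", "NTM")
SEXES = ("male", "female")

SAMPLE_SHEET_COLUMNS = ("sample_id", "tissue", "sex")


class SampleSheetError(ValueError):
    """Raised when a sample sheet is malformed or inconsistent with a matrix."""


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    Requires the three canonical columns, non-missing tissue/sex entries,
    tissue labels drawn from ``ATM/CAM/NTM`` and sex labels from
    ``male/female``.  Returns a copy indexed 0..n-1.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise SampleSheetError(f"sample sheet is missing columns: {missing}")
    sheet = samples.loc[:, list(SAMPLE_SHEET_COLUMNS)].reset_index(drop=True).copy()
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleSheetError(f"duplicated sample ids: {dups}")
    if sheet[["tissue", "sex"]].isna().any().any():
        raise SampleSheetError("tissue and sex must be non-missing for every sample")
    bad_tissue = sheet.loc[~sheet["tissue"].isin(TISSUES)]
    if len(bad_tissue):
        raise SampleSheetError(
            "unknown tissue label(s) "
            f"{sorted(bad_tissue['tissue'].unique())} for sample(s) "
            f"{bad_tissue['sample_id'].tolist()}; expected one of {TISSUES}"
        )
    bad_sex = sheet.loc[~sheet["sex"].isin(SEXES)]
    if len(bad_sex):
        raise SampleSheetError(
            f"unknown sex label(s) {sorted(bad_sex['sex'].unique())} "
            f"for sample(s) {bad_sex['sample_id'].tolist()}; expected one of {SEXES}"
        )
    return sheet


@dataclass
class FeatureMatrix:
    """A feature-by-sample matrix with tissue/sex annotations.

    ``values`` is a :class:`pandas.DataFrame` whose rows are features
    (probes or genes) and whose columns are sample IDs, in the order of the
    sample sheet.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        ids = list(self.samples["sample_id"])
        if list(self.values.columns) != ids:
            if set(self.values.columns) == set(ids):
                self.values = self.values.loc[:, ids]
            else:
                raise SampleSheetError(
                    "matrix columns do not match sample sheet sample_ids"
                )
        for tissue in TISSUES:
            if not (self.samples["tissue"] == tissue).any():
                warnings.warn(f"tissue group {tissue} has no samples", stacklevel=2)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tissue_labels(self) -> pd.Series:
        return self.samples.set_index("sample_id")["tissue"].loc[self.values.columns]

    def subset(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[feature_ids], self.samples)


def read_matrix(path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix (first column = feature IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path))


def read_feature_matrix(matrix_path, sample_sheet_path) -> FeatureMatrix:
    return FeatureMatrix(read_matrix(matrix_path), read_sample_sheet(sample_sheet_path))
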