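"""Trajectory clusters and cross-sex patterns.

A probe's methylation trajectory over the three tissue groups ATM -> CAM ->
NTM is summarised, per sex stratum, by the signs of two regression slopes
relative to the CAM reference level:

    mean(ATM) = a + b1,   mean(CAM) = a,   mean(NTM) = a + b2.

``b1 > 0`` means the level *decreases* from ATM to CAM (first segment
"Down"); ``b2 > 0`` means it *increases* from CAM to NTM (second segment
"Up").  The nine sign combinations give nine named clusters (DownUp, FlatUp,
..., UpDown); the ordered pair of clusters for the (male, female) strata is a
*pattern*, of which there are 81.  The null pattern is FlatFlat-FlatFlat: no
tissue effect in either sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SEXES, TISSUES

#: segment words keyed by slope sign; first segment is ATM->CAM, second CAM->NTM
_SEG1 = {1: "Down", 0: "Flat", -1: "Up"}
_SEG2 = {1: "Up", 0: "Flat", -1: "Down"}

#: canonical cluster enumeration: second-segment sign major (+, 0, -),
#: first-segment sign minor (+, 0, -) -- DownUp, FlatUp, UpUp, DownFlat, ...
CLUSTER_SIGNS: tuple[tuple[int, int], ...] = tuple(
    (g1, g2) for g2 in (1, 0, -1) for g1 in (1, 0, -1)
)
CLUSTER_NAMES: tuple[str, ...] = tuple(
    _SEG1[g1] + _SEG2[g2] for (g1, g2) in CLUSTER_SIGNS
)
N_CLUSTERS = len(CLUSTER_NAMES)  # 9
FLAT_FLAT = CLUSTER_NAMES.index("FlatFlat")

_NAME_TO_INDEX = {name: i for i, name in enumerate(CLUSTER_NAMES)}


def cluster_label_from_signs(g1: int, g2: int) -> str:
    """Cluster name for a pair of slope signs in {-1, 0, +1}."""
    if g1 not in (-1, 0, 1) or g2 not in (-1, 0, 1):
        raise ValueError(f"signs must be in {{-1, 0, 1}}, got ({g1}, {g2})")
    return _SEG1[g1] + _SEG2[g2]


def signs_from_label(name: str) -> tuple[int, int]:
    """Inverse of :func:`cluster_label_from_signs`."""
    try:
        return CLUSTER_SIGNS[_NAME_TO_INDEX[name]]
    except KeyError:
        raise ValueError(f"unknown cluster label {name!r}") from None


def cluster_index(name: str) -> int:
    try:
        return _NAME_TO_INDEX[name]
    except KeyError:
        raise ValueError(f"unknown cluster label {name!r}") from None


def trajectory_means(intercept: float, beta1: float, beta2: float):
    """Tissue-group means (ATM, CAM, NTM) implied by intercept and slopes."""
    return (intercept + beta1, intercept, intercept + beta2)


@dataclass(frozen=True, order=True)
class Pattern:
    """An ordered (male-stratum, female-stratum) pair of cluster labels."""

    male_cluster: str
    female_cluster: str

    def __post_init__(self) -> None:
        cluster_index(self.male_cluster)
        cluster_index(self.female_cluster)

    @property
    def index(self) -> int:
        """Flat index in the 81-pattern enumeration (male major, female minor)."""
        return cluster_index(self.male_cluster) * N_CLUSTERS + cluster_index(
            self.female_cluster
        )

    @property
    def is_null(self) -> bool:
        return self.male_cluster == "FlatFlat" and self.female_cluster == "FlatFlat"

    @property
    def is_discordant(self) -> bool:
        """True when the male and female strata have different trajectory shapes."""
        return self.male_cluster != self.female_cluster

    def __str__(self) -> str:
        return f"{self.male_cluster}-{self.female_cluster}"

    @classmethod
    def from_string(cls, text: str) -> "Pattern":
        male, _, female = text.partition("-")
        if not female:
            raise ValueError(f"pattern string must be 'Male-Female', got {text!r}")
        return cls(male, female)

    @classmethod
    def from_index(cls, idx: int) -> "Pattern":
        if not 0 <= idx < N_CLUSTERS**2:
            raise ValueError(f"pattern index out of range: {idx}")
        return cls(CLUSTER_NAMES[idx // N_CLUSTERS], CLUSTER_NAMES[idx % N_CLUSTERS])


NULL_PATTERN = Pattern("FlatFlat", "FlatFlat")

ALL_PATTERNS: tuple[Pattern, ...] = tuple(
    Pattern(m, f) for m in CLUSTER_NAMES for f in CLUSTER_NAMES
)
PATTERN_NAMES: tuple[str, ...] = tuple(str(p) for p in ALL_PATTERNS)


def differential_pattern_catalog() -> tuple[Pattern, ...]:
    """The eight sex-discordant pattern families of primary biological interest.

    Four families differ between the sexes in the NTM segment
    (e.g. UpUp-UpDown) and four in the CAM segment (e.g. UpUp-DownUp).
    """
    return tuple(
        Pattern.from_string(s)
        for s in (
            "UpUp-UpDown",
            "UpDown-UpUp",
            "DownUp-DownDown",
            "DownDown-DownUp",
            "UpUp-DownUp",
            "UpDown-DownDown",
            "DownUp-UpUp",
            "DownDown-UpDown",
        )
    )


@dataclass
class DesignEncoding:
    """Per-stratum tissue indicator design.

    For every sample: ``x1 = 1`` if ATM, ``x2 = 1`` if NTM; CAM is the
    reference level ``(0, 0)``.  Samples are split into the male and female
    strata; ``columns[s]`` holds the integer positions of stratum ``s``'s
    samples among the matrix columns and ``design[s]`` the corresponding
    n_s-by-2 indicator matrix.
    """

    strata: tuple[str, ...]
    columns: dict[str, np.ndarray]
    design: dict[str, np.ndarray]
    sample_ids: dict[str, list[str]]


def encode_design(samples: pd.DataFrame) -> DesignEncoding:
    """Build the two-stratum ATM/NTM indicator encoding from a sample sheet.

    Raises if any sample carries an unknown tissue or sex label, or if a sex
    stratum is empty.
    """
    for _, row in samples.iterrows():
        if row["tissue"] not in TISSUES:
            raise ValueError(
                f"sample {row['sample_id']!r} has unknown tissue {row['tissue']!r}"
            )
        if row["sex"] not in SEXES:
            raise ValueError(
                f"sample {row['sample_id']!r} has unknown sex {row['sex']!r}"
            )
    columns: dict[str, np.ndarray] = {}
    design: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    for sex in SEXES:
        mask = (samples["sex"] == sex).to_numpy()
        if not mask.any():
            raise ValueError(f"stratum {sex!r} contains no samples")
        columns[sex] = np.flatnonzero(mask)
        tissues = samples.loc[mask, "tissue"].to_numpy()
        design[sex] = np.column_stack(
            [(tissues == "ATM").astype(float), (tissues == "NTM").astype(float)]
        )
        ids[sex] = samples.loc[mask, "sample_id"].tolist()
    return DesignEncoding(strata=SEXES, columns=columns, design=design, sample_ids=ids)
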