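"""ITH scoring: signed sums of cohort z-score normalized radiomic features.

The imaging intratumor-heterogeneity (ITH) score of a patient is the
arithmetic sum of that patient's z-scored features, with features that
indicate homogeneity entering with a minus sign.  Because every z-scored
column has mean zero over the normalization cohort, the cohort mean ITH
score is exactly zero; scores are therefore relative within the chosen
normalization cohort, which the caller selects explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radiomics import FeatureRegistry

__all__ = [
    "CohortFeatureMatrix",
    "ITHResult",
    "DegenerateFeatureError",
    "zscore_columns",
    "ith_scores",
    "cohort_feature_matrix",
]


class DegenerateFeatureError(ValueError):
    """A feature column is constant and cannot be z-scored."""


@dataclass(frozen=True)
class CohortFeatureMatrix:
    """Patients x features table aligned to a feature registry's order."""

    patient_ids: tuple
    feature_names: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("matrix shape must be (n_patients, n_features)")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature matrix contains missing/non-finite values")
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.patient_ids), columns=list(self.feature_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortFeatureMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class ITHResult:
    patient_id: object
    ith_score: float


def cohort_feature_matrix(
    feature_vectors: dict, registry: FeatureRegistry
) -> CohortFeatureMatrix:
    """Assemble {patient_id: feature dict} into a registry-ordered matrix."""
    ids = tuple(feature_vectors)
    names = tuple(registry.names)
    m = np.array([[feature_vectors[pid][n] for n in names] for pid in ids], dtype=float)
    return CohortFeatureMatrix(ids, names, m)


def zscore_columns(
    m: CohortFeatureMatrix, drop_constant: bool = False
) -> CohortFeatureMatrix:
    """Z-score each column with sample SD (denominator n - 1).

    Constant columns raise :class:`DegenerateFeatureError` naming the
    column, unless ``drop_constant`` is set, in which case they are dropped
    with a warning.
    """
    if len(m.patient_ids) < 2:
        raise ValueError("need >= 2 patients for z-score normalization")
    sd = m.matrix.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        bad = [n for n, c in zip(m.feature_names, const) if c]
        if not drop_constant:
            raise DegenerateFeatureError(f"constant feature column(s): {bad}")
        warnings.warn(f"dropping constant feature column(s): {bad}", stacklevel=2)
    keep = ~const
    z = (m.matrix[:, keep] - m.matrix[:, keep].mean(axis=0)) / sd[keep]
    return CohortFeatureMatrix(m.patient_ids, tuple(np.array(m.feature_names)[keep]), z)


def ith_scores(z: CohortFeatureMatrix, registry: FeatureRegistry) -> list[ITHResult]:
    """score_i = sum_j sign_j * z_ij over the registry-signed columns."""
    signs_map = registry.signs
    missing = [n for n in z.feature_names if n not in signs_map]
    if missing:
        raise KeyError(f"no registry sign for column(s): {missing}")
    signs = np.array([signs_map[n] for n in z.feature_names], dtype=float)
    scores = z.matrix @ signs
    return [ITHResult(pid, float(s)) for pid, s in zip(z.patient_ids, scores)]


def ith_results_frame(results: list[ITHResult]) -> pd.DataFrame:
    """Tidy (patient_id, ith_score) table for CSV export."""
    return pd.DataFrame(
        {"patient_id": [r.patient_id for r in results], "ith_score": [r.ith_score for r in results]}
    )
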