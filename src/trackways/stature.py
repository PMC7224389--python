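"""Stature prediction from footprint dimensions.

Regressions of subject stature on per-subject median footprint
dimensions (heel-to-hallux length L, forefoot breadth FB, heel breadth
HB) are fit on walking trials only, over a fixed family of predictor
subsets, and ranked by 10-fold cross-validated RMSE.  The top-ranked
model is applied to fossil trackway medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .data import TrackwaySummary

__all__ = [
    "SubjectAnthropometry",
    "StatureModel",
    "CANDIDATE_PREDICTOR_SETS",
    "subject_median_footprints",
    "build_stature_models",
    "predict_stature",
    "predict_stature_table",
]

#: Predictor subsets evaluated, in a fixed order.
CANDIDATE_PREDICTOR_SETS: tuple[tuple[str, ...], ...] = (
    ("length_mm",),
    ("length_mm", "forefoot_breadth_mm"),
    ("length_mm", "heel_breadth_mm"),
    ("length_mm", "forefoot_breadth_mm", "heel_breadth_mm"),
    ("forefoot_breadth_mm",),
    ("heel_breadth_mm",),
)

_SUMMARY_FIELD = {
    "length_mm": "median_footprint_length_mm",
    "forefoot_breadth_mm": "median_forefoot_breadth_mm",
    "heel_breadth_mm": "median_heel_breadth_mm",
}


@dataclass(frozen=True)
class SubjectAnthropometry:
    subject_id: str
    stature_m: float
    foot_length_mm: float

    def __post_init__(self) -> None:
        if not 0.5 < self.stature_m < 2.5:
            raise ValueError(f"implausible stature {self.stature_m} m")
        if not 100 < self.foot_length_mm < 400:
            raise ValueError(f"implausible foot length {self.foot_length_mm} mm")


@dataclass(frozen=True)
class StatureModel:
    """One fitted stature regression with its cross-validation score."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]  # aligned with predictors; stature in m
    rmse_m: float                    # in-sample
    cv_rmse_m: float                 # k-fold cross-validated
    n_subjects: int
    training_ranges: dict            # predictor -> (min, max)

    def predict(self, values: dict) -> float:
        missing = [p for p in self.predictors if values.get(p) is None]
        if missing:
            raise ValueError(f"missing predictor(s): {', '.join(missing)}")
        return self.intercept + sum(
            c * float(values[p]) for c, p in zip(self.coefficients, self.predictors)
        )

    def is_extrapolation(self, values: dict) -> bool:
        for p in self.predictors:
            lo, hi = self.training_ranges[p]
            if not lo <= float(values[p]) <= hi:
                return True
        return False


def subject_median_footprints(walking_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject median footprint dimensions from walking trials."""
    cols = [c for c in ("footprint_length_mm", "forefoot_breadth_mm", "heel_breadth_mm")
            if c in walking_trials.columns]
    med = walking_trials.groupby("subject_id")[cols].median().reset_index()
    return med.rename(columns={"footprint_length_mm": "length_mm"})


def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(beta[0]), beta[1:]


def build_stature_models(
    subjects: pd.DataFrame,
    walking_trials: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> list[StatureModel]:
    """Fit every candidate predictor subset and rank by CV-RMSE (ascending).

    ``subjects`` needs columns ``subject_id`` and ``stature_m``;
    ``walking_trials`` one row per walking trial with footprint
    dimensions.  Requires at least 10 subjects.
    """
    med = subject_median_footprints(walking_trials)
    df = med.merge(subjects[["subject_id", "stature_m"]], on="subject_id", how="inner")
    n = len(df)
    if n < 10:
        raise ValueError(f"insufficient sample: {n} subjects with walking trials (need >= 10)")
    y = df["stature_m"].to_numpy(dtype=float)

    models = []
    for preds in CANDIDATE_PREDICTOR_SETS:
        if any(p not in df.columns or df[p].isna().any() for p in preds):
            continue
        X = df[list(preds)].to_numpy(dtype=float)
        b0, coefs = _fit_ols(X, y)
        resid = y - (b0 + X @ coefs)
        rmse = float(np.sqrt(np.mean(resid**2)))

        kf = KFold(n_splits=min(k, n), shuffle=True, random_state=seed)
        sq = []
        for train, test in kf.split(X):
            tb0, tcoef = _fit_ols(X[train], y[train])
            pred = tb0 + X[test] @ tcoef
            sq.extend((y[test] - pred) ** 2)
        cv_rmse = float(np.sqrt(np.mean(sq)))

        models.append(
            StatureModel(
                predictors=preds,
                intercept=b0,
                coefficients=tuple(float(c) for c in coefs),
                rmse_m=rmse,
                cv_rmse_m=cv_rmse,
                n_subjects=n,
                training_ranges={
                    p: (float(df[p].min()), float(df[p].max())) for p in preds
                },
            )
        )
    models.sort(key=lambda m: m.cv_rmse_m)
    return models


def _summary_values(summary: TrackwaySummary) -> dict:
    return {k: getattr(summary, v) for k, v in _SUMMARY_FIELD.items()}


def predict_stature(m: StatureModel, summary: TrackwaySummary) -> tuple[float, bool]:
    """Point stature prediction (m) and an extrapolation flag."""
    values = _summary_values(summary)
    stature = m.predict(values)
    return stature, m.is_extrapolation(values)


def predict_stature_table(
    m: StatureModel, summaries: Sequence[TrackwaySummary]
) -> pd.DataFrame:
    rows = []
    for s in summaries:
        stature, extrap = predict_stature(m, s)
        rows.append(
            {
                "trackway_id": s.trackway_id,
                "median_footprint_length_mm": s.median_footprint_length_mm,
                "predicted_stature_m": stature,
                "extrapolated": extrap,
            }
        )
    return pd.DataFrame(rows)
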