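"""Gait classification and velocity prediction from relative stride length.

Speed estimation is a two-step procedure fit on experimental trials of
habitually barefoot subjects producing footprints at self-selected
speeds.  First a logistic classifier separates walking from running on
relative stride length (RSL = stride length / footprint length), with
the decision threshold set by Youden's J on the training ROC.  Second,
a gait-specific linear mixed model (random intercept per subject)
predicts velocity (m/s) from RSL; fossil predictions use the fixed
effects only, with a +/- RMSE band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.metrics import roc_auc_score, roc_curve

from .data import TrackwaySummary

__all__ = [
    "WALK_CATEGORIES",
    "RUN_CATEGORIES",
    "ExperimentalTrial",
    "GaitClassifier",
    "VelocityModel",
    "SpeedPrediction",
    "gait_from_category",
    "frame_from_trials",
    "trial_rsl",
    "fit_gait_classifier",
    "classify_gait",
    "fit_velocity_model",
    "predict_velocity",
    "predict_assemblage",
]

WALK_CATEGORIES = ("normal walk", "fast walk")
RUN_CATEGORIES = ("endurance run", "fast run")


def gait_from_category(speed_category: str) -> str:
    if speed_category in WALK_CATEGORIES:
        return "walk"
    if speed_category in RUN_CATEGORIES:
        return "run"
    raise ValueError(f"unknown speed category {speed_category!r}")


@dataclass(frozen=True)
class ExperimentalTrial:
    """One footprint-making trial with known subject kinematics."""

    subject_id: str
    speed_category: str
    velocity_mps: float
    stride_length_mm: float
    footprint_length_mm: float
    forefoot_breadth_mm: Optional[float] = None
    heel_breadth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.velocity_mps > 0:
            raise ValueError("velocity must be > 0")
        gait_from_category(self.speed_category)  # validates

    @property
    def gait_label(self) -> str:
        return gait_from_category(self.speed_category)


def frame_from_trials(trials: Sequence[ExperimentalTrial]) -> pd.DataFrame:
    df = pd.DataFrame([vars(t) for t in trials])
    df["gait"] = df["speed_category"].map(gait_from_category)
    return df


def trial_rsl(trials: pd.DataFrame) -> pd.Series:
    """Per-trial RSL: trial stride divided by trial footprint length."""
    return trials["stride_length_mm"] / trials["footprint_length_mm"]


def _prepare(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    if "gait" not in df.columns:
        df["gait"] = df["speed_category"].map(gait_from_category)
    if "rsl" not in df.columns:
        df["rsl"] = trial_rsl(df)
    return df


@dataclass(frozen=True)
class GaitClassifier:
    """Logistic walk/run classifier on relative stride length."""

    intercept: float
    slope: float
    decision_threshold: float  # probability cutoff; ties classify as run
    rsl_threshold: float       # RSL at which P(run) = decision_threshold
    auc: float
    confusion: Mapping[str, int]  # tn, fp, fn, tp at the decision threshold

    def run_probability(self, rsl) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(rsl, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def fit_gait_classifier(trials: pd.DataFrame, seed: int = 0) -> GaitClassifier:
    """Fit the logistic gait classifier and pick its ROC threshold.

    The decision threshold maximizes Youden's J (TPR - FPR) on the
    training ROC, with "run" the positive class.  Raises if only one
    gait is present.
    """
    from sklearn.linear_model import LogisticRegression

    df = _prepare(trials)
    y = (df["gait"] == "run").to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("cannot fit classifier: training data contain a single gait")
    x = df[["rsl"]].to_numpy(dtype=float)

    # weak regularization: near-ML fit that stays finite under separation
    lr = LogisticRegression(C=1e4, max_iter=10_000, random_state=seed)
    lr.fit(x, y)
    b0, b1 = float(lr.intercept_[0]), float(lr.coef_[0, 0])

    prob = lr.predict_proba(x)[:, 1]
    auc = float(roc_auc_score(y, prob))
    fpr, tpr, thr = roc_curve(y, prob)
    j = tpr - fpr
    best = int(np.argmax(j))
    p_thr = float(min(thr[best], 1.0))  # roc_curve pads the first threshold above 1

    pred = prob >= p_thr
    confusion = {
        "tn": int(np.sum(~pred & (y == 0))),
        "fp": int(np.sum(pred & (y == 0))),
        "fn": int(np.sum(~pred & (y == 1))),
        "tp": int(np.sum(pred & (y == 1))),
    }
    if b1 > 0 and 0 < p_thr < 1:
        rsl_thr = (math.log(p_thr / (1 - p_thr)) - b0) / b1
    else:
        rsl_thr = math.nan
    return GaitClassifier(
        intercept=b0, slope=b1, decision_threshold=p_thr,
        rsl_threshold=rsl_thr, auc=auc, confusion=confusion,
    )


def classify_gait(c: GaitClassifier, rsl: float) -> str:
    """"run" iff the run probability is at or above the decision
    threshold (ties classify as run), else "walk"."""
    if not rsl > 0:
        raise ValueError(f"rsl must be > 0, got {rsl}")
    return "run" if float(c.run_probability(rsl)) >= c.decision_threshold else "walk"


@dataclass(frozen=True)
class VelocityModel:
    """Linear mixed model of velocity (m/s) on RSL for one gait.

    Fixed effects ``velocity = intercept + slope * RSL`` are used for
    prediction; the per-subject random-intercept variance is a training
    diagnostic only.
    """

    gait: str
    intercept: float
    slope: float
    slope_se: float
    rmse_mps: float           # population-level (fixed-effects) RMSE
    subject_intercept_var: float
    rsl_range: tuple[float, float]
    n_trials: int
    n_subjects: int

    def predict(self, rsl) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(rsl, dtype=float)


def fit_velocity_model(trials: pd.DataFrame, gait: str) -> VelocityModel:
    """Fit ``velocity ~ RSL`` with random subject intercepts for one gait."""
    df = _prepare(trials)
    df = df[df["gait"] == gait].reset_index(drop=True)
    if df["subject_id"].nunique() < 2:
        raise ValueError(f"need trials of gait {gait!r} from >= 2 subjects")
    if float(df["rsl"].std()) < 1e-12:
        raise ValueError("degenerate design: RSL is constant")

    x = df["rsl"].to_numpy(dtype=float)
    v = df["velocity_mps"].to_numpy(dtype=float)

    # exact linear data first: the mixed model is singular there
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), v, rcond=None)
    ols_resid = v - (coef[0] + coef[1] * x)
    if float(np.sqrt(np.mean(ols_resid**2))) < 1e-9:
        return VelocityModel(
            gait=gait, intercept=float(coef[0]), slope=float(coef[1]),
            slope_se=0.0, rmse_mps=float(np.sqrt(np.mean(ols_resid**2))),
            subject_intercept_var=0.0,
            rsl_range=(float(x.min()), float(x.max())),
            n_trials=len(df), n_subjects=df["subject_id"].nunique(),
        )

    model = smf.mixedlm("velocity_mps ~ rsl", df, groups=df["subject_id"])
    fit = model.fit(reml=True)
    b0 = float(fit.fe_params["Intercept"])
    b1 = float(fit.fe_params["rsl"])
    se1 = float(fit.bse_fe["rsl"])
    resid = v - (b0 + b1 * x)
    return VelocityModel(
        gait=gait, intercept=b0, slope=b1, slope_se=se1,
        rmse_mps=float(np.sqrt(np.mean(resid**2))),
        subject_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        rsl_range=(float(x.min()), float(x.max())),
        n_trials=len(df), n_subjects=df["subject_id"].nunique(),
    )


@dataclass(frozen=True)
class SpeedPrediction:
    trackway_id: str
    rsl: float
    gait: str
    velocity_mps: float
    band_low_mps: float
    band_high_mps: float
    extrapolated: bool


def predict_velocity(
    summary: TrackwaySummary,
    classifier: GaitClassifier,
    walk_model: VelocityModel,
    run_model: VelocityModel,
) -> SpeedPrediction:
    """Classify a trackway's gait and predict its velocity with an RMSE band.

    The extrapolation flag is set when the trackway RSL lies outside
    the chosen model's training RSL range.
    """
    rsl = summary.relative_stride_length
    if rsl is None:
        raise ValueError(
            f"trackway {summary.trackway_id!r}: stride length required for speed estimation"
        )
    gait = classify_gait(classifier, rsl)
    m = run_model if gait == "run" else walk_model
    v = float(m.predict(rsl))
    lo, hi = m.rsl_range
    return SpeedPrediction(
        trackway_id=summary.trackway_id,
        rsl=rsl,
        gait=gait,
        velocity_mps=v,
        band_low_mps=v - m.rmse_mps,
        band_high_mps=v + m.rmse_mps,
        extrapolated=not (lo <= rsl <= hi),
    )


def predict_assemblage(
    summaries: Sequence[TrackwaySummary],
    classifier: GaitClassifier,
    walk_model: VelocityModel,
    run_model: VelocityModel,
) -> pd.DataFrame:
    """Per-trackway speed table (trackways without strides are skipped)."""
    rows = []
    for s in summaries:
        if s.relative_stride_length is None:
            continue
        p = predict_velocity(s, classifier, walk_model, run_model)
        rows.append(vars(p))
    return pd.DataFrame(rows)
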