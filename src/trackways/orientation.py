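"""Circular statistics for trackway compass orientations.

Orientations are compass bearings in degrees clockwise from north.
The analysis pipeline groups trackways into two opposed directional
modes, tests each for directionality with Rayleigh's test of
uniformity, fits a von Mises distribution, and attaches a bootstrapped
percentile confidence interval to the mean direction of travel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import Trackway

__all__ = [
    "OrientationSample",
    "DirectionalSummary",
    "circular_mean",
    "rayleigh_test",
    "fit_vonmises",
    "bootstrap_direction_ci",
    "split_by_direction",
    "directional_summary",
    "KAPPA_CAP",
]

#: kappa returned for numerically degenerate (all-identical) samples.
KAPPA_CAP = 1e6

_RESULTANT_EPS = 1e-12


@dataclass(frozen=True)
class OrientationSample:
    """A set of compass bearings, optionally labelled (e.g. "NE")."""

    angles_deg: tuple[float, ...]
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        for a in self.angles_deg:
            if not 0 <= a < 360:
                raise ValueError(f"angle {a} outside [0, 360)")


@dataclass(frozen=True)
class DirectionalSummary:
    """Directional statistics for one orientation group."""

    group_label: Optional[str]
    n: int
    mean_direction_deg: float
    resultant_length: float
    rayleigh_statistic: float
    rayleigh_p: float
    vonmises_mu_deg: float
    vonmises_kappa: float
    ci_low_deg: float
    ci_high_deg: float


def _to_rad(angles_deg) -> np.ndarray:
    return np.deg2rad(np.asarray(angles_deg, dtype=float))


def circular_mean(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Vector-sum mean direction and mean resultant length R-bar.

    Returns ``(nan, R)`` when the resultant is numerically zero
    (e.g. antipodal angles), where the mean direction is undefined.
    """
    a = _to_rad(angles_deg)
    if a.size == 0:
        raise ValueError("need at least one angle")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = math.hypot(c, s)
    if r < _RESULTANT_EPS:
        return (math.nan, r)
    return (math.degrees(math.atan2(s, c)) % 360.0, r)


def rayleigh_test(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Rayleigh's test of circular uniformity.

    The statistic is ``Z = n * R-bar**2``; the p-value uses the
    standard small-sample exponential approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with
    ``R = n * R-bar``, accurate for small n and stable at high
    concentration.
    """
    n = len(angles_deg)
    if n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    _, rbar = circular_mean(angles_deg)
    z = n * rbar**2
    r = n * rbar
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - r**2)) - (1 + 2 * n))
    return z, float(min(max(p, 0.0), 1.0))


def _kappa_mle(rbar: float) -> float:
    # Best & Fisher inverse-A approximation, three regimes.
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    denom = rbar**3 - 4 * rbar**2 + 3 * rbar
    if denom <= 0:
        return KAPPA_CAP
    return min(1.0 / denom, KAPPA_CAP)


def fit_vonmises(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit: ``(mu_deg, kappa)``.

    mu is the circular mean; kappa uses the standard inverse-A
    approximation, capped at :data:`KAPPA_CAP` for degenerate
    (all-identical) samples.
    """
    if len(angles_deg) < 2:
        raise ValueError("von Mises fit needs n >= 2")
    mu, rbar = circular_mean(angles_deg)
    if rbar < _RESULTANT_EPS:
        raise ValueError("kappa undefined: zero resultant length")
    return mu, _kappa_mle(rbar)


def _wrap_180(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


def bootstrap_direction_ci(
    angles_deg: Sequence[float],
    B: int = 10_000,
    level: float = 0.95,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the von Mises mean direction.

    Resamples the angles with replacement ``B`` times, takes the
    von Mises ML mean direction (the circular mean) of each resample,
    and forms the percentile interval of the angular deviations from
    the full-sample mean, re-centred on that mean.  Working in
    deviations handles wrap-around at 0/360 and guarantees the interval
    brackets the full-sample mean on the circle.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 3:
        raise ValueError("bootstrap CI needs n >= 3")
    if B < 100:
        warnings.warn(f"B={B} is very small for a percentile interval", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    full_mean, _ = circular_mean(angles)
    if math.isnan(full_mean):
        raise ValueError("mean direction undefined: zero resultant length")

    idx = rng.integers(0, n, size=(B, n))
    rad = np.deg2rad(angles[idx])
    means = np.degrees(np.arctan2(np.sin(rad).mean(axis=1), np.cos(rad).mean(axis=1))) % 360.0
    dev = _wrap_180(means - full_mean)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(dev, [100 * alpha, 100 * (1 - alpha)])
    return ((full_mean + lo) % 360.0, (full_mean + hi) % 360.0)


def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    return np.abs(_wrap_180(a - b))


def split_by_direction(
    trackways: Sequence[Trackway],
) -> tuple[list[Trackway], list[Trackway], list[Trackway]]:
    """Partition trackways into the two modal travel directions.

    A 2-mode circular partition: initial groups are the half-circles
    split at 135/315 degrees (NE-facing vs SW-facing); each trackway is
    then reassigned to the nearer group mean until stable.  The group
    whose mean lies in [0, 180) is returned first (NE), the other
    second (SW); trackways without compass degrees go to ``ungrouped``.
    If all angles fall in a single mode the empty group is returned
    empty (callers should treat that as a single-mode sample).
    """
    with_deg = [t for t in trackways if t.compass_deg is not None]
    ungrouped = [t for t in trackways if t.compass_deg is None]
    if not with_deg:
        return [], [], ungrouped
    angles = np.array([t.compass_deg for t in with_deg], dtype=float)

    # initial split: NE half-circle is [315, 360) U [0, 135)
    assign = np.where((angles >= 315) | (angles < 135), 0, 1)
    for _ in range(100):
        means = []
        for g in (0, 1):
            sub = angles[assign == g]
            means.append(circular_mean(sub)[0] if sub.size else math.nan)
        if any(math.isnan(m) for m in means):
            break  # one mode empty or degenerate: keep current assignment
        new = np.where(_circ_dist(angles, means[0]) <= _circ_dist(angles, means[1]), 0, 1)
        if np.array_equal(new, assign):
            break
        assign = new

    g0 = [t for t, a in zip(with_deg, assign) if a == 0]
    g1 = [t for t, a in zip(with_deg, assign) if a == 1]
    mean0 = circular_mean([t.compass_deg for t in g0])[0] if g0 else math.nan
    if g0 and g1:
        if not 0 <= mean0 < 180:
            g0, g1 = g1, g0
    elif g1 and not g0:
        g0, g1 = g1, g0
        mean0 = circular_mean([t.compass_deg for t in g0])[0]
        if not 0 <= mean0 < 180:
            g0, g1 = g1, g0
    return g0, g1, ungrouped


def directional_summary(
    sample: OrientationSample,
    B: int = 10_000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> DirectionalSummary:
    """Full directional report for one orientation group."""
    angles = sample.angles_deg
    mean_deg, rbar = circular_mean(angles)
    z, p = rayleigh_test(angles)
    mu, kappa = fit_vonmises(angles)
    lo, hi = bootstrap_direction_ci(angles, B=B, level=level, seed=seed)
    return DirectionalSummary(
        group_label=sample.group_label,
        n=len(angles),
        mean_direction_deg=mean_deg,
        resultant_length=rbar,
        rayleigh_statistic=z,
        rayleigh_p=p,
        vonmises_mu_deg=mu,
        vonmises_kappa=kappa,
        ci_low_deg=lo,
        ci_high_deg=hi,
    )
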