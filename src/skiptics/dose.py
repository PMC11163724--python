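"""Nuclear TDP-43 dose model: total-nuclear estimation, passive-diffusion
fraction, and exon-skipping onset threshold.

Levels are expressed in multiples of the normal endogenous nuclear TDP-43
("fold" units). A wild-type construct is fully nuclear, so

    total_nuclear = endogenous + construct_level

while an NLS-mutant (NLSm) construct only reaches the nucleus by passive
diffusion of a fraction of its protein:

    total_nuclear = endogenous + diffusion_fraction * construct_level

with 0.45 as the default diffusion multiplier. The skipping response as a
function of total nuclear fold is modelled as an isotonic (non-decreasing)
piecewise-linear curve through the pooled observations — an interpolation, not
a parametric Hill/logistic fit, because only monotonicity is assumed.

The diffusion fraction is estimated by equal-response matching: each NLSm
observation whose skipping response is bracketed by the wild-type curve is
inverted to the equivalent nuclear fold, giving one per-point estimate
``(equivalent_fold - endogenous) / construct_level``; the median and min–max
range across matched points are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import DataError

Construct = Literal["WT", "NLSm"]

DEFAULT_DIFFUSION_FRACTION = 0.45
DEFAULT_DETECTION_FLOOR = 5.0  # percent skipping


@dataclass(frozen=True, slots=True)
class DoseObservation:
    """One expression-vs-skipping measurement (e.g. one FACS fraction)."""

    construct: str  # "WT" | "NLSm"
    construct_level: float  # multiples of normal endogenous TDP-43
    endogenous_level: float  # multiples of normal (autoregulation may drive < 1)
    skipping_percent: float  # [0, 100]
    fraction_id: str = ""

    def __post_init__(self) -> None:
        if self.construct not in ("WT", "NLSm"):
            raise ValueError(f"construct must be 'WT' or 'NLSm', got {self.construct!r}")
        if self.construct_level < 0 or self.endogenous_level < 0:
            raise ValueError("expression levels must be >= 0")
        if not 0.0 <= self.skipping_percent <= 100.0:
            raise ValueError(
                f"skipping_percent must be in [0, 100], got {self.skipping_percent}"
            )


def total_nuclear_tdp43(
    endogenous_level: float,
    construct_level: float,
    construct: Construct,
    diffusion_fraction: float = DEFAULT_DIFFUSION_FRACTION,
) -> float:
    """Total nuclear TDP-43 in multiples of normal.

    WT constructs are fully nuclear; NLSm constructs contribute only their
    passively diffusing fraction.
    """
    if endogenous_level < 0 or construct_level < 0:
        raise ValueError("expression levels must be >= 0")
    if not 0.0 <= diffusion_fraction <= 1.0:
        raise ValueError(
            f"diffusion_fraction must be in [0, 1], got {diffusion_fraction}"
        )
    if construct not in ("WT", "NLSm"):
        raise ValueError(f"construct must be 'WT' or 'NLSm', got {construct!r}")
    if construct == "WT":
        return endogenous_level + construct_level
    return endogenous_level + diffusion_fraction * construct_level


@dataclass(frozen=True)
class ResponseCurve:
    """Non-decreasing piecewise-linear skipping response vs. nuclear fold.

    Evaluation between knots interpolates linearly; beyond the knot range the
    terminal values are clamped.
    """

    folds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        folds = np.asarray(self.folds, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "folds", folds)
        object.__setattr__(self, "values", values)
        if folds.ndim != 1 or folds.shape != values.shape or folds.size < 2:
            raise ValueError("a response curve needs >= 2 (fold, value) knots")
        if np.any(np.diff(folds) <= 0):
            raise ValueError("curve folds must be strictly increasing")
        if np.any(np.diff(values) < -1e-12):
            raise ValueError("curve values must be non-decreasing")

    def __call__(self, fold):
        return np.interp(fold, self.folds, self.values)

    @property
    def min_value(self) -> float:
        return float(self.values[0])

    @property
    def max_value(self) -> float:
        return float(self.values[-1])

    def invert(self, response: float) -> float | None:
        """Smallest fold mapping to ``response``; None when not bracketed.

        On a flat segment whose value equals ``response``, the leftmost fold is
        returned.
        """
        if response < self.min_value or response > self.max_value:
            return None
        idx = int(np.searchsorted(self.values, response, side="left"))
        if idx < self.values.size and self.values[idx] == response:
            return float(self.folds[idx])
        lo, hi = idx - 1, idx
        span = self.values[hi] - self.values[lo]
        frac = (response - self.values[lo]) / span
        return float(self.folds[lo] + frac * (self.folds[hi] - self.folds[lo]))


def fit_response_curve(
    observations: Iterable[DoseObservation],
    diffusion_fraction: float = DEFAULT_DIFFUSION_FRACTION,
) -> ResponseCurve:
    """Isotonic piecewise-linear fit of skipping vs. total nuclear fold.

    Folds are computed per observation from its construct rule; violations of
    monotonicity are pooled by isotonic regression (pool-adjacent-violators
    with equal weights).
    """
    observations = list(observations)
    folds = np.array(
        [
            total_nuclear_tdp43(
                o.endogenous_level, o.construct_level, o.construct, diffusion_fraction
            )
            for o in observations
        ]
    )
    values = np.array([o.skipping_percent for o in observations])
    return fit_curve_from_points(folds, values)


def fit_curve_from_points(
    folds: Sequence[float], values: Sequence[float]
) -> ResponseCurve:
    """Isotonic piecewise-linear curve through raw (fold, response) points."""
    folds = np.asarray(folds, dtype=float)
    values = np.asarray(values, dtype=float)
    unique_folds = np.unique(folds)
    if unique_folds.size < 2:
        raise DataError(
            "fitting a response curve requires >= 2 distinct total-nuclear folds"
        )
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(folds, values)
    fitted = iso.predict(unique_folds)
    return ResponseCurve(folds=unique_folds, values=fitted)


@dataclass(frozen=True, slots=True)
class DiffusionEstimate:
    """Median and spread of per-point passive-diffusion estimates."""

    median: float
    low: float
    high: float
    per_point: tuple[float, ...]
    n_matched: int


def estimate_diffusion_fraction(
    wt_obs: Iterable[DoseObservation],
    nlsm_obs: Iterable[DoseObservation],
) -> DiffusionEstimate:
    """Estimate the NLSm passive-diffusion fraction by equal-response matching.

    The wild-type observations define the response curve; every NLSm
    observation whose skipping response the curve brackets is inverted to its
    equivalent nuclear fold. Estimates are clipped to [0, 1].
    """
    curve = fit_response_curve(list(wt_obs), diffusion_fraction=1.0)
    estimates: list[float] = []
    for obs in nlsm_obs:
        if obs.construct_level <= 0:
            continue
        fold = curve.invert(obs.skipping_percent)
        if fold is None:
            continue
        est = (fold - obs.endogenous_level) / obs.construct_level
        estimates.append(float(np.clip(est, 0.0, 1.0)))
    if not estimates:
        raise DataError(
            "no NLSm observation falls within the wild-type response range; "
            "the diffusion fraction cannot be estimated"
        )
    return DiffusionEstimate(
        median=float(np.median(estimates)),
        low=min(estimates),
        high=max(estimates),
        per_point=tuple(estimates),
        n_matched=len(estimates),
    )


def skipping_threshold(
    response_curve: ResponseCurve,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> float:
    """Smallest fold >= 1 whose response reaches the detection floor.

    Found by linear inversion of the piecewise-linear curve. Returns
    ``math.inf`` when the floor is never reached (onset not attained).
    """
    if not 0.0 <= detection_floor <= 100.0:
        raise ValueError(
            f"detection_floor must be in [0, 100] percent, got {detection_floor}"
        )
    start = float(response_curve(1.0))
    if start >= detection_floor:
        return 1.0
    if response_curve.max_value < detection_floor:
        return math.inf
    folds, values = response_curve.folds, response_curve.values
    prev_fold, prev_value = 1.0, start
    for fold, value in zip(folds, values):
        if fold <= 1.0:
            continue
        if value >= detection_floor:
            if value == prev_value:
                return float(fold)
            frac = (detection_floor - prev_value) / (value - prev_value)
            return float(max(1.0, prev_fold + frac * (fold - prev_fold)))
        prev_fold, prev_value = float(fold), float(value)
    return math.inf


@dataclass(frozen=True)
class DoseModelFit:
    """Fitted dose model: diffusion fraction, response curve, onset fold."""

    diffusion_fraction: float
    diffusion_range: tuple[float, float] | None
    response_curve: ResponseCurve
    threshold_fold: float
    detection_floor: float
    n_wt: int = 0
    n_nlsm: int = 0
    per_point: tuple[float, ...] = field(default_factory=tuple)

    def summary(self) -> dict:
        return {
            "diffusion_fraction": self.diffusion_fraction,
            "diffusion_range": list(self.diffusion_range)
            if self.diffusion_range
            else None,
            "threshold_fold": None
            if math.isinf(self.threshold_fold)
            else self.threshold_fold,
            "threshold_attained": not math.isinf(self.threshold_fold),
            "detection_floor_percent": self.detection_floor,
            "n_wt": self.n_wt,
            "n_nlsm": self.n_nlsm,
        }


def fit_dose_model(
    observations: Iterable[DoseObservation],
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> DoseModelFit:
    """Full dose-model fit from a mixed WT/NLSm observation table.

    The WT series defines the response curve and the onset threshold; the
    NLSm series, when present, yields the diffusion-fraction estimate
    (otherwise the 0.45 default is carried through).
    """
    observations = list(observations)
    wt = [o for o in observations if o.construct == "WT"]
    nlsm = [o for o in observations if o.construct == "NLSm"]
    if len(wt) < 2:
        raise DataError("dose model requires >= 2 wild-type observations")
    curve = fit_response_curve(wt, diffusion_fraction=1.0)
    if nlsm:
        est = estimate_diffusion_fraction(wt, nlsm)
        fraction, rng, per_point = est.median, (est.low, est.high), est.per_point
    else:
        fraction, rng, per_point = DEFAULT_DIFFUSION_FRACTION, None, ()
    return DoseModelFit(
        diffusion_fraction=fraction,
        diffusion_range=rng,
        response_curve=curve,
        threshold_fold=skipping_threshold(curve, detection_floor),
        detection_floor=detection_floor,
        n_wt=len(wt),
        n_nlsm=len(nlsm),
        per_point=per_point,
    )


def read_dose_tsv(path: str | Path) -> list[DoseObservation]:
    """Read a dose table (construct, fraction_id, construct_level,
    endogenous_level, skipping_percent)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"construct", "construct_level", "endogenous_level", "skipping_percent"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"dose table missing columns: {sorted(missing)}")
    return [
        DoseObservation(
            construct=str(row.construct),
            construct_level=float(row.construct_level),
            endogenous_level=float(row.endogenous_level),
            skipping_percent=float(row.skipping_percent),
            fraction_id=str(getattr(row, "fraction_id", "")),
        )
        for row in frame.itertuples(index=False)
    ]


def write_dose_tsv(observations: Iterable[DoseObservation], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "# levels in multiples of normal endogenous TDP-43; skipping in percent\n"
        )
        pd.DataFrame(
            [
                {
                    "construct": o.construct,
                    "fraction_id": o.fraction_id,
                    "construct_level": o.construct_level,
                    "endogenous_level": o.endogenous_level,
                    "skipping_percent": o.skipping_percent,
                }
                for o in observations
            ]
        ).to_csv(handle, sep="\t", index=False)
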