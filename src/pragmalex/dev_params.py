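"""Developmental parameter trajectories: map age, object and condition to model parameters.

Each sensitivity follows a regression on age centred at ``AGE_CENTER`` years:

* speaker informativeness ``alpha`` — linear predictor, clipped at zero
  (``identity_clip``; a log link is available as a config switch);
* common-ground sensitivity ``rho`` and semantic knowledge ``theta`` —
  logistic (inverse-logit of intercept + slope * centred age), with
  object-specific intercept/slope offsets for ``theta`` (random effects around
  the population trajectory);
* the bias weight ``phi`` of the biased models — logistic, slope fixed to
  zero for the constant-bias variant.

Common ground enters the referent prior by condition: the contextually new
object carries prior ``rho`` when novelty is congruent with the
mutual-exclusivity inference and ``1 - rho`` when incongruent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from .rsa_core import BIASED_MODELS, ModelName, ParamSlice

__all__ = [
    "AGE_CENTER",
    "DEFAULT_OBJECT_IDS",
    "Condition",
    "TrajectoryCoefficients",
    "alpha_at",
    "logistic_trajectory_at",
    "prior_novel_for",
    "param_slice_at",
]

AGE_CENTER = 3.0
"""Age (years) at which all regression intercepts are evaluated."""

N_OBJECTS = 12
DEFAULT_OBJECT_IDS: Tuple[str, ...] = tuple(f"obj{i:02d}" for i in range(1, 13))


class Condition(str, enum.Enum):
    """Alignment between discourse novelty and the mutual-exclusivity inference.

    ``NONE`` marks trials without a common-ground manipulation (Experiments 1-2).
    """

    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"
    NONE = "none"


@dataclass(frozen=True)
class TrajectoryCoefficients:
    """Intercepts and slopes defining every parameter's age trajectory.

    ``theta_object_intercepts``/``theta_object_slopes`` are per-object
    deviations (logit scale) around the population semantic-knowledge
    trajectory, one pair per familiar object, indexed like ``object_ids``.
    """

    alpha_intercept: float
    alpha_slope: float
    rho_intercept: float
    rho_slope: float
    theta_intercept: float
    theta_slope: float
    theta_object_intercepts: np.ndarray
    theta_object_slopes: np.ndarray
    phi_intercept: Optional[float] = None
    phi_slope: Optional[float] = None
    object_ids: Tuple[str, ...] = DEFAULT_OBJECT_IDS
    alpha_link: str = "identity_clip"

    def __post_init__(self) -> None:
        oi = np.asarray(self.theta_object_intercepts, dtype=float)
        os_ = np.asarray(self.theta_object_slopes, dtype=float)
        object.__setattr__(self, "theta_object_intercepts", oi)
        object.__setattr__(self, "theta_object_slopes", os_)
        if oi.shape != (len(self.object_ids),) or os_.shape != (len(self.object_ids),):
            raise ValueError(
                "need exactly one (intercept, slope) offset pair per object: "
                f"{len(self.object_ids)} objects, offsets {oi.shape}/{os_.shape}"
            )
        if self.alpha_link not in ("identity_clip", "log"):
            raise ValueError(f"unknown alpha_link {self.alpha_link!r}")

    def object_index(self, object_id: str) -> int:
        try:
            return self.object_ids.index(object_id)
        except ValueError:
            raise KeyError(
                f"unknown object {object_id!r}; configured: {self.object_ids}"
            ) from None

    def with_phi(self, phi_intercept: float, phi_slope: float = 0.0) -> "TrajectoryCoefficients":
        return replace(self, phi_intercept=phi_intercept, phi_slope=phi_slope)


def alpha_at(
    age,
    coeffs: TrajectoryCoefficients,
    age_center: float = AGE_CENTER,
):
    """Speaker informativeness at ``age``: linear in centred age, floored at 0."""
    age = np.asarray(age, dtype=float)
    eta = coeffs.alpha_intercept + coeffs.alpha_slope * (age - age_center)
    if coeffs.alpha_link == "log":
        return np.exp(eta)
    return np.maximum(0.0, eta)


def logistic_trajectory_at(
    age,
    intercept: float,
    slope: float,
    offsets: Optional[Tuple[float, float]] = None,
    age_center: float = AGE_CENTER,
):
    """Inverse-logit trajectory, optionally shifted by (intercept, slope) offsets."""
    age = np.asarray(age, dtype=float)
    off_i, off_s = offsets if offsets is not None else (0.0, 0.0)
    return expit(intercept + off_i + (slope + off_s) * (age - age_center))


def prior_novel_for(condition: Condition, rho: float):
    """Referent prior on the novel object implied by the condition.

    Congruent: the novel object is also the contextually new one → prior rho.
    Incongruent: the familiar object is new in context → the novel object
    carries 1 - rho. No manipulation → uniform.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0) or np.any(rho_arr > 1):
        raise ValueError("rho must lie in [0, 1]")
    condition = Condition(condition)
    if condition is Condition.CONGRUENT:
        return rho_arr + 0.0
    if condition is Condition.INCONGRUENT:
        return 1.0 - rho_arr
    return np.full_like(rho_arr, 0.5)


def param_slice_at(
    age: float,
    object_id: Optional[str],
    condition: Condition,
    coeffs: TrajectoryCoefficients,
    model: ModelName = ModelName.INTEGRATION,
    age_center: float = AGE_CENTER,
):
    """Assemble the ParamSlice one model needs for one trial cell.

    Returns ``(params, theta_pooled)``; ``theta_pooled`` is the object-blind
    semantic-knowledge value and is ``None`` except for the no-word-knowledge
    model. The no-common-ground lesion forces a uniform prior; the
    no-speaker-informativeness lesion forces ``alpha = 0``.
    """
    model = ModelName(model)
    condition = Condition(condition)
    alpha = float(alpha_at(age, coeffs, age_center))
    if model is ModelName.NO_SPEAKER_INFORMATIVENESS:
        alpha = 0.0

    if object_id is None:
        offsets = (0.0, 0.0)
    else:
        j = coeffs.object_index(object_id)
        offsets = (
            float(coeffs.theta_object_intercepts[j]),
            float(coeffs.theta_object_slopes[j]),
        )
    theta = float(
        logistic_trajectory_at(
            age, coeffs.theta_intercept, coeffs.theta_slope, offsets, age_center
        )
    )

    rho = float(
        logistic_trajectory_at(age, coeffs.rho_intercept, coeffs.rho_slope, None, age_center)
    )
    if model is ModelName.NO_COMMON_GROUND:
        prior = 0.5
    else:
        prior = float(prior_novel_for(condition, rho))

    phi = None
    if model in BIASED_MODELS:
        if coeffs.phi_intercept is None:
            raise ValueError(f"model {model.value!r} requires phi coefficients")
        phi_slope = coeffs.phi_slope or 0.0
        if model is ModelName.BIASED:
            phi_slope = 0.0  # constant bias: intercept only
        phi = float(
            logistic_trajectory_at(age, coeffs.phi_intercept, phi_slope, None, age_center)
        )

    theta_pooled = None
    if model is ModelName.NO_WORD_KNOWLEDGE:
        theta_pooled = float(
            logistic_trajectory_at(
                age, coeffs.theta_intercept, coeffs.theta_slope, None, age_center
            )
        )

    return ParamSlice(alpha=alpha, theta=theta, prior_novel=prior, phi=phi), theta_pooled
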