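"""Rational-speech-act core: listener/speaker recursion for two-referent scenes.

The scene is always the same: two referents (a novel object without a label in
the child's lexicon, and a familiar object) and two candidate utterances (the
novel word actually produced by the speaker, and the familiar word she could
have produced). A pragmatic listener (L1) infers the referent of the novel
word by reasoning about an informative speaker (S1), who in turn reasons about
a literal listener (L0) with graded lexical knowledge.

Semantics of the familiar word follow a lexicon-uncertainty mixture: with
probability ``theta`` the listener knows the word and it denotes the familiar
object exclusively; with probability ``1 - theta`` the word is unknown and
applies to either referent. The novel word never denotes anything in
particular and always applies uniformly. This choice yields the limiting
behaviour the model family requires: ``theta = 0`` or ``alpha = 0`` collapse
the posterior onto the referent prior, while ``theta = 1`` gives the classic
mutual-exclusivity inference.

All heavy lifting happens in vectorised kernels (``*_p_novel`` functions)
that accept numpy arrays; the dataclass API wraps them for scalar use.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "Referent",
    "Utterance",
    "ModelName",
    "ParamSlice",
    "ReferentDistribution",
    "UtteranceDistribution",
    "DegenerateSceneError",
    "literal_listener",
    "speaker",
    "integrate",
    "mutual_exclusivity",
    "biased_mix",
    "predict_choice",
    "integrate_p_novel",
    "mutual_exclusivity_p_novel",
    "biased_p_novel",
    "choice_probability",
]

_NORM_TOL = 1e-12


class Referent(enum.Enum):
    """One of the two objects in a scene."""

    NOVEL_OBJECT = "novel_object"
    FAMILIAR_OBJECT = "familiar_object"


class Utterance(enum.Enum):
    """One of the two candidate words; the speaker always utters the novel word."""

    NOVEL_WORD = "novel_word"
    FAMILIAR_WORD = "familiar_word"


class ModelName(str, enum.Enum):
    """The six model variants: the full integration model, three lesions, two biased."""

    INTEGRATION = "integration"
    NO_WORD_KNOWLEDGE = "no_word_knowledge"
    NO_COMMON_GROUND = "no_common_ground"
    NO_SPEAKER_INFORMATIVENESS = "no_speaker_informativeness"
    BIASED = "biased"
    DEVELOPMENTAL_BIAS = "developmental_bias"


BIASED_MODELS = frozenset({ModelName.BIASED, ModelName.DEVELOPMENTAL_BIAS})


class DegenerateSceneError(ValueError):
    """Raised when a distribution cannot be normalised (all mass zero)."""


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ParamSlice:
    """Point parameters at which one model prediction is evaluated.

    Parameters
    ----------
    alpha
        Speaker informativeness (soft-max exponent), >= 0.
    theta
        Probability the listener knows the familiar word, in [0, 1].
    prior_novel
        Prior probability that the novel object is the referent, in [0, 1].
    phi
        Mutual-exclusivity bias weight, in [0, 1]; only the biased models use it.
    """

    alpha: float
    theta: float
    prior_novel: float
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        _check_unit("theta", self.theta)
        _check_unit("prior_novel", self.prior_novel)
        if self.phi is not None:
            _check_unit("phi", self.phi)


@dataclass(frozen=True)
class ReferentDistribution:
    """Normalised probability over {novel object, familiar object}."""

    p_novel: float
    p_familiar: float

    def __post_init__(self) -> None:
        if self.p_novel < 0 or self.p_familiar < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_novel + self.p_familiar - 1.0) > _NORM_TOL:
            raise ValueError("referent distribution must sum to 1")


@dataclass(frozen=True)
class UtteranceDistribution:
    """Normalised probability over {novel word, familiar word}."""

    p_novel_word: float
    p_familiar_word: float

    def __post_init__(self) -> None:
        if self.p_novel_word < 0 or self.p_familiar_word < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_novel_word + self.p_familiar_word - 1.0) > _NORM_TOL:
            raise ValueError("utterance distribution must sum to 1")


# ---------------------------------------------------------------------------
# vectorised kernels
# ---------------------------------------------------------------------------

def _speaker_p_novel_word(ratio, alpha):
    """P_S1(novel_word | r) where ``ratio`` = L0(r|familiar_word)/L0(r|novel_word).

    Equals expit(-alpha * log(ratio)); computed with guards so that exact
    endpoints (theta = 1, alpha = 0, very large alpha) propagate exactly.
    """
    ratio = np.asarray(ratio, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = alpha * np.log(ratio)
    # alpha = 0 flattens the choice regardless of the (possibly -inf) log-ratio
    t = np.where(alpha == 0, 0.0, t)
    t = np.where((ratio == 0) & (alpha > 0), -np.inf, t)
    return expit(-t)


def speaker_p_novel_word_given_novel(alpha, theta):
    """P_S1(novel_word | novel object); in [1/2, 1]."""
    return _speaker_p_novel_word(1.0 - np.asarray(theta, dtype=float), alpha)


def speaker_p_novel_word_given_familiar(alpha, theta):
    """P_S1(novel_word | familiar object); in (0, 1/2]."""
    return _speaker_p_novel_word(1.0 + np.asarray(theta, dtype=float), alpha)


def integrate_p_novel(alpha, theta, prior_novel):
    """P_L1(novel object | novel word) for the rational-integration listener.

    p_novel ∝ prior_novel * P_S1(novel_word|novel);
    p_familiar ∝ (1 - prior_novel) * P_S1(novel_word|familiar).
    Broadcasts over array arguments.
    """
    prior_novel = np.asarray(prior_novel, dtype=float)
    s_nov = speaker_p_novel_word_given_novel(alpha, theta)
    s_fam = speaker_p_novel_word_given_familiar(alpha, theta)
    num = prior_novel * s_nov
    den = num + (1.0 - prior_novel) * s_fam
    with np.errstate(invalid="ignore"):
        out = num / den
    return out


def mutual_exclusivity_p_novel(alpha, theta):
    """Mutual-exclusivity inference: integration under a uniform referent prior."""
    return integrate_p_novel(alpha, theta, 0.5)


def biased_p_novel(phi, me_p_novel, prior_novel):
    """Convex mixture of the ME inference and the common-ground prior."""
    phi = np.asarray(phi, dtype=float)
    return phi * np.asarray(me_p_novel, dtype=float) + (1.0 - phi) * np.asarray(
        prior_novel, dtype=float
    )


def choice_probability(
    model: ModelName,
    alpha,
    theta,
    prior_novel,
    phi=None,
    theta_pooled=None,
):
    """Vectorised probability of choosing the novel object, per model variant."""
    model = ModelName(model)
    if model is ModelName.INTEGRATION:
        return integrate_p_novel(alpha, theta, prior_novel)
    if model is ModelName.NO_WORD_KNOWLEDGE:
        if theta_pooled is None:
            raise ValueError("no_word_knowledge requires theta_pooled")
        return integrate_p_novel(alpha, theta_pooled, prior_novel)
    if model is ModelName.NO_COMMON_GROUND:
        return mutual_exclusivity_p_novel(alpha, theta)
    if model is ModelName.NO_SPEAKER_INFORMATIVENESS:
        return np.asarray(prior_novel, dtype=float) + 0.0
    if model in BIASED_MODELS:
        if phi is None:
            raise ValueError(f"{model.value} requires phi")
        return biased_p_novel(phi, mutual_exclusivity_p_novel(alpha, theta), prior_novel)
    raise ValueError(f"unknown model {model!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# scalar dataclass API
# ---------------------------------------------------------------------------

def literal_listener(utterance: Utterance, theta: float) -> ReferentDistribution:
    """Literal listener L0: interpret one utterance under the mixture lexicon."""
    _check_unit("theta", theta)
    if Utterance(utterance) is Utterance.NOVEL_WORD:
        return ReferentDistribution(p_novel=0.5, p_familiar=0.5)
    # familiar word: theta * exclusive familiar denotation + (1-theta) * uniform
    p_familiar = theta * 1.0 + (1.0 - theta) * 0.5
    return ReferentDistribution(p_novel=1.0 - p_familiar, p_familiar=p_familiar)


def speaker(referent: Referent, alpha: float, theta: float) -> UtteranceDistribution:
    """Informative speaker S1: soft-max over utterance informativities with exponent alpha."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha!r}")
    _check_unit("theta", theta)
    if Referent(referent) is Referent.NOVEL_OBJECT:
        p_nov_word = float(speaker_p_novel_word_given_novel(alpha, theta))
    else:
        p_nov_word = float(speaker_p_novel_word_given_familiar(alpha, theta))
    if not np.isfinite(p_nov_word):
        raise DegenerateSceneError("speaker distribution is unnormalisable")
    return UtteranceDistribution(p_novel_word=p_nov_word, p_familiar_word=1.0 - p_nov_word)


def integrate(params: ParamSlice) -> ReferentDistribution:
    """Pragmatic listener L1 hearing the novel word: speaker likelihood x referent prior."""
    p = integrate_p_novel(params.alpha, params.theta, params.prior_novel)
    p = float(p)
    if not np.isfinite(p):
        raise DegenerateSceneError(
            "all referent mass is zero; cannot normalise the posterior"
        )
    return ReferentDistribution(p_novel=p, p_familiar=1.0 - p)


def mutual_exclusivity(alpha: float, theta: float) -> ReferentDistribution:
    """ME inference: integration with a uniform referent prior (no common ground)."""
    return integrate(ParamSlice(alpha=alpha, theta=theta, prior_novel=0.5))


def biased_mix(
    phi: float, me: ReferentDistribution, prior_novel: float
) -> ReferentDistribution:
    """Weight the ME inference against the common-ground prior by phi."""
    _check_unit("phi", phi)
    _check_unit("prior_novel", prior_novel)
    p = float(biased_p_novel(phi, me.p_novel, prior_novel))
    return ReferentDistribution(p_novel=p, p_familiar=1.0 - p)


def predict_choice(
    model: ModelName,
    params: ParamSlice,
    theta_pooled: Optional[float] = None,
) -> float:
    """Probability of choosing the condition's correct referent under one model.

    ``theta_pooled`` (the age-level semantic-knowledge trajectory without
    object-specific variation) must be given exactly for the no-word-knowledge
    model; ``params.phi`` must be set exactly for the biased models.
    """
    model = ModelName(model)
    needs_phi = model in BIASED_MODELS
    if needs_phi and params.phi is None:
        raise ValueError(f"model {model.value!r} requires ParamSlice.phi")
    if not needs_phi and params.phi is not None:
        raise ValueError(f"model {model.value!r} does not accept ParamSlice.phi")
    if model is ModelName.NO_WORD_KNOWLEDGE:
        if theta_pooled is None:
            raise ValueError("no_word_knowledge requires theta_pooled")
        _check_unit("theta_pooled", theta_pooled)
    elif theta_pooled is not None:
        raise ValueError(f"model {model.value!r} does not accept theta_pooled")
    return float(
        choice_probability(
            model,
            params.alpha,
            params.theta,
            params.prior_novel,
            phi=params.phi,
            theta_pooled=theta_pooled,
        )
    )
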