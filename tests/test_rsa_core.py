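"""Listener/speaker recursion: frozen examples, limits and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pragmalex.rsa_core import (
    ModelName,
    ParamSlice,
    Referent,
    Utterance,
    biased_mix,
    integrate,
    integrate_p_novel,
    literal_listener,
    mutual_exclusivity,
    predict_choice,
    speaker,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate the 2x2 utterance/referent scene
# ---------------------------------------------------------------------------

def oracle_l0(theta):
    """Meaning-weighted interpretation: rows = utterance, cols = (novel, familiar)."""
    fam_word = np.array([(1 - theta) * 0.5, theta * 1.0 + (1 - theta) * 0.5])
    nov_word = np.array([0.5, 0.5])
    return {
        "familiar_word": fam_word / fam_word.sum(),
        "novel_word": nov_word / nov_word.sum(),
    }


def oracle_speaker(referent_index, alpha, theta):
    l0 = oracle_l0(theta)
    scores = np.array(
        [l0["novel_word"][referent_index] ** alpha, l0["familiar_word"][referent_index] ** alpha]
    )
    return scores / scores.sum()  # (novel_word, familiar_word)


def oracle_integrate(alpha, theta, prior_novel):
    post = np.array(
        [
            prior_novel * oracle_speaker(0, alpha, theta)[0],
            (1 - prior_novel) * oracle_speaker(1, alpha, theta)[0],
        ]
    )
    return post[0] / post.sum()


# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "utterance, theta, expected",
    [
        (Utterance.FAMILIAR_WORD, 1.0, (0.0, 1.0)),
        (Utterance.NOVEL_WORD, 0.3, (0.5, 0.5)),
        (Utterance.FAMILIAR_WORD, 0.5, (0.25, 0.75)),
    ],
)
def test_literal_listener_examples(utterance, theta, expected):
    d = literal_listener(utterance, theta)
    assert d.p_novel == pytest.approx(expected[0], abs=1e-12)
    assert d.p_familiar == pytest.approx(expected[1], abs=1e-12)


@pytest.mark.parametrize(
    "referent, alpha, theta, p_fam_word",
    [
        (Referent.FAMILIAR_OBJECT, 1.0, 1.0, 2 / 3),
        (Referent.FAMILIAR_OBJECT, 0.0, 0.7, 0.5),
        (Referent.NOVEL_OBJECT, 0.0, 0.2, 0.5),
    ],
)
def test_speaker_examples(referent, alpha, theta, p_fam_word):
    d = speaker(referent, alpha, theta)
    assert d.p_familiar_word == pytest.approx(p_fam_word, abs=1e-12)


def test_speaker_argmax_limit():
    d = speaker(Referent.FAMILIAR_OBJECT, 50.0, 1.0)
    assert d.p_familiar_word > 1 - 1e-9


@pytest.mark.parametrize(
    "alpha, theta, prior, p_novel",
    [
        (1.0, 1.0, 0.5, 0.75),
        (0.0, 0.9, 0.8, 0.8),  # alpha = 0: posterior equals the prior
        (1.0, 0.0, 0.3, 0.3),  # theta = 0: both words uninformative
    ],
)
def test_integrate_examples(alpha, theta, prior, p_novel):
    d = integrate(ParamSlice(alpha=alpha, theta=theta, prior_novel=prior))
    assert d.p_novel == pytest.approx(p_novel, abs=1e-12)
    assert d.p_novel == pytest.approx(oracle_integrate(alpha, theta, prior), abs=1e-10)


@pytest.mark.parametrize(
    "alpha, theta, p_novel",
    [
        (1.0, 1.0, 0.75),
        (0.0, 1.0, 0.5),
        (2.0, 1.0, 5.0 / 6.0),  # enumeration: s_nov = 1, s_fam = 1/5 at uniform prior
    ],
)
def test_mutual_exclusivity_examples(alpha, theta, p_novel):
    d = mutual_exclusivity(alpha, theta)
    assert d.p_novel == pytest.approx(p_novel, abs=1e-12)
    assert d.p_novel == pytest.approx(oracle_integrate(alpha, theta, 0.5), abs=1e-10)


def test_biased_mix_examples():
    me = mutual_exclusivity(1.0, 1.0)  # p_novel = 0.75
    assert biased_mix(1.0, me, 0.9).p_novel == pytest.approx(0.75)
    assert biased_mix(0.0, me, 0.9).p_novel == pytest.approx(0.9)
    assert biased_mix(0.65, me, 0.5).p_novel == pytest.approx(0.6625)


def test_predict_choice_dispatch():
    assert predict_choice(
        ModelName.NO_SPEAKER_INFORMATIVENESS, ParamSlice(0.0, 0.5, 0.7)
    ) == pytest.approx(0.7)
    # the no-common-ground lesion ignores the condition prior entirely
    high = predict_choice(ModelName.NO_COMMON_GROUND, ParamSlice(1.0, 1.0, 0.9))
    low = predict_choice(ModelName.NO_COMMON_GROUND, ParamSlice(1.0, 1.0, 0.1))
    assert high == pytest.approx(0.75) and high == low
    assert predict_choice(
        ModelName.INTEGRATION, ParamSlice(1.0, 1.0, 0.5)
    ) == pytest.approx(0.75)
    nwk = predict_choice(
        ModelName.NO_WORD_KNOWLEDGE, ParamSlice(1.0, 0.9, 0.5), theta_pooled=0.4
    )
    assert nwk == pytest.approx(oracle_integrate(1.0, 0.4, 0.5), abs=1e-10)


def test_predict_choice_configuration_errors():
    with pytest.raises(ValueError):
        predict_choice(ModelName.BIASED, ParamSlice(1.0, 0.5, 0.5))  # phi missing
    with pytest.raises(ValueError):
        predict_choice(ModelName.INTEGRATION, ParamSlice(1.0, 0.5, 0.5, phi=0.5))
    with pytest.raises(ValueError):
        predict_choice(ModelName.NO_WORD_KNOWLEDGE, ParamSlice(1.0, 0.5, 0.5))
    with pytest.raises(ValueError):
        predict_choice(ModelName.INTEGRATION, ParamSlice(1.0, 0.5, 0.5), theta_pooled=0.3)


def test_domain_errors():
    with pytest.raises(ValueError):
        literal_listener(Utterance.FAMILIAR_WORD, 1.2)
    with pytest.raises(ValueError):
        speaker(Referent.NOVEL_OBJECT, -0.5, 0.5)
    with pytest.raises(ValueError):
        ParamSlice(alpha=1.0, theta=0.5, prior_novel=0.5, phi=1.5)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

unit = st.floats(0.0, 1.0, allow_nan=False)
alphas = st.floats(0.0, 5.0, allow_nan=False)


@settings(max_examples=300, deadline=None)
@given(alpha=alphas, theta=unit, prior=unit)
def test_oracle_equivalence_and_normalization(alpha, theta, prior):
    d = integrate(ParamSlice(alpha=alpha, theta=theta, prior_novel=prior))
    assert abs(d.p_novel + d.p_familiar - 1.0) < 1e-12
    assert d.p_novel == pytest.approx(oracle_integrate(alpha, theta, prior), abs=1e-10)
    s = speaker(Referent.FAMILIAR_OBJECT, alpha, theta)
    assert abs(s.p_novel_word + s.p_familiar_word - 1.0) < 1e-12
    assert s.p_novel_word == pytest.approx(
        oracle_speaker(1, alpha, theta)[0], abs=1e-10
    )


@settings(max_examples=200, deadline=None)
@given(alpha=alphas, theta=unit, prior=unit, phi=unit)
def test_limit_identities(alpha, theta, prior, phi):
    assert integrate(ParamSlice(0.0, theta, prior)).p_novel == pytest.approx(prior, abs=1e-12)
    assert integrate(ParamSlice(alpha, 0.0, prior)).p_novel == pytest.approx(prior, abs=1e-12)
    me = mutual_exclusivity(alpha, theta)
    assert biased_mix(0.0, me, prior).p_novel == pytest.approx(prior, abs=1e-12)
    assert biased_mix(1.0, me, prior).p_novel == pytest.approx(me.p_novel, abs=1e-12)
    # biased output always lies between its two components
    b = biased_mix(phi, me, prior).p_novel
    assert min(me.p_novel, prior) - 1e-12 <= b <= max(me.p_novel, prior) + 1e-12


def test_monotonicity_on_grid():
    """Integration p_novel is nondecreasing in alpha, theta and the prior."""
    alpha = np.linspace(0, 5, 21)
    theta = np.linspace(0, 1, 21)
    prior = np.linspace(0, 1, 21)
    p_a = integrate_p_novel(alpha[:, None, None], theta[None, :, None], prior[None, None, 1:-1])
    assert np.all(np.diff(p_a, axis=0) >= -1e-12)
    assert np.all(np.diff(p_a, axis=1) >= -1e-12)
    p_r = integrate_p_novel(alpha[:, None, None], theta[None, :, None], prior[None, None, :])
    assert np.all(np.diff(p_r, axis=2) >= -1e-12)


def test_congruent_dominance():
    """With aligned cues the integration model out-predicts every lesion."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        alpha = rng.uniform(0.1, 4.0)
        theta = rng.uniform(0.05, 1.0)
        prior = rng.uniform(0.5 + 1e-6, 1.0)
        theta_pooled = rng.uniform(0.0, theta)  # pooled knowledge below object-specific
        full = integrate_p_novel(alpha, theta, prior)
        assert full > integrate_p_novel(alpha, theta_pooled, prior) - 1e-12
        assert full > integrate_p_novel(alpha, theta, 0.5)
        assert full > prior
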