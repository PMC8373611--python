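"""Internal: encode trial tables as arrays and evaluate choice probabilities.

One code path computes the per-trial probability of a correct response for
any model variant and any batch of coefficient values; the simulator (batch
of one), the sampler and the evidence estimator all call it, so likelihood
evaluation is identical everywhere. The arithmetic itself lives in the
numba kernels of ``_kernels``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import MODEL_CODES, bernoulli_loglik_kernel, probability_kernel
from .dev_params import AGE_CENTER, Condition
from .rsa_core import BIASED_MODELS, ModelName

COND_CODES = {Condition.NONE: 0, Condition.CONGRUENT: 1, Condition.INCONGRUENT: 2}

TRIAL_COLUMNS = ["child_id", "age", "experiment", "condition", "object_id", "correct"]


@dataclass(frozen=True)
class TrialArrays:
    """Columnar view of a trial table, ready for vectorised evaluation."""

    age_c: np.ndarray  # age - AGE_CENTER, (N,)
    obj_idx: np.ndarray  # int index into the object roster; -1 when blank
    cond: np.ndarray  # 0 none / 1 congruent / 2 incongruent
    exp: np.ndarray  # 1 / 2 / 3
    correct: Optional[np.ndarray]  # 0/1, absent for pure prediction grids

    @property
    def n(self) -> int:
        return self.age_c.shape[0]


def trial_arrays(
    df: pd.DataFrame,
    object_ids: Sequence[str],
    age_center: float = AGE_CENTER,
    require_correct: bool = True,
) -> TrialArrays:
    obj_lookup = {oid: i for i, oid in enumerate(object_ids)}
    obj_col = df["object_id"].fillna("").astype(str)
    obj_idx = np.array([obj_lookup.get(o, -1) for o in obj_col], dtype=np.int64)
    bad = (obj_idx < 0) & (obj_col != "").to_numpy()
    if bad.any():
        unknown = sorted(set(obj_col[bad]))
        raise ValueError(f"unknown object ids {unknown}; roster: {list(object_ids)}")
    cond = np.array(
        [COND_CODES[Condition(c)] for c in df["condition"].astype(str)], dtype=np.int64
    )
    exp = df["experiment"].astype(str).str.replace("exp", "", regex=False).astype(np.int64).to_numpy()
    correct = None
    if require_correct:
        correct = df["correct"].to_numpy(dtype=float)
    return TrialArrays(
        age_c=np.ascontiguousarray(df["age"].to_numpy(dtype=float) - age_center),
        obj_idx=obj_idx,
        cond=cond,
        exp=exp,
        correct=correct,
    )


def probability_correct(
    model: ModelName,
    arrays: TrialArrays,
    params: Dict[str, np.ndarray],
    exp1_as_me: bool = True,
) -> np.ndarray:
    """Per-trial correct-choice probability, batched over coefficient sets.

    ``params`` holds batched coefficients: scalars of shape ``(B,)``
    (``alpha_intercept``, ``alpha_slope``, ``rho_intercept``, ``rho_slope``,
    ``theta_intercept``, ``theta_slope``, optionally ``phi_intercept`` and
    ``phi_slope``) and object offsets of shape ``(B, n_objects)``
    (``theta_object_intercepts``, ``theta_object_slopes``). Returns ``(B, N)``.

    Experiment 2 measures common-ground sensitivity alone, so its rows get
    probability ``rho(age)`` directly. When ``exp1_as_me`` is set (the
    fitting convention), Experiment 1 rows are evaluated with a uniform
    referent prior under the mutual-exclusivity adaptation of the integration
    model for every variant — the lesions and biases then apply only to
    Experiment 3 rows. With ``exp1_as_me=False`` (the simulator's generating
    convention) Experiment 1 rows follow the model variant itself, still at
    the uniform prior their condition implies.
    """
    model = ModelName(model)

    def vec(name):
        return np.ascontiguousarray(np.asarray(params[name], dtype=float))

    a_int = vec("alpha_intercept")
    B = a_int.shape[0]
    if model in BIASED_MODELS:
        phi_int = vec("phi_intercept")
        if model is ModelName.DEVELOPMENTAL_BIAS and "phi_slope" in params:
            phi_sl = vec("phi_slope")
        else:
            phi_sl = np.zeros(B)
    else:
        phi_int = np.zeros(B)
        phi_sl = np.zeros(B)
    return probability_kernel(
        MODEL_CODES[model.value],
        bool(exp1_as_me),
        arrays.age_c,
        arrays.obj_idx,
        arrays.cond,
        arrays.exp,
        a_int,
        vec("alpha_slope"),
        vec("rho_intercept"),
        vec("rho_slope"),
        vec("theta_intercept"),
        vec("theta_slope"),
        np.ascontiguousarray(np.asarray(params["theta_object_intercepts"], dtype=float)),
        np.ascontiguousarray(np.asarray(params["theta_object_slopes"], dtype=float)),
        phi_int,
        phi_sl,
    )


def bernoulli_log_likelihood(p: np.ndarray, correct: np.ndarray) -> np.ndarray:
    """Row-summed Bernoulli log likelihood, ``(B, N) x (N,) -> (B,)``."""
    return bernoulli_loglik_kernel(
        np.ascontiguousarray(p), np.ascontiguousarray(correct, dtype=float)
    )
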