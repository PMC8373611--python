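"""Synthetic trial-level data with the structure of the three child experiments.

The generator emulates the study designs that the models are meant to fit:

* Experiment 1 — mutual-exclusivity trials: each child sees all 12 familiar
  objects once (novel word, uniform referent prior), 12 trials.
* Experiment 2 — discourse-novelty trials: 10 trials per child with two
  unfamiliar objects each, no familiar object; the probability of choosing
  the object that is new to the speaker is the common-ground trajectory
  ``rho(age)`` itself.
* Experiment 3 — integration trials: 12 trials per child, each familiar
  object once, six congruent and six incongruent (which object lands in
  which alignment is randomised per child), 24 cells in total.

Responses are Bernoulli draws from the chosen generating model's predicted
choice probability at the child's age; ages are uniform within each year bin
(2-, 3-, 4-year-olds). Default bin sizes mirror the study samples
(30/30/30, 18/19/21 and 76/72/72 children). Dropout and counterbalancing of
sides/speakers are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple, Union

import numpy as np
import pandas as pd

from ._trials import TRIAL_COLUMNS, probability_correct, trial_arrays
from .dev_params import DEFAULT_OBJECT_IDS, Condition, TrajectoryCoefficients
from .rsa_core import ModelName

__all__ = [
    "ExperimentDesign",
    "DEFAULT_N_PER_YEAR",
    "default_design",
    "default_truth",
    "simulate_experiment",
    "simulate_study",
]

AGE_YEARS = (2, 3, 4)

DEFAULT_N_PER_YEAR: Dict[str, Dict[int, int]] = {
    "exp1": {2: 30, 3: 30, 4: 30},
    "exp2": {2: 18, 3: 19, 4: 21},
    "exp3": {2: 76, 3: 72, 4: 72},
}

_TRIALS_PER_CHILD = {"exp1": 12, "exp2": 10, "exp3": 12}


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural description of one experiment's trial layout."""

    experiment_id: str
    n_children_per_year: Mapping[int, int]
    trials_per_child: int
    object_roster: Tuple[str, ...] = DEFAULT_OBJECT_IDS

    def __post_init__(self) -> None:
        if self.experiment_id not in ("exp1", "exp2", "exp3"):
            raise ValueError(f"unknown experiment id {self.experiment_id!r}")
        if self.experiment_id == "exp2":
            if self.trials_per_child <= 0:
                raise ValueError("trials_per_child must be positive")
        else:
            if self.trials_per_child != len(self.object_roster):
                raise ValueError(
                    "exp1/exp3 designs give each child each familiar object "
                    f"exactly once: trials_per_child={self.trials_per_child} "
                    f"!= {len(self.object_roster)} objects"
                )
            if self.experiment_id == "exp3" and self.trials_per_child % 2:
                raise ValueError("exp3 needs an even trial count (balanced alignments)")

    @property
    def n_children(self) -> int:
        return int(sum(self.n_children_per_year.values()))


def default_design(
    experiment_id: str,
    n_children_per_year: Union[None, int, Mapping[int, int]] = None,
) -> ExperimentDesign:
    """Design with the study's trial structure; child counts default to the study's."""
    if n_children_per_year is None:
        n_map = dict(DEFAULT_N_PER_YEAR[experiment_id])
    elif isinstance(n_children_per_year, int):
        n_map = {y: n_children_per_year for y in AGE_YEARS}
    else:
        n_map = dict(n_children_per_year)
    return ExperimentDesign(
        experiment_id=experiment_id,
        n_children_per_year=n_map,
        trials_per_child=_TRIALS_PER_CHILD[experiment_id],
    )


def default_truth() -> TrajectoryCoefficients:
    """Ground-truth trajectory fixture used throughout tests and simulations.

    All three sensitivities increase with age: speaker informativeness rises
    linearly from ~0.6 at age 2 to ~1.8 at age 4; common-ground sensitivity
    from ~0.55 to ~0.85; population semantic knowledge from ~0.43 to ~0.89.
    Object intercept offsets span ±2.2 logits (easiest to hardest word, i.e.
    ordered by age of acquisition) and sum to zero, with small slope offsets.
    The bias coefficients put the constant bias at 0.65 (the mixture weight on
    the mutual-exclusivity inference) and let the developmental-bias variant
    cross 0.5 shortly before age 3.
    """
    n = len(DEFAULT_OBJECT_IDS)
    intercept_offsets = np.linspace(2.2, -2.2, n)
    intercept_offsets -= intercept_offsets.mean()
    slope_offsets = np.linspace(-0.3, 0.3, n)
    slope_offsets -= slope_offsets.mean()
    return TrajectoryCoefficients(
        alpha_intercept=1.2,
        alpha_slope=0.6,
        rho_intercept=0.7,
        rho_slope=0.75,
        theta_intercept=0.5,
        theta_slope=0.8,
        theta_object_intercepts=intercept_offsets,
        theta_object_slopes=slope_offsets,
        phi_intercept=float(np.log(0.65 / 0.35)),
        phi_slope=0.8,
    )


def _children_frame(design: ExperimentDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for year in sorted(design.n_children_per_year):
        n = design.n_children_per_year[year]
        ages = rng.uniform(year, year + 1, size=n)
        for k, age in enumerate(ages):
            rows.append((f"{design.experiment_id}_{year}y_c{k:03d}", float(age)))
    return pd.DataFrame(rows, columns=["child_id", "age"])


def simulate_experiment(
    design: ExperimentDesign,
    truth: TrajectoryCoefficients,
    generating_model: ModelName = ModelName.INTEGRATION,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one experiment's trial table from known ground-truth coefficients.

    Each trial's success probability is the generating model's predicted
    choice probability at the child's age, object and condition; the response
    is a Bernoulli draw. Deterministic given ``seed``.
    """
    generating_model = ModelName(generating_model)
    if design.object_roster != truth.object_ids:
        raise ValueError(
            "design roster and truth object ids disagree: "
            f"{design.object_roster} vs {truth.object_ids}"
        )
    rng = np.random.default_rng(seed)
    children = _children_frame(design, rng)

    records = []
    for child_id, age in children.itertuples(index=False):
        if design.experiment_id == "exp1":
            for oid in design.object_roster:
                records.append((child_id, age, "exp1", Condition.NONE.value, oid))
        elif design.experiment_id == "exp2":
            for _ in range(design.trials_per_child):
                records.append((child_id, age, "exp2", Condition.NONE.value, ""))
        else:
            order = rng.permutation(len(design.object_roster))
            half = design.trials_per_child // 2
            for pos, j in enumerate(order):
                cond = Condition.CONGRUENT if pos < half else Condition.INCONGRUENT
                records.append(
                    (child_id, age, "exp3", cond.value, design.object_roster[j])
                )
    df = pd.DataFrame(
        records, columns=["child_id", "age", "experiment", "condition", "object_id"]
    )
    df["correct"] = 0

    arrays = trial_arrays(df, truth.object_ids, require_correct=False)
    params = _truth_params(truth, generating_model)
    # Experiment-1 rows follow the mutual-exclusivity adaptation for every
    # generating model, mirroring the estimation convention exactly
    p = probability_correct(generating_model, arrays, params, exp1_as_me=True)[0]
    df["correct"] = (rng.random(arrays.n) < p).astype(int)
    return df[TRIAL_COLUMNS]


def _truth_params(truth: TrajectoryCoefficients, model: ModelName) -> Dict[str, np.ndarray]:
    params = {
        "alpha_intercept": np.array([truth.alpha_intercept]),
        "alpha_slope": np.array([truth.alpha_slope]),
        "rho_intercept": np.array([truth.rho_intercept]),
        "rho_slope": np.array([truth.rho_slope]),
        "theta_intercept": np.array([truth.theta_intercept]),
        "theta_slope": np.array([truth.theta_slope]),
        "theta_object_intercepts": truth.theta_object_intercepts[None, :],
        "theta_object_slopes": truth.theta_object_slopes[None, :],
    }
    if model in (ModelName.BIASED, ModelName.DEVELOPMENTAL_BIAS):
        if truth.phi_intercept is None:
            raise ValueError("generating a biased model needs phi coefficients")
        params["phi_intercept"] = np.array([truth.phi_intercept])
        params["phi_slope"] = np.array([truth.phi_slope or 0.0])
    return params


def simulate_study(
    truth: TrajectoryCoefficients,
    generating_model: ModelName = ModelName.INTEGRATION,
    seed: int = 0,
    n_children_per_year: Union[None, int, Mapping[str, Mapping[int, int]]] = None,
) -> pd.DataFrame:
    """Simulate all three experiments and concatenate their trial tables.

    ``n_children_per_year`` may be an int (applied to every experiment) or a
    mapping ``{"exp1": {2: n, ...}, ...}``; by default the study's own sample
    sizes are used. Seeds for the three experiments are derived from ``seed``.
    """
    tables = []
    for i, exp in enumerate(("exp1", "exp2", "exp3")):
        if n_children_per_year is None or isinstance(n_children_per_year, int):
            design = default_design(exp, n_children_per_year)
        else:
            design = default_design(exp, n_children_per_year.get(exp))
        tables.append(
            simulate_experiment(design, truth, generating_model, seed=seed * 7 + i)
        )
    return pd.concat(tables, ignore_index=True)
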