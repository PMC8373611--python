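"""Bayesian estimation of developmental trajectories and model comparison.

The generative model for a trial table is: every trial is a Bernoulli draw
whose success probability comes from the model variant's predicted choice
probability at the child's age, object and condition (Experiment 1 rows use
the mutual-exclusivity adaptation with a uniform referent prior; Experiment 2
rows measure the common-ground trajectory ``rho(age)`` directly). Trajectory
coefficients get weakly-informative normal priors; object-specific
semantic-knowledge offsets are modelled hierarchically (non-centred, with
half-normal scale hyperpriors).

Sampling uses preconditioned Hamiltonian Monte Carlo: analytic trial-level
gradients, a Laplace approximation (posterior mode plus exact Hessian) as
the preconditioner, chains advanced in lock-step so each leapfrog step costs
one batched gradient evaluation, and dual-averaging step-size adaptation.
Convergence is summarised with effective sample sizes, split-R-hat across
chains (``arviz``), the acceptance rate and the divergence count.

Model evidence is estimated by simple Monte Carlo: average the data
likelihood over parameter draws from a sampling distribution (the prior, or
an Experiment-1/2 posterior for out-of-sample evidence), in log space via
log-sum-exp, with a delta-method standard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from ._trials import (
    TrialArrays,
    bernoulli_log_likelihood,
    probability_correct,
    trial_arrays,
)
from .dev_params import AGE_CENTER, DEFAULT_OBJECT_IDS, TrajectoryCoefficients
from .evaluation import hdi
from .rsa_core import BIASED_MODELS, ModelName

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorSamples",
    "ModelEvidence",
    "BayesFactor",
    "fit",
    "posterior_predict",
    "predict_for_trials",
    "marginal_likelihood",
    "monte_carlo_evidence",
    "bayes_factor",
    "log_likelihood_draws",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

_DEFAULT_COEFF_PRIORS: Dict[str, Tuple[float, float]] = {
    "alpha_intercept": (1.0, 1.0),
    "alpha_slope": (0.0, 1.0),
    "rho_intercept": (0.0, 2.5),
    "rho_slope": (0.0, 2.5),
    "theta_intercept": (0.0, 2.5),
    "theta_slope": (0.0, 2.5),
    "phi_intercept": (0.0, 2.5),
    "phi_slope": (0.0, 2.5),
}


@dataclass(frozen=True)
class PriorSpec:
    """Normal (location, scale) priors per coefficient; half-normal offset scales."""

    coefficients: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COEFF_PRIORS)
    )
    theta_offset_intercept_scale: float = 1.0
    theta_offset_slope_scale: float = 1.0

    def __post_init__(self) -> None:
        merged = dict(_DEFAULT_COEFF_PRIORS)
        merged.update(self.coefficients)
        object.__setattr__(self, "coefficients", merged)
        for name, (_, scale) in merged.items():
            if scale <= 0:
                raise ValueError(f"prior scale for {name} must be > 0")
        if self.theta_offset_intercept_scale <= 0 or self.theta_offset_slope_scale <= 0:
            raise ValueError("offset scale hyperpriors must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    """HMC sampler settings; ``reduced()`` gives a faster test-scale preset."""

    n_chains: int = 4
    n_warmup: int = 250
    n_draws: int = 550
    n_leapfrog: int = 12
    target_accept: float = 0.8
    map_maxiter: int = 500
    min_ess: float = 400.0
    max_rhat: float = 1.05

    @staticmethod
    def reduced() -> "MCMCSettings":
        return MCMCSettings(n_warmup=150, n_draws=250, n_leapfrog=10, map_maxiter=300)


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

_FIXED_NAMES = (
    "alpha_intercept",
    "alpha_slope",
    "rho_intercept",
    "rho_slope",
    "theta_intercept",
    "theta_slope",
)


@dataclass(frozen=True)
class _ParamLayout:
    """Mapping between a model's flat sample vector and named coefficients."""

    model: ModelName
    n_objects: int

    @property
    def fixed_names(self) -> Tuple[str, ...]:
        names = list(_FIXED_NAMES)
        if self.model in BIASED_MODELS:
            names.append("phi_intercept")
        if self.model is ModelName.DEVELOPMENTAL_BIAS:
            names.append("phi_slope")
        return tuple(names)

    @property
    def ndim(self) -> int:
        return len(self.fixed_names) + 2 * self.n_objects + 2

    def slices(self) -> Dict[str, slice]:
        k = len(self.fixed_names)
        m = self.n_objects
        out = {name: slice(i, i + 1) for i, name in enumerate(self.fixed_names)}
        out["z_intercept"] = slice(k, k + m)
        out["z_slope"] = slice(k + m, k + 2 * m)
        out["log_sigma_intercept"] = slice(k + 2 * m, k + 2 * m + 1)
        out["log_sigma_slope"] = slice(k + 2 * m + 1, k + 2 * m + 2)
        return out

    def unpack(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        """Flat draws ``(S, ndim)`` -> natural coefficient arrays (offsets centred)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sl = self.slices()
        params: Dict[str, np.ndarray] = {
            name: X[:, sl[name]][:, 0] for name in self.fixed_names
        }
        sig_i = np.exp(np.clip(X[:, sl["log_sigma_intercept"]], -30.0, 30.0))
        sig_s = np.exp(np.clip(X[:, sl["log_sigma_slope"]], -30.0, 30.0))
        params["theta_object_intercepts"] = X[:, sl["z_intercept"]] * sig_i
        params["theta_object_slopes"] = X[:, sl["z_slope"]] * sig_s
        params["sigma_intercept"] = sig_i[:, 0]
        params["sigma_slope"] = sig_s[:, 0]
        return params

    def log_prior(self, X: np.ndarray, priors: PriorSpec) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sl = self.slices()
        lp = np.zeros(X.shape[0])
        for name in self.fixed_names:
            loc, scale = priors.coefficients[name]
            x = X[:, sl[name]][:, 0]
            lp += -0.5 * ((x - loc) / scale) ** 2 - np.log(scale) - 0.5 * _LOG_2PI
        def log_sigma_terms(skey: str, scale: float) -> np.ndarray:
            ls = X[:, sl[skey]][:, 0]
            out_of_range = np.abs(ls) > 30.0  # exp() under/overflow guard
            ls = np.clip(ls, -30.0, 30.0)
            sigma = np.exp(ls)
            # half-normal hyperprior on sigma plus log-Jacobian of the log transform
            term = (
                0.5 * np.log(2.0 / np.pi)
                - np.log(scale)
                - 0.5 * (sigma / scale) ** 2
                + ls
            )
            return np.where(out_of_range, -np.inf, term)

        # non-centred offsets: z ~ N(0, 1), offset = z * sigma
        for zkey in ("z_intercept", "z_slope"):
            z = X[:, sl[zkey]]
            lp += (-0.5 * z**2 - 0.5 * _LOG_2PI).sum(axis=1)
        lp += log_sigma_terms("log_sigma_intercept", priors.theta_offset_intercept_scale)
        lp += log_sigma_terms("log_sigma_slope", priors.theta_offset_slope_scale)
        return lp

    def sample_prior(self, n: int, priors: PriorSpec, rng: np.random.Generator) -> np.ndarray:
        sl = self.slices()
        X = np.empty((n, self.ndim))
        for name in self.fixed_names:
            loc, scale = priors.coefficients[name]
            X[:, sl[name]] = rng.normal(loc, scale, size=(n, 1))
        sig_i = np.abs(rng.normal(0.0, priors.theta_offset_intercept_scale, size=(n, 1))) + 1e-12
        sig_s = np.abs(rng.normal(0.0, priors.theta_offset_slope_scale, size=(n, 1))) + 1e-12
        X[:, sl["z_intercept"]] = rng.standard_normal((n, self.n_objects))
        X[:, sl["z_slope"]] = rng.standard_normal((n, self.n_objects))
        X[:, sl["log_sigma_intercept"]] = np.log(sig_i)
        X[:, sl["log_sigma_slope"]] = np.log(sig_s)
        return X

    def start_vector(self, priors: PriorSpec) -> np.ndarray:
        sl = self.slices()
        x = np.zeros(self.ndim)
        for name in self.fixed_names:
            x[sl[name]] = priors.coefficients[name][0]
        x[sl["log_sigma_intercept"]] = np.log(0.5)
        x[sl["log_sigma_slope"]] = np.log(0.25)
        return x

    def log_prior_grad(self, X: np.ndarray, priors: PriorSpec) -> np.ndarray:
        """Gradient of ``log_prior`` wrt the flat coordinates; shape like X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sl = self.slices()
        G = np.zeros_like(X)
        for name in self.fixed_names:
            loc, scale = priors.coefficients[name]
            G[:, sl[name]] = -(X[:, sl[name]] - loc) / scale**2
        G[:, sl["z_intercept"]] = -X[:, sl["z_intercept"]]
        G[:, sl["z_slope"]] = -X[:, sl["z_slope"]]
        sig_i = np.exp(np.clip(X[:, sl["log_sigma_intercept"]], -30.0, 30.0))
        sc_i = priors.theta_offset_intercept_scale
        G[:, sl["log_sigma_intercept"]] = -sig_i**2 / sc_i**2 + 1.0
        sig_s = np.exp(np.clip(X[:, sl["log_sigma_slope"]], -30.0, 30.0))
        sc_s = priors.theta_offset_slope_scale
        G[:, sl["log_sigma_slope"]] = -sig_s**2 / sc_s**2 + 1.0
        return G


def layout_for(model: ModelName, n_objects: int = len(DEFAULT_OBJECT_IDS)) -> _ParamLayout:
    return _ParamLayout(ModelName(model), n_objects)


# ---------------------------------------------------------------------------
# likelihood (single code path for fitting and evidence)
# ---------------------------------------------------------------------------

def log_likelihood_draws(
    model: ModelName,
    arrays: TrialArrays,
    X: np.ndarray,
    layout: _ParamLayout,
) -> np.ndarray:
    """Data log likelihood for each flat parameter draw; shape ``(S,)``.

    This is the single likelihood code path: ``fit`` evaluates it inside the
    sampler's log-posterior and ``marginal_likelihood`` averages it over
    sampler draws.
    """
    params = layout.unpack(X)
    p = probability_correct(ModelName(model), arrays, params, exp1_as_me=True)
    return bernoulli_log_likelihood(p, arrays.correct)


_GRAD_COLS = (
    "alpha_intercept",
    "alpha_slope",
    "rho_intercept",
    "rho_slope",
    "theta_intercept",
    "theta_slope",
    "phi_intercept",
    "phi_slope",
)


def log_likelihood_and_grad(
    model: ModelName,
    arrays: TrialArrays,
    X: np.ndarray,
    layout: _ParamLayout,
) -> Tuple[np.ndarray, np.ndarray]:
    """Log likelihood and its gradient wrt the flat coordinates, batched.

    Natural-coefficient gradients from the trial kernel are chained through
    the layout: centred intercept offsets map one-to-one, non-centred slope
    offsets pick up the sigma factor, and ``log_sigma_slope`` collects the
    offsets' inner product.
    """
    from ._kernels import MODEL_CODES, loglik_grad_kernel

    model = ModelName(model)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    params = layout.unpack(X)
    B = X.shape[0]
    zeros = np.zeros(B)

    def vec(name):
        return np.ascontiguousarray(params.get(name, zeros), dtype=float)

    ll, d_scalars, d_oi, d_osl = loglik_grad_kernel(
        MODEL_CODES[model.value],
        True,
        arrays.age_c,
        arrays.obj_idx,
        arrays.cond,
        arrays.exp,
        np.ascontiguousarray(arrays.correct, dtype=float),
        vec("alpha_intercept"),
        vec("alpha_slope"),
        vec("rho_intercept"),
        vec("rho_slope"),
        vec("theta_intercept"),
        vec("theta_slope"),
        np.ascontiguousarray(params["theta_object_intercepts"]),
        np.ascontiguousarray(params["theta_object_slopes"]),
        vec("phi_intercept"),
        vec("phi_slope"),
    )
    sl = layout.slices()
    G = np.zeros_like(X)
    for i, name in enumerate(_GRAD_COLS):
        if name in sl:
            G[:, sl[name]] = d_scalars[:, i : i + 1]
    G[:, sl["z_intercept"]] = d_oi * params["sigma_intercept"][:, None]
    G[:, sl["z_slope"]] = d_osl * params["sigma_slope"][:, None]
    G[:, sl["log_sigma_intercept"]] = (d_oi * params["theta_object_intercepts"]).sum(
        axis=1, keepdims=True
    )
    G[:, sl["log_sigma_slope"]] = (d_osl * params["theta_object_slopes"]).sum(
        axis=1, keepdims=True
    )
    return ll, G


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Joint posterior draws of trajectory coefficients with sampler diagnostics."""

    model: ModelName
    chain: np.ndarray  # (chains, draws, ndim)
    layout: _ParamLayout
    object_ids: Tuple[str, ...]
    priors: PriorSpec
    diagnostics: Dict[str, float]
    map_vector: Optional[np.ndarray] = None
    age_center: float = AGE_CENTER

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    def draws(self, n: Optional[int] = None, rng=None) -> np.ndarray:
        X = self.flat()
        if n is None or n == X.shape[0]:
            return X
        rng = np.random.default_rng(rng)
        idx = rng.choice(X.shape[0], size=n, replace=n > X.shape[0])
        return X[idx]

    def params(self, n: Optional[int] = None, rng=None) -> Dict[str, np.ndarray]:
        return self.layout.unpack(self.draws(n, rng))

    def coefficients(self, i: int) -> TrajectoryCoefficients:
        p = self.layout.unpack(self.flat()[i : i + 1])
        kwargs = dict(
            alpha_intercept=float(p["alpha_intercept"][0]),
            alpha_slope=float(p["alpha_slope"][0]),
            rho_intercept=float(p["rho_intercept"][0]),
            rho_slope=float(p["rho_slope"][0]),
            theta_intercept=float(p["theta_intercept"][0]),
            theta_slope=float(p["theta_slope"][0]),
            theta_object_intercepts=p["theta_object_intercepts"][0],
            theta_object_slopes=p["theta_object_slopes"][0],
            object_ids=self.object_ids,
        )
        if "phi_intercept" in p:
            kwargs["phi_intercept"] = float(p["phi_intercept"][0])
            kwargs["phi_slope"] = float(p.get("phi_slope", np.zeros(1))[0])
        return TrajectoryCoefficients(**kwargs)

    def credible_interval(self, name: str, mass: float = 0.95) -> Tuple[float, float]:
        """Equal-draw HDI of one named population coefficient."""
        values = self.params()[name]
        return hdi(values, mass)

    def map_params(self) -> Optional[Dict[str, np.ndarray]]:
        if self.map_vector is None:
            return None
        return self.layout.unpack(self.map_vector[None, :])

    def phi_map(self) -> Optional[float]:
        """Posterior-mode bias weight at the centring age (biased models)."""
        p = self.map_params()
        if p is None or "phi_intercept" not in p:
            return None
        return float(expit(p["phi_intercept"][0]))

    def to_dataframe(self) -> pd.DataFrame:
        X = self.flat()
        sl = self.layout.slices()
        cols: Dict[str, np.ndarray] = {}
        for name in self.layout.fixed_names:
            cols[name] = X[:, sl[name]][:, 0]
        p = self.layout.unpack(X)
        for j, oid in enumerate(self.object_ids):
            cols[f"theta_offset_intercept[{oid}]"] = p["theta_object_intercepts"][:, j]
            cols[f"theta_offset_slope[{oid}]"] = p["theta_object_slopes"][:, j]
        cols["sigma_intercept"] = p["sigma_intercept"]
        cols["sigma_slope"] = p["sigma_slope"]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _validate_stage(data: pd.DataFrame, stage: str) -> None:
    if stage not in ("prediction", "explanation"):
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "prediction":
        exps = set(data["experiment"].astype(str))
        if "exp3" in exps:
            raise ValueError(
                "prediction-stage fits are out-of-sample and must not see "
                "Experiment 3 rows; filter them out or use stage='explanation'"
            )


def _map_and_laplace(
    log_post: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int,
    bounds: Optional[Sequence[Tuple[Optional[float], Optional[float]]]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a Laplace covariance used as the HMC preconditioner.

    ``log_post`` must return ``(lp, grad)`` for a batch of points. ``bounds``
    keeps the optimiser away from the centred hierarchy's sigma -> 0 density
    spike (an initialisation detail only; the sampled target is unbounded).
    """
    ndim = x0.shape[0]

    def f_and_g(x):
        lp, g = log_post(x[None, :])
        return -float(lp[0]), -g[0]

    res = optimize.minimize(
        f_and_g, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter},
    )

    # exact Hessian at the mode: central differences of the analytic
    # gradient, all 2*ndim evaluation points in one batched call
    x = res.x
    h = 1e-5 * np.maximum(np.abs(x), 1.0)
    eye_h = np.diag(h)
    stacked = np.concatenate([x[None, :] + eye_h, x[None, :] - eye_h], axis=0)
    _, grads = log_post(stacked)
    hess = -(grads[:ndim] - grads[ndim:]) / (2.0 * h[:, None])
    hess = 0.5 * (hess + hess.T)
    w, V = np.linalg.eigh(hess)
    # prior curvature bounds genuinely flat directions from below; the floor
    # only guards against boundary-mode artefacts in the numerical Hessian
    w = np.clip(w, 0.05, None)
    cov = (V / w) @ V.T
    return x, cov


def _chain_diagnostics(chain: np.ndarray, layout: _ParamLayout) -> Dict[str, float]:
    import arviz as az

    sl = layout.slices()
    data = {name: chain[:, :, sl[name]][:, :, 0] for name in layout.fixed_names}
    data["log_sigma_intercept"] = chain[:, :, sl["log_sigma_intercept"]][:, :, 0]
    data["log_sigma_slope"] = chain[:, :, sl["log_sigma_slope"]][:, :, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(data)
        ess = az.ess(ds).to_array().values
        rhat = az.rhat(ds).to_array().values
    return {
        "ess_min": float(np.nanmin(ess)),
        "rhat_max": float(np.nanmax(rhat)),
    }


def _prior_whitening(layout: _ParamLayout, priors: PriorSpec) -> np.ndarray:
    """Diagonal scale vector for prior-only sampling (no Laplace available)."""
    sl = layout.slices()
    scale = np.ones(layout.ndim)
    for name in layout.fixed_names:
        scale[sl[name]] = priors.coefficients[name][1]
    scale[sl["z_intercept"]] = 1.0
    scale[sl["z_slope"]] = 1.0
    return scale


def _run_hmc(
    log_post,
    layout: _ParamLayout,
    priors: PriorSpec,
    settings: MCMCSettings,
    map_vec: Optional[np.ndarray],
    cov: Optional[np.ndarray],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Run whitened HMC; returns ``(chain (chains, draws, ndim), stats)``."""
    from ._hmc import hmc_sample

    ndim = layout.ndim
    if map_vec is not None:
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(ndim))
        center = map_vec
    else:
        L = np.diag(_prior_whitening(layout, priors))
        center = layout.start_vector(priors)

    def logp_grad_u(U):
        X = center[None, :] + U @ L.T
        lp, gx = log_post(X)
        return lp, gx @ L

    u0 = 0.3 * rng.standard_normal((settings.n_chains, ndim))
    result = hmc_sample(
        logp_grad_u,
        u0,
        settings.n_warmup,
        settings.n_draws,
        rng,
        n_leapfrog=settings.n_leapfrog,
        target_accept=settings.target_accept,
    )
    chain = center[None, None, :] + result.draws @ L.T
    stats = {
        "accept_rate": float(result.accept_rate),
        "step_size": float(result.step_size),
        "divergences": float(result.divergences),
    }
    return chain, stats


def fit(
    model: ModelName,
    data: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    settings: Optional[MCMCSettings] = None,
    seed: int = 0,
    stage: str = "explanation",
    object_ids: Sequence[str] = DEFAULT_OBJECT_IDS,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Sample the posterior over trajectory coefficients for one model variant.

    ``stage='prediction'`` enforces the out-of-sample protocol: Experiment 3
    rows are rejected so that later Experiment-3 predictions are parameter
    free. ``prior_only=True`` ignores the data term (and allows an empty
    table), which yields prior samples and is useful for calibration checks.

    Non-convergence (low ESS or high R-hat) is flagged in
    ``result.diagnostics['converged']`` and logged; the samples are still
    returned.
    """
    model = ModelName(model)
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    layout = layout_for(model, len(object_ids))
    rng = np.random.default_rng(seed)

    if len(data) == 0 and not prior_only:
        raise ValueError("cannot fit an empty trial table (use prior_only=True "
                         "for prior sampling)")
    if len(data):
        _validate_stage(data, stage)
    if model in BIASED_MODELS and stage == "prediction":
        logger.warning(
            "the bias weight phi is unidentified without Experiment 3 data; "
            "its draws will follow the prior"
        )

    ndim = layout.ndim

    if prior_only or len(data) == 0:
        arrays = None

        def log_post(X):
            lp = layout.log_prior(X, priors)
            g = layout.log_prior_grad(X, priors)
            return np.where(np.isnan(lp), -np.inf, lp), g

    else:
        arrays = trial_arrays(data, object_ids)

        def log_post(X):
            X = np.atleast_2d(X)
            lp = layout.log_prior(X, priors)
            g = layout.log_prior_grad(X, priors)
            finite = np.isfinite(lp)
            if finite.any():
                ll, gl = log_likelihood_and_grad(model, arrays, X[finite], layout)
                lp[finite] = lp[finite] + ll
                g[finite] = g[finite] + gl
            return np.where(np.isnan(lp), -np.inf, lp), np.where(np.isfinite(g), g, 0.0)

    if arrays is not None:
        sl = layout.slices()
        bounds: list = [(None, None)] * ndim
        for key in ("log_sigma_intercept", "log_sigma_slope"):
            bounds[sl[key].start] = (np.log(0.05), np.log(3.0))
        map_vec, cov = _map_and_laplace(
            log_post, layout.start_vector(priors), settings.map_maxiter, bounds
        )
    else:
        map_vec = None
        cov = None

    # retry once with a doubled budget if the chains clearly disagree
    attempt_settings = settings
    for attempt in range(2):
        chain, sampler_stats = _run_hmc(
            log_post, layout, priors, attempt_settings, map_vec, cov, rng
        )
        diagnostics = _chain_diagnostics(chain, layout)
        if diagnostics["rhat_max"] <= 1.15 or attempt == 1:
            break
        attempt_settings = replace(
            attempt_settings,
            n_warmup=2 * attempt_settings.n_warmup,
            n_draws=2 * attempt_settings.n_draws,
        )
        logger.info(
            "rhat_max=%.2f after attempt %d; re-running with warmup=%d draws=%d",
            diagnostics["rhat_max"], attempt + 1,
            attempt_settings.n_warmup, attempt_settings.n_draws,
        )
    diagnostics.update(sampler_stats)
    diagnostics["n_draws"] = float(chain.shape[0] * chain.shape[1])
    converged = (
        diagnostics["ess_min"] >= settings.min_ess
        and diagnostics["rhat_max"] <= settings.max_rhat
    )
    diagnostics["converged"] = float(converged)
    if not converged:
        logger.warning(
            "sampler convergence flagged: ess_min=%.0f (want >= %.0f), "
            "rhat_max=%.3f (want <= %.3f); results returned with warning status",
            diagnostics["ess_min"], settings.min_ess,
            diagnostics["rhat_max"], settings.max_rhat,
        )

    return PosteriorSamples(
        model=model,
        chain=chain,
        layout=layout,
        object_ids=tuple(object_ids),
        priors=priors,
        diagnostics=diagnostics,
        map_vector=map_vec,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _prediction_frame(
    age_grid: Sequence[float],
    conditions: Sequence[str],
    objects: Sequence[str],
) -> pd.DataFrame:
    rows = [
        (float(a), str(c), str(o))
        for a in age_grid
        for c in conditions
        for o in objects
    ]
    df = pd.DataFrame(rows, columns=["age", "condition", "object_id"])
    df["experiment"] = "exp3"
    df["child_id"] = "grid"
    df["correct"] = 0
    return df


def predict_for_trials(
    model: ModelName,
    posterior: PosteriorSamples,
    trials: pd.DataFrame,
    n_draws: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-draw predicted correct-choice probability for each trial row, ``(S, N)``.

    Predictions follow the model variant itself on every row (no fitting-stage
    Experiment-1 adaptation), so lesions apply to whatever rows are passed in.
    """
    model = ModelName(model)
    if posterior.n_draws == 0:
        raise ValueError("posterior is empty")
    arrays = trial_arrays(trials, posterior.object_ids, require_correct=False)
    X = posterior.draws(n_draws, rng=seed)
    params = posterior.layout.unpack(X)
    if model in BIASED_MODELS and "phi_intercept" not in params:
        raise ValueError(
            f"posterior for {posterior.model.value!r} has no phi draws; fit the "
            "biased model or supply one that includes phi"
        )
    return probability_correct(model, arrays, params, exp1_as_me=False)


def posterior_predict(
    model: ModelName,
    posterior: PosteriorSamples,
    age_grid: Sequence[float],
    conditions: Sequence[str] = ("congruent", "incongruent"),
    objects: Optional[Sequence[str]] = None,
    n_draws: int = 500,
    hdi_mass: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior mean and HDI of the predicted choice probability per cell.

    The default condition x object grid covers the 24 Experiment-3 cells at
    each age in ``age_grid``.
    """
    objects = list(objects) if objects is not None else list(posterior.object_ids)
    grid = _prediction_frame(age_grid, conditions, objects)
    draws = predict_for_trials(model, posterior, grid, n_draws=n_draws, seed=seed)
    lows, highs = np.empty(draws.shape[1]), np.empty(draws.shape[1])
    for j in range(draws.shape[1]):
        lows[j], highs[j] = hdi(draws[:, j], hdi_mass)
    out = grid[["age", "condition", "object_id"]].copy()
    out["predicted_mean"] = draws.mean(axis=0)
    out["predicted_hdi_low"] = lows
    out["predicted_hdi_high"] = highs
    return out


# ---------------------------------------------------------------------------
# evidence and Bayes factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelEvidence:
    """Monte-Carlo estimate of a model's log marginal likelihood."""

    log_marginal_likelihood: float
    standard_error: float
    n_samples: int
    model: Optional[ModelName] = None


@dataclass(frozen=True)
class BayesFactor:
    """Evidence ratio of model A over model B."""

    value: float
    log10: float


def monte_carlo_evidence(
    log_likelihood_fn: Callable[[np.ndarray], np.ndarray],
    sampler_fn: Callable[[int, np.random.Generator], np.ndarray],
    n_samples: int,
    seed: int = 0,
) -> ModelEvidence:
    """Generic simple-MC evidence: average exp(log lik) over sampler draws.

    ``sampler_fn(n, rng)`` returns draws ``(n, D)`` from the weighting
    distribution (a prior, or a posterior from earlier experiments);
    ``log_likelihood_fn`` maps them to data log likelihoods ``(n,)``.
    Computed with log-sum-exp; the standard error is the delta-method error
    of the log of a Monte-Carlo mean.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a reportable estimate")
    rng = np.random.default_rng(seed)
    draws = sampler_fn(n_samples, rng)
    ll = np.asarray(log_likelihood_fn(draws), dtype=float)
    if np.all(np.isneginf(ll)):
        warnings.warn("all likelihoods are zero; evidence is -inf", RuntimeWarning)
        return ModelEvidence(-np.inf, np.nan, n_samples)
    m = np.max(ll[np.isfinite(ll)])
    w = np.exp(ll - m)
    mean_w = float(np.mean(w))
    sd_w = float(np.std(w, ddof=1))
    log_ml = m + float(np.log(mean_w))
    se = sd_w / (np.sqrt(n_samples) * mean_w)
    return ModelEvidence(log_ml, se, n_samples)


def marginal_likelihood(
    model: ModelName,
    data: pd.DataFrame,
    prior_sampler: Union[PriorSpec, PosteriorSamples],
    n_samples: int = 10_000,
    seed: int = 0,
    priors: Optional[PriorSpec] = None,
    object_ids: Sequence[str] = DEFAULT_OBJECT_IDS,
) -> ModelEvidence:
    """Evidence for ``data`` under one model variant.

    ``prior_sampler`` is either a ``PriorSpec`` (marginalise over the prior —
    the explanation-stage comparison) or a ``PosteriorSamples`` from an
    Experiment-1/2 fit (out-of-sample evidence for Experiment-3 data — the
    prediction-stage comparison). When the supplied posterior lacks
    coefficients the target model needs (the bias weight phi), those are
    drawn from ``priors``.
    """
    model = ModelName(model)
    if len(data) == 0:
        raise ValueError("cannot compute evidence for an empty trial table")
    fill_priors = priors or (
        prior_sampler if isinstance(prior_sampler, PriorSpec) else prior_sampler.priors
    )
    layout = layout_for(model, len(object_ids))
    if isinstance(prior_sampler, PosteriorSamples):
        object_ids = prior_sampler.object_ids
        layout = layout_for(model, len(object_ids))
    arrays = trial_arrays(data, object_ids)

    def sampler_fn(n: int, rng: np.random.Generator) -> np.ndarray:
        if isinstance(prior_sampler, PriorSpec):
            return layout.sample_prior(n, prior_sampler, rng)
        return _draws_for_layout(prior_sampler, layout, n, fill_priors, rng)

    def loglik_fn(X: np.ndarray) -> np.ndarray:
        return log_likelihood_draws(model, arrays, X, layout)

    ev = monte_carlo_evidence(loglik_fn, sampler_fn, n_samples, seed)
    return replace(ev, model=model)


def _draws_for_layout(
    posterior: PosteriorSamples,
    layout: _ParamLayout,
    n: int,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map posterior draws into a (possibly larger) target layout.

    Shared coefficients are copied; coefficients absent from the source
    posterior (phi for biased targets evaluated from an integration
    posterior) are drawn from their priors.
    """
    src = posterior.layout
    if n > posterior.n_draws:
        logger.info(
            "requested %d evidence samples from a posterior with %d draws; "
            "resampling with replacement", n, posterior.n_draws,
        )
    X_src = posterior.draws(n, rng=rng)
    src_sl, dst_sl = src.slices(), layout.slices()
    X = np.empty((n, layout.ndim))
    for name, dsl in dst_sl.items():
        if name in src_sl:
            X[:, dsl] = X_src[:, src_sl[name]]
        else:
            loc, scale = priors.coefficients[name]
            X[:, dsl] = rng.normal(loc, scale, size=(n, dsl.stop - dsl.start))
    return X


def bayes_factor(evidence_a: ModelEvidence, evidence_b: ModelEvidence) -> BayesFactor:
    """Evidence ratio exp(logML_a - logML_b), also on the log10 scale."""
    la, lb = evidence_a.log_marginal_likelihood, evidence_b.log_marginal_likelihood
    if not (np.isfinite(la) and np.isfinite(lb)):
        warnings.warn("infinite evidence input; Bayes factor degenerates", RuntimeWarning)
        diff = la - lb if not (np.isneginf(la) and np.isneginf(lb)) else np.nan
        return BayesFactor(float(np.exp(diff)), float(diff / np.log(10.0)))
    diff = la - lb
    with np.errstate(over="ignore"):
        value = float(np.exp(diff))
    return BayesFactor(value, float(diff / np.log(10.0)))
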