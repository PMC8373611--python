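"""Numba-compiled scalar kernels for trial-probability evaluation.

The sampler evaluates the likelihood tens of thousands of times per fit; a
fused scalar loop over (draw, trial) avoids the dozens of large temporary
arrays a numpy formulation needs. Semantics are identical to the closed-form
listener posterior in ``rsa_core``:

    p_novel = prior * s_nov / (prior * s_nov + (1 - prior) * s_fam)
    s_nov   = 1 / (1 + (1 - theta)^alpha)       # P_S1(novel word | novel)
    s_fam   = 1 / (1 + (1 + theta)^alpha)       # P_S1(novel word | familiar)

Model codes: 0 integration, 1 no-word-knowledge, 2 no-common-ground,
3 no-speaker-informativeness, 4 biased, 5 developmental bias.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODEL_CODES = {
    "integration": 0,
    "no_word_knowledge": 1,
    "no_common_ground": 2,
    "no_speaker_informativeness": 3,
    "biased": 4,
    "developmental_bias": 5,
}


@njit(cache=True, inline="always")
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _integrate(alpha, theta, prior):
    # alpha = 0 or theta = 0 leave both utterances uninformative: posterior = prior
    if alpha == 0.0 or theta == 0.0:
        return prior
    omt = 1.0 - theta
    if omt <= 0.0:
        s_nov = 1.0
    else:
        s_nov = 1.0 / (1.0 + omt**alpha)
    s_fam = 1.0 / (1.0 + (1.0 + theta) ** alpha)
    num = prior * s_nov
    den = num + (1.0 - prior) * s_fam
    if den == 0.0:
        return np.nan
    return num / den


@njit(cache=True)
def probability_kernel(
    model_code,
    exp1_as_me,
    age_c,
    obj_idx,
    cond,
    exp,
    a_int,
    a_sl,
    r_int,
    r_sl,
    t_int,
    t_sl,
    oi,
    osl,
    phi_int,
    phi_sl,
):
    """Per-trial correct-choice probability for a batch of coefficient sets."""
    B = a_int.shape[0]
    N = age_c.shape[0]
    out = np.empty((B, N))
    for b in range(B):
        for n in range(N):
            ac = age_c[n]
            rho = _expit(r_int[b] + r_sl[b] * ac)
            if exp[n] == 2:
                out[b, n] = rho
                continue
            alpha = a_int[b] + a_sl[b] * ac
            if alpha < 0.0:
                alpha = 0.0
            j = obj_idx[n]
            if j >= 0:
                theta = _expit(t_int[b] + oi[b, j] + (t_sl[b] + osl[b, j]) * ac)
            else:
                theta = _expit(t_int[b] + t_sl[b] * ac)
            if cond[n] == 1:
                prior = rho
            elif cond[n] == 2:
                prior = 1.0 - rho
            else:
                prior = 0.5

            if exp1_as_me and exp[n] == 1:
                out[b, n] = _integrate(alpha, theta, 0.5)
                continue

            if model_code == 0:
                p = _integrate(alpha, theta, prior)
            elif model_code == 1:
                theta_pooled = _expit(t_int[b] + t_sl[b] * ac)
                p = _integrate(alpha, theta_pooled, prior)
            elif model_code == 2:
                p = _integrate(alpha, theta, 0.5)
            elif model_code == 3:
                p = prior
            else:
                phi = _expit(phi_int[b] + phi_sl[b] * ac)
                p = phi * _integrate(alpha, theta, 0.5) + (1.0 - phi) * prior
            out[b, n] = p
    return out


@njit(cache=True)
def bernoulli_loglik_kernel(p, correct):
    """Row-summed Bernoulli log likelihood with probability clipping."""
    B, N = p.shape
    out = np.empty(B)
    for b in range(B):
        acc = 0.0
        for n in range(N):
            q = p[b, n]
            if q < 1e-12:
                q = 1e-12
            elif q > 1.0 - 1e-12:
                q = 1.0 - 1e-12
            if correct[n] > 0.5:
                acc += math.log(q)
            else:
                acc += math.log1p(-q)
        out[b] = acc
    return out


@njit(cache=True, inline="always")
def _integrate_with_grads(alpha, theta, prior):
    """Listener posterior and its partials wrt alpha, the theta logit and the prior.

    The theta derivative is taken wrt the linear predictor yt (theta =
    expit(yt)) because the chain-rule factor theta*(1-theta) cancels the
    (1-theta)^(alpha-1) singularity at theta -> 1.
    Returns (p, dp_dalpha, dp_dyt, dp_dprior).
    """
    if theta == 0.0:
        # both words uninformative: p = prior; alpha direction flat,
        # theta direction flat at the boundary of expit saturation
        return prior, 0.0, 0.0, 1.0
    if alpha == 0.0:
        # clipped-at-zero alpha: posterior = prior, flat in the clipped region
        return prior, 0.0, 0.0, 1.0
    omt = 1.0 - theta
    opt = 1.0 + theta
    if omt <= 0.0:
        A = 0.0
        dA_dalpha = 0.0
    else:
        A = omt**alpha
        dA_dalpha = A * math.log(omt)
    B = opt**alpha
    dB_dalpha = B * math.log(opt)
    dA_dyt = -alpha * theta * A
    dB_dyt = alpha * B * theta * omt / opt

    s_nov = 1.0 / (1.0 + A)
    s_fam = 1.0 / (1.0 + B)
    dsn_dalpha = -s_nov * s_nov * dA_dalpha
    dsf_dalpha = -s_fam * s_fam * dB_dalpha
    dsn_dyt = -s_nov * s_nov * dA_dyt
    dsf_dyt = -s_fam * s_fam * dB_dyt

    N = prior * s_nov
    M = (1.0 - prior) * s_fam
    T = N + M
    if T == 0.0:
        return np.nan, 0.0, 0.0, 0.0
    inv_T2 = 1.0 / (T * T)
    p = N / T
    dp_dalpha = (prior * dsn_dalpha * M - N * (1.0 - prior) * dsf_dalpha) * inv_T2
    dp_dyt = (prior * dsn_dyt * M - N * (1.0 - prior) * dsf_dyt) * inv_T2
    dp_dprior = (s_nov * M + N * s_fam) * inv_T2
    return p, dp_dalpha, dp_dyt, dp_dprior


@njit(cache=True)
def loglik_grad_kernel(
    model_code,
    exp1_as_me,
    age_c,
    obj_idx,
    cond,
    exp,
    correct,
    a_int,
    a_sl,
    r_int,
    r_sl,
    t_int,
    t_sl,
    oi,
    osl,
    phi_int,
    phi_sl,
):
    """Log likelihood and its gradient wrt natural coefficients, batched.

    Returns ``(ll, d_scalars, d_oi, d_osl)`` where ``d_scalars`` has columns
    (a_int, a_sl, r_int, r_sl, t_int, t_sl, phi_int, phi_sl) and the offset
    gradients are wrt the natural (already scaled) per-object offsets.
    """
    B = a_int.shape[0]
    N = age_c.shape[0]
    ll = np.zeros(B)
    d_scalars = np.zeros((B, 8))
    n_obj = oi.shape[1]
    d_oi = np.zeros((B, n_obj))
    d_osl = np.zeros((B, n_obj))
    for b in range(B):
        for n in range(N):
            ac = age_c[n]
            yr = r_int[b] + r_sl[b] * ac
            rho = _expit(yr)
            drho = rho * (1.0 - rho)
            j = obj_idx[n]

            if exp[n] == 2:
                p = rho
                dp_dyr = drho
                dp_dalpha = 0.0
                dp_dyt = 0.0
                pooled_theta = True
                use_phi = False
                dp_dyphi = 0.0
            else:
                ya = a_int[b] + a_sl[b] * ac
                if ya > 0.0:
                    alpha = ya
                    dalpha = 1.0
                else:
                    alpha = 0.0
                    dalpha = 0.0
                if j >= 0:
                    yt = t_int[b] + oi[b, j] + (t_sl[b] + osl[b, j]) * ac
                else:
                    yt = t_int[b] + t_sl[b] * ac
                theta = _expit(yt)
                if cond[n] == 1:
                    prior = rho
                    dprior_dyr = drho
                elif cond[n] == 2:
                    prior = 1.0 - rho
                    dprior_dyr = -drho
                else:
                    prior = 0.5
                    dprior_dyr = 0.0

                pooled_theta = False
                use_phi = False
                dp_dyphi = 0.0
                mc = model_code
                if exp1_as_me and exp[n] == 1:
                    mc = 0
                    prior = 0.5
                    dprior_dyr = 0.0

                if mc == 0:
                    p, da, dyt, dpr = _integrate_with_grads(alpha, theta, prior)
                elif mc == 1:
                    yt = t_int[b] + t_sl[b] * ac
                    theta = _expit(yt)
                    pooled_theta = True
                    p, da, dyt, dpr = _integrate_with_grads(alpha, theta, prior)
                elif mc == 2:
                    p, da, dyt, dpr = _integrate_with_grads(alpha, theta, 0.5)
                    dpr = 0.0
                    dprior_dyr = 0.0
                elif mc == 3:
                    p = prior
                    da = 0.0
                    dyt = 0.0
                    dpr = 1.0
                else:
                    yphi = phi_int[b] + phi_sl[b] * ac
                    phi = _expit(yphi)
                    pme, da_me, dyt_me, _ = _integrate_with_grads(alpha, theta, 0.5)
                    p = phi * pme + (1.0 - phi) * prior
                    da = phi * da_me
                    dyt = phi * dyt_me
                    dpr = 1.0 - phi
                    use_phi = True
                    dp_dyphi = (pme - prior) * phi * (1.0 - phi)

                dp_dalpha = da * dalpha
                dp_dyt = dyt
                dp_dyr = dpr * dprior_dyr

            # clip and accumulate log likelihood + dll/dp
            q = p
            if q < 1e-12:
                q = 1e-12
            elif q > 1.0 - 1e-12:
                q = 1.0 - 1e-12
            if correct[n] > 0.5:
                ll[b] += math.log(q)
                g = 1.0 / q if 1e-12 < p < 1.0 - 1e-12 else 0.0
            else:
                ll[b] += math.log1p(-q)
                g = -1.0 / (1.0 - q) if 1e-12 < p < 1.0 - 1e-12 else 0.0

            if g == 0.0:
                continue
            d_scalars[b, 2] += g * dp_dyr
            d_scalars[b, 3] += g * dp_dyr * ac
            if exp[n] != 2:
                d_scalars[b, 0] += g * dp_dalpha
                d_scalars[b, 1] += g * dp_dalpha * ac
                d_scalars[b, 4] += g * dp_dyt
                d_scalars[b, 5] += g * dp_dyt * ac
                if (not pooled_theta) and j >= 0:
                    d_oi[b, j] += g * dp_dyt
                    d_osl[b, j] += g * dp_dyt * ac
                if use_phi:
                    d_scalars[b, 6] += g * dp_dyphi
                    d_scalars[b, 7] += g * dp_dyphi * ac
    return ll, d_scalars, d_oi, d_osl
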