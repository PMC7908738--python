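"""Numba kernels for the per-SNP Metropolis–Hastings sweep.

The sweep is the hot loop: every cycle each non-fitted SNP is evaluated
only with its schedule probability vᵢ, and an evaluation is an O(N) dot
product against the current corrected data y*.  Genotypes stay 2-bit
packed and are unpacked on the fly; all random numbers are drawn by the
caller (numpy Generator) and passed in, so the kernels are pure functions
of their inputs.

Log-quantity convention: ``delta`` below is θᵢ − θ₀, i.e.

    delta = rhs²/(2σ²ₑ(diag+λ)) + ½log λ − ½log(diag+λ) + log(π/(1−π)),

with rhs and diag the centered cross-products formed from uncentered
codes via the cached weighted means.  Acceptance tests are done as
log(u) < log α, which cannot overflow however extreme θᵢ − θ₀ gets.
"""

import numpy as np
from numba import njit

__all__ = ["snp_sweep", "log_bf_all", "bayesc_values"]


@njit(cache=True, inline="always")
def _code(packed, i, j):
    return (packed[i, j >> 2] >> (2 * (j & 3))) & 3


@njit(cache=True)
def _raw_dot(packed, i, n_ind, wy):
    """x̃ᵢ'R⁻¹y* given the elementwise product wy = w ⊙ y*."""
    acc = 0.0
    for j in range(n_ind):
        c = _code(packed, i, j)
        if c != 0:
            acc += c * wy[j]
    return acc


@njit(cache=True)
def _apply_effect(packed, i, n_ind, xbar, delta_s, y_star, wy, w):
    """y* -= (x̃ᵢ − x̄ᵢ)·Δs, keeping wy = w ⊙ y* in sync."""
    for j in range(n_ind):
        d = (_code(packed, i, j) - xbar) * delta_s
        y_star[j] -= d
        wy[j] -= w[j] * d


@njit(cache=True)
def log_bf_all(packed, n_ind, w, y_star, xbar, diag_c, lam, sigma2_e):
    """θᵢ − θ₀ − log(π/(1−π)) for every SNP against the current y*.

    Used in cycle 1 (no SNPs fitted) to rank SNPs for the update schedule.
    """
    m = packed.shape[0]
    out = np.empty(m)
    wy = w * y_star
    swy = wy.sum()
    half_log_lam = 0.5 * np.log(lam)
    for i in range(m):
        rhs = _raw_dot(packed, i, n_ind, wy) - xbar[i] * swy
        dpl = diag_c[i] + lam
        out[i] = (
            0.5 * rhs * rhs / (sigma2_e * dpl)
            + half_log_lam
            - 0.5 * np.log(dpl)
        )
    return out


@njit(cache=True)
def snp_sweep(
    packed,
    n_ind,
    w,
    y_star,
    xbar,
    diag_c,
    indicator,
    s,
    v,
    skip_u,
    accept_u,
    effect_z,
    lam,
    sigma2_e,
    log_pi_ratio,
):
    """One MH sweep over all SNPs; mutates y_star, indicator, s in place.

    Non-fitted SNPs are skipped outright with probability 1−vᵢ (no θ
    computation).  Fitted SNPs are always evaluated: their effect is first
    added back to y* so rhs is "corrected for all other effects", then the
    exit proposal is tested; if the SNP stays in (or a non-fitted SNP is
    accepted in), a fresh effect is drawn from its conditional normal and
    subtracted from y*.  Returns the number of θ evaluations.
    """
    m = packed.shape[0]
    wy = w * y_star
    swy = wy.sum()  # invariant under centered effect updates
    half_log_lam = 0.5 * np.log(lam)
    n_evals = 0
    for i in range(m):
        fitted = indicator[i] != 0
        if not fitted and skip_u[i] >= v[i]:
            continue
        if fitted:
            # add the current effect back so y* excludes SNP i
            _apply_effect(packed, i, n_ind, xbar[i], -s[i], y_star, wy, w)
        rhs = _raw_dot(packed, i, n_ind, wy) - xbar[i] * swy
        dpl = diag_c[i] + lam
        delta = (
            0.5 * rhs * rhs / (sigma2_e * dpl)
            + half_log_lam
            - 0.5 * np.log(dpl)
            + log_pi_ratio
        )
        n_evals += 1
        log_v = np.log(v[i])
        if fitted:
            # propose exit with probability 1; accept w.p. min(1, e^{θ0}v/e^{θi})
            stays_in = not (np.log(accept_u[i]) < -delta + log_v)
        else:
            # propose entry; accept w.p. min(1, e^{θi}/(e^{θ0}v))
            stays_in = np.log(accept_u[i]) < delta - log_v
        if stays_in:
            s_new = rhs / dpl + effect_z[i] * np.sqrt(sigma2_e / dpl)
            _apply_effect(packed, i, n_ind, xbar[i], s_new, y_star, wy, w)
            s[i] = s_new
            indicator[i] = 1
        else:
            s[i] = 0.0
            indicator[i] = 0
    return n_evals


@njit(cache=True)
def bayesc_values(packed, n_ind, xbar, s, fitted_idx):
    """Σ over fitted SNPs of centered genotype × current effect, per individual."""
    g = np.zeros(n_ind)
    for k in range(fitted_idx.size):
        i = fitted_idx[k]
        si = s[i]
        xb = xbar[i]
        for j in range(n_ind):
            g[j] += (_code(packed, i, j) - xb) * si
    return g
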