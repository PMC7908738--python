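"""MCMC engine for the hybrid GBLUP + Bayes C ("Bayes GC") model.

Model (per record j, one record per individual):

    y = F b + u + Σᵢ Iᵢ xᵢ sᵢ + e,

with fixed breed×sex effects b, polygenic effects u ~ N(0, G σ²ᵤ),
spike-and-slab SNP effects (Iᵢ ~ Bernoulli(π), sᵢ ~ N(0, σ²ₛ) when in),
and heteroscedastic residuals Var(e) = R σ²ₑ, R⁻¹ = diag(record weights).
σ²ₑ is a known input; σ²ₛ and σ²ᵤ are sampled from scaled inverse-χ²
conditionals; π is fixed.  π = 0 disables the SNP term entirely (pure
GBLUP mode).

One cycle: Gibbs update of each fixed-effect class; block Gibbs update of
u through the pre-computed eigen-system of R½G⁻¹R½; variance draws; a
Metropolis–Hastings sweep over SNPs in which non-fitted SNPs are evaluated
only with probability vᵢ (geometric in the SNP's first-cycle rank, the
acceptance ratios carry the 1/vᵢ correction); and draws for missing
records.  Cycle 1 only updates b and u, then computes θᵢ for every SNP
against that corrected data to fix the update schedule for the whole
chain; it contributes no posterior samples.

Throughout, y* denotes the data corrected for *all* effects currently in
the model; individual updates add their own term back before drawing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genotypes import PackedGenotypeMatrix, SnpStats, compute_snp_stats, snp_cross_products
from .grm import GRM, EigenSystem, prepare_eigensystem

__all__ = [
    "SamplerConfig",
    "ModelData",
    "ChainState",
    "UpdateSchedule",
    "PosteriorAccumulator",
    "PosteriorSummary",
    "compute_theta0",
    "compute_theta_i",
    "build_update_schedule",
    "sample_fixed_effect",
    "sample_polygenic_block",
    "sample_sigma_s",
    "sample_sigma_u",
    "sample_missing_records",
    "mh_update_snp",
    "run_chain",
    "run_chains",
]

VARIANCE_FLOOR = 1e-12


@dataclass
class SamplerConfig:
    """Chain settings.  Defaults follow the reference analysis protocol:
    10,000 cycles, 2,000 burn-in, 10 chains, lowest-ranked SNP expected to
    be evaluated 100 times."""

    pi: float
    sigma2_e: float
    n_cycles: int = 10_000
    burn_in: int = 2_000
    n_chains: int = 10
    target_evals_lowest: float = 100.0
    seed: int = 0
    min_fitted_for_sigma_s: int = 3
    fit_polygenic: bool = True
    update_sigma2_s: bool = True
    update_sigma2_u: bool = True
    uniform_updates: bool = False  # v ≡ 1 (no skip-sampling)
    init_sigma2_s: float | None = None  # default σ²ₑ/100
    init_sigma2_u: float | None = None  # default σ²ₑ

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must be in [0, 1)")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if not 1 <= self.burn_in < self.n_cycles:
            raise ValueError("need 1 <= burn_in < n_cycles")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.init_sigma2_s is None:
            self.init_sigma2_s = self.sigma2_e / 100.0
        if self.init_sigma2_u is None:
            self.init_sigma2_u = self.sigma2_e

    @property
    def gblup_mode(self) -> bool:
        return self.pi == 0.0


@dataclass
class ModelData:
    """Phenotypes, weights and design aligned to the genotype store.

    ``class_index`` holds the breed×sex class of each record (columns of
    the one-hot fixed-effect design F) or None for a model without fixed
    effects.  Missing phenotypes are flagged in ``missing_mask`` (NaNs in
    ``y`` are detected automatically) and sampled within the MCMC scheme;
    a missing record with no usable weight gets weight 1.
    """

    y: np.ndarray
    weights: np.ndarray
    genotypes: PackedGenotypeMatrix
    class_index: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    record_to_individual: np.ndarray | None = None  # identity in v1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        n = self.y.size
        if n != self.genotypes.n_individuals:
            raise ValueError("one record per genotyped individual is required")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.y)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=np.float64).copy()
        self.weights[self.missing_mask & ~(self.weights > 0)] = 1.0
        if np.any(self.weights <= 0):
            raise ValueError("record weights must be strictly positive")
        if self.class_index is not None:
            self.class_index = np.asarray(self.class_index, dtype=np.int64)
            for c in range(self.n_classes):
                if not np.any(self.class_index == c):
                    raise ValueError(f"fixed-effect class {c} has no records")
        if self.record_to_individual is None:
            self.record_to_individual = np.arange(n)

    @property
    def n_records(self) -> int:
        return int(self.y.size)

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    @property
    def n_classes(self) -> int:
        return 0 if self.class_index is None else int(self.class_index.max()) + 1

    def class_records(self, class_i: int) -> np.ndarray:
        return np.flatnonzero(self.class_index == class_i)


@dataclass
class UpdateSchedule:
    """Geometric per-SNP evaluation probabilities vᵢ = (1−ρ)^{rᵢ}."""

    rank: np.ndarray  # 1-based, 1 = highest θ
    rho: float
    v: np.ndarray
    theta_first_cycle: np.ndarray | None = None

    @classmethod
    def uniform(cls, n_snps: int) -> "UpdateSchedule":
        return cls(
            rank=np.arange(1, n_snps + 1),
            rho=0.0,
            v=np.ones(n_snps),
            theta_first_cycle=None,
        )

    def expected_evaluations_per_cycle(self) -> float:
        """Σᵢ vᵢ — the expected number of non-fitted-SNP θ evaluations."""
        return float(self.v.sum())


def build_update_schedule(
    theta_first_cycle: np.ndarray,
    n_cycles: int,
    target_evals_lowest: float = 100.0,
) -> UpdateSchedule:
    """Calibrate ρ so the lowest-θ SNP is evaluated ``target`` times.

    (1−ρ)^M · C = target  ⇒  1−ρ = (target/C)^{1/M}; ranks are assigned
    from the highest θ (rank 1) down, ties broken by SNP index.
    """
    theta = np.asarray(theta_first_cycle, dtype=np.float64)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta values must be finite")
    if target_evals_lowest >= n_cycles:
        raise ValueError(
            "target_evals_lowest must be < n_cycles "
            "(update probability would exceed 1)"
        )
    m = theta.size
    order = np.argsort(-theta, kind="stable")  # ties -> lower SNP index first
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(1, m + 1)
    one_minus_rho = (target_evals_lowest / n_cycles) ** (1.0 / m)
    v = one_minus_rho ** rank.astype(np.float64)
    return UpdateSchedule(
        rank=rank, rho=1.0 - one_minus_rho, v=v, theta_first_cycle=theta
    )


@dataclass
class ChainState:
    """Current parameter values of one chain; y_star = y − Fb − u − ΣIxs."""

    b: np.ndarray
    u: np.ndarray
    indicator: np.ndarray  # uint8
    s: np.ndarray
    sigma2_s: float
    sigma2_u: float
    sigma2_e: float
    y: np.ndarray
    y_star: np.ndarray
    rng: np.random.Generator
    L0: float = 0.0
    cycle: int = 0

    @property
    def kappa(self) -> float:
        return self.sigma2_e / self.sigma2_u

    @property
    def lambda_(self) -> float:
        return self.sigma2_e / self.sigma2_s

    @property
    def n_fitted(self) -> int:
        return int(self.indicator.sum())


@dataclass
class PosteriorAccumulator:
    gebv_sum: np.ndarray
    polygenic_sum: np.ndarray
    inclusion_count: np.ndarray
    effect_sum: np.ndarray
    fitted_trace: list
    n_samples: int = 0
    n_theta_evals: int = 0

    @classmethod
    def empty(cls, n_individuals: int, n_snps: int) -> "PosteriorAccumulator":
        return cls(
            gebv_sum=np.zeros(n_individuals),
            polygenic_sum=np.zeros(n_individuals),
            inclusion_count=np.zeros(n_snps, dtype=np.int64),
            effect_sum=np.zeros(n_snps),
            fitted_trace=[],
        )

    def add_sample(self, u: np.ndarray, g_snp: np.ndarray,
                   indicator: np.ndarray, s: np.ndarray,
                   fitted_idx: np.ndarray) -> None:
        self.gebv_sum += u + g_snp
        self.polygenic_sum += u
        self.inclusion_count += indicator
        self.effect_sum += s
        self.fitted_trace.append(
            (fitted_idx.astype(np.int64), s[fitted_idx].copy())
        )
        self.n_samples += 1

    @classmethod
    def merge(cls, accumulators) -> "PosteriorAccumulator":
        accs = list(accumulators)
        out = cls.empty(accs[0].gebv_sum.size, accs[0].inclusion_count.size)
        for a in accs:
            out.gebv_sum += a.gebv_sum
            out.polygenic_sum += a.polygenic_sum
            out.inclusion_count += a.inclusion_count
            out.effect_sum += a.effect_sum
            out.fitted_trace.extend(a.fitted_trace)
            out.n_samples += a.n_samples
            out.n_theta_evals += a.n_theta_evals
        return out


@dataclass
class PosteriorSummary:
    """Merged multi-chain posterior: inclusion probabilities, mean effects,
    GEBV, and between-chain agreement diagnostics."""

    pp: np.ndarray
    mean_effect: np.ndarray
    gebv: np.ndarray
    gebv_by_chain: np.ndarray  # (n_chains, N)
    pp_by_chain: np.ndarray  # (n_chains, M)
    chain_gebv_corr: np.ndarray  # (n_chains, n_chains)
    fitted_trace: list
    n_samples: int
    n_cycles: int
    burn_in: int
    n_chains: int
    polygenic_gebv: np.ndarray | None = None  # posterior mean of u alone

    @property
    def snp_gebv(self) -> np.ndarray | None:
        """Posterior-mean Bayes C contribution (GEBV minus polygenic part)."""
        if self.polygenic_gebv is None:
            return None
        return self.gebv - self.polygenic_gebv

    def min_chain_correlation(self) -> float:
        if self.n_chains < 2:
            return float("nan")
        iu = np.triu_indices(self.n_chains, k=1)
        return float(self.chain_gebv_corr[iu].min())


# ---------------------------------------------------------------------------
# individual sampling operations
# ---------------------------------------------------------------------------

def compute_theta0(
    y_star: np.ndarray,
    weights: np.ndarray,
    sigma2_e: float,
    pi: float,
    n_observed: int | None = None,
) -> tuple[float, float]:
    """Log posterior (up to a constant) of fitting no SNP.

    θ₀ = −y*'R⁻¹y*/(2σ²ₑ) − (n/2)log σ²ₑ − ½log|R| + log(1−π) = L₀ + log(1−π).
    """
    if pi >= 1.0:
        raise ValueError("pi must be < 1")
    y_star = np.asarray(y_star, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    n = y_star.size if n_observed is None else n_observed
    quad = float(weights @ (y_star * y_star))
    log_det_r = -float(np.log(weights).sum())  # |R| = Π 1/wⱼ
    L0 = -quad / (2.0 * sigma2_e) - 0.5 * n * math.log(sigma2_e) - 0.5 * log_det_r
    return L0, L0 + math.log1p(-pi)


def compute_theta_i(
    rhs: float, diag: float, L0: float, lambda_: float, sigma2_e: float, pi: float
) -> float:
    """Log posterior (up to the same constant) of fitting SNP i.

    θᵢ = L₀ + (x'R⁻¹y*)²/(2σ²ₑ(x'R⁻¹x+λ)) + ½log λ − ½log(x'R⁻¹x+λ) + log π.
    """
    if pi <= 0.0:
        raise ValueError("theta_i is undefined in GBLUP mode (pi = 0)")
    dpl = diag + lambda_
    return (
        L0
        + 0.5 * rhs * rhs / (sigma2_e * dpl)
        + 0.5 * math.log(lambda_)
        - 0.5 * math.log(dpl)
        + math.log(pi)
    )


def sample_fixed_effect(
    state: ChainState, class_i: int, data: ModelData,
    class_records: np.ndarray | None = None,
) -> float:
    """Gibbs draw bᵢ ~ N(Fᵢ'R⁻¹y*/Fᵢ'R⁻¹Fᵢ, σ²ₑ/Fᵢ'R⁻¹Fᵢ); updates y*."""
    idx = data.class_records(class_i) if class_records is None else class_records
    w = data.weights[idx]
    sw = w.sum()
    state.y_star[idx] += state.b[class_i]
    mean = float(w @ state.y_star[idx]) / sw
    b_new = mean + state.rng.standard_normal() * math.sqrt(state.sigma2_e / sw)
    state.b[class_i] = b_new
    state.y_star[idx] -= b_new
    return b_new


def sample_polygenic_block(
    state: ChainState, eigensystem: EigenSystem, data: ModelData
) -> np.ndarray:
    """Block Gibbs draw u ~ N[(R⁻¹+κG⁻¹)⁻¹R⁻¹y*, (R⁻¹+κG⁻¹)⁻¹σ²ₑ].

    The mean is a chain of matrix–vector products through the eigen-system;
    the draw adds σₑ·R½E'(I+κD)^{-1/2}z, which has exactly the stated
    covariance.
    """
    kappa = state.kappa
    if not math.isfinite(kappa):
        raise ValueError("kappa is not finite; polygenic update impossible")
    state.y_star += state.u
    mean = eigensystem.apply_inverse(kappa, data.weights * state.y_star)
    z = state.rng.standard_normal(state.u.size)
    noise = math.sqrt(state.sigma2_e) * (
        eigensystem.r_half * (eigensystem.E.T @ (z / np.sqrt(1.0 + kappa * eigensystem.D)))
    )
    u_new = mean + noise
    state.u = u_new
    state.y_star -= u_new
    return u_new


def sample_sigma_s(
    state: ChainState, min_fitted: int = 3, floor: float = VARIANCE_FLOOR
) -> float:
    """σ²ₛ ~ s's/χ²(ΣIᵢ−2); kept unchanged when fewer than ``min_fitted``
    SNPs are in the model (df would be ≤ 0)."""
    k = state.n_fitted
    if k >= min_fitted:
        ssq = float(state.s @ state.s)  # s is 0 for excluded SNPs
        draw = ssq / state.rng.chisquare(k - 2)
        state.sigma2_s = max(draw, floor)
    return state.sigma2_s


def sample_sigma_u(
    state: ChainState, G_inv: np.ndarray, floor: float = VARIANCE_FLOOR
) -> float:
    """σ²ᵤ ~ u'G⁻¹u/χ²(N−2)."""
    n = state.u.size
    if n < 3:
        raise ValueError("polygenic variance draw needs N >= 3 individuals")
    quad = float(state.u @ (G_inv @ state.u))
    draw = quad / state.rng.chisquare(n - 2)
    state.sigma2_u = max(draw, floor)
    return state.sigma2_u


def sample_missing_records(state: ChainState, data: ModelData) -> None:
    """Draw each missing y from N(Fb + u + ΣIxs, σ²ₑ/weight)."""
    idx = np.flatnonzero(data.missing_mask)
    if idx.size == 0:
        return
    fitted = state.y[idx] - state.y_star[idx]
    e = state.rng.standard_normal(idx.size) * np.sqrt(
        state.sigma2_e / data.weights[idx]
    )
    state.y[idx] = fitted + e
    state.y_star[idx] = e


def mh_update_snp(
    state: ChainState,
    snp_index: int,
    schedule: UpdateSchedule,
    data: ModelData,
    stats: SnpStats,
    pi: float,
    skip_draw: float | None = None,
) -> bool:
    """Single-SNP MH update (reference implementation of one sweep step).

    The production sweep runs the same logic in a compiled kernel
    (:func:`bayesgc._kernels.snp_sweep`); this version exists for the
    model-free unit tests and for clarity.  Returns True if the SNP was
    evaluated.
    """
    i = snp_index
    rng = state.rng
    v_i = schedule.v[i]
    fitted = bool(state.indicator[i])
    if not fitted:
        u_skip = rng.random() if skip_draw is None else skip_draw
        if u_skip >= v_i:
            return False
    x_c = data.genotypes.column(i).astype(np.float64) - stats.weighted_mean[i]
    if fitted:
        state.y_star += x_c * state.s[i]
    rhs, diag = snp_cross_products(
        data.genotypes, i, state.y_star, data.weights, stats
    )
    lam = state.lambda_
    L0, theta0 = compute_theta0(
        state.y_star, data.weights, state.sigma2_e, pi, data.n_observed
    )
    theta_i = compute_theta_i(rhs, diag, L0, lam, state.sigma2_e, pi)
    log_v = math.log(v_i)
    log_u = math.log(rng.random())
    if fitted:
        stays_in = not (log_u < theta0 + log_v - theta_i)
    else:
        stays_in = log_u < theta_i - log_v - theta0
    if stays_in:
        dpl = diag + lam
        s_new = rhs / dpl + rng.standard_normal() * math.sqrt(state.sigma2_e / dpl)
        state.y_star -= x_c * s_new
        state.s[i] = s_new
        state.indicator[i] = 1
    else:
        state.s[i] = 0.0
        state.indicator[i] = 0
    return True


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------

def _init_state(
    config: SamplerConfig, data: ModelData, rng: np.random.Generator
) -> ChainState:
    n = data.n_records
    m = data.genotypes.n_snps
    y = data.y.copy()
    obs = ~data.missing_mask
    fill = float(
        np.average(y[obs], weights=data.weights[obs]) if obs.any() else 0.0
    )
    y[data.missing_mask] = fill
    return ChainState(
        b=np.zeros(max(data.n_classes, 1)),
        u=np.zeros(n),
        indicator=np.zeros(m, dtype=np.uint8),
        s=np.zeros(m),
        sigma2_s=float(config.init_sigma2_s),
        sigma2_u=float(config.init_sigma2_u) if config.fit_polygenic else np.inf,
        sigma2_e=float(config.sigma2_e),
        y=y,
        y_star=y.copy(),
        rng=rng,
    )


def run_chain(
    config: SamplerConfig,
    data: ModelData,
    grm: GRM | None,
    eigensystem: EigenSystem | None,
    chain_seed,
    stats: SnpStats | None = None,
) -> tuple[PosteriorAccumulator, ChainState]:
    """Execute one MCMC chain and accumulate post-burn-in samples."""
    if config.fit_polygenic and (grm is None or eigensystem is None):
        raise ValueError("polygenic term requires a GRM and its eigen-system")
    rng = np.random.default_rng(chain_seed)
    store = data.genotypes
    n, m = data.n_records, store.n_snps
    if stats is None:
        stats = compute_snp_stats(store, data.weights)
    diag_c = stats.centered_diag
    state = _init_state(config, data, rng)
    acc = PosteriorAccumulator.empty(n, m)
    schedule: UpdateSchedule | None = None
    class_records = [data.class_records(c) for c in range(data.n_classes)]

    for cycle in range(1, config.n_cycles + 1):
        state.cycle = cycle
        for c, idx in enumerate(class_records):
            sample_fixed_effect(state, c, data, class_records=idx)
        if config.fit_polygenic:
            sample_polygenic_block(state, eigensystem, data)

        if cycle == 1:
            if not config.gblup_mode:
                log_bf = _kernels.log_bf_all(
                    store.packed, n, data.weights, state.y_star,
                    stats.weighted_mean, diag_c, state.lambda_, state.sigma2_e,
                )
                L0, _ = compute_theta0(
                    state.y_star, data.weights, state.sigma2_e, config.pi,
                    data.n_observed,
                )
                state.L0 = L0
                theta = L0 + math.log(config.pi) + log_bf
                if config.uniform_updates:
                    schedule = UpdateSchedule.uniform(m)
                    schedule.theta_first_cycle = theta
                else:
                    schedule = build_update_schedule(
                        theta, config.n_cycles, config.target_evals_lowest
                    )
            continue  # cycle 1 contributes no samples

        if not config.gblup_mode and config.update_sigma2_s:
            sample_sigma_s(state, config.min_fitted_for_sigma_s)
        if config.fit_polygenic and config.update_sigma2_u:
            sample_sigma_u(state, grm.G_inv)

        if not config.gblup_mode:
            acc.n_theta_evals += _kernels.snp_sweep(
                store.packed, n, data.weights, state.y_star,
                stats.weighted_mean, diag_c,
                state.indicator, state.s, schedule.v,
                rng.random(m), rng.random(m), rng.standard_normal(m),
                state.lambda_, state.sigma2_e,
                math.log(config.pi) - math.log1p(-config.pi),
            )

        sample_missing_records(state, data)

        if cycle > config.burn_in:
            fitted_idx = np.flatnonzero(state.indicator)
            if fitted_idx.size:
                g_snp = _kernels.bayesc_values(
                    store.packed, n, stats.weighted_mean, state.s,
                    fitted_idx.astype(np.int64),
                )
            else:
                g_snp = np.zeros(n)
            acc.add_sample(state.u, g_snp, state.indicator, state.s, fitted_idx)
    return acc, state


def run_chains(
    config: SamplerConfig,
    data: ModelData,
    grm: GRM | None = None,
    eigensystem: EigenSystem | None = None,
) -> PosteriorSummary:
    """Run ``config.n_chains`` chains against shared read-only inputs.

    Chain k is seeded from SeedSequence(config.seed, spawn_key=(k,)); the
    genotype store, GRM and eigen-system are shared and never mutated.
    """
    if config.fit_polygenic and eigensystem is None:
        if grm is None:
            raise ValueError("polygenic term requires a GRM")
        eigensystem = prepare_eigensystem(grm.G_inv, data.weights)
    stats = compute_snp_stats(data.genotypes, data.weights)
    accs = []
    for k in range(config.n_chains):
        seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(k,))
        try:
            acc, _ = run_chain(config, data, grm, eigensystem, seed, stats=stats)
        except Exception as exc:
            raise RuntimeError(f"MCMC chain {k} failed: {exc}") from exc
        accs.append(acc)

    merged = PosteriorAccumulator.merge(accs)
    n_chains = len(accs)
    gebv_by_chain = np.stack(
        [a.gebv_sum / max(a.n_samples, 1) for a in accs]
    )
    pp_by_chain = np.stack(
        [a.inclusion_count / max(a.n_samples, 1) for a in accs]
    )
    corr = np.corrcoef(gebv_by_chain) if n_chains > 1 else np.ones((1, 1))
    ns = max(merged.n_samples, 1)
    return PosteriorSummary(
        pp=merged.inclusion_count / ns,
        mean_effect=merged.effect_sum / ns,
        gebv=merged.gebv_sum / ns,
        gebv_by_chain=gebv_by_chain,
        pp_by_chain=pp_by_chain,
        chain_gebv_corr=np.atleast_2d(corr),
        fitted_trace=merged.fitted_trace,
        n_samples=merged.n_samples,
        n_cycles=config.n_cycles,
        burn_in=config.burn_in,
        n_chains=n_chains,
        polygenic_gebv=merged.polygenic_sum / ns,
    )
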