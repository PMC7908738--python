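"""Model/Results front end.

``BayesGC`` bundles phenotypes, weights, fixed-effect classes and the
packed genotype store, builds the genomic relationship machinery once,
and ``fit()`` runs the MCMC chains, returning a ``BayesGCResults`` that
carries GEBV, posterior inclusion probabilities, mean SNP effects,
between-chain diagnostics, and the QTL-mapping methods.

    >>> model = BayesGC(y, genotypes, weights=w, class_index=cls)
    >>> res = model.fit(pi=5e-4, sigma2_e=0.5, n_cycles=10_000, seed=1)
    >>> res.gebv, res.pp
    >>> res.top_regions(10)

``fit(pi=0, ...)`` (or :meth:`fit_gblup`) is the pure-GBLUP special case:
no SNP is ever fitted and the GEBV reduce to the averaged polygenic term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import PackedGenotypeMatrix, compute_snp_stats, pack_genotypes
from .grm import DEFAULT_RIDGE, GRM, build_grm, invert_grm, prepare_eigensystem
from .qtl import (
    DEFAULT_MASS,
    DEFAULT_MAX_SNP_DISTANCE,
    DEFAULT_REGION_WIDTH,
    CredibleInterval,
    credibility_interval,
    region_table,
    region_variances,
    snp_table,
    top_regions,
)
from .sampler import ModelData, PosteriorSummary, SamplerConfig, run_chains

__all__ = ["BayesGC", "BayesGCResults"]


class BayesGC:
    """Hybrid GBLUP + spike-and-slab whole-genome regression model.

    Parameters
    ----------
    y : (N,) phenotypes (DYD/YD); NaN marks a missing record, which is
        sampled within the MCMC scheme.
    genotypes : packed genotype store (or an N×M {0,1,2} code matrix,
        packed on the fly).
    weights : (N,) record weights, the diagonal of R⁻¹; default 1.
    class_index : (N,) breed×sex class per record, or None for a model
        with no fixed effects.
    grm_snp_subset : SNP indices used to build G (default: all SNPs).
    grm_ridge : ridge added to diag(G) before inversion.
    """

    def __init__(
        self,
        y,
        genotypes,
        weights=None,
        class_index=None,
        grm_snp_subset=None,
        grm_ridge: float = DEFAULT_RIDGE,
    ) -> None:
        if not isinstance(genotypes, PackedGenotypeMatrix):
            genotypes = pack_genotypes(np.asarray(genotypes))
        y = np.asarray(y, dtype=np.float64)
        if weights is None:
            weights = np.ones(y.size)
        self.data = ModelData(
            y=y, weights=np.asarray(weights, dtype=np.float64),
            genotypes=genotypes, class_index=class_index,
        )
        self.grm_snp_subset = grm_snp_subset
        self.grm_ridge = grm_ridge
        self._grm: GRM | None = None
        self._eigensystem = None

    @classmethod
    def from_dataframe(
        cls, pheno: pd.DataFrame, genotypes: PackedGenotypeMatrix, **kwargs
    ) -> "BayesGC":
        """Build from a phenotype table with columns id, y, weight, breed, sex.

        Rows are aligned to the genotype store's individual ids; individuals
        without a phenotype row become missing records (weight 1).
        """
        ids = genotypes.individual_ids
        if ids is None:
            raise ValueError("genotype store carries no individual ids")
        pheno = pheno.set_index("id").reindex(ids)
        y = pheno["y"].to_numpy(dtype=np.float64)
        w = pheno["weight"].to_numpy(dtype=np.float64)
        w[~(w > 0)] = 1.0
        breed = pd.factorize(pheno["breed"].fillna(-1))[0]
        sex = pd.factorize(pheno["sex"].fillna(-1))[0]
        class_index = pd.factorize(pd.Series(zip(breed, sex)))[0]
        return cls(y, genotypes, weights=w, class_index=class_index, **kwargs)

    # -- lazy GRM machinery ----------------------------------------------
    @property
    def grm(self) -> GRM:
        if self._grm is None:
            subset = self.grm_snp_subset
            if subset is None:
                # monomorphic SNPs carry no relationship information and
                # break the per-SNP scaling; drop them
                p = self.data.genotypes.allele_frequencies()
                poly = np.flatnonzero((p > 0.0) & (p < 1.0))
                subset = None if poly.size == self.data.genotypes.n_snps else poly
            G = build_grm(self.data.genotypes, subset)
            self._grm = GRM(
                G=G,
                G_inv=invert_grm(G, self.grm_ridge),
                ridge=self.grm_ridge,
                snp_subset=subset,
            )
        return self._grm

    @property
    def eigensystem(self):
        if self._eigensystem is None:
            self._eigensystem = prepare_eigensystem(
                self.grm.G_inv, self.data.weights
            )
        return self._eigensystem

    def set_grm(self, grm: GRM) -> None:
        """Install a pre-built GRM (e.g. from a SNP-chip subset)."""
        self._grm = grm
        self._eigensystem = None

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        pi: float,
        sigma2_e: float,
        n_cycles: int = 10_000,
        burn_in: int = 2_000,
        n_chains: int = 10,
        seed: int = 0,
        **config_kwargs,
    ) -> "BayesGCResults":
        config = SamplerConfig(
            pi=pi, sigma2_e=sigma2_e, n_cycles=n_cycles, burn_in=burn_in,
            n_chains=n_chains, seed=seed, **config_kwargs,
        )
        grm = eig = None
        if config.fit_polygenic:
            grm, eig = self.grm, self.eigensystem
        summary = run_chains(config, self.data, grm, eig)
        return BayesGCResults(self, config, summary)

    def fit_gblup(self, sigma2_e: float, **kwargs) -> "BayesGCResults":
        """GBLUP mode: π = 0, only the polygenic term is fitted."""
        return self.fit(pi=0.0, sigma2_e=sigma2_e, **kwargs)


@dataclass
class BayesGCResults:
    """Posterior summaries of a fitted model."""

    model: BayesGC
    config: SamplerConfig
    posterior: PosteriorSummary

    # -- primary estimates -------------------------------------------------
    @property
    def gebv(self) -> np.ndarray:
        """Posterior-mean genomic breeding values u + ΣIxs (centered x)."""
        return self.posterior.gebv

    @property
    def pp(self) -> np.ndarray:
        """Posterior inclusion probability per SNP."""
        return self.posterior.pp

    @property
    def snp_effects(self) -> np.ndarray:
        """Posterior-mean SNP effects (zeros included, i.e. PP-weighted)."""
        return self.posterior.mean_effect

    @property
    def chain_gebv_correlation(self) -> np.ndarray:
        return self.posterior.chain_gebv_corr

    # -- QTL mapping --------------------------------------------------------
    def region_variances(self, width: int = DEFAULT_REGION_WIDTH):
        return region_variances(
            self.posterior, self.model.data.genotypes, width=width,
            weights=self.model.data.weights,
        )

    def top_regions(self, k: int = 10, width: int = DEFAULT_REGION_WIDTH):
        return top_regions(self.region_variances(width=width), k)

    def credibility_interval(
        self,
        top_snp: int,
        max_snp_distance: int = DEFAULT_MAX_SNP_DISTANCE,
        mass: float = DEFAULT_MASS,
    ) -> CredibleInterval | None:
        return credibility_interval(
            self.posterior.fitted_trace,
            self.model.data.genotypes.variant_map,
            top_snp,
            max_snp_distance=max_snp_distance,
            mass=mass,
            pp=self.pp,
        )

    # -- tables --------------------------------------------------------------
    def gebv_table(self) -> pd.DataFrame:
        ids = self.model.data.genotypes.individual_ids
        if ids is None:
            ids = np.array(
                [f"id{j}" for j in range(self.gebv.size)], dtype=object
            )
        return pd.DataFrame(
            {
                "id": ids,
                "gebv": self.gebv,
                "polygenic": self.posterior.polygenic_gebv,
                "snp": self.posterior.snp_gebv,
            }
        )

    def snp_table(self) -> pd.DataFrame:
        return snp_table(self.posterior, self.model.data.genotypes.variant_map)

    def region_table(self, width: int = DEFAULT_REGION_WIDTH) -> pd.DataFrame:
        return region_table(self.region_variances(width=width))

    def summary(self) -> str:
        p = self.posterior
        cfg = self.config
        mode = "GBLUP (pi = 0)" if cfg.gblup_mode else "Bayes GC"
        lines = [
            f"{mode} MCMC fit",
            "=" * 34,
            f"records / SNPs        {self.model.data.n_records} / "
            f"{self.model.data.genotypes.n_snps}",
            f"cycles (burn-in)      {cfg.n_cycles} ({cfg.burn_in})",
            f"chains / samples      {p.n_chains} / {p.n_samples}",
            f"pi / sigma2_e         {cfg.pi:g} / {cfg.sigma2_e:g}",
            f"mean fitted SNPs      {p.pp.sum():.2f}",
            f"mean |GEBV|           {np.abs(p.gebv).mean():.4f}",
        ]
        if p.n_chains > 1:
            lines.append(
                f"min chain GEBV corr   {p.min_chain_correlation():.4f}"
            )
        if not cfg.gblup_mode:
            k = min(5, p.pp.size)
            top = np.argsort(-p.pp)[:k]
            vmap = self.model.data.genotypes.variant_map
            lines.append("top SNPs by PP:")
            for i in top:
                lines.append(
                    f"  {vmap.snp_id[i]:>10}  chr{vmap.chromosome[i]}:"
                    f"{vmap.position_bp[i]}  PP={p.pp[i]:.3f}  "
                    f"effect={p.mean_effect[i]:+.4f}"
                )
        return "\n".join(lines)
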