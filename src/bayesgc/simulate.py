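"""Multi-breed genotype and trait simulator.

Genotypes: each breed's allele frequencies diverge from a shared ancestral
frequency by the Balding–Nichols construction (ancestral p ~ U(0.05, 0.95);
breed frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target Fst).
Linkage disequilibrium is produced by Markov lineage copying: each
haplotype carries a lineage quantile along the chromosome, refreshed with
probability ``ld_decay`` per SNP; the allele at a SNP is the indicator
that the quantile falls below the breed frequency.  Haplotypes sharing a
lineage segment are identical over it, giving LD that decays geometrically
with SNP distance while marginal frequencies stay exact — adequate for
testing tagging/fine-mapping behaviour, not a population-genetic model
(no mutation, no recombination map, no selection).

Trait: a few large-effect QTL plus a polygenic background over all other
SNPs, scaled so the QTL explain ``prop_var_qtl`` of the genetic variance
and heritability is ``h2`` for a weight-1 record.  Records carry
heterogeneous weights (progeny-test-like for "bulls", 1 for "cows");
residual variance of record j is σ²ₑ/weightⱼ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import PackedGenotypeMatrix, VariantMap, pack_genotypes
from .sampler import ModelData

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_trait", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study-condition defaults: three breeds of 400/300/300, 5,000 SNPs,
    20 QTL explaining half of a h² = 0.5 trait, Fst = 0.05."""

    n_per_breed: tuple = (400, 300, 300)
    n_snps: int = 5_000
    n_chromosomes: int = 5
    fst: float = 0.05
    ld_decay: float = 0.1
    n_qtl: int = 20
    h2: float = 0.5
    prop_var_qtl: float = 0.5
    bull_fraction: float = 0.4
    bull_weight_range: tuple = (5.0, 100.0)
    snp_spacing_bp: int = 10_000
    drop_breed_from_training: int | None = None  # across-breed validation flag
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 < self.ld_decay <= 1.0:
            raise ValueError("ld_decay must be in (0, 1]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.prop_var_qtl <= 1.0:
            raise ValueError("prop_var_qtl must be in [0, 1]")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must be <= n_snps")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.n_per_breed))


@dataclass
class SimTruth:
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    breed_labels: np.ndarray
    sex_labels: np.ndarray
    class_effects: np.ndarray
    sigma2_e: float
    training_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"qtl_index": self.qtl_indices, "effect": self.qtl_effects}
        )


def _breed_frequencies(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)


def _breed_haplotypes(rng, p_breed, n_haplotypes, ld_decay):
    """Markov haplotypes with frequency-quantile sharing, shape (H, M) uint8.

    Each haplotype walks along the chromosome carrying a lineage quantile
    u ∈ (0,1); at every SNP it switches to a fresh lineage with probability
    ``ld_decay``, otherwise it keeps the current one.  The allele at SNP m
    is 1 iff u < p_m, so marginal frequencies are exact while haplotypes
    sharing a lineage segment are identical over it — producing LD that
    decays geometrically with SNP distance.
    """
    m = p_breed.size
    switch = rng.random((n_haplotypes, m)) < ld_decay
    switch[:, 0] = True
    fresh_u = rng.random((n_haplotypes, m))
    # forward-fill the lineage quantile between switches
    seg = np.maximum.accumulate(np.where(switch, np.arange(m), -1), axis=1)
    u = fresh_u[np.arange(n_haplotypes)[:, None], seg]
    return (u < p_breed).astype(np.uint8)


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PackedGenotypeMatrix, np.ndarray]:
    """Genotypes for all breeds plus per-individual breed labels."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    codes = np.empty((config.n_individuals, m), dtype=np.uint8)
    labels = np.empty(config.n_individuals, dtype=np.int64)
    row = 0
    for breed, n_b in enumerate(config.n_per_breed):
        p_b = _breed_frequencies(rng, p_anc, config.fst)
        hap1 = _breed_haplotypes(rng, p_b, n_b, config.ld_decay)
        hap2 = _breed_haplotypes(rng, p_b, n_b, config.ld_decay)
        codes[row: row + n_b] = hap1 + hap2
        labels[row: row + n_b] = breed
        row += n_b

    # chromosome layout: equal-length chromosomes, evenly spaced SNPs
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = 1 + np.arange(m) // per_chrom
    within = np.arange(m) % per_chrom
    vmap = VariantMap(
        chromosome=chrom,
        position_bp=(within + 1) * config.snp_spacing_bp,
        snp_id=np.array([f"snp{i}" for i in range(m)], dtype=object),
    )
    store = pack_genotypes(
        codes, variant_map=vmap,
        individual_ids=np.array([f"id{j}" for j in range(config.n_individuals)],
                                dtype=object),
    )
    return store, labels


def simulate_trait(
    store: PackedGenotypeMatrix,
    config: SimConfig,
    breed_labels: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[ModelData, SimTruth]:
    """Phenotypes with a QTL + polygenic architecture and DYD/YD-like weights."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, m = store.n_individuals, store.n_snps
    x = store.to_matrix().astype(np.float64)
    x_c = x - x.mean(axis=0)

    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    var_g_target = config.h2  # phenotypic variance targeted at 1 for weight-1 records

    qtl_eff = rng.standard_normal(config.n_qtl)
    g_qtl = x_c[:, qtl] @ qtl_eff
    target_qtl = config.prop_var_qtl * var_g_target
    v = float(np.var(g_qtl))
    scale = np.sqrt(target_qtl / v) if v > 0 and target_qtl > 0 else 0.0
    qtl_eff *= scale
    g_qtl *= scale

    bg = np.setdiff1d(np.arange(m), qtl)
    bg_eff = rng.standard_normal(bg.size)
    g_bg = x_c[:, bg] @ bg_eff
    target_bg = (1.0 - config.prop_var_qtl) * var_g_target
    v = float(np.var(g_bg))
    scale = np.sqrt(target_bg / v) if v > 0 and target_bg > 0 else 0.0
    g_bg *= scale

    tbv = g_qtl + g_bg
    var_g = float(np.var(tbv))
    if config.h2 >= 1.0 and var_g > 0:
        raise ValueError("h2 = 1 leaves no residual variance to draw from")
    sigma2_e = var_g * (1.0 - config.h2) / config.h2 if config.h2 > 0 else 1.0

    sex = (rng.random(n) < config.bull_fraction).astype(np.int64)  # 1 = bull
    lo, hi = config.bull_weight_range
    weights = np.ones(n)
    bulls = sex == 1
    weights[bulls] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=bulls.sum()))

    class_index = breed_labels * 2 + sex  # breed×sex classes
    class_effects = rng.normal(0.0, 0.5, size=int(class_index.max()) + 1)

    e = rng.standard_normal(n) * np.sqrt(sigma2_e / weights)
    y = class_effects[class_index] + tbv + e

    training = np.ones(n, dtype=bool)
    if config.drop_breed_from_training is not None:
        training = breed_labels != config.drop_breed_from_training
    missing = ~training  # dropped breed: phenotype masked, genotypes kept

    data = ModelData(
        y=np.where(missing, np.nan, y),
        weights=weights,
        genotypes=store,
        class_index=class_index,
        missing_mask=missing,
    )
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=qtl_eff,
        true_breeding_values=tbv,
        breed_labels=breed_labels,
        sex_labels=sex,
        class_effects=class_effects,
        sigma2_e=sigma2_e,
        training_mask=training,
    )
    return data, truth


def simulate_dataset(config: SimConfig) -> tuple[ModelData, SimTruth]:
    """Genotypes + trait in one call, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    store, labels = simulate_genotypes(config, rng)
    return simulate_trait(store, config, labels, rng)


def phenotype_frame(data: ModelData, breed_labels: np.ndarray,
                    sex_labels: np.ndarray) -> pd.DataFrame:
    """Tab-separable phenotype table: id, trait, weight, breed, sex."""
    ids = data.genotypes.individual_ids
    if ids is None:
        ids = np.array([f"id{j}" for j in range(data.n_records)], dtype=object)
    return pd.DataFrame(
        {
            "id": ids,
            "y": data.y,
            "weight": data.weights,
            "breed": breed_labels,
            "sex": sex_labels,
        }
    )
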