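"""Genomic relationship matrix and the diagonalized polygenic system.

The polygenic term u ~ N(0, G σ²ᵤ) needs, every MCMC cycle, the inverse of
(R⁻¹ + κ G⁻¹) with κ = σ²ₑ/σ²ᵤ changing from cycle to cycle.  Writing
R⁻¹ + κG⁻¹ = R^{-1/2}(I + κ R^{1/2} G⁻¹ R^{1/2}) R^{-1/2} and
eigen-decomposing the fixed matrix R^{1/2} G⁻¹ R^{1/2} = E'DE once up
front turns each cycle's inverse into

    (R⁻¹ + κG⁻¹)⁻¹ = R^{1/2} E' (I + κD)⁻¹ E R^{1/2},

a chain of matrix–vector products (never a dense inverse).  Here R⁻¹ is
the diagonal matrix of record weights, so R^{1/2} = diag(1/√w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genotypes import PackedGenotypeMatrix

__all__ = ["GRM", "EigenSystem", "build_grm", "invert_grm", "prepare_eigensystem"]

DEFAULT_RIDGE = 0.01


@dataclass
class GRM:
    G: np.ndarray
    G_inv: np.ndarray
    ridge: float
    snp_subset: np.ndarray | None = None


@dataclass
class EigenSystem:
    """Orthonormal E and eigenvalues D with R^{1/2}G⁻¹R^{1/2} = E' diag(D) E."""

    E: np.ndarray
    D: np.ndarray
    r_half: np.ndarray      # diag of R^{1/2} = 1/√w
    r_inv_half: np.ndarray  # diag of R^{-1/2} = √w

    @property
    def n(self) -> int:
        return self.D.size

    def reconstruct(self) -> np.ndarray:
        return self.E.T @ (self.D[:, None] * self.E)

    def apply_inverse(self, kappa: float, rhs: np.ndarray) -> np.ndarray:
        """(R⁻¹ + κG⁻¹)⁻¹ @ rhs via right-to-left matrix–vector products."""
        v = self.r_half * rhs
        v = self.E @ v
        v = v / (1.0 + kappa * self.D)
        v = self.E.T @ v
        return self.r_half * v


def build_grm(
    store_or_codes, snp_subset: np.ndarray | None = None
) -> np.ndarray:
    """VanRaden Method 2 GRM with one pooled allele frequency per SNP.

    G = (1/m) Σᵢ (x̃ᵢ − 2pᵢ1)(x̃ᵢ − 2pᵢ1)' / (2pᵢ(1−pᵢ)), i.e. the
    cross-product of genotypes centered and scaled per SNP, averaged over
    the m SNPs used.  pᵢ is the unweighted counted-allele frequency across
    all individuals of all breeds.
    """
    if isinstance(store_or_codes, PackedGenotypeMatrix):
        codes = store_or_codes.to_matrix()
    else:
        codes = np.asarray(store_or_codes)
    x = codes.astype(np.float64)
    if snp_subset is not None:
        x = x[:, np.asarray(snp_subset)]
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = int(np.flatnonzero((p <= 0.0) | (p >= 1.0))[0])
        raise ValueError(
            f"monomorphic SNP (subset column {bad}) in GRM subset; "
            "filter monomorphic SNPs before building G"
        )
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (z @ z.T) / z.shape[1]


def invert_grm(G: np.ndarray, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Inverse of (G + ridge·I) via Cholesky; raises if not positive definite."""
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    Gr = np.asarray(G, dtype=np.float64)
    Gr = Gr + ridge * np.eye(Gr.shape[0])
    try:
        c, low = scipy.linalg.cho_factor(Gr, lower=True)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            f"G + {ridge}·I is not positive definite; increase the ridge"
        ) from exc
    return scipy.linalg.cho_solve((c, low), np.eye(Gr.shape[0]))


def prepare_eigensystem(G_inv: np.ndarray, weights: np.ndarray) -> EigenSystem:
    """Eigen-decompose R^{1/2}G⁻¹R^{1/2}; done once before sampling."""
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights <= 0):
        raise ValueError("record weights must be strictly positive")
    if not np.all(np.isfinite(G_inv)):
        raise ValueError("G_inv contains non-finite entries")
    r_half = 1.0 / np.sqrt(weights)
    m = (r_half[:, None] * G_inv) * r_half[None, :]
    # symmetrize against round-off before eigh
    m = 0.5 * (m + m.T)
    d, v = np.linalg.eigh(m)
    d = np.clip(d, 0.0, None)
    return EigenSystem(E=v.T, D=d, r_half=r_half, r_inv_half=np.sqrt(weights))
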