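"""Bit-packed genotype storage with PLINK .bed/.bim/.fam I/O.

Genotypes are biallelic allele counts in {0, 1, 2}, stored SNP-major at
2 bits each (4 genotypes per byte), the same layout PLINK uses for .bed
files.  Packing individual j of a SNP into bits 2*(j mod 4) .. 2*(j mod 4)+1
of byte j // 4 means a .bed data block can be memcpy'd after code
translation.  Internally codes 0/1/2 map to bit patterns 00/01/10; the
pattern 11 is illegal once a file has been loaded (PLINK's missing code is
resolved at read time by the chosen missing policy).

The store also carries the per-SNP quantities the sampler needs every
cycle but that only depend on the record weights: the weighted genotype
mean x̄ᵢ = 1'R⁻¹x̃ᵢ / 1'R⁻¹1 and the raw weighted sum of squares
x̃ᵢ'R⁻¹x̃ᵢ.  They are computed once (see :func:`compute_snp_stats`) so the
MCMC sweep can form centered cross-products from uncentered 2-bit codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantMap",
    "SnpStats",
    "PackedGenotypeMatrix",
    "pack_genotypes",
    "unpack_genotypes",
    "read_plink_bed",
    "write_plink_bed",
    "snp_weighted_mean",
    "compute_snp_stats",
    "snp_cross_products",
    "maf_filter",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 1 .bed 2-bit values: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Counting the A2 allele (default) maps 00->0, 10->1, 11->2.
_PLINK_MISSING = 0b01


class InvalidGenotypeError(ValueError):
    pass


class MissingGenotypeError(ValueError):
    pass


@dataclass
class VariantMap:
    """Per-SNP chromosome / basepair / id bookkeeping.

    Positions are 1-based bp as in .bim files; any region arithmetic
    elsewhere in the package uses half-open [start, end) intervals.
    """

    chromosome: np.ndarray  # int
    position_bp: np.ndarray  # int, 1-based
    snp_id: np.ndarray  # str (object array)

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        if not (self.chromosome.size == self.position_bp.size == self.snp_id.size):
            raise ValueError("variant map columns must have equal length")
        for chrom in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"positions must be non-decreasing within chromosome {chrom}"
                )

    def __len__(self) -> int:
        return int(self.chromosome.size)

    @classmethod
    def default(cls, n_snps: int, chromosome: int = 1, spacing_bp: int = 1000
                ) -> "VariantMap":
        """Evenly spaced placeholder map for matrices built in memory."""
        return cls(
            chromosome=np.full(n_snps, chromosome, dtype=np.int64),
            position_bp=np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp,
            snp_id=np.array([f"snp{i}" for i in range(n_snps)], dtype=object),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "snp_id": self.snp_id,
                "bp": self.position_bp,
            }
        )


@dataclass
class SnpStats:
    """Weight-dependent per-SNP caches (one pass, reused every MCMC cycle)."""

    weighted_mean: np.ndarray   # x̄ᵢ = 1'R⁻¹x̃ᵢ / 1'R⁻¹1
    raw_weighted_ssq: np.ndarray  # x̃ᵢ'R⁻¹x̃ᵢ
    sum_weights: float          # 1'R⁻¹1

    @property
    def centered_diag(self) -> np.ndarray:
        """x'R⁻¹x of the centered genotype: x̃'R⁻¹x̃ − (1'R⁻¹1)·x̄²."""
        return self.raw_weighted_ssq - self.sum_weights * self.weighted_mean**2


@dataclass
class PackedGenotypeMatrix:
    """N×M genotype codes packed 2 bits each, SNP-major.

    ``packed`` has shape (M, ceil(N/4)) uint8, so ``packed[i]`` is the byte
    block for SNP i.
    """

    n_individuals: int
    n_snps: int
    packed: np.ndarray
    variant_map: VariantMap
    allele_order: str = "count-A2"
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        bytes_per_snp = (self.n_individuals + 3) // 4
        if self.packed.shape != (self.n_snps, bytes_per_snp):
            raise ValueError(
                f"packed buffer shape {self.packed.shape} != "
                f"({self.n_snps}, {bytes_per_snp})"
            )
        if len(self.variant_map) != self.n_snps:
            raise ValueError("variant map length != n_snps")

    # -- element access -------------------------------------------------
    def column(self, snp_index: int) -> np.ndarray:
        """Unpacked codes for one SNP, shape (N,), dtype uint8."""
        b = self.packed[snp_index]
        out = np.empty(4 * b.size, dtype=np.uint8)
        out[0::4] = b & 3
        out[1::4] = (b >> 2) & 3
        out[2::4] = (b >> 4) & 3
        out[3::4] = (b >> 6) & 3
        return out[: self.n_individuals]

    def to_matrix(self) -> np.ndarray:
        """Full unpacked N×M code matrix (uint8). Intended for small data."""
        b = self.packed  # (M, B)
        out = np.empty((self.n_snps, 4 * b.shape[1]), dtype=np.uint8)
        out[:, 0::4] = b & 3
        out[:, 1::4] = (b >> 2) & 3
        out[:, 2::4] = (b >> 4) & 3
        out[:, 3::4] = (b >> 6) & 3
        return out[:, : self.n_individuals].T

    def allele_frequencies(self) -> np.ndarray:
        """Unweighted counted-allele frequency per SNP."""
        return self.to_matrix().mean(axis=0) / 2.0

    def nbytes(self) -> int:
        return int(self.packed.size)


def pack_genotypes(
    codes: np.ndarray,
    variant_map: VariantMap | None = None,
    individual_ids: np.ndarray | None = None,
) -> PackedGenotypeMatrix:
    """Pack an N×M matrix of codes over {0,1,2} into 2-bit SNP-major storage."""
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("codes must be a 2-D N×M matrix")
    n, m = codes.shape
    bad = (codes < 0) | (codes > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidGenotypeError(
            f"invalid genotype code {codes[i, j]!r} for individual {i}, SNP {j}"
        )
    bytes_per_snp = (n + 3) // 4
    cm = np.zeros((m, 4 * bytes_per_snp), dtype=np.uint8)
    cm[:, :n] = codes.T
    packed = (
        cm[:, 0::4]
        | (cm[:, 1::4] << 2)
        | (cm[:, 2::4] << 4)
        | (cm[:, 3::4] << 6)
    ).astype(np.uint8)
    if variant_map is None:
        variant_map = VariantMap.default(m)
    return PackedGenotypeMatrix(
        n_individuals=n,
        n_snps=m,
        packed=np.ascontiguousarray(packed),
        variant_map=variant_map,
        individual_ids=individual_ids,
    )


def unpack_genotypes(store: PackedGenotypeMatrix) -> np.ndarray:
    """Inverse of :func:`pack_genotypes` (exact round-trip)."""
    return store.to_matrix()


# ---------------------------------------------------------------------------
# PLINK I/O
# ---------------------------------------------------------------------------

def read_plink_bed(
    bed_path,
    bim_path=None,
    fam_path=None,
    missing_policy: str = "error",
) -> PackedGenotypeMatrix:
    """Read a SNP-major PLINK 1 .bed/.bim/.fam triple.

    The counted allele is A2 (PLINK's "other" allele), so PLINK bit codes
    00/10/11 become 0/1/2.  PLINK's missing code (01) is handled by
    ``missing_policy``: ``"error"`` (default) raises naming the SNP and
    individual; ``"impute_mean_rounded"`` substitutes the rounded mean code
    of the SNP's observed genotypes.
    """
    bed_path = str(bed_path)
    if bim_path is None:
        bim_path = bed_path[:-4] + ".bim" if bed_path.endswith(".bed") else bed_path + ".bim"
    if fam_path is None:
        fam_path = bed_path[:-4] + ".fam" if bed_path.endswith(".bed") else bed_path + ".fam"
    if missing_policy not in ("error", "impute_mean_rounded"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major (mode 0x01) .bed supported")
    data = raw[3:]
    if data.size != m * bytes_per_snp:
        raise ValueError(
            f"{bed_path}: data block is {data.size} bytes, expected "
            f"{m} SNPs × {bytes_per_snp} bytes for {n} individuals"
        )
    packed = data.reshape(m, bytes_per_snp)

    # split into 2-bit fields (M × 4B), translate PLINK codes -> counts of A2
    fields = np.empty((m, 4 * bytes_per_snp), dtype=np.uint8)
    fields[:, 0::4] = packed & 3
    fields[:, 1::4] = (packed >> 2) & 3
    fields[:, 2::4] = (packed >> 4) & 3
    fields[:, 3::4] = (packed >> 6) & 3
    fields = fields[:, :n]
    missing = fields == _PLINK_MISSING
    # 00->0, 10->1, 11->2
    codes = np.zeros_like(fields)
    codes[fields == 0b10] = 1
    codes[fields == 0b11] = 2

    if missing.any():
        if missing_policy == "error":
            i, j = np.argwhere(missing)[0]  # SNP i, individual j
            raise MissingGenotypeError(
                f"missing genotype at SNP {bim['snp_id'].iloc[i]!r} (index {i}), "
                f"individual {fam['iid'].iloc[j]!r} (index {j})"
            )
        for i in np.flatnonzero(missing.any(axis=1)):
            obs = codes[i, ~missing[i]]
            fill = int(np.rint(obs.mean())) if obs.size else 0
            codes[i, missing[i]] = fill

    vmap = VariantMap(
        chromosome=bim["chrom"].to_numpy(),
        position_bp=bim["bp"].to_numpy(),
        snp_id=bim["snp_id"].to_numpy(dtype=object),
    )
    return pack_genotypes(
        codes.T, variant_map=vmap,
        individual_ids=fam["iid"].to_numpy(dtype=object),
    )


def write_plink_bed(store: PackedGenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam readable by :func:`read_plink_bed`.

    Alleles are written as A1='A', A2='B'; the store counts A2, so internal
    codes 0/1/2 become PLINK bit codes 00/10/11.
    """
    if store.n_snps == 0:
        raise ValueError("refusing to write a .bed file with zero SNPs")
    prefix = str(prefix)
    codes = store.to_matrix()  # N×M
    # translate to PLINK fields: 0->00, 1->10, 2->11
    plink = np.array([0b00, 0b10, 0b11], dtype=np.uint8)[codes].T  # M×N
    n, m = store.n_individuals, store.n_snps
    bytes_per_snp = (n + 3) // 4
    cm = np.zeros((m, 4 * bytes_per_snp), dtype=np.uint8)
    cm[:, :n] = plink
    out = (
        cm[:, 0::4] | (cm[:, 1::4] << 2) | (cm[:, 2::4] << 4) | (cm[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_SNP_MAJOR]))
        fh.write(out.tobytes())

    vm = store.variant_map
    with open(prefix + ".bim", "w") as fh:
        for i in range(m):
            fh.write(
                f"{vm.chromosome[i]}\t{vm.snp_id[i]}\t0\t{vm.position_bp[i]}\tA\tB\n"
            )
    ids = (
        store.individual_ids
        if store.individual_ids is not None
        else [f"id{j}" for j in range(n)]
    )
    with open(prefix + ".fam", "w") as fh:
        for j in range(n):
            fh.write(f"0\t{ids[j]}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# weighted statistics and cross-products
# ---------------------------------------------------------------------------

def _check_weights(weights: np.ndarray, n: int) -> np.ndarray:
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    if np.any(weights <= 0):
        raise ValueError("record weights must be strictly positive")
    return weights


def snp_weighted_mean(
    store: PackedGenotypeMatrix, snp_index: int, weights: np.ndarray
) -> float:
    """x̄ᵢ = 1'R⁻¹x̃ᵢ / 1'R⁻¹1 with R⁻¹ = diag(weights)."""
    weights = _check_weights(weights, store.n_individuals)
    x = store.column(snp_index).astype(np.float64)
    return float(weights @ x / weights.sum())


def compute_snp_stats(store: PackedGenotypeMatrix, weights: np.ndarray) -> SnpStats:
    """One pass over all SNPs caching x̄ᵢ and x̃ᵢ'R⁻¹x̃ᵢ for the sampler."""
    weights = _check_weights(weights, store.n_individuals)
    sw = float(weights.sum())
    means = np.empty(store.n_snps)
    ssq = np.empty(store.n_snps)
    # chunked to bound the unpacked footprint on large M
    chunk = max(1, int(4e6) // max(store.n_individuals, 1))
    for lo in range(0, store.n_snps, chunk):
        hi = min(lo + chunk, store.n_snps)
        sub = PackedGenotypeMatrix(
            n_individuals=store.n_individuals,
            n_snps=hi - lo,
            packed=store.packed[lo:hi],
            variant_map=VariantMap(
                store.variant_map.chromosome[lo:hi],
                store.variant_map.position_bp[lo:hi],
                store.variant_map.snp_id[lo:hi],
            ),
        )
        x = sub.to_matrix().astype(np.float64)  # N×chunk
        means[lo:hi] = weights @ x / sw
        ssq[lo:hi] = weights @ (x * x)
    return SnpStats(weighted_mean=means, raw_weighted_ssq=ssq, sum_weights=sw)


def snp_cross_products(
    store: PackedGenotypeMatrix,
    snp_index: int,
    y_star: np.ndarray,
    weights: np.ndarray,
    stats: SnpStats,
    sum_weights: float | None = None,
) -> tuple[float, float]:
    """Centered cross-products from uncentered codes.

    rhs  = x'R⁻¹y*  = x̃'R⁻¹y* − x̄·(1'R⁻¹y*)
    diag = x'R⁻¹x   = x̃'R⁻¹x̃  − (1'R⁻¹1)·x̄²

    where x = x̃ − x̄·1 is the (weighted-mean) centered genotype.
    """
    weights = _check_weights(weights, store.n_individuals)
    y_star = np.asarray(y_star, dtype=np.float64)
    if y_star.shape != (store.n_individuals,):
        raise ValueError("y_star length must equal the number of individuals")
    if sum_weights is None:
        sum_weights = stats.sum_weights
    x = store.column(snp_index).astype(np.float64)
    wy = weights * y_star
    xbar = stats.weighted_mean[snp_index]
    rhs = float(x @ wy - xbar * wy.sum())
    diag = float(stats.raw_weighted_ssq[snp_index] - sum_weights * xbar**2)
    return rhs, diag


def maf_filter(store: PackedGenotypeMatrix, min_maf: float) -> np.ndarray:
    """Indices of SNPs with (unweighted) minor allele frequency >= min_maf."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    p = store.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    return np.flatnonzero(maf >= min_maf)
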