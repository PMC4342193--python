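"""Deterministic synthetic genotype/phenotype generator.

Emulates the statistical structure the analysis methods assume: per-variant
Hardy-Weinberg genotype proportions (p^2, 2pq, q^2) at minor-allele
frequencies drawn uniformly from [maf_min, 0.5], optional inbreeding
(heterozygote frequency 2pq(1-F)), block-wise LD generated by copying a
latent haplotype pair with per-site mutation noise calibrated to a target
within-block r^2, case/control phenotypes with planted per-allele odds
ratios, and uniform missingness.  One seeded 64-bit generator drives all
draws in a fixed order, so a spec + seed pair reproduces the fileset
byte-for-byte.

It does not emulate coalescent genealogy, recombination-rate variation,
allele-frequency spectra, population structure, or genotyping-error modes
of real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import Dataset, PackedGenotypeMatrix, SampleRecord, VariantRecord

__all__ = ["SimSpec", "simulate"]


@dataclass(frozen=True)
class SimSpec:
    """Specification of a synthetic dataset.

    ``ld_blocks`` lists (n_variants, target_r2) groups placed at the start
    of the variant list; ``effects`` lists (variant_index, allelic odds
    ratio) pairs entering a logistic phenotype model; ``inbreeding`` is
    Wright's F (0 = Hardy-Weinberg equilibrium).
    """

    n_samples: int
    n_variants: int
    maf_min: float = 0.05
    missing_rate: float = 0.0
    inbreeding: float = 0.0
    ld_blocks: tuple = ()
    case_fraction: float = 0.5
    effects: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("need at least one sample and one variant")
        for rate, name in (
            (self.missing_rate, "missing_rate"),
            (self.case_fraction, "case_fraction"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding F must be in [0, 1]")
        if sum(size for size, _ in self.ld_blocks) > self.n_variants:
            raise ValueError("LD blocks exceed the variant count")
        for _, r2 in self.ld_blocks:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"infeasible r^2 target {r2}")


def _hwe_genotypes(rng, p: float, n: int, f: float) -> np.ndarray:
    """Draw n genotypes with minor-allele frequency p and inbreeding f."""
    p_hom1 = p * p + f * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - f)
    u = rng.random(n)
    return np.where(u < p_hom1, 2, np.where(u < p_hom1 + p_het, 1, 0)).astype(np.int8)


def _ld_block(rng, p: float, size: int, r2: float, n: int) -> np.ndarray:
    """Correlated genotype block: latent haplotype pair + mutation noise.

    Each haplotype copy carries a latent allele z ~ Bernoulli(p); every
    site copies z with probability 1 - eps and redraws Bernoulli(p)
    otherwise, giving pairwise haplotype correlation (1 - eps)^2 and
    genotype r^2 of (1 - eps)^4; eps = 1 - r2^(1/4) hits the target while
    keeping every site marginally Bernoulli(p) (hence at HWE).
    """
    eps = 1.0 - r2**0.25
    block = np.empty((size, n), dtype=np.int8)
    hap = np.empty((2, size, n), dtype=np.int8)
    for copy in range(2):
        z = (rng.random(n) < p).astype(np.int8)
        keep = rng.random((size, n)) >= eps
        fresh = (rng.random((size, n)) < p).astype(np.int8)
        hap[copy] = np.where(keep, z[None, :], fresh)
    block[:] = hap[0] + hap[1]
    return block


def simulate(spec: SimSpec) -> tuple[Dataset, dict]:
    """Generate a dataset per ``spec``; returns (dataset, truth record).

    The truth record stores every latent parameter: per-variant MAFs,
    block memberships and noise rates, effect coefficients, and each
    sample's case probability.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants
    mafs = rng.uniform(spec.maf_min, 0.5, size=m)
    g = np.empty((m, n), dtype=np.int8)
    block_id = np.full(m, -1, dtype=np.int64)
    block_eps = []
    j = 0
    for bi, (size, r2) in enumerate(spec.ld_blocks):
        p = float(mafs[j])
        mafs[j : j + size] = p  # one frequency per block
        g[j : j + size] = _ld_block(rng, p, size, r2, n)
        block_id[j : j + size] = bi
        block_eps.append(1.0 - r2**0.25)
        j += size
    for k in range(j, m):
        g[k] = _hwe_genotypes(rng, float(mafs[k]), n, spec.inbreeding)

    # phenotype: logistic model on centred dosages of the effect variants
    if 0.0 < spec.case_fraction < 1.0:
        base = math.log(spec.case_fraction / (1.0 - spec.case_fraction))
    else:
        base = math.inf if spec.case_fraction >= 1.0 else -math.inf
    eta = np.full(n, base)
    betas = {}
    for vidx, odds in spec.effects:
        beta = math.log(odds)
        betas[int(vidx)] = beta
        eta = eta + beta * (g[vidx] - 2.0 * mafs[vidx])
    p_case = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng.random(n) < p_case

    if spec.missing_rate > 0.0:
        miss = rng.random((m, n)) < spec.missing_rate
        g = np.where(miss, np.int8(-1), g)

    samples = [
        SampleRecord(
            fid=f"F{i:04d}", iid=f"I{i:04d}", sex=0,
            phenotype=2.0 if is_case[i] else 1.0,
        )
        for i in range(n)
    ]
    variants = [
        VariantRecord(
            chrom="1", vid=f"var{k:05d}", cm=0.0, bp=1 + 1000 * k, a1="A", a2="B"
        )
        for k in range(m)
    ]
    dataset = Dataset(samples, variants, PackedGenotypeMatrix.from_dosages(g))
    truth = {
        "mafs": mafs.tolist(),
        "block_id": block_id.tolist(),
        "block_eps": block_eps,
        "betas": betas,
        "case_probability": p_case.tolist(),
        "inbreeding": spec.inbreeding,
        "seed": spec.seed,
    }
    return dataset, truth
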