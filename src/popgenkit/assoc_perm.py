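"""Case/control association statistics and max(T) permutation testing.

Per-variant contingency tables are filled with masked population counts:
each variant keeps 1-bit-per-sample indicators of its genotype classes,
and a permutation is just a new case bit-mask ANDed against them.  This
makes re-testing every variant under thousands of relabelings cheap
(the PERMORY-style approach) and keeps Fisher's exact test practical
inside permutation loops.

Family-wise error is controlled by max(T): each observed statistic is
compared against the permutation distribution of the per-permutation
*maximum* statistic (minimum p-value for the Fisher test).  Empirical
p-values use the (k + 1) / (R + 1) estimator, so they are never zero and
unbiased under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bitkernels import pack_bits, popcount_words
from .exact_tests import fisher_2x2
from .genotype_io import Dataset

__all__ = [
    "PhenotypeVector",
    "PermutationReport",
    "allelic_counts",
    "trend_statistic",
    "max_t",
]


@dataclass(frozen=True)
class PhenotypeVector:
    """Case/control status per sample: 1 = case, 0 = control, -1 = missing."""

    status: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.status, dtype=np.int8)
        if not np.isin(s, (-1, 0, 1)).all():
            raise ValueError("status must be -1 (missing), 0 (control) or 1 (case)")
        object.__setattr__(self, "status", s)

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "PhenotypeVector":
        """Decode PLINK .fam phenotypes (1 = control, 2 = case, else missing)."""
        s = np.full(dataset.n_samples, -1, dtype=np.int8)
        for i, rec in enumerate(dataset.samples):
            if rec.phenotype == 2:
                s[i] = 1
            elif rec.phenotype == 1:
                s[i] = 0
        return cls(s)

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    @property
    def case_mask(self) -> np.ndarray:
        return pack_bits(self.status == 1)


def allelic_counts(row_dosages, case_status) -> np.ndarray:
    """2x2 allele-count table [[case_a1, case_a2], [ctrl_a1, ctrl_a2]].

    Counts are masked popcounts over the variant's genotype-class bit
    vectors; genotypes missing at this variant are excluded.
    """
    d = np.asarray(row_dosages, dtype=np.int8)
    s = np.asarray(case_status, dtype=np.int8)
    if d.size != s.size:
        raise ValueError("mask length must match samples")
    het = pack_bits(d == 1)
    hom1 = pack_bits(d == 2)
    nm = pack_bits(d >= 0)
    out = np.empty((2, 2), dtype=np.int64)
    for row, grp in enumerate((1, 0)):
        gmask = pack_bits(s == grp)
        a1 = 2 * int(popcount_words(hom1 & gmask).sum()) + int(
            popcount_words(het & gmask).sum()
        )
        tot = 2 * int(popcount_words(nm & gmask).sum())
        out[row] = (a1, tot - a1)
    return out


def trend_statistic(table_2x3) -> float:
    """Cochran-Armitage trend chi-square with weights (0, 1, 2).

    ``table_2x3`` rows are (case, control) genotype counts ordered by
    dosage.  Returns NaN for degenerate margins (no cases, no controls,
    or no genotype variation).
    """
    t = np.asarray(table_2x3, dtype=np.float64)
    r = t[0]
    ncol = t.sum(axis=0)
    big_r, big_n = t[0].sum(), t.sum()
    w = np.array([0.0, 1.0, 2.0])
    if big_r == 0 or big_r == big_n or big_n == 0:
        return float("nan")
    num = big_n * (w @ r) - big_r * (w @ ncol)
    var = big_r * (big_n - big_r) * (big_n * (w**2 @ ncol) - (w @ ncol) ** 2)
    if var <= 0:
        return float("nan")
    return float(big_n * num * num / var)


def _allelic_chi2(case_a1, case_tot, ctrl_a1, ctrl_tot):
    """Vectorized 1-df allele-count chi-square."""
    a, b = case_a1, case_tot - case_a1
    c, d = ctrl_a1, ctrl_tot - ctrl_a1
    n = case_tot + ctrl_tot
    r1, r2 = a + c, b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / (case_tot * ctrl_tot * r1 * r2)
    return np.where((case_tot > 0) & (ctrl_tot > 0) & (r1 > 0) & (r2 > 0), stat, np.nan)


@dataclass(frozen=True)
class PermutationReport:
    """Observed statistics with pointwise and max(T)-corrected empirical p."""

    vids: list[str]
    statistic: np.ndarray
    p_pointwise: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    seed: int
    test: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vid": self.vids,
                "stat": self.statistic,
                "emp1": self.p_pointwise,
                "emp2": self.p_corrected,
            }
        )


class _BitCounter:
    """Per-variant genotype-class bit vectors with masked-count evaluation."""

    def __init__(self, g: np.ndarray, phen_present: np.ndarray):
        m, n = g.shape
        self.het = np.stack([pack_bits((g[j] == 1) & phen_present) for j in range(m)])
        self.hom1 = np.stack([pack_bits((g[j] == 2) & phen_present) for j in range(m)])
        self.nm = np.stack([pack_bits((g[j] >= 0) & phen_present) for j in range(m)])
        self.tot_het = popcount_words(self.het).sum(axis=1).astype(np.int64)
        self.tot_hom1 = popcount_words(self.hom1).sum(axis=1).astype(np.int64)
        self.tot_nm = popcount_words(self.nm).sum(axis=1).astype(np.int64)

    def case_counts(self, mask: np.ndarray):
        """Per-variant (case het, case hom1, case non-missing) counts."""
        het = popcount_words(self.het & mask).sum(axis=1).astype(np.int64)
        hom1 = popcount_words(self.hom1 & mask).sum(axis=1).astype(np.int64)
        nm = popcount_words(self.nm & mask).sum(axis=1).astype(np.int64)
        return het, hom1, nm


def _stats_for_mask(counter: _BitCounter, mask: np.ndarray, test: str) -> np.ndarray:
    het_ca, hom1_ca, nm_ca = counter.case_counts(mask)
    het_co = counter.tot_het - het_ca
    hom1_co = counter.tot_hom1 - hom1_ca
    nm_co = counter.tot_nm - nm_ca
    if test == "trend":
        out = np.empty(het_ca.size)
        tbl = np.empty((2, 3))
        for j in range(het_ca.size):
            tbl[0] = (nm_ca[j] - het_ca[j] - hom1_ca[j], het_ca[j], hom1_ca[j])
            tbl[1] = (nm_co[j] - het_co[j] - hom1_co[j], het_co[j], hom1_co[j])
            out[j] = trend_statistic(tbl)
        return out
    case_a1 = 2 * hom1_ca + het_ca
    ctrl_a1 = 2 * hom1_co + het_co
    if test == "allelic":
        return _allelic_chi2(case_a1, 2 * nm_ca, ctrl_a1, 2 * nm_co)
    if test == "fisher":
        out = np.empty(case_a1.size)
        for j in range(case_a1.size):
            tbl = (
                (int(case_a1[j]), int(2 * nm_ca[j] - case_a1[j])),
                (int(ctrl_a1[j]), int(2 * nm_co[j] - ctrl_a1[j])),
            )
            out[j] = fisher_2x2(tbl).p
        return out
    raise ValueError(f"unknown test {test!r}")


def max_t(
    dataset: Dataset,
    phenotype: PhenotypeVector,
    test: str = "trend",
    n_permutations: int = 1000,
    seed: int = 1,
) -> PermutationReport:
    """max(T) permutation association test with bit-parallel counting.

    Case labels are permuted among phenotyped samples (case count fixed)
    with a seeded generator; every variant's statistic is recomputed per
    permutation from masked popcounts.  Pointwise p for variant v is
    (1 + #{r : T_vr >= T_v}) / (R + 1); the corrected p replaces T_vr by
    the permutation's maximum statistic (minimum p for ``test="fisher"``),
    guaranteeing corrected >= pointwise.  Fully reproducible given seed.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    status = phenotype.status
    if status.size != dataset.n_samples:
        raise ValueError("phenotype length mismatch")
    present = status >= 0
    n_cases = int((status == 1).sum())
    n_phen = int(present.sum())
    if n_cases == 0 or n_cases == n_phen:
        raise ValueError("constant phenotype: need both cases and controls")

    g = dataset.genotypes.dosages()
    counter = _BitCounter(g, present)
    obs_mask = pack_bits(status == 1)
    obs = _stats_for_mask(counter, obs_mask, test)

    smaller_is_extreme = test == "fisher"
    # NaN statistics (degenerate variants) can never look extreme
    obs_cmp = np.where(np.isnan(obs), np.inf if smaller_is_extreme else -np.inf, obs)

    rng = np.random.default_rng(seed)
    phen_idx = np.nonzero(present)[0]
    m = g.shape[0]
    hits_point = np.zeros(m, dtype=np.int64)
    hits_max = np.zeros(m, dtype=np.int64)
    flags = np.zeros(dataset.n_samples, dtype=bool)
    for _ in range(n_permutations):
        perm = rng.permutation(phen_idx)  # Fisher-Yates shuffle of sample ids
        flags[:] = False
        flags[perm[:n_cases]] = True
        mask = pack_bits(flags)
        stat = _stats_for_mask(counter, mask, test)
        if smaller_is_extreme:
            stat = np.where(np.isnan(stat), np.inf, stat)
            hits_point += stat <= obs_cmp
            hits_max += stat.min() <= obs_cmp
        else:
            stat = np.where(np.isnan(stat), -np.inf, stat)
            hits_point += stat >= obs_cmp
            hits_max += stat.max() >= obs_cmp
    r = n_permutations
    return PermutationReport(
        vids=[v.vid for v in dataset.variants],
        statistic=obs,
        p_pointwise=(1 + hits_point) / (r + 1),
        p_corrected=(1 + hits_max) / (r + 1),
        n_permutations=r,
        seed=seed,
        test=test,
    )
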