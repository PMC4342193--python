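"""Linkage disequilibrium: correlations, pruning, D' CIs, haplotype blocks.

The genotype correlation r between two variants is computed over their
jointly non-missing samples from popcount-derived class counts and the
packed dot-product kernel; recoded dosages v = 1 - (minor dosage) take
values {-1, 0, +1} with missing contributing zero to the dot product.

D'-based pair classification follows the Gabriel et al. / Haploview
scheme: the diplotype-frequency MLE comes from the analytic solution of
Hill's cubic (log-likelihoods are compared only when several roots are in
the valid range), 90% confidence intervals for |D'| are read off a
101-point grid of relative likelihoods, and pairs are classified as
strong LD, historical recombination, or inconclusive.  A lossless fast
path classifies most "recombination" pairs from just a few of the 101
likelihoods by exploiting unimodality; haplotype blocks are then selected
greedily by descending base-pair span among contiguous windows whose
informative pairs are >19:1 strong-LD versus recombination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bitkernels import DotEncoding, dot_product_packed, encode_dot, pack_bits, popcount
from .genotype_io import Dataset

__all__ = [
    "LdPairStats",
    "DiplotypeMle",
    "DprimeCI",
    "HaploBlock",
    "GabrielThresholds",
    "pair_r",
    "r_matrix",
    "precompute_nomissing_moments",
    "indep_pairwise",
    "diplotype_counts",
    "diplotype_mle",
    "dprime_ci",
    "classify_pair_fast",
    "gabriel_blocks",
]


@dataclass(frozen=True)
class LdPairStats:
    """Moments of the recoded dosages over the jointly observed samples."""

    n_obs: int
    mean_v: float
    mean_w: float
    mean_v2: float
    mean_w2: float
    dot: int
    r: float

    @property
    def r2(self) -> float:
        return self.r * self.r


class _VariantBits:
    """Bit-packed per-variant indicators used by the LD kernels."""

    __slots__ = ("nm", "d0", "d2", "dot_enc", "n", "c0", "c2", "n_obs")

    def __init__(self, dosages: np.ndarray):
        d = np.asarray(dosages, dtype=np.int8)
        self.n = d.size
        self.nm = pack_bits(d >= 0)
        self.d0 = pack_bits(d == 0)
        self.d2 = pack_bits(d == 2)
        self.dot_enc: DotEncoding = encode_dot(d)
        self.c0 = popcount(self.d0)
        self.c2 = popcount(self.d2)
        self.n_obs = popcount(self.nm)

    @property
    def has_missing(self) -> bool:
        return self.n_obs != self.n


def _r_from_counts(
    n_obs: int, c0x: int, c2x: int, c0y: int, c2y: int, dot: int
) -> LdPairStats:
    if n_obs == 0:
        return LdPairStats(0, math.nan, math.nan, math.nan, math.nan, dot, math.nan)
    mean_v = (c0x - c2x) / n_obs
    mean_w = (c0y - c2y) / n_obs
    mean_v2 = (c0x + c2x) / n_obs
    mean_w2 = (c0y + c2y) / n_obs
    var_v = mean_v2 - mean_v * mean_v
    var_w = mean_w2 - mean_w * mean_w
    if var_v <= 0.0 or var_w <= 0.0:
        r = math.nan  # no variance over the intersection
    else:
        r = (dot / n_obs - mean_v * mean_w) / math.sqrt(var_v * var_w)
        r = max(-1.0, min(1.0, r))
    return LdPairStats(n_obs, mean_v, mean_w, mean_v2, mean_w2, dot, r)


def _pair_stats(bx: _VariantBits, by: _VariantBits) -> LdPairStats:
    dot = dot_product_packed(bx.dot_enc, by.dot_enc, bx.n)
    if not (bx.has_missing or by.has_missing):
        # no-missing fast path: per-variant counts are the intersection counts
        return _r_from_counts(bx.n, bx.c0, bx.c2, by.c0, by.c2, dot)
    n_obs = popcount(bx.nm & by.nm)
    c0x = popcount(bx.d0 & by.nm)
    c2x = popcount(bx.d2 & by.nm)
    c0y = popcount(by.d0 & bx.nm)
    c2y = popcount(by.d2 & bx.nm)
    return _r_from_counts(n_obs, c0x, c2x, c0y, c2y, dot)


def pair_r(row_x, row_y) -> LdPairStats:
    """Correlation between two variants' dosage rows (-1 = missing)."""
    x = np.asarray(row_x, dtype=np.int8)
    y = np.asarray(row_y, dtype=np.int8)
    if x.size != y.size:
        raise ValueError("rows must cover the same samples")
    return _pair_stats(_VariantBits(x), _VariantBits(y))


def precompute_nomissing_moments(dataset: Dataset):
    """Per-variant recoded-dosage means and second moments (no-missing path).

    Returns (mean, second_moment, has_missing); entries of variants with
    missing calls are NaN and fall back to the general per-pair path.
    """
    g = dataset.genotypes.dosages()
    m, n = g.shape
    c0 = (g == 0).sum(axis=1)
    c2 = (g == 2).sum(axis=1)
    has_missing = (g < 0).any(axis=1)
    mean = np.where(has_missing, np.nan, (c0 - c2) / n)
    m2 = np.where(has_missing, np.nan, (c0 + c2) / n)
    return mean, m2, has_missing


def r_matrix(dataset: Dataset) -> np.ndarray:
    """All-pairs variant correlation matrix (NaN where undefined)."""
    g = dataset.genotypes.dosages()
    bits = [_VariantBits(g[j]) for j in range(g.shape[0])]
    m = len(bits)
    out = np.ones((m, m))
    for i in range(m):
        out[i, i] = _pair_stats(bits[i], bits[i]).r
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = _pair_stats(bits[i], bits[j]).r
    return out


def indep_pairwise(
    dataset: Dataset,
    window_size: int,
    step: int,
    r2_threshold: float,
) -> tuple[list[str], list[str]]:
    """Window-based LD pruning with PLINK's --indep-pairwise semantics.

    Within each ``window_size``-variant window (sliding by ``step`` within
    a chromosome), while any surviving pair has r^2 above the threshold
    one member is removed: the one with smaller minor-allele frequency,
    ties removing the later-positioned variant.  Correlations are computed
    lazily and never against already-removed variants.  Returns
    (kept_ids, pruned_ids) in variant order.
    """
    if not (window_size > step >= 1):
        raise ValueError("require window_size > step >= 1")
    if not 0.0 < r2_threshold < 1.0:
        raise ValueError("r2 threshold must be in (0, 1)")
    g = dataset.genotypes.dosages()
    bits = [_VariantBits(g[j]) for j in range(g.shape[0])]
    maf = np.array(
        [
            min(f, 1.0 - f) if n_obs else 0.0
            for f, n_obs in (
                (
                    (2 * b.c2 + (b.n_obs - b.c0 - b.c2)) / (2 * b.n_obs)
                    if b.n_obs
                    else 0.0,
                    b.n_obs,
                )
                for b in bits
            )
        ]
    )
    alive = np.ones(len(bits), dtype=bool)
    r2_cache: dict[tuple[int, int], float] = {}

    def r2(i: int, j: int) -> float:
        key = (i, j)
        if key not in r2_cache:
            r = _pair_stats(bits[i], bits[j]).r
            r2_cache[key] = 0.0 if math.isnan(r) else r * r
        return r2_cache[key]

    # chromosome runs, in file order
    chroms: list[tuple[int, int]] = []
    start = 0
    for j in range(1, len(dataset.variants) + 1):
        if j == len(dataset.variants) or (
            dataset.variants[j].chrom != dataset.variants[start].chrom
        ):
            chroms.append((start, j))
            start = j
    for lo, hi in chroms:
        for wstart in range(lo, hi, step):
            widx = [j for j in range(wstart, min(wstart + window_size, hi))]
            changed = True
            while changed:
                changed = False
                for ai, i in enumerate(widx):
                    if not alive[i]:
                        continue
                    for j in widx[ai + 1 :]:
                        if not alive[j]:
                            continue
                        if r2(i, j) > r2_threshold:
                            # remove the lower-MAF member; tie -> later variant
                            victim = i if maf[i] < maf[j] else j
                            alive[victim] = False
                            changed = True
                            if victim == i:
                                break
            if wstart + window_size >= hi:
                break
    kept = [dataset.variants[j].vid for j in range(len(bits)) if alive[j]]
    pruned = [dataset.variants[j].vid for j in range(len(bits)) if not alive[j]]
    return kept, pruned


# ---------------------------------------------------------------------------
# D' estimation and Gabriel-style pair classification


def diplotype_counts(row_x, row_y) -> np.ndarray:
    """3x3 genotype-pair count table over jointly non-missing samples."""
    x = np.asarray(row_x, dtype=np.int64)
    y = np.asarray(row_y, dtype=np.int64)
    ok = (x >= 0) & (y >= 0)
    return np.bincount(3 * x[ok] + y[ok], minlength=9).reshape(3, 3)


@dataclass(frozen=True)
class DiplotypeMle:
    """Maximum-likelihood two-locus haplotype frequency solution."""

    p11: float
    loglik: float
    d: float
    dprime: float
    p_a: float
    p_b: float


def _real_cubic_roots(c0: float, c1: float, c2: float, c3: float) -> list[float]:
    """Real roots of c3 x^3 + c2 x^2 + c1 x + c0 (analytic, Cardano/trig)."""
    scale = max(abs(c0), abs(c1), abs(c2), abs(c3), 1e-300)
    if abs(c3) < 1e-12 * scale:
        if abs(c2) < 1e-12 * scale:
            if abs(c1) < 1e-300:
                return []
            return [-c0 / c1]
        disc = c1 * c1 - 4 * c2 * c0
        if disc < 0:
            return []
        s = math.sqrt(disc)
        return [(-c1 + s) / (2 * c2), (-c1 - s) / (2 * c2)]
    a, b, c = c2 / c3, c1 / c3, c0 / c3
    # depressed cubic t^3 + p t + q with x = t - a/3
    p = b - a * a / 3.0
    q = 2.0 * a**3 / 27.0 - a * b / 3.0 + c
    shift = -a / 3.0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    if disc > 0:
        s = math.sqrt(disc)
        u = math.copysign(abs(-q / 2.0 + s) ** (1.0 / 3.0), -q / 2.0 + s)
        v = math.copysign(abs(-q / 2.0 - s) ** (1.0 / 3.0), -q / 2.0 - s)
        return [u + v + shift]
    if p == 0.0:
        return [shift]
    m = 2.0 * math.sqrt(-p / 3.0)
    arg = max(-1.0, min(1.0, 3.0 * q / (p * m)))
    theta = math.acos(arg) / 3.0
    return [
        m * math.cos(theta) + shift,
        m * math.cos(theta - 2.0 * math.pi / 3.0) + shift,
        m * math.cos(theta - 4.0 * math.pi / 3.0) + shift,
    ]


def _hap_stats(counts: np.ndarray):
    """Unambiguous haplotype tallies and allele frequencies from a 3x3 table."""
    c = np.asarray(counts, dtype=np.int64)
    n = int(c.sum())
    if n == 0:
        raise ValueError("empty diplotype table")
    n_ab_hap = 2 * c[2, 2] + c[2, 1] + c[1, 2]  # minor-minor haplotypes
    n_a_only = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    n_b_only = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    n_none = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    ndh = int(c[1, 1])
    p_a = (2 * c[2].sum() + c[1].sum()) / (2 * n)
    p_b = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("variant monomorphic over the jointly observed samples")
    return n, int(n_ab_hap), int(n_a_only), int(n_b_only), int(n_none), ndh, p_a, p_b


def _loglik_p11(p11, p_a, p_b, n_ab, n_a, n_b, n_0, ndh) -> float:
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p_a - p_b + p11

    def term(cnt, p):
        if cnt == 0:
            return 0.0
        if p <= 0.0:
            return -math.inf
        return cnt * math.log(p)

    ll = (
        term(n_ab, p11)
        + term(n_a, p10)
        + term(n_b, p01)
        + term(n_0, p00)
        + term(ndh, p11 * p00 + p10 * p01)
    )
    return ll


def _mle_cubic_roots(n, n_ab, ndh, p_a, p_b) -> list[float]:
    """Roots of the EM stationarity cubic for p11 with margins fixed."""
    k00 = 1.0 - p_a - p_b
    # Q(p11) = p11*p00 + p10*p01 (quadratic); stationarity:
    # (2N p11 - n_ab) Q(p11) - ndh * p11 * p00 = 0
    q_c = [p_a * p_b, k00 - p_a - p_b, 2.0]  # ascending coefficients of Q
    lin = [-float(n_ab), 2.0 * n]
    cubic = [0.0, 0.0, 0.0, 0.0]
    for i, li in enumerate(lin):
        for j, qj in enumerate(q_c):
            cubic[i + j] += li * qj
    cubic[1] -= ndh * k00
    cubic[2] -= ndh * 1.0
    return _real_cubic_roots(*cubic)


def diplotype_mle(counts) -> DiplotypeMle:
    """MLE haplotype frequency, D and D' from a 3x3 genotype-pair table.

    The double-heterozygote cell is phase-ambiguous; with allele
    frequencies fixed at their MLEs the stationary points of the
    likelihood satisfy a cubic in the minor-minor haplotype frequency
    p11, solved analytically.  Log-likelihoods are compared only when
    several roots fall in the feasible range.
    """
    c = np.asarray(counts, dtype=np.int64)
    n, n_ab, n_a, n_b, n_0, ndh, p_a, p_b = _hap_stats(c)
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)

    if ndh == 0:
        cands = [n_ab / (2.0 * n)]
    else:
        eps = 1e-12
        cands = [r for r in _mle_cubic_roots(n, n_ab, ndh, p_a, p_b)
                 if lo - eps <= r <= hi + eps]
        if not cands:
            cands = []
    cands = [min(max(r, lo), hi) for r in cands] + [lo, hi]
    args = (p_a, p_b, n_ab, n_a, n_b, n_0, ndh)
    best = max(cands, key=lambda r: _loglik_p11(r, *args))
    ll = _loglik_p11(best, *args)
    d = best - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    dprime = d / dmax if dmax > 0 else 0.0
    return DiplotypeMle(p11=best, loglik=ll, d=d, dprime=dprime, p_a=p_a, p_b=p_b)


@dataclass(frozen=True)
class GabrielThresholds:
    """CI cutoffs for Gabriel-style pair classification."""

    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90


@dataclass(frozen=True)
class DprimeCI:
    """|D'| MLE with Wall-Pritchard 90% CI bounds and pair classification."""

    dprime_mle: float
    ci_low: float
    ci_high: float
    classification: str  # strong_LD | recombination | inconclusive


def _oriented_stats(counts: np.ndarray):
    """Flip the second locus if needed so the MLE D is non-negative."""
    c = np.asarray(counts, dtype=np.int64)
    mle = diplotype_mle(c)
    if mle.d < 0:
        c = c[:, ::-1].copy()
        mle = diplotype_mle(c)
    n, n_ab, n_a, n_b, n_0, ndh, p_a, p_b = _hap_stats(c)
    dmax = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    return c, mle, (p_a, p_b, n_ab, n_a, n_b, n_0, ndh), dmax


def _grid_loglik(args, p_a, p_b, dmax, k: int) -> float:
    p11 = p_a * p_b + (k / 100.0) * dmax
    return _loglik_p11(p11, *args)


def _classify(ci_low: float, ci_high: float, th: GabrielThresholds) -> str:
    if ci_high < th.recomb_high:
        return "recombination"
    if ci_low >= th.strong_low and ci_high >= th.strong_high:
        return "strong_LD"
    return "inconclusive"


def dprime_ci(counts, thresholds: GabrielThresholds | None = None) -> DprimeCI:
    """101-point Wall-Pritchard 90% confidence interval for |D'|.

    Relative likelihoods are evaluated at D' = 0, 0.01, ..., 1 (allele
    frequencies fixed at their MLEs); ci_low is the largest grid value
    with cdf <= 5% and ci_high the smallest with cdf >= 95%.
    """
    th = thresholds or GabrielThresholds()
    _, mle, args, dmax = _oriented_stats(counts)
    if dmax <= 0:
        raise ValueError("degenerate allele frequencies; D' undefined")
    p_a, p_b = args[0], args[1]
    ll = np.array([_grid_loglik(args, p_a, p_b, dmax, k) for k in range(101)])
    ll -= ll.max()
    lik = np.exp(ll)
    cdf = np.cumsum(lik) / lik.sum()
    below = np.nonzero(cdf <= 0.05)[0]
    ci_low = (below.max() / 100.0) if below.size else 0.0
    ci_high = int(np.nonzero(cdf >= 0.95)[0].min()) / 100.0
    return DprimeCI(
        dprime_mle=min(abs(mle.dprime), 1.0),
        ci_low=ci_low,
        ci_high=ci_high,
        classification=_classify(ci_low, ci_high, th),
    )


def classify_pair_fast(counts, thresholds: GabrielThresholds | None = None) -> str:
    """Pair classification identical to :func:`dprime_ci` but usually cheaper.

    When the grid likelihood is provably unimodal (a unique interior
    stationary point of Hill's cubic) with its peak left of D' = 0.90,
    monotonicity bounds the upper 11 grid likelihoods: establishing
    L(0.90) < L(peak)/209 proves they sum to under 5% of the total, so the
    pair is "recombination" after a couple of evaluations.  Anything not
    settled by the bound falls back to the full 101-point grid.
    """
    th = thresholds or GabrielThresholds()
    _, mle, args, dmax = _oriented_stats(counts)
    if dmax <= 0:
        raise ValueError("degenerate allele frequencies; D' undefined")
    p_a, p_b = args[0], args[1]
    n_ab, n_a, n_b, n_0, ndh = args[2:]
    n = (n_ab + n_a + n_b + n_0 + 2 * ndh) // 2
    p11_lo, p11_hi = p_a * p_b, p_a * p_b + dmax
    interior = [
        r
        for r in _mle_cubic_roots(n, n_ab, ndh, p_a, p_b)
        if p11_lo < r < p11_hi
    ]
    lik = lambda k: _grid_loglik(args, p_a, p_b, dmax, k)
    if len(interior) == 1:
        d_star = (interior[0] - p11_lo) / dmax
        l_star = _loglik_p11(interior[0], p_a, p_b, *args[2:])
        if l_star < max(lik(0), lik(100)):
            return dprime_ci(counts, th).classification  # interior minimum
    elif len(interior) == 0:
        d_star = 0.0 if lik(0) >= lik(100) else 1.0
    else:
        return dprime_ci(counts, th).classification  # multimodal: full grid
    if d_star < 0.895:
        k_star = min(max(int(round(d_star * 100.0)), 0), 89)
        l_ref = max(
            lik(k) for k in (k_star - 1, k_star, k_star + 1) if 0 <= k <= 89
        )
        if lik(90) <= l_ref - math.log(209.0) - 1e-9:
            return "recombination"
    return dprime_ci(counts, th).classification


@dataclass(frozen=True)
class HaploBlock:
    """A greedy Gabriel haplotype block (indices into the dataset variants)."""

    chrom: str
    first: int
    last: int
    bp_first: int
    bp_last: int

    @property
    def span_bp(self) -> int:
        return self.bp_last - self.bp_first


def gabriel_blocks(
    dataset: Dataset,
    max_span_kb: float = 200.0,
    maf_min: float = 0.05,
    thresholds: GabrielThresholds | None = None,
    use_skip_bound: bool = True,
) -> list[HaploBlock]:
    """Greedy Gabriel-style haplotype block estimation.

    Variants below ``maf_min`` are excluded first.  A candidate block is a
    contiguous run of (filtered) variants spanning at most ``max_span_kb``
    whose endpoint pair is strong-LD and whose informative pairs (strong
    or recombination) are more than 19:1 strong.  Candidates are chosen
    greedily by descending base-pair span (ties: leftmost), skipping
    overlaps.  ``use_skip_bound`` aborts a candidate as soon as the 19:1
    ratio is provably unreachable; it never changes the output.
    """
    th = thresholds or GabrielThresholds()
    g = dataset.genotypes.dosages()
    variants = dataset.variants
    for i in range(1, len(variants)):
        a, b = variants[i - 1], variants[i]
        if a.chrom == b.chrom and b.bp < a.bp:
            raise ValueError("variants must be sorted by (chrom, bp)")

    # MAF filter
    keep: list[int] = []
    for j in range(len(variants)):
        d = g[j]
        obs = int((d >= 0).sum())
        if obs == 0:
            continue
        f = float(d[d >= 0].sum()) / (2 * obs)
        if min(f, 1.0 - f) >= maf_min:
            keep.append(j)

    cls_cache: dict[tuple[int, int], str] = {}

    def classify(i: int, j: int) -> str:
        key = (i, j)
        if key not in cls_cache:
            try:
                cls_cache[key] = classify_pair_fast(
                    diplotype_counts(g[keep[i]], g[keep[j]]), th
                )
            except ValueError:
                cls_cache[key] = "inconclusive"
        return cls_cache[key]

    max_span = int(max_span_kb * 1000)
    # per-chromosome candidate windows
    candidates: list[tuple[int, int, int]] = []  # (span_bp, first, last)
    by_chrom: dict[str, list[int]] = {}
    for fi, j in enumerate(keep):
        by_chrom.setdefault(variants[j].chrom, []).append(fi)
    for fis in by_chrom.values():
        for ai in range(len(fis)):
            for bi in range(ai + 1, len(fis)):
                i, j = fis[ai], fis[bi]
                span = variants[keep[j]].bp - variants[keep[i]].bp
                if span > max_span:
                    break
                if classify(i, j) != "strong_LD":
                    continue
                if _window_passes(i, j, classify, use_skip_bound):
                    candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(len(keep), dtype=bool)
    blocks: list[HaploBlock] = []
    for span, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            HaploBlock(
                chrom=variants[keep[i]].chrom,
                first=keep[i],
                last=keep[j],
                bp_first=variants[keep[i]].bp,
                bp_last=variants[keep[j]].bp,
            )
        )
    blocks.sort(key=lambda b: (b.chrom, b.bp_first))
    return blocks


def _window_passes(i: int, j: int, classify, use_skip_bound: bool) -> bool:
    """Check the >19:1 strong:recombination rule over all pairs in [i, j]."""
    strong = recomb = 0
    remaining = (j - i + 1) * (j - i) // 2
    for a in range(i, j + 1):
        for b in range(a + 1, j + 1):
            cl = classify(a, b)
            remaining -= 1
            if cl == "strong_LD":
                strong += 1
            elif cl == "recombination":
                recomb += 1
            if use_skip_bound and strong + remaining <= 19 * recomb:
                return False  # 19:1 provably unreachable
    return strong > 19 * recomb
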