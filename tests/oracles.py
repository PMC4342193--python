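"""Independent reference implementations used to validate the fast paths.

Everything here is deliberately naive: per-element loops, exact rational
arithmetic (big integers / fractions), high-precision decimal summation,
and brute-force enumeration.  None of it shares code with the package's
optimized implementations.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np


# --- exact-test oracles -----------------------------------------------------

def hwe_weights(n_hom1: int, n_het: int, n_hom2: int) -> dict[int, int]:
    """Exact integer HWE weights 2^k * n! / ((n1-k)/2)! k! ((n2-k)/2)! ."""
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    n2 = 2 * n_hom2 + n_het
    rare = min(n1, n2)
    fac = math.factorial
    return {
        k: (1 << k) * fac(n) // (fac((n1 - k) // 2) * fac(k) * fac((n2 - k) // 2))
        for k in range(rare % 2, rare + 1, 2)
    }


def hwe_exact_fraction(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Two-sided HWE exact p by exact-rational full enumeration."""
    ws = hwe_weights(n_hom1, n_het, n_hom2)
    w_obs = ws[n_het]
    return Fraction(sum(w for w in ws.values() if w <= w_obs), sum(ws.values()))


def hwe_exact_decimal(n_hom1: int, n_het: int, n_hom2: int, prec: int = 40) -> Decimal:
    """Full-summation HWE p at ``prec`` decimal digits via ratio recurrence.

    Usable at sample sizes where exact factorials are impractical.
    """
    getcontext().prec = prec
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    n2 = 2 * n_hom2 + n_het
    rare = min(n1, n2)
    k0 = rare % 2
    lik = Decimal(1)
    liks = {k0: lik}
    for k in range(k0, rare - 1, 2):
        lik = lik * Decimal((n1 - k) * (n2 - k)) / Decimal((k + 1) * (k + 2))
        liks[k + 2] = lik
    l_obs = liks[n_het]
    num = sum(v for v in liks.values() if v <= l_obs)
    return num / sum(liks.values())


def fisher_2x2_fraction(table) -> Fraction:
    """Two-sided Fisher 2x2 p by exact hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    ws = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    w_obs = ws[a]
    return Fraction(sum(w for w in ws.values() if w <= w_obs), sum(ws.values()))


def fisher_2x3_fraction(table) -> Fraction:
    """Two-sided Fisher 2x3 p by exact enumeration of the whole lattice."""
    top, bot = table
    r1 = sum(top)
    c1, c2, c3 = (top[j] + bot[j] for j in range(3))
    w_obs = (
        math.comb(c1, top[0]) * math.comb(c2, top[1]) * math.comb(c3, top[2])
    )
    num = den = 0
    for a in range(0, min(r1, c1) + 1):
        wa = math.comb(c1, a)
        for b in range(max(0, r1 - a - c3), min(c2, r1 - a) + 1):
            w = wa * math.comb(c2, b) * math.comb(c3, r1 - a - b)
            den += w
            if w <= w_obs:
                num += w
    return Fraction(num, den)


def log_support_range(r1: int, c1: int, n: int) -> tuple[int, int]:
    """Brute-force log-likelihood enumeration of the 2^-53 support range."""
    r2 = n - r1
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    logw = {
        x: math.lgamma(r1 + 1)
        - math.lgamma(x + 1)
        - math.lgamma(r1 - x + 1)
        + math.lgamma(r2 + 1)
        - math.lgamma(c1 - x + 1)
        - math.lgamma(r2 - c1 + x + 1)
        for x in xs
    }
    mx = max(logw.values())
    total = mx + math.log(sum(math.exp(v - mx) for v in logw.values()))
    cut = total - 53 * math.log(2)
    sup = [x for x in xs if logw[x] >= cut]
    return min(sup), max(sup)


def agreeing_digits(approx: float, exact) -> int:
    """Leading significant digits on which ``approx`` matches ``exact``."""
    exact_f = float(exact)
    if approx == exact_f:
        return 17
    rel = abs(approx - exact_f) / abs(exact_f)
    return int(math.floor(-math.log10(rel))) if rel < 1 else 0


# --- kernel oracles ---------------------------------------------------------

def ibs_loop(a, b):
    """Scalar IBS0/IBS1/IBS2 loop over dosage vectors (-1 = missing)."""
    ibs0 = ibs1 = ibs2 = 0
    for x, y in zip(a, b):
        if x < 0 or y < 0:
            continue
        if x == y:
            ibs2 += 1
        elif abs(x - y) == 2:
            ibs0 += 1
        else:
            ibs1 += 1
    obs = 2 * (ibs0 + ibs1 + ibs2)
    sim = (0 * ibs0 + 1 * ibs1 + 2 * ibs2) / obs if obs else float("nan")
    return ibs0, ibs1, ibs2, sim


def dot_loop(x, y) -> int:
    """Naive sum of v_i * w_i with v = 1 - dosage, missing contributing 0."""
    tot = 0
    for a, b in zip(x, y):
        v = 0 if a < 0 else 1 - a
        w = 0 if b < 0 else 1 - b
        tot += v * w
    return tot


def r_naive(x, y) -> float:
    """Plain floating-point correlation over the jointly observed samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = (x >= 0) & (y >= 0)
    if ok.sum() == 0:
        return float("nan")
    v, w = 1.0 - x[ok], 1.0 - y[ok]
    sv, sw = v.std(), w.std()
    if sv == 0 or sw == 0:
        return float("nan")
    return float(((v - v.mean()) * (w - w.mean())).mean() / (sv * sw))


def grm_naive(g: np.ndarray, q: np.ndarray):
    """Direct per-genotype GRM: values and per-pair denominators."""
    m, n = g.shape
    vals = np.zeros((n, n))
    den = np.zeros((n, n), dtype=np.int64)
    for j in range(n):
        for k in range(n):
            s = 0.0
            cnt = 0
            for v in range(m):
                xj, xk = g[v, j], g[v, k]
                if xj < 0 or xk < 0:
                    continue
                s += (xj - 2 * q[v]) * (xk - 2 * q[v]) / (2 * q[v] * (1 - q[v]))
                cnt += 1
            vals[j, k] = s / cnt if cnt else np.nan
            den[j, k] = cnt
    return vals, den


def catt_oracle(table) -> float:
    """Textbook Cochran-Armitage trend statistic, weights (0, 1, 2)."""
    t = np.asarray(table, dtype=float)
    w = np.array([0.0, 1.0, 2.0])
    big_n = t.sum()
    big_r = t[0].sum()
    n_i = t.sum(axis=0)
    u = (w * (t[0] - big_r * n_i / big_n)).sum()
    var = (big_r / big_n) * (1 - big_r / big_n) * (
        (w**2 * n_i).sum() - (w * n_i).sum() ** 2 / big_n
    )
    return float(u * u / var) if var > 0 else float("nan")


def em_diplotype(counts, iters: int = 10000) -> float:
    """EM (gene-counting) estimate of the minor-minor haplotype frequency."""
    c = np.asarray(counts, dtype=np.int64)
    n = c.sum()
    n_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    n_a = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    n_b = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    n_0 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    ndh = c[1, 1]
    p_a = (2 * c[2].sum() + c[1].sum()) / (2 * n)
    p_b = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    p11 = p_a * p_b
    for _ in range(iters):
        p10, p01 = p_a - p11, p_b - p11
        p00 = 1 - p_a - p_b + p11
        cis = p11 * p00
        trans = p10 * p01
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        p11_new = (n_ab + ndh * w) / (2 * n)
        if abs(p11_new - p11) < 1e-15:
            p11 = p11_new
            break
        p11 = p11_new
    return float(p11)


def complete_linkage_heights(d: np.ndarray) -> list[float]:
    """Naive O(n^3) complete-linkage; returns the sorted merge heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def gabriel_blocks_bruteforce(dataset, max_span_kb, maf_min, thresholds):
    """Non-streaming Gabriel reference: classify every within-span pair with
    the full 101-point grid, enumerate all candidates, greedy by span."""
    from popgenkit.ld import diplotype_counts, dprime_ci

    g = dataset.genotypes.dosages()
    variants = dataset.variants
    keep = []
    for j in range(len(variants)):
        d = g[j]
        obs = int((d >= 0).sum())
        if obs == 0:
            continue
        f = float(d[d >= 0].sum()) / (2 * obs)
        if min(f, 1 - f) >= maf_min:
            keep.append(j)
    cls = {}

    def classify(i, j):
        if (i, j) not in cls:
            try:
                cls[i, j] = dprime_ci(
                    diplotype_counts(g[keep[i]], g[keep[j]]), thresholds
                ).classification
            except ValueError:
                cls[i, j] = "inconclusive"
        return cls[i, j]

    cands = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            vi, vj = variants[keep[i]], variants[keep[j]]
            if vi.chrom != vj.chrom:
                continue
            span = vj.bp - vi.bp
            if span > max_span_kb * 1000:
                continue
            if classify(i, j) != "strong_LD":
                continue
            strong = recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    cl = classify(a, b)
                    strong += cl == "strong_LD"
                    recomb += cl == "recombination"
            if strong > 19 * recomb:
                cands.append((span, i, j))
    cands.sort(key=lambda t: (-t[0], t[1]))
    taken = set()
    blocks = []
    for span, i, j in cands:
        if any(k in taken for k in range(i, j + 1)):
            continue
        taken.update(range(i, j + 1))
        blocks.append((variants[keep[i]].chrom, keep[i], keep[j]))
    return sorted(blocks)
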