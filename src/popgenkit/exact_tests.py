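"""Early-termination exact tests: Hardy-Weinberg, Fisher 2x2 and 2x3.

All three tests share one idea: the null likelihoods of the contingency
tables in a fixed-margin family are connected by simple adjacent-table
ratios (the large factorials cancel), and they decay super-geometrically
away from the most probable table.  Likelihoods are therefore accumulated
*relative* to the modal table, walking outward from the mode and stopping
as soon as new terms are too small to change any IEEE-754 double partial
sum.  This costs O(sqrt(n)) likelihood evaluations and constant memory,
with no loss of precision in the final p-value (agreement with full
high-precision enumeration to 10+ significant digits).

The two-sided p-value counts a table as "at least as extreme" when its
null likelihood is <= that of the observed table (ties included); the
mid-p variant subtracts half of the observed table's probability.

For the Hardy-Weinberg test the family is indexed by the heterozygote
count n12: given n diploids with n1 copies of A1 and n2 of A2, the
likelihood ratio between n12 = k+2 and n12 = k is
(n1 - k)(n2 - k) / ((k + 1)(k + 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExactTestResult",
    "HweInput",
    "hwe_ratio",
    "hwe_exact",
    "fisher_2x2",
    "fisher_2x3",
    "relative_likelihood_support",
]

_LN2_53 = 53.0 * math.log(2.0)
_TIE_EPS = 1e-9  # relative slack so exact likelihood ties are kept together


@dataclass(frozen=True)
class ExactTestResult:
    """Exact-test outcome.

    ``p`` is the two-sided tail probability, ``midp`` the mid-p adjusted
    value (p minus half the observed table's null probability), and
    ``obs_mass`` that observed-table probability itself.  ``n_terms``
    records how many family members the early-terminating walk visited.
    """

    p: float
    midp: float
    obs_mass: float
    n_terms: int

    def __post_init__(self):
        assert -1e-12 <= self.midp <= self.p <= 1.0 + 1e-12


@dataclass(frozen=True)
class HweInput:
    """Genotype counts for the Hardy-Weinberg exact test."""

    n_hom1: int
    n_het: int
    n_hom2: int

    def __post_init__(self):
        if min(self.n_hom1, self.n_het, self.n_hom2) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom1 + self.n_het + self.n_hom2

    @property
    def n1(self) -> int:
        return 2 * self.n_hom1 + self.n_het

    @property
    def n2(self) -> int:
        return 2 * self.n_hom2 + self.n_het


def hwe_ratio(k: int, n1: int, n2: int) -> float:
    """Likelihood ratio L(n12 = k + 2) / L(n12 = k) under HWE, fixed margins."""
    if k < 0 or (n1 - k) % 2 or (n2 - k) % 2 or k + 2 > min(n1, n2) + 2:
        raise ValueError(f"invalid heterozygote count {k} for margins ({n1}, {n2})")
    if n1 - k < 0 or n2 - k < 0:
        raise ValueError(f"heterozygote count {k} exceeds margins ({n1}, {n2})")
    return (n1 - k) * (n2 - k) / ((k + 1) * (k + 2))


def _family_pvalue(ratio, t_min: int, t_max: int, t_obs: int, t_hint: int):
    """Early-terminating two-tail walk over a log-concave likelihood family.

    ``ratio(t)`` = L(t+1)/L(t) must be decreasing in t.  Returns
    (p, midp, obs_mass, n_terms) with likelihoods accumulated relative to
    the modal table.
    """
    if not t_min <= t_obs <= t_max:
        raise ValueError("observed table outside the family range")
    visits = 0
    # locate the mode (ratio crosses 1)
    t = min(max(t_hint, t_min), t_max)
    while t < t_max and ratio(t) > 1.0:
        t += 1
        visits += 1
    while t > t_min and ratio(t - 1) < 1.0:
        t -= 1
        visits += 1
    mode = t

    # observed table's likelihood relative to the mode
    l_obs = 1.0
    if t_obs > mode:
        for s in range(mode, t_obs):
            l_obs *= ratio(s)
    elif t_obs < mode:
        for s in range(mode, t_obs, -1):
            l_obs /= ratio(s - 1)
    thresh = l_obs * (1.0 + _TIE_EPS)

    denom = 1.0
    numer = 1.0 if 1.0 <= thresh else 0.0
    for step in (-1, +1):
        lik = 1.0
        s = mode
        while (s > t_min) if step < 0 else (s < t_max):
            lik = lik / ratio(s - 1) if step < 0 else lik * ratio(s)
            s += step
            visits += 1
            if lik <= 0.0 or math.isinf(lik):
                break  # underflow: remaining tail mass is below double range
            new_denom = denom + lik
            in_tail = lik <= thresh  # at-least-as-extreme region of this tail
            new_numer = numer + lik if in_tail else numer
            obs_ahead = (t_obs < s) if step < 0 else (t_obs > s)
            # a tail is exhausted only once *both* partial sums stop moving;
            # the numerator can only saturate after the walk has entered the
            # extreme region, which may lie beyond the denominator's horizon
            if new_denom == denom and in_tail and new_numer == numer and not obs_ahead:
                break
            denom, numer = new_denom, new_numer
    p = min(1.0, numer / denom)
    obs_mass = l_obs / denom
    midp = p - 0.5 * obs_mass
    return p, midp, obs_mass, visits


def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> ExactTestResult:
    """Hardy-Weinberg exact test from genotype counts (two-sided, mid-p too).

    Sums the HWE null likelihoods of all heterozygote counts compatible
    with the observed allele counts, from the most probable count outward,
    in constant space with early termination.
    """
    hwe = HweInput(n_hom1, n_het, n_hom2)
    n, n1, n2 = hwe.n, hwe.n1, hwe.n2
    if n == 0:
        raise ValueError("empty genotype table")
    rare = min(n1, n2)
    k_min = rare % 2
    k_max = rare
    if k_max < k_min:  # rare == 0: single possible table
        return ExactTestResult(p=1.0, midp=0.5, obs_mass=1.0, n_terms=1)

    def ratio(t: int) -> float:
        k = k_min + 2 * t
        return (n1 - k) * (n2 - k) / ((k + 1) * (k + 2))

    t_max = (k_max - k_min) // 2
    # expected heterozygote count under HWE ~ rare * (2n - rare) / (2n)
    k_hint = int(rare * (2 * n - rare) / (2 * n))
    k_hint += (k_hint - k_min) % 2
    p, midp, obs_mass, visits = _family_pvalue(
        ratio, 0, t_max, (n_het - k_min) // 2, (k_hint - k_min) // 2
    )
    return ExactTestResult(p=p, midp=midp, obs_mass=obs_mass, n_terms=visits)


def _fisher_2x2_family(r1: int, r2: int, c1: int):
    """Upper-left-cell range and adjacent ratio for fixed 2x2 margins."""
    x_min = max(0, c1 - r2)
    x_max = min(r1, c1)

    def ratio(x: int) -> float:
        return (r1 - x) * (c1 - x) / ((x + 1) * (r2 - c1 + x + 1))

    return x_min, x_max, ratio


def fisher_2x2(table) -> ExactTestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Same early-termination machinery as :func:`hwe_exact` applied to the
    hypergeometric family with the table's margins.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty 2x2 table")
    x_min, x_max, ratio = _fisher_2x2_family(r1, r2, c1)
    if x_min == x_max:  # a zero margin: single possible table
        return ExactTestResult(p=1.0, midp=0.5, obs_mass=1.0, n_terms=1)
    hint = int((r1 + 1) * (c1 + 1) / (n + 2))
    p, midp, obs_mass, visits = _family_pvalue(
        lambda t: ratio(x_min + t), 0, x_max - x_min, a - x_min, hint - x_min
    )
    return ExactTestResult(p=p, midp=midp, obs_mass=obs_mass, n_terms=visits)


def relative_likelihood_support(
    top_row_sum: int, left_col_sum: int, grand_total: int
) -> tuple[int, int]:
    """Upper-left-cell values whose null probability is >= 2^-53.

    For the 2x2 family with the given margins, returns the smallest and
    largest upper-left cell values whose hypergeometric probability
    (likelihood normalized over the whole family, which sums to 1)
    reaches 2^-53.  Tables outside this range underflow out of a
    double-precision p-value denominator when summed naively.  Boundaries
    are located with log-space ratio recurrences and then confirmed with
    exact integer arithmetic.
    """
    r1, c1, n = top_row_sum, left_col_sum, grand_total
    r2 = n - r1
    if r1 < 0 or c1 < 0 or r2 < 0 or c1 > n:
        raise ValueError("impossible margins")
    x_min, x_max, ratio = _fisher_2x2_family(r1, r2, c1)
    if x_min == x_max:
        return x_min, x_max
    # cumulative log-likelihood profile via the adjacent-table recurrence
    logl = 0.0
    profile = [0.0]
    for x in range(x_min, x_max):
        logl += math.log(ratio(x))
        profile.append(logl)
    # normalize over the family: total weight is C(n, c1) (Vandermonde)
    pmax = max(profile)
    log_total = pmax + math.log(sum(math.exp(v - pmax) for v in profile))
    cut = log_total - _LN2_53
    lo = next(i for i, v in enumerate(profile) if v >= cut)
    hi = next(i for i in range(len(profile) - 1, -1, -1) if profile[i] >= cut)

    # exact integer confirmation at the float-located boundaries
    def weight(x: int) -> int:
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    total = math.comb(n, c1)

    def supported(x: int) -> bool:
        return x_min <= x <= x_max and weight(x) << 53 >= total

    lo_x, hi_x = x_min + lo, x_min + hi
    while not supported(lo_x):
        lo_x += 1
    while supported(lo_x - 1):
        lo_x -= 1
    while not supported(hi_x):
        hi_x -= 1
    while supported(hi_x + 1):
        hi_x += 1
    return lo_x, hi_x


def fisher_2x3(table) -> ExactTestResult:
    """Two-sided Fisher's exact test on a 2x3 count table.

    The family of tables with the observed margins is a two-parameter
    lattice (top-row cells a, b free).  Work is restricted to (i) the
    elliptical region of tables whose likelihood, relative to the modal
    table, exceeds 2^-53 (the p-value denominator) and (ii) the annulus of
    tables with likelihood within a factor 2^53 below the observed table's
    (the numerator); rows lying entirely at-or-below the observed
    likelihood are added in one step using the identity that a "row" of
    2x3 likelihoods sums to a single 2x2 table likelihood.
    """
    (a0, b0, c0), (d0, e0, f0) = table
    cells = (a0, b0, c0, d0, e0, f0)
    if min(cells) < 0:
        raise ValueError("cells must be non-negative")
    r1 = a0 + b0 + c0
    r2 = d0 + e0 + f0
    n = r1 + r2
    if n == 0:
        raise ValueError("empty 2x3 table")
    col = (a0 + d0, b0 + e0, c0 + f0)
    # degenerate margins: drop empty columns and fall back to 2x2 / trivial
    if 0 in col:
        keep = [j for j in range(3) if col[j] > 0]
        if len(keep) <= 1 or r1 == 0 or r2 == 0:
            return ExactTestResult(p=1.0, midp=0.5, obs_mass=1.0, n_terms=1)
        top = [(a0, b0, c0)[j] for j in keep]
        bot = [(d0, e0, f0)[j] for j in keep]
        return fisher_2x2((top, bot))
    if r1 == 0 or r2 == 0:
        return ExactTestResult(p=1.0, midp=0.5, obs_mass=1.0, n_terms=1)
    c1, c2, c3 = col

    # log-factorial table built by recurrence (no factorials, no lgamma)
    lf = np.zeros(n + 1)
    np.cumsum(np.log(np.arange(1, n + 1)), out=lf[1:])

    def logl(a: int, b: int) -> float:
        c = r1 - a - b
        return -(lf[a] + lf[c1 - a] + lf[b] + lf[c2 - b] + lf[c] + lf[c3 - c])

    def b_range(a: int) -> tuple[int, int]:
        return max(0, r1 - a - c3), min(c2, r1 - a)

    a_lo, a_hi = max(0, r1 - c2 - c3), min(c1, r1)

    def row_apex(a: int) -> int:
        bmin, bmax = b_range(a)
        b = min(max(int(round((r1 - a) * c2 / (c2 + c3))), bmin), bmax)
        while b < bmax and logl(a, b + 1) > logl(a, b):
            b += 1
        while b > bmin and logl(a, b - 1) > logl(a, b):
            b -= 1
        return b

    # global mode by hill climb from the independence expectation
    a = min(max(int(round(r1 * c1 / n)), a_lo), a_hi)
    b = row_apex(a)
    cur = logl(a, b)
    while True:
        best = (cur, a, b)
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)):
            aa, bb = a + da, b + db
            if a_lo <= aa <= a_hi:
                bmin, bmax = b_range(aa)
                if bmin <= bb <= bmax:
                    v = logl(aa, bb)
                    if v > best[0]:
                        best = (v, aa, bb)
        if best[1] == a and best[2] == b:
            break
        cur, a, b = best
    l_max = cur
    l_obs = logl(a0, b0)
    tie = 1e-9
    num_floor = l_obs - _LN2_53 - 5.0  # numerator annulus lower edge (+ slack)
    den_floor = l_max - _LN2_53
    floor_all = min(num_floor, den_floor)

    # collapsed row weight: sum over b of L(a, b) = 2x2 likelihood of (a | r1, c1)
    def log_row(a: int) -> float:
        return -(lf[a] + lf[c1 - a] + lf[r1 - a] + lf[c2 + c3 - r1 + a]) + (
            lf[c2 + c3] - lf[c2] - lf[c3]
        )

    s_den = 0.0  # in units of exp(l_max)
    s_num = 0.0  # in units of exp(l_obs)
    visits = 0
    for ai in range(a_lo, a_hi + 1):
        lr = log_row(ai)
        if lr < floor_all:  # every term in this row is below both regions
            continue
        bm = row_apex(ai)
        row_max = logl(ai, bm)
        whole_row_extreme = row_max <= l_obs + tie
        if whole_row_extreme:
            s_num += math.exp(lr - l_obs)
        # walk b outward from the row apex until below every active region
        for step in (-1, +1):
            bb = bm if step == +1 else bm - 1
            bmin, bmax = b_range(ai)
            while bmin <= bb <= bmax:
                v = logl(ai, bb)
                visits += 1
                if v < floor_all:
                    break
                if v > den_floor:
                    s_den += math.exp(v - l_max)
                if not whole_row_extreme and v <= l_obs + tie and v >= num_floor:
                    s_num += math.exp(v - l_obs)
                bb += step
    # p = sum(extreme L) / sum(all L), both relative to the modal table
    log_p = (l_obs - l_max) + math.log(s_num) - math.log(s_den)
    p = min(1.0, math.exp(log_p))
    obs_mass = math.exp(l_obs - l_max) / s_den
    midp = p - 0.5 * obs_mass
    return ExactTestResult(p=p, midp=midp, obs_mass=obs_mass, n_terms=visits)
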