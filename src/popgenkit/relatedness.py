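"""Sample-by-sample matrices: GRM via partial-sum lookup, IBS, clustering.

The GCTA genomic relationship matrix accumulates, for every sample pair
(j, k) and marker with minor-allele frequency q,

    (x_j - 2q)(x_k - 2q) / (2q(1 - q)),

where x is the minor-allele dosage; a pair's final entry divides by its
count of jointly non-missing markers (a missing call contributes zero and
decrements that denominator).  Per marker only seven genotype-pair cases
exist, so each case fits in 3 bits, twenty markers fit in one 64-bit word,
and the twenty per-marker increments of a block collapse into four lookups
in precomputed 2^15-entry partial-sum tables.

The IBS similarity matrix uses the XOR/AND popcount kernel, and the
complete-linkage clustering of its distance transform delegates to scipy's
O(n^2 log n) nearest-neighbor-chain implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bitkernels import encode_ibs, popcount_words
from .genotype_io import Dataset

__all__ = [
    "GrmIncrementSet",
    "GrmResult",
    "Dendrogram",
    "MISSING_CASE",
    "grm_increments",
    "encode_case_codes",
    "build_partial_sum_table",
    "grm",
    "ibs_matrix",
    "complete_linkage",
    "row_chunk_bounds",
]

#: 3-bit case code for "at least one genotype missing".
MISSING_CASE = 6

# unordered genotype-pair case codes, indexed by (dosage_x + 1, dosage_y + 1):
#   0 (0,0)  1 (0,1)  2 (0,2)  3 (1,1)  4 (1,2)  5 (2,2)  6 missing
_CASE_LUT = np.array(
    [
        [6, 6, 6, 6],  # x missing
        [6, 0, 1, 2],  # x = 0
        [6, 1, 3, 4],  # x = 1
        [6, 2, 4, 5],  # x = 2
    ],
    dtype=np.uint64,
)

# case code -> (x, y) minor-allele dosages (cases 0..5)
_CASE_XY = np.array([(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)])


@dataclass(frozen=True)
class GrmIncrementSet:
    """The per-marker GRM increments for the seven genotype-pair cases.

    ``f[c]`` is the increment of case c; the missing case (and the unused
    code 7) map to zero, with the denominator decremented separately.
    """

    q: float
    f: np.ndarray = field(repr=False)

    @classmethod
    def from_frequency(cls, q: float) -> "GrmIncrementSet":
        if not 0.0 < q < 1.0:
            raise ValueError(f"monomorphic variant (q={q}) must be excluded upstream")
        f = np.zeros(8)
        x = _CASE_XY[:, 0]
        y = _CASE_XY[:, 1]
        f[:6] = (x - 2 * q) * (y - 2 * q) / (2 * q * (1 - q))
        return cls(q=q, f=f)


def grm_increments(q: float) -> GrmIncrementSet:
    """Increment set for one marker with minor-allele frequency ``q``."""
    return GrmIncrementSet.from_frequency(q)


def encode_case_codes(dosages_x, dosages_y) -> np.ndarray:
    """Pack per-marker genotype-pair case codes, 20 3-bit codes per word.

    Bits 0-2 describe marker 0, ..., bits 57-59 marker 19 of each word.
    Inputs are minor-allele dosage vectors (-1 = missing); marker counts
    are padded to a multiple of 20 with the missing case (increment zero).
    """
    x = np.asarray(dosages_x, dtype=np.int8)
    y = np.asarray(dosages_y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    codes = _CASE_LUT[x + 1, y + 1]
    n = codes.size
    padded = -(-max(n, 1) // 20) * 20
    if padded != n:
        codes = np.concatenate(
            [codes, np.full(padded - n, MISSING_CASE, dtype=np.uint64)]
        )
    codes = codes.reshape(-1, 20)
    shifts = (np.uint64(3) * np.arange(20, dtype=np.uint64))[None, :]
    return np.bitwise_or.reduce(codes << shifts, axis=1)


def build_partial_sum_table(fs: np.ndarray) -> np.ndarray:
    """Partial-sum lookup table for a group of (up to) five markers.

    ``fs`` is a (5, 8) array of per-marker case increments.  Entry i of
    the returned 2^15 table equals f0(i&7) + f1((i>>3)&7) + ... summed
    left to right, so one lookup replaces five.
    """
    fs = np.asarray(fs, dtype=np.float64)
    if fs.shape != (5, 8):
        raise ValueError("expected increments for exactly 5 markers x 8 codes")
    idx = np.arange(1 << 15)
    table = fs[0][idx & 7].copy()
    for g in range(1, 5):
        table += fs[g][(idx >> (3 * g)) & 7]
    return table


@dataclass
class GrmResult:
    """Relationship values with per-pair non-missing denominators.

    For a full run, ``values`` and ``denominators`` are symmetric n x n;
    for a row chunk they hold rows ``row_start .. row_stop - 1``.
    """

    values: np.ndarray
    denominators: np.ndarray
    row_start: int = 0
    row_stop: int | None = None


def row_chunk_bounds(n: int, k: int, total: int) -> tuple[int, int]:
    """Row range [start, stop) of chunk k of ``total`` (k is 1-based)."""
    if not 1 <= k <= total:
        raise ValueError("chunk index out of range")
    return -(-n * (k - 1) // total), -(-n * k // total)


def _minor_frequencies(dosages: np.ndarray) -> np.ndarray:
    present = dosages >= 0
    obs = 2 * present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(present, dosages, 0).sum(axis=1) / obs
    return q


def grm(
    dataset: Dataset,
    row_chunk: tuple[int, int] | None = None,
    frequencies=None,
    gcta_diagonal: bool = False,
) -> GrmResult:
    """GCTA-style genomic relationship matrix via 3-bit partial-sum lookup.

    ``row_chunk=(k, K)`` computes only the k-th of K row bands (1-based);
    stacking the K bands reproduces the full-matrix run exactly.  Allele
    frequencies default to the sample a1 frequencies over non-missing
    calls; all variants must be polymorphic (0 < q < 1).

    With ``gcta_diagonal`` the diagonal uses GCTA's self-relationship form
    1 + (x^2 - (1+2q)x + 2q^2) / (2q(1-q)) instead of the squared-deviate
    increment.
    """
    g = dataset.genotypes.dosages()
    m, n = g.shape
    if m == 0 or n == 0:
        raise ValueError("empty dataset")
    q = (
        np.asarray(frequencies, dtype=np.float64)
        if frequencies is not None
        else _minor_frequencies(g)
    )
    if np.any(~(q > 0.0) | ~(q < 1.0)):
        bad = np.where(~((q > 0.0) & (q < 1.0)))[0]
        raise ValueError(
            f"monomorphic or all-missing variants reached the GRM kernel: {bad[:5]}"
        )
    row_start, row_stop = (0, n) if row_chunk is None else row_chunk_bounds(
        n, row_chunk[0], row_chunk[1]
    )
    rows = range(row_start, row_stop)
    acc = np.zeros((len(rows), n))

    shifts3 = (np.uint64(3) * np.arange(20, dtype=np.uint64))[:, None]
    mask15 = np.uint64(0x7FFF)
    for start in range(0, m, 20):
        gb = g[start : start + 20]
        nb = gb.shape[0]
        fs = np.zeros((20, 8))
        for i in range(nb):
            fs[i] = GrmIncrementSet.from_frequency(q[start + i]).f
        tables = [build_partial_sum_table(fs[5 * t : 5 * t + 5]) for t in range(4)]
        gb1 = gb.astype(np.int16) + 1
        if nb < 20:
            pad = np.zeros((20 - nb, n), dtype=np.int16)  # dosage -1 -> missing case
            gb1 = np.concatenate([gb1, pad], axis=0)
        for jj, j in enumerate(rows):
            codes = _CASE_LUT[gb1[:, j][:, None], gb1]  # (20, n)
            words = np.bitwise_or.reduce(codes << shifts3, axis=0)
            acc[jj] += tables[0][(words & mask15).astype(np.int64)]
            acc[jj] += tables[1][((words >> np.uint64(15)) & mask15).astype(np.int64)]
            acc[jj] += tables[2][((words >> np.uint64(30)) & mask15).astype(np.int64)]
            acc[jj] += tables[3][((words >> np.uint64(45)) & mask15).astype(np.int64)]

    present = (g >= 0).astype(np.float64)
    denom = present[:, row_start:row_stop].T @ present  # jointly non-missing counts
    denom = np.rint(denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, acc / denom, np.nan)

    if gcta_diagonal:
        for jj, j in enumerate(rows):
            xs = g[:, j].astype(np.float64)
            ok = xs >= 0
            num = xs[ok] ** 2 - (1 + 2 * q[ok]) * xs[ok] + 2 * q[ok] ** 2
            den = 2 * q[ok] * (1 - q[ok])
            values[jj, j] = 1.0 + np.sum(num / den) / ok.sum() if ok.any() else np.nan
    return GrmResult(values=values, denominators=denom, row_start=row_start,
                     row_stop=row_stop)


def ibs_matrix(dataset: Dataset, row_chunk: tuple[int, int] | None = None) -> np.ndarray:
    """Pairwise IBS similarity (obs - diff) / obs via the XOR/AND kernel.

    Entries for pairs with no jointly observed calls are NaN; diagonal
    entries are 1 where the sample has any observed call.
    """
    g = dataset.genotypes.dosages()
    m, n = g.shape
    encs = [encode_ibs(g[:, j]) for j in range(n)]
    a = np.stack([e.a_bits for e in encs]) if n else np.zeros((0, 0), dtype=np.uint64)
    msk = np.stack([e.mask_bits for e in encs]) if n else a
    row_start, row_stop = (0, n) if row_chunk is None else row_chunk_bounds(
        n, row_chunk[0], row_chunk[1]
    )
    out = np.empty((row_stop - row_start, n))
    for jj, j in enumerate(range(row_start, row_stop)):
        f = msk[j][None, :] & msk
        e = (a[j][None, :] ^ a) & f
        diff = popcount_words(e).sum(axis=1).astype(np.float64)
        obs = popcount_words(f).sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[jj] = np.where(obs > 0, (obs - diff) / obs, np.nan)
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge list: (cluster_a, cluster_b, height) triples.

    Original points are clusters 0..n-1; merge i creates cluster n+i
    (scipy convention).  Heights are non-decreasing.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


def complete_linkage(distances: np.ndarray) -> Dendrogram:
    """Complete-linkage hierarchy of a symmetric distance matrix.

    Merge heights equal the maximum inter-cluster pairwise distance
    (the farthest-point criterion); computed with scipy's
    nearest-neighbor-chain algorithm in O(n^2 log n).
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        return Dendrogram(merges=[], n_leaves=n)
    z = linkage(squareform(d, checks=False), method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(merges=merges, n_leaves=n)
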