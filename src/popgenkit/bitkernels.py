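"""Word-level bit-parallel primitives for packed genotype data.

All heavy per-genotype loops in this package reduce to a handful of
operations on 64-bit words holding 32 two-bit genotype codes each:

* :func:`popcount` -- number of set bits in a word vector,
* :func:`popcount2` -- sum of the 32 two-bit fields of each word,
* the XOR/AND identity-by-state kernel (:func:`ibs_counts`),
* the packed dot-product kernel (:func:`dot_product_packed`) feeding
  genotype correlations.

Genotype calls are represented internally as minor-allele dosages
``{0, 1, 2}`` with ``-1`` for missing.  The IBS kernel re-encodes calls so
that the Hamming weight of an XOR equals the dosage difference; the dot
kernel re-encodes so each per-sample product term ``1 - v*w`` fits in two
bits.  Both encodings are padded with neutral codes to a whole number of
960-call blocks, so block-at-a-time and whole-row evaluation agree exactly.

The population counts are pure-integer SWAR algorithms (no hardware
intrinsic required); being exact integer arithmetic, any bit-identical
vectorized formulation may be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BLOCK_CALLS",
    "IbsCounts",
    "IbsEncoding",
    "DotEncoding",
    "popcount",
    "popcount2",
    "pack_2bit",
    "encode_ibs",
    "encode_dot",
    "ibs_counts",
    "dot_product_packed",
    "genotype_counts",
]

#: IBS processing granularity in genotype calls (30 words of 32 calls).
BLOCK_CALLS = 960
_CALLS_PER_WORD = 32

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_EVEN = _M1  # 01 repeated: low bit of every 2-bit field
_ODD = np.uint64(0xAAAAAAAAAAAAAAAA)  # 10 repeated


def _as_words(bits) -> np.ndarray:
    w = np.asarray(bits, dtype=np.uint64)
    return np.atleast_1d(w)


def _popcount_words(w: np.ndarray) -> np.ndarray:
    """Per-word set-bit counts via the classic SWAR reduction."""
    x = w.astype(np.uint64, copy=True)
    x -= (x >> np.uint64(1)) & _M1
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


def _popcount2_words(w: np.ndarray) -> np.ndarray:
    """Per-word sums of the 32 two-bit fields (each field in 0..3)."""
    x = (w & _M2) + ((w >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


def popcount(bits) -> int:
    """Total number of set bits in a uint64 word vector."""
    return int(_popcount_words(_as_words(bits)).sum())


def popcount_words(bits) -> np.ndarray:
    """Per-word set-bit counts (uint64 in, uint64 out); vector form of popcount."""
    return _popcount_words(_as_words(bits))


def pack_bits(flags) -> np.ndarray:
    """Pack a boolean/0-1 vector into uint64 words, 64 flags per word.

    Flag i lands in bit (i mod 64) of word (i // 64); trailing pad bits
    are zero.
    """
    f = np.asarray(flags, dtype=bool)
    n_words = -(-max(f.size, 1) // 64)
    buf = np.zeros(n_words * 64, dtype=bool)
    buf[: f.size] = f
    return np.packbits(buf.reshape(-1, 8)[:, ::-1]).view("<u8").copy()


def popcount2(bits) -> int:
    """Sum of all 2-bit fields (values 0..3) of a uint64 word vector."""
    return int(_popcount2_words(_as_words(bits)).sum())


def pack_2bit(codes, pad_code: int = 0, block_calls: int = _CALLS_PER_WORD) -> np.ndarray:
    """Pack per-call 2-bit codes into uint64 words, low-order calls first.

    ``codes`` holds one value in 0..3 per call; the output is padded with
    ``pad_code`` to a multiple of ``block_calls`` calls (``block_calls``
    must itself be a multiple of 32).
    """
    if block_calls % _CALLS_PER_WORD:
        raise ValueError("block_calls must be a multiple of 32")
    codes = np.asarray(codes, dtype=np.uint64)
    n = codes.size
    padded = -(-max(n, 1) // block_calls) * block_calls
    if padded != n:
        codes = np.concatenate(
            [codes, np.full(padded - n, pad_code, dtype=np.uint64)]
        )
    codes = codes.reshape(-1, _CALLS_PER_WORD)
    shifts = (np.uint64(2) * np.arange(_CALLS_PER_WORD, dtype=np.uint64))[None, :]
    return np.bitwise_or.reduce(codes << shifts, axis=1)


@dataclass(frozen=True)
class IbsEncoding:
    """Two-bit re-encoding of one sample's genotype vector for the IBS kernel.

    ``a_bits`` maps dosage 0 -> 00, 1 -> 10, 2 -> 11 and missing -> 01 so
    that XOR Hamming weights reproduce |dosage differences|; ``mask_bits``
    is 11 where a call is present and 00 where missing (or padding).
    """

    a_bits: np.ndarray
    mask_bits: np.ndarray
    n_calls: int


@dataclass(frozen=True)
class DotEncoding:
    """Two-bit encoding for the packed dot-product kernel.

    Recoded term v = dosage - 1 in {-1, 0, +1}: one homozygote class -> 00,
    heterozygote or missing -> 01, the other homozygote -> 10.  Code 11
    never occurs.  Padding uses 01 (contributes zero to the dot product).
    """

    x_bits: np.ndarray
    n_calls: int


@dataclass(frozen=True)
class IbsCounts:
    """Accumulated IBS tallies: diff = sum |a_i - b_i|, obs = 2|I_{a,b}|."""

    diff: int
    obs: int
    ibs0: int
    ibs1: int
    ibs2: int

    @property
    def similarity(self) -> float:
        """(obs - diff) / obs; NaN when no overlapping calls exist."""
        if self.obs == 0:
            return float("nan")
        return (self.obs - self.diff) / self.obs


# dosage -1(missing),0,1,2  ->  IBS code 01, 00, 10, 11
_IBS_CODE = np.array([1, 0, 2, 3], dtype=np.uint64)
# dosage -1,0,1,2 -> dot code: het/missing 01, dosage0 hom 10, dosage2 hom 00
_DOT_CODE = np.array([1, 2, 1, 0], dtype=np.uint64)


def encode_ibs(dosages) -> IbsEncoding:
    """Build the IBS bit encoding for a dosage vector ({0,1,2}, -1 missing)."""
    d = np.asarray(dosages, dtype=np.int8)
    codes = _IBS_CODE[d + 1]
    mask = np.where(d >= 0, np.uint64(3), np.uint64(0))
    return IbsEncoding(
        a_bits=pack_2bit(codes, pad_code=1, block_calls=BLOCK_CALLS),
        mask_bits=pack_2bit(mask, pad_code=0, block_calls=BLOCK_CALLS),
        n_calls=d.size,
    )


def encode_dot(dosages) -> DotEncoding:
    """Build the dot-product bit encoding for a dosage vector."""
    d = np.asarray(dosages, dtype=np.int8)
    codes = _DOT_CODE[d + 1]
    return DotEncoding(x_bits=pack_2bit(codes, pad_code=1), n_calls=d.size)


def ibs_counts(enc_a: IbsEncoding, enc_b: IbsEncoding) -> IbsCounts:
    """XOR/AND identity-by-state kernel over two encoded samples.

    diff accumulates popcount((A XOR B) AND C AND D) and obs accumulates
    popcount(C AND D); the IBS similarity is (obs - diff) / obs.
    """
    if enc_a.a_bits.size != enc_b.a_bits.size:
        raise ValueError("encodings must have equal padded lengths")
    e = (enc_a.a_bits ^ enc_b.a_bits) & enc_a.mask_bits & enc_b.mask_bits
    f = enc_a.mask_bits & enc_b.mask_bits
    diff = popcount(e)
    obs = popcount(f)
    both = (e >> np.uint64(1)) & e & _EVEN  # 11 fields: dosage difference 2
    ibs0 = popcount(both)
    nonzero = ((e >> np.uint64(1)) | e) & _EVEN
    ibs1 = popcount(nonzero) - ibs0
    ibs2 = obs // 2 - ibs0 - ibs1
    return IbsCounts(diff=diff, obs=obs, ibs0=ibs0, ibs1=ibs1, ibs2=ibs2)


def dot_product_packed(enc_x: DotEncoding, enc_y: DotEncoding, n: int) -> int:
    """Sum of per-sample products v_i * w_i with v, w in {-1, 0, +1}.

    Evaluates, per 2-bit field, t = 1 - v*w in {0, 1, 2} via
    Z := (X OR Y) AND 0101...; t-fields := ((X XOR Y) AND (1010... - Z)) OR Z
    and returns #fields - popcount2(t-fields).  Padding fields are encoded
    as 01 (t = 1) so the result equals the sum over the first ``n`` calls.
    """
    x, y = enc_x.x_bits, enc_y.x_bits
    if x.size != y.size:
        raise ValueError("encodings must have equal padded lengths")
    z = (x | y) & _EVEN
    t = ((x ^ y) & (_ODD - z)) | z
    total_fields = x.size * _CALLS_PER_WORD
    return total_fields - popcount2(t)


def genotype_counts(packed_row: np.ndarray, n_samples: int) -> tuple[int, int, int, int]:
    """Tally (hom-a1, het, hom-a2, missing) calls of one packed variant row.

    ``packed_row`` uses the .bed byte dialect (00 hom-a1, 01 missing,
    10 het, 11 hom-a2, four calls per byte, first sample in the low bits).
    Pad calls beyond ``n_samples`` are excluded via a validity mask.
    """
    row = np.asarray(packed_row, dtype=np.uint8)
    n_words = -(-row.size // 8)
    buf = np.zeros(n_words * 8, dtype=np.uint8)
    buf[: row.size] = row
    w = buf.view("<u8")
    low = w & _EVEN
    high = (w >> np.uint64(1)) & _EVEN
    # validity: 1 at the low bit of each in-range call's field
    valid_codes = np.zeros(n_words * _CALLS_PER_WORD, dtype=np.uint64)
    valid_codes[:n_samples] = 1
    vmask = pack_2bit(valid_codes)
    vmask = np.resize(vmask, n_words)
    n_hom_a1 = popcount(~low & ~high & vmask)
    n_missing = popcount(low & ~high & vmask)
    n_het = popcount(high & ~low & vmask)
    n_hom_a2 = popcount(high & low & vmask)
    return n_hom_a1, n_het, n_hom_a2, n_missing
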