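"""PLINK 1 binary fileset I/O, lossy VCF import, and the packed genotype model.

The central container is :class:`PackedGenotypeMatrix`: a variant-major
store of 2-bit genotype codes using the standard .bed dialect

    ``00`` = homozygous a1,  ``01`` = missing,  ``10`` = heterozygous,
    ``11`` = homozygous a2,

four calls per byte with the first sample in the two lowest-order bits.
By convention a1 is the minor allele, so the decoded *dosage* of a call is
its a1-allele count (0, 1, 2; -1 for missing).  Pad bits beyond the last
sample are held at a fixed code (zero) and never reach any kernel.

VCF import is deliberately lossy, mirroring PLINK 1.9: phase is discarded;
at multiallelic sites either the variant is skipped (``biallelic_only``) or
only the most common alternate allele is retained with all other alternate
calls set missing; when genotype probabilities (GP) are present, a call is
kept only if its largest probability reaches ``hard_call_threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bitkernels import genotype_counts

__all__ = [
    "MISSING_PHENOTYPE",
    "BedFormatError",
    "VcfFormatError",
    "SampleRecord",
    "VariantRecord",
    "PackedGenotypeMatrix",
    "Dataset",
    "read_bed",
    "write_bed",
    "import_vcf",
    "allele_frequencies",
]

#: PLINK missing-phenotype sentinel.
MISSING_PHENOTYPE = -9.0

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_VARIANT_MAJOR = 0x01


class BedFormatError(ValueError):
    """Malformed .bed/.bim/.fam fileset."""


class VcfFormatError(ValueError):
    """Malformed or unusable VCF input."""


@dataclass
class SampleRecord:
    fid: str
    iid: str
    pid: str = "0"
    mid: str = "0"
    sex: int = 0  # 1 male, 2 female, 0 unknown
    phenotype: float = MISSING_PHENOTYPE

    @property
    def phenotype_missing(self) -> bool:
        return self.phenotype == MISSING_PHENOTYPE or math.isnan(self.phenotype)


@dataclass
class VariantRecord:
    chrom: str
    vid: str
    cm: float
    bp: int
    a1: str  # minor by convention
    a2: str  # major


# dosage -> 2-bit .bed code (dosage is the a1 count; -1 = missing)
_DOSAGE_TO_CODE = np.array([1, 3, 2, 0], dtype=np.uint8)  # index d+1
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)

_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 3]


class PackedGenotypeMatrix:
    """Variant-major 2-bit genotype matrix (one padded byte row per variant)."""

    def __init__(self, data: np.ndarray, n_samples: int):
        data = np.ascontiguousarray(data, dtype=np.uint8)
        if data.ndim != 2:
            raise ValueError("packed data must be 2-D (variants x bytes)")
        if data.shape[1] != -(-n_samples // 4):
            raise ValueError("row byte count must be ceil(n_samples / 4)")
        self.data = data
        self.n_samples = int(n_samples)
        self.n_variants = int(data.shape[0])
        self._zero_pad_bits()

    def _zero_pad_bits(self) -> None:
        rem = self.n_samples % 4
        if rem and self.data.shape[1]:
            keep = np.uint8((1 << (2 * rem)) - 1)
            self.data[:, -1] &= keep

    @classmethod
    def from_dosages(cls, dosages) -> "PackedGenotypeMatrix":
        """Pack an (n_variants, n_samples) a1-dosage matrix (-1 = missing)."""
        d = np.asarray(dosages, dtype=np.int8)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        m, n = d.shape
        if m == 0:
            return cls(np.zeros((0, -(-n // 4)), dtype=np.uint8), n_samples=n)
        codes = _DOSAGE_TO_CODE[d + 1]
        n_pad = -(-n // 4) * 4
        if n_pad != n:
            pad = np.zeros((m, n_pad - n), dtype=np.uint8)
            codes = np.concatenate([codes, pad], axis=1)
        codes = codes.reshape(m, -1, 4).astype(np.uint8)
        packed = (
            codes[:, :, 0]
            | (codes[:, :, 1] << 2)
            | (codes[:, :, 2] << 4)
            | (codes[:, :, 3] << 6)
        )
        return cls(packed, n_samples=n)

    def dosages(self) -> np.ndarray:
        """Decode to an (n_variants, n_samples) int8 a1-dosage matrix."""
        if self.n_variants == 0:
            return np.empty((0, self.n_samples), dtype=np.int8)
        full = _BYTE_LUT[self.data].reshape(self.n_variants, -1)
        return full[:, : self.n_samples]

    def row_dosages(self, j: int) -> np.ndarray:
        return _BYTE_LUT[self.data[j]].reshape(-1)[: self.n_samples]

    def row_bytes(self, j: int) -> np.ndarray:
        return self.data[j]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PackedGenotypeMatrix)
            and self.n_samples == other.n_samples
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        return (
            f"PackedGenotypeMatrix(n_variants={self.n_variants}, "
            f"n_samples={self.n_samples})"
        )


@dataclass
class Dataset:
    samples: list[SampleRecord]
    variants: list[VariantRecord]
    genotypes: PackedGenotypeMatrix

    def __post_init__(self):
        if self.genotypes.n_samples != len(self.samples):
            raise ValueError("sample count mismatch between .fam and genotypes")
        if self.genotypes.n_variants != len(self.variants):
            raise ValueError("variant count mismatch between .bim and genotypes")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _paths(prefix_or_paths) -> tuple[Path, Path, Path]:
    if isinstance(prefix_or_paths, (tuple, list)):
        bed, bim, fam = map(Path, prefix_or_paths)
    else:
        p = str(prefix_or_paths)
        bed, bim, fam = Path(p + ".bed"), Path(p + ".bim"), Path(p + ".fam")
    return bed, bim, fam


def read_bed(bed_path, bim_path=None, fam_path=None) -> Dataset:
    """Read a PLINK 1 binary fileset (.bed + .bim + .fam).

    ``read_bed(prefix)`` expands the three paths from a shared prefix;
    alternatively pass the three paths explicitly.
    """
    if bim_path is None or fam_path is None:
        bed_path, bim_path, fam_path = _paths(bed_path)
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "pid": str, "mid": str},
    )
    samples = [
        SampleRecord(r.fid, r.iid, r.pid, r.mid, int(r.sex), float(r.phenotype))
        for r in fam.itertuples()
    ]
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    )
    variants = [
        VariantRecord(r.chrom, r.vid, float(r.cm), int(r.bp), r.a1, r.a2)
        for r in bim.itertuples()
    ]

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise BedFormatError(f"{bed_path}: bad magic bytes (not a .bed file)")
    if raw[2] == 0x00:
        raise BedFormatError(f"{bed_path}: sample-major unsupported")
    if raw[2] != _BED_VARIANT_MAJOR:
        raise BedFormatError(f"{bed_path}: unknown mode byte 0x{raw[2]:02x}")
    n, m = len(samples), len(variants)
    bpv = -(-n // 4)
    expected = 3 + m * bpv
    if len(raw) != expected:
        raise BedFormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected {m} variants"
            f" x {bpv} bytes = {expected - 3} (truncated or mismatched fileset)"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpv).copy()
    return Dataset(samples, variants, PackedGenotypeMatrix(data, n_samples=n))


def _fmt_pheno(p: float) -> str:
    return str(int(p)) if float(p).is_integer() else repr(float(p))


def _fmt_cm(cm: float) -> str:
    return str(int(cm)) if float(cm).is_integer() else repr(float(cm))


def write_bed(dataset: Dataset, out_prefix) -> tuple[Path, Path, Path]:
    """Write ``dataset`` as .bed/.bim/.fam; returns the three paths."""
    bed, bim, fam = _paths(str(out_prefix))
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_VARIANT_MAJOR]))
        fh.write(dataset.genotypes.data.tobytes())
    with open(bim, "w") as fh:
        for v in dataset.variants:
            fh.write(
                f"{v.chrom}\t{v.vid}\t{_fmt_cm(v.cm)}\t{v.bp}\t{v.a1}\t{v.a2}\n"
            )
    with open(fam, "w") as fh:
        for s in dataset.samples:
            fh.write(
                f"{s.fid}\t{s.iid}\t{s.pid}\t{s.mid}\t{s.sex}\t"
                f"{_fmt_pheno(s.phenotype)}\n"
            )
    return bed, bim, fam


def import_vcf(
    vcf_path,
    biallelic_only: bool = False,
    hard_call_threshold: float = 0.9,
) -> Dataset:
    """Import a text VCF (optionally gzipped) into the packed data model.

    Lossy rules: phase separators are ignored; multiallelic sites are
    skipped under ``biallelic_only``, otherwise only the most common
    alternate allele is kept and calls carrying any other alternate become
    missing; when a GP field is present, a biallelic call is accepted only
    if its maximum genotype probability is >= ``hard_call_threshold``.
    After import, a1 is assigned the lower-frequency allele (tie: ALT).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path), gts012=False)
    except Exception as exc:  # htslib open/parse failure
        raise VcfFormatError(f"{vcf_path}: {exc}") from exc
    if "GT" not in (vcf.raw_header or ""):
        raise VcfFormatError(f"{vcf_path}: no GT FORMAT field declared")
    sample_names = list(vcf.samples)
    n = len(sample_names)
    if n == 0:
        raise VcfFormatError(f"{vcf_path}: VCF has no sample columns")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for idx, v in enumerate(vcf):
        try:
            gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        except Exception as exc:
            raise VcfFormatError(
                f"{vcf_path}: variant #{idx + 1} ({v.CHROM}:{v.POS}): {exc}"
            ) from exc
        alts = list(v.ALT)
        if len(alts) == 0:
            continue  # no alternate allele: nothing to encode
        if len(alts) > 1 and biallelic_only:
            continue
        g = np.array([[gt[0], gt[1]] for gt in gts], dtype=np.int16)
        if len(alts) > 1:
            counts = [int((g == k + 1).sum()) for k in range(len(alts))]
            k = int(np.argmax(counts))  # tie -> first-listed alternate
        else:
            k = 0
        alt_code = k + 1
        ok = np.all((g == 0) | (g == alt_code), axis=1)
        alt_dose = np.where(ok, (g == alt_code).sum(axis=1), -1).astype(np.int8)

        if len(alts) == 1:
            gp = v.format("GP")
            if gp is not None and gp.ndim == 2 and gp.shape[1] == 3:
                with np.errstate(invalid="ignore"):
                    maxp = np.nanmax(gp, axis=1)
                alt_dose = np.where(
                    np.isnan(maxp) | (maxp >= hard_call_threshold), alt_dose, -1
                ).astype(np.int8)

        ref, alt = v.REF, alts[k]
        called = alt_dose >= 0
        alt_count = int(alt_dose[called].sum())
        obs = 2 * int(called.sum())
        if obs > 0 and alt_count > obs - alt_count:
            a1, a2 = ref, alt
            alt_dose = np.where(called, 2 - alt_dose, -1).astype(np.int8)
        else:
            a1, a2 = alt, ref  # tie -> ALT is a1
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        variants.append(VariantRecord(str(v.CHROM), vid, 0.0, int(v.POS), a1, a2))
        rows.append(alt_dose)

    dosages = (
        np.array(rows, dtype=np.int8) if rows else np.empty((0, n), dtype=np.int8)
    )
    samples = [SampleRecord(s, s) for s in sample_names]
    return Dataset(samples, variants, PackedGenotypeMatrix.from_dosages(dosages))


def allele_frequencies(dataset: Dataset) -> pd.DataFrame:
    """Per-variant a1 allele counts and frequencies over non-missing calls.

    Returns a DataFrame with columns vid, chrom, a1, a2, a1_count,
    obs_allele_count, maf; an all-missing variant reports maf NaN.
    """
    recs = []
    g = dataset.genotypes
    for j, v in enumerate(dataset.variants):
        h1, het, h2, miss = genotype_counts(g.row_bytes(j), g.n_samples)
        a1_count = 2 * h1 + het
        obs = 2 * (h1 + het + h2)
        maf = a1_count / obs if obs else float("nan")
        recs.append((v.vid, v.chrom, v.a1, v.a2, a1_count, obs, maf))
    return pd.DataFrame(
        recs,
        columns=["vid", "chrom", "a1", "a2", "a1_count", "obs_allele_count", "maf"],
    )
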