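"""Genotype containers and PLINK / VCF input-output.

The in-memory model shared by every analysis stage is :class:`GenotypeMatrix`:
an ``n_samples x n_variants`` dosage matrix counting copies of ``allele2``
(values 0/1/2, missing encoded as -1), together with a sample table and a
variant table.  Positions are 1-based base pairs; variants are stably sorted
by ``(chrom, pos)`` on load and all inter-marker distances downstream are
``|pos_i - pos_j|``.

PLINK 1.9 binary (bed/bim/fam, SNP-major) is the primary on-disk format; the
2-bit codec is implemented here directly.  VCF (4.x, GT field, biallelic) is
read through cyvcf2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the dosage matrix (int8).
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit code -> dosage of allele2.  00 = hom allele1, 01 = missing,
# 10 = het, 11 = hom allele2.
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

VARIANT_COLUMNS = ["chrom", "pos", "vid", "allele1", "allele2"]


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triplet violates the PLINK 1.9 format."""


class DimensionError(ValueError):
    """Raised when file payload sizes disagree with the declared dimensions."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for one cohort.

    Parameters
    ----------
    samples
        DataFrame with columns ``iid`` (unique sample id) and ``population``.
    variants
        DataFrame with columns ``chrom`` (positive int), ``pos`` (1-based bp),
        ``vid`` (unique variant id), ``allele1``, ``allele2``.
    dosage
        ``(n_samples, n_variants)`` int8 array counting copies of ``allele2``;
        ``-1`` marks a missing call.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True).astype(
            {"chrom": np.int64, "pos": np.int64, "vid": str}
        )
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise DimensionError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, -1}")
        if self.variants["vid"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if len(self.variants) and (self.variants["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with variants stably sorted by (chrom, pos)."""
        order = self.variants.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        return GenotypeMatrix(
            samples=self.samples.copy(),
            variants=self.variants.iloc[order],
            dosage=self.dosage[:, order],
        )

    def select_variants(self, mask_or_index) -> "GenotypeMatrix":
        """Subset variants (boolean mask or integer index), preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=self.samples.copy(),
            variants=self.variants.iloc[idx],
            dosage=self.dosage[:, idx],
        )

    def select_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            list(self.samples["iid"]) == list(other.samples["iid"])
            and self.variants[VARIANT_COLUMNS]
            .reset_index(drop=True)
            .equals(other.variants[VARIANT_COLUMNS].reset_index(drop=True))
            and np.array_equal(self.dosage, other.dosage)
        )


def _parse_chrom(label) -> int:
    """Parse an autosome label as a positive integer; reject anything else."""
    text = str(label)
    if text.lower().startswith("chr"):
        text = text[3:]
    try:
        chrom = int(text)
    except ValueError:
        raise ValueError(
            f"non-numeric chromosome label {label!r}: only integer autosome "
            "labels are supported"
        ) from None
    if chrom < 1:
        raise ValueError(f"chromosome label must be a positive integer, got {label!r}")
    return chrom


def _triplet(prefix_or_paths) -> tuple[Path, Path, Path]:
    if isinstance(prefix_or_paths, (tuple, list)):
        bed, bim, fam = map(Path, prefix_or_paths)
    else:
        prefix = str(prefix_or_paths)
        bed, bim, fam = (Path(prefix + s) for s in (".bed", ".bim", ".fam"))
    return bed, bim, fam


def read_plink(prefix_or_paths, population: str | None = None) -> GenotypeMatrix:
    """Read a PLINK 1.9 bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    ``prefix_or_paths`` is either a shared path prefix or an explicit
    ``(bed, bim, fam)`` triple.  The fam FID column is used as the population
    label unless ``population`` overrides it.  Variants are sorted by
    ``(chrom, pos)``; sample order is preserved.
    """
    bed_path, bim_path, fam_path = _triplet(prefix_or_paths)

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"vid": str, "a1": str, "a2": str},
    )
    n_samples, n_variants = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2].hex()} (expected 6c1b)"
        )
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_variant = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * n_variants:
        raise DimensionError(
            f"{bed_path}: payload of {payload.size} bytes inconsistent with "
            f"{n_samples} samples x {n_variants} variants"
        )

    if n_variants:
        blocks = payload.reshape(n_variants, bytes_per_variant)
        # Unpack the four 2-bit fields of every byte (sample order is LSB first).
        codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (blocks >> (2 * k)) & 0b11
        dosage = _CODE_TO_DOSAGE[codes[:, :n_samples]].T
    else:
        dosage = np.empty((n_samples, 0), dtype=np.int8)

    variants = pd.DataFrame(
        {
            "chrom": [_parse_chrom(c) for c in bim["chrom"]],
            "pos": bim["pos"].astype(np.int64),
            "vid": bim["vid"],
            "allele1": bim["a1"],
            "allele2": bim["a2"],
        }
    )
    samples = pd.DataFrame(
        {
            "iid": fam["iid"],
            "population": population if population is not None else fam["fid"],
        }
    )
    return GenotypeMatrix(samples, variants, dosage).sorted_by_position()


def write_plink(G: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write ``G`` as a PLINK 1.9 bed/bim/fam triplet readable by read_plink."""
    bed_path, bim_path, fam_path = _triplet(prefix)
    bed_path.parent.mkdir(parents=True, exist_ok=True)

    n_samples, n_variants = G.n_samples, G.n_variants
    bytes_per_variant = (n_samples + 3) // 4
    width = bytes_per_variant * 4
    code_lut = np.zeros(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        code_lut[dos % 256] = code  # -1 (missing) wraps to 255
    codes = np.full((n_variants, width), 0b01, dtype=np.uint8)  # pad = missing
    codes[:, :n_samples] = code_lut[G.dosage.T.astype(np.uint8)]
    packed = np.zeros((n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)

    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    with open(bim_path, "w") as fh:
        for row in G.variants.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.vid}\t0\t{row.pos}\t{row.allele1}\t{row.allele2}\n"
            )
    with open(fam_path, "w") as fh:
        for row in G.samples.itertuples(index=False):
            fh.write(f"{row.population}\t{row.iid}\t0\t0\t0\t-9\n")
    return bed_path, bim_path, fam_path


def read_vcf(path, population: str = "unknown") -> GenotypeMatrix:
    """Read a VCF with GT calls into a :class:`GenotypeMatrix`.

    Only biallelic records are loaded; multiallelic records are skipped with a
    logged warning and counted in the matrix's ``n_skipped_multiallelic``
    attribute on the variants table.  Phasing separators are accepted but
    phase is discarded (dosage only).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = pd.DataFrame({"iid": vcf.samples, "population": population})

    rows, columns = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        rows.append(
            (
                _parse_chrom(rec.CHROM),
                int(rec.POS),
                rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}",
                rec.REF,
                rec.ALT[0],
            )
        )
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2 dosage, 3 = missing
        gt[gt == 3] = MISSING
        columns.append(gt)
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic record(s)", n_skipped)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(samples, variants, dosage).sorted_by_position()
    G.variants.attrs["n_skipped_multiallelic"] = n_skipped
    return G
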