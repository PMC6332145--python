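"""Variant quality control: call rate, minor allele frequency, exact HWE.

Filters follow the standard SNP-array convention: retain variants with
call rate >= 0.95, MAF >= 0.05 and Hardy-Weinberg exact-test p >= 1e-6.
Removal is attributed to the first failed filter in the order
call rate -> MAF -> HWE, so the per-filter counters depend on that order
while the retained set does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Per-filter removal counts for one :func:`apply_qc` run."""

    n_input: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    retained_ids: list[str] = field(repr=False)
    thresholds: tuple[float, float, float] = (0.95, 0.05, 1e-6)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QC counters do not add up to the input count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["input", "call_rate", "maf", "hwe", "retained"],
                "threshold": [
                    "",
                    f">={self.thresholds[0]}",
                    f">={self.thresholds[1]}",
                    f"p>={self.thresholds[2]}",
                    "",
                ],
                "n_removed": [0, self.n_removed_callrate, self.n_removed_maf, self.n_removed_hwe, 0],
                "n_variants": [self.n_input, "", "", "", self.n_retained],
            }
        )


def allele2_freq(G: GenotypeMatrix) -> np.ndarray:
    """Per-variant frequency of allele2 among non-missing calls (NaN if none)."""
    dosage = G.dosage
    observed = dosage != MISSING
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)


def maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency in [0, 0.5]; NaN when all calls missing."""
    p = allele2_freq(G)
    return np.minimum(p, 1.0 - p)


def call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Per-variant fraction of non-missing genotypes."""
    if G.n_samples == 0:
        return np.zeros(G.n_variants)
    return (G.dosage != MISSING).sum(axis=0) / G.n_samples


def genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """``(n_variants, 3)`` counts of dosage 0 / 1 / 2 among non-missing calls."""
    return np.stack([(G.dosage == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed minor-allele count ``nA = 2*n_hom_minor + n_het``
    and sums P(het count) over all heterozygote counts (same parity as nA)
    whose conditional probability does not exceed that of the observed table.
    Computed with the standard stable recurrence from the distribution mode.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_minor == 0:
        return 1.0

    # P(het = k | n, n_minor) for k in {n_minor % 2, ..., n_minor} step 2,
    # via the ratio P(k+2)/P(k) = 4*hom_minor(k)*hom_major(k) / ((k+2)*(k+1)).
    ks = np.arange(n_minor % 2, n_minor + 1, 2)
    probs = np.empty(ks.size)
    mid = ks.size // 2  # start the recurrence near the mode for stability
    probs[mid] = 1.0
    for i in range(mid, ks.size - 1):
        k = ks[i]
        hom_minor = (n_minor - k) // 2
        hom_major = n - k - hom_minor
        probs[i + 1] = probs[i] * 4.0 * hom_minor * hom_major / ((k + 2.0) * (k + 1.0))
    for i in range(mid, 0, -1):
        k = ks[i]
        hom_minor_prev = (n_minor - k) // 2 + 1  # hom-minor count at het = k - 2
        hom_major_prev = n - (k - 2) - hom_minor_prev
        probs[i - 1] = probs[i] * k * (k - 1.0) / (4.0 * hom_minor_prev * hom_major_prev)
    probs /= probs.sum()

    p_obs = probs[np.searchsorted(ks, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Vector of exact HWE p-values, one per variant (1.0 if no data)."""
    counts = genotype_counts(G)
    out = np.ones(G.n_variants)
    for i, (a, h, b) in enumerate(counts):
        if a + h + b >= 1:
            out[i] = hwe_exact(int(a), int(h), int(b))
    return out


def apply_qc(
    G: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by call rate, MAF and HWE (in that attribution order).

    Returns the retained matrix (variant order preserved) and a
    :class:`QCReport`.  A variant with all calls missing has undefined MAF and
    fails the call-rate filter (or, at ``call_rate_min = 0``, the MAF filter).
    """
    for name, value in (
        ("call_rate_min", call_rate_min),
        ("maf_min", maf_min),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    if not 0.0 <= hwe_p_min <= 1.0:
        raise ValueError(f"hwe_p_min must be in [0, 1], got {hwe_p_min}")

    cr = call_rate(G)
    freq = maf(G)
    fail_cr = cr < call_rate_min
    fail_maf = np.isnan(freq) | (freq < maf_min)

    # HWE is only evaluated where it can still decide the variant's fate.
    undecided = ~(fail_cr | fail_maf)
    pvals = np.ones(G.n_variants)
    counts = genotype_counts(G)
    for i in np.flatnonzero(undecided):
        a, h, b = counts[i]
        pvals[i] = hwe_exact(int(a), int(h), int(b))
    fail_hwe = pvals < hwe_p_min

    removed_cr = fail_cr
    removed_maf = fail_maf & ~fail_cr
    removed_hwe = fail_hwe & ~fail_cr & ~fail_maf
    retained = ~(removed_cr | removed_maf | removed_hwe)

    report = QCReport(
        n_input=G.n_variants,
        n_removed_callrate=int(removed_cr.sum()),
        n_removed_maf=int(removed_maf.sum()),
        n_removed_hwe=int(removed_hwe.sum()),
        n_retained=int(retained.sum()),
        retained_ids=list(G.variants.loc[retained, "vid"]),
        thresholds=(call_rate_min, maf_min, hwe_p_min),
    )
    return G.select_variants(retained), report


def chromosome_summary(
    G: GenotypeMatrix, adjacent_ld: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-chromosome SNP distribution summary with a genome totals row.

    ``length_mb`` is the span max(pos) - min(pos) in Mb and
    ``mean_spacing_kb`` the span divided by (n_snps - 1) in kb, so the two
    columns reproduce the length/(n-1) ~ spacing relationship of array
    summaries.  ``adjacent_ld`` (from :func:`ldscape.ld.adjacent_r2_summary`)
    contributes the mean/sd adjacent-pair r2 columns when given.
    """
    rows = []
    for chrom, sub in G.variants.groupby("chrom", sort=True):
        n = len(sub)
        span = int(sub["pos"].max() - sub["pos"].min())
        rows.append(
            {
                "chrom": chrom,
                "length_mb": span / 1e6 if n >= 2 else np.nan,
                "n_snps": n,
                "mean_spacing_kb": span / (n - 1) / 1e3 if n >= 2 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        total_span = out["length_mb"].sum(skipna=True)
        total_n = int(out["n_snps"].sum())
        spanned = out["length_mb"].notna()
        denom = int((out.loc[spanned, "n_snps"] - 1).sum())
        totals = {
            "chrom": "All",
            "length_mb": total_span,
            "n_snps": total_n,
            "mean_spacing_kb": total_span * 1e3 / denom if denom > 0 else np.nan,
        }
        out = pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["chrom", "length_mb", "n_snps", "mean_spacing_kb"]
        )
    if adjacent_ld is not None:
        out = out.merge(
            adjacent_ld[["chrom", "mean_r2", "sd_r2"]].rename(
                columns={"mean_r2": "mean_adjacent_r2", "sd_r2": "sd_adjacent_r2"}
            ),
            on="chrom",
            how="left",
        )
    return out
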