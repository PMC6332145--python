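"""Persistence of LD phase between two populations.

For SNP pairs computed in both populations over a shared variant map, the
phase correlation in a distance interval l is the product-moment correlation
of the signed r values,

    R_PC = sum_{(i,j) in l} (r_ij(P) - rbar(P)) (r_ij(C) - rbar(C))
           / (n * S_P * S_C),

with S the divide-by-(n-1) sample standard deviation, so R_PC is bounded in
[-1, 1].  High short-range R_PC means marker-QTL phase carries over between
populations (relevant for multi-population genomic selection); the statistic
is expected to decline with inter-marker distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASE_COLUMNS = [
    "lo_bp",
    "hi_bp",
    "n_pairs",
    "R_PC",
    "rbar_P",
    "rbar_C",
    "S_P",
    "S_C",
]


def _flip_signs(records: pd.DataFrame, flipped_vids: set[str]) -> pd.DataFrame:
    """Negate r for every pair touching an odd number of flipped variants."""
    if not flipped_vids:
        return records
    records = records.copy()
    flip = records["i_vid"].isin(flipped_vids) ^ records["j_vid"].isin(flipped_vids)
    records.loc[flip, "r"] = -records.loc[flip, "r"]
    return records


def harmonize_orientation(
    records: pd.DataFrame,
    variants_ref: pd.DataFrame,
    variants_other: pd.DataFrame,
) -> pd.DataFrame:
    """Align the allele orientation of ``records`` to a reference variant table.

    A shared vid whose (allele1, allele2) pair is swapped relative to the
    reference has its dosage counting the opposite allele; every LD record
    touching exactly one such variant gets its r sign flipped (two flips
    cancel).  Variants whose allele sets do not match at all are left alone
    but logged.
    """
    ref = variants_ref.set_index("vid")[["allele1", "allele2"]]
    oth = variants_other.set_index("vid")[["allele1", "allele2"]]
    shared = ref.index.intersection(oth.index)
    a1r, a2r = ref.loc[shared, "allele1"], ref.loc[shared, "allele2"]
    a1o, a2o = oth.loc[shared, "allele1"], oth.loc[shared, "allele2"]
    swapped = (a1r == a2o) & (a2r == a1o) & (a1r != a2r)
    mismatched = ~swapped & ~((a1r == a1o) & (a2r == a2o))
    if mismatched.any():
        logger.warning(
            "harmonize_orientation: %d shared variant(s) with incompatible "
            "allele codes left unflipped",
            int(mismatched.sum()),
        )
    flipped = set(shared[swapped])
    if flipped:
        logger.info(
            "harmonize_orientation: flipped r sign at %d variant(s)", len(flipped)
        )
    return _flip_signs(records, flipped)


def shared_ld(
    records_P: pd.DataFrame,
    records_C: pd.DataFrame,
    variants_P: pd.DataFrame | None = None,
    variants_C: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inner-join signed-r records of two populations on the SNP pair.

    Both record sets must come from the same variant-ID space with the same
    allele orientation; passing the two variant tables additionally detects
    allele1/allele2 swaps and corrects the r sign of the affected pairs.
    Pairs present in only one population are dropped and counted in
    ``result.attrs['n_dropped']``.
    """
    if variants_P is not None and variants_C is not None:
        records_C = harmonize_orientation(records_C, variants_P, variants_C)
    merged = records_P.merge(
        records_C,
        on=["i_vid", "j_vid"],
        how="inner",
        suffixes=("_P", "_C"),
    )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom_P"],
            "i_vid": merged["i_vid"],
            "j_vid": merged["j_vid"],
            "dist_bp": merged["dist_bp_P"],
            "r_P": merged["r_P"],
            "r_C": merged["r_C"],
        }
    )
    out.attrs["n_dropped"] = (
        len(records_P) + len(records_C) - 2 * len(out)
    )
    return out


def phase_correlation(
    paired: pd.DataFrame,
    bin_bp: int = 100_000,
    max_bp: int = 1_000_000,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Phase correlation R_PC per half-open distance interval.

    ``positive_only`` restricts each interval to pairs with r > 0 in the
    first (reference) population before correlating; the default uses all
    signed r values (the standard definition).  Intervals with fewer than two
    pairs or zero variance report NaN.
    """
    if len(paired) == 0:
        raise ValueError("phase_correlation requires a non-empty paired table")
    n_bins = int(np.ceil(max_bp / bin_bp))
    rows = []
    dist = paired["dist_bp"].to_numpy()
    rP = paired["r_P"].to_numpy()
    rC = paired["r_C"].to_numpy()
    for k in range(n_bins):
        lo, hi = k * bin_bp, (k + 1) * bin_bp
        sel = (dist >= lo) & (dist < hi)
        if positive_only:
            sel &= rP > 0
        x, y = rP[sel], rC[sel]
        n = int(sel.sum())
        if n >= 2:
            sx = float(np.std(x, ddof=1))
            sy = float(np.std(y, ddof=1))
            if sx > 0 and sy > 0:
                rpc = float(
                    np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy)
                )
            else:
                rpc = np.nan
        else:
            sx = sy = rpc = np.nan
        rows.append(
            {
                "lo_bp": lo,
                "hi_bp": hi,
                "n_pairs": n,
                "R_PC": rpc,
                "rbar_P": float(x.mean()) if n else np.nan,
                "rbar_C": float(y.mean()) if n else np.nan,
                "S_P": sx,
                "S_C": sy,
            }
        )
    return pd.DataFrame(rows, columns=PHASE_COLUMNS)
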