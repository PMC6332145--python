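"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by expectation-maximisation
over the 3x3 genotype table: every cell except the double heterozygote
resolves its two haplotypes deterministically; the double-heterozygote count
is split between the coupling (AB/ab) and repulsion (Ab/aB) phases in the
ratio pAB*pab : pAb*paB at each iteration.  From the fitted frequencies,

    D  = pAB*pab - pAb*paB,
    r  = D / sqrt(pA*pa*pB*pb),      r2 = r**2,

where A and B denote the dosage-counted allele (allele2) at each locus, so
the sign of r is reproducible across populations genotyped on the same
array.  Missing data are handled pairwise-complete: allele and haplotype
frequencies are recomputed per SNP pair from the samples called at both
loci.

The module also provides the distance-binned decay curve, adjacent-pair
summaries, MAF-threshold sweeps, subsampling experiments and the
marker-density arithmetic used to size an array for a target LD horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .qc import maf as _maf

EM_TOL = 1e-10
EM_MAX_ITER = 10_000

LD_COLUMNS = ["chrom", "i_vid", "j_vid", "dist_bp", "r", "r2"]


class MonomorphicPairError(ValueError):
    """LD is undefined: a locus is monomorphic among the pairwise-complete samples."""


@dataclass
class HaplotypeFreqs:
    """Two-locus allele and haplotype frequencies (A/B = allele2 at each locus)."""

    pA: float
    pa: float
    pB: float
    pb: float
    pAB: float
    pAb: float
    paB: float
    pab: float
    D: float
    n_complete: int
    em_iters: int


def _pair_counts(
    X: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """3x3 genotype cross-tables for SNP pairs.

    Returns ``(n_pairs, 3, 3)`` counts over pairwise-complete samples, cell
    ``[gi, gj]`` counting samples with dosage gi at locus i and gj at locus j.
    """
    n_pairs = len(i_idx)
    counts = np.empty((n_pairs, 3, 3), dtype=np.int64)
    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        Gi = X[:, i_idx[lo:hi]]
        Gj = X[:, j_idx[lo:hi]]
        for g in range(3):
            gi_is = Gi == g
            for h in range(3):
                counts[lo:hi, g, h] = (gi_is & (Gj == h)).sum(axis=0)
    return counts


def _em_iterate(h11, h10, h01, h00, k11, k10, k01, k00, dh, two_n, tol, max_iter):
    """Run the EM fixed-point iteration in place; returns iteration counts.

    Only still-unconverged pairs are updated each round, so a few slow
    plateau cases do not make the whole batch iterate.
    """
    n_pairs = h11.shape[0]
    iters = np.zeros(n_pairs, dtype=np.int64)
    idx = np.flatnonzero(two_n > 0)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        coup = h00[idx] * h11[idx]
        rep = h01[idx] * h10[idx]
        denom = coup + rep
        frac = np.where(denom > 0, coup / np.where(denom > 0, denom, 1.0), 0.5)
        new11 = (k11[idx] + dh[idx] * frac) / two_n[idx]
        new00 = (k00[idx] + dh[idx] * frac) / two_n[idx]
        new10 = (k10[idx] + dh[idx] * (1 - frac)) / two_n[idx]
        new01 = (k01[idx] + dh[idx] * (1 - frac)) / two_n[idx]
        delta = np.max(
            np.abs(
                np.stack(
                    [new11 - h11[idx], new10 - h10[idx],
                     new01 - h01[idx], new00 - h00[idx]]
                )
            ),
            axis=0,
        )
        h11[idx], h10[idx], h01[idx], h00[idx] = new11, new10, new01, new00
        iters[idx] += 1
        idx = idx[(delta >= tol) & (dh[idx] > 0)]
    return iters


def _table_loglik(counts, h11, h10, h01, h00):
    """Multinomial log-likelihood of each 3x3 genotype table at the given
    haplotype frequencies (double heterozygote mixes both phases)."""
    tiny = 1e-300
    cell = np.empty(counts.shape, dtype=np.float64)
    cell[:, 0, 0] = h00**2
    cell[:, 0, 1] = 2 * h00 * h01
    cell[:, 0, 2] = h01**2
    cell[:, 1, 0] = 2 * h00 * h10
    cell[:, 1, 1] = 2 * h00 * h11 + 2 * h01 * h10
    cell[:, 1, 2] = 2 * h01 * h11
    cell[:, 2, 0] = h10**2
    cell[:, 2, 1] = 2 * h10 * h11
    cell[:, 2, 2] = h11**2
    return (counts * np.log(np.maximum(cell, tiny))).sum(axis=(1, 2))


def _em_from_counts(
    counts: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> dict[str, np.ndarray]:
    """Vectorised two-locus EM over a batch of 3x3 genotype tables.

    Haplotype labels: index 1 = allele2 ("A"/"B"), index 0 = allele1.
    The fixed-point iteration runs from three initialisations -- linkage
    equilibrium plus both near-boundary phase assignments, since the LE
    start can sit exactly on the saddle where the double heterozygotes
    split 50:50 -- and the highest-likelihood fixed point is kept (the LE
    solution wins ties).  Returns haplotype frequencies h00/h01/h10/h11,
    allele2 frequencies p_i/p_j, completed-sample counts and the iteration
    count of the selected start.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 2:
        counts = counts[None]
    n = counts.sum(axis=(1, 2))
    two_n = 2.0 * n

    # Unambiguous haplotype counts (all cells but the double heterozygote).
    k00 = 2 * counts[:, 0, 0] + counts[:, 0, 1] + counts[:, 1, 0]
    k01 = 2 * counts[:, 0, 2] + counts[:, 0, 1] + counts[:, 1, 2]
    k10 = 2 * counts[:, 2, 0] + counts[:, 1, 0] + counts[:, 2, 1]
    k11 = 2 * counts[:, 2, 2] + counts[:, 2, 1] + counts[:, 1, 2]
    dh = counts[:, 1, 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = (2 * counts[:, 2, :].sum(axis=1) + counts[:, 1, :].sum(axis=1)) / two_n
        p_j = (2 * counts[:, :, 2].sum(axis=1) + counts[:, :, 1].sum(axis=1)) / two_n

    q_i, q_j = 1 - p_i, 1 - p_j
    lo = np.maximum(0.0, p_i + p_j - 1.0)
    hi = np.minimum(p_i, p_j)
    starts = [
        p_i * p_j,                    # linkage equilibrium
        lo + 0.02 * (hi - lo),        # near-repulsion boundary
        hi - 0.02 * (hi - lo),        # near-coupling boundary
    ]

    best = None
    for s, h11_init in enumerate(starts):
        h11 = np.where(np.isfinite(h11_init), h11_init, 0.0).copy()
        h10 = p_i - h11
        h01 = p_j - h11
        h00 = q_i - h01
        iters = _em_iterate(
            h11, h10, h01, h00, k11, k10, k01, k00, dh, two_n, tol, max_iter
        )
        ll = _table_loglik(counts, h11, h10, h01, h00)
        if best is None:
            best = {"h11": h11, "h10": h10, "h01": h01, "h00": h00,
                    "ll": ll, "iters": iters}
        else:
            better = ll > best["ll"] + 1e-9  # strict: LE start wins ties
            for key, val in (("h11", h11), ("h10", h10), ("h01", h01),
                             ("h00", h00), ("ll", ll), ("iters", iters)):
                best[key] = np.where(better, val, best[key])
        if not dh.any():
            break  # no double heterozygotes: every start counts gametes

    return {
        "h00": best["h00"],
        "h01": best["h01"],
        "h10": best["h10"],
        "h11": best["h11"],
        "p_i": p_i,
        "p_j": p_j,
        "n": n.astype(np.int64),
        "iters": best["iters"].astype(np.int64),
    }


def _signed_r(em: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r, r2, defined-mask) from a batch EM result."""
    D = em["h11"] * em["h00"] - em["h10"] * em["h01"]
    var = em["p_i"] * (1 - em["p_i"]) * em["p_j"] * (1 - em["p_j"])
    defined = var > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(defined, D / np.sqrt(np.where(defined, var, 1.0)), np.nan)
    r = np.clip(r, -1.0, 1.0)
    return r, r * r, defined


def em_haplotype_freqs(g_i: np.ndarray, g_j: np.ndarray) -> HaplotypeFreqs:
    """EM two-locus haplotype frequencies for a single SNP pair.

    ``g_i`` and ``g_j`` are dosage vectors over the same samples (-1 missing).
    Raises :class:`MonomorphicPairError` if either locus is monomorphic among
    the pairwise-complete samples.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("dosage vectors must cover the same samples")
    ok = (g_i != MISSING) & (g_j != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(g_i[ok], g_j[ok]):
        counts[a, b] += 1
    em = _em_from_counts(counts)
    p_i, p_j = float(em["p_i"][0]), float(em["p_j"][0])
    if not (0 < p_i < 1) or not (0 < p_j < 1):
        raise MonomorphicPairError(
            "a locus is monomorphic among pairwise-complete samples"
        )
    h00, h01 = float(em["h00"][0]), float(em["h01"][0])
    h10, h11 = float(em["h10"][0]), float(em["h11"][0])
    return HaplotypeFreqs(
        pA=p_i,
        pa=1 - p_i,
        pB=p_j,
        pb=1 - p_j,
        pAB=h11,
        pAb=h10,
        paB=h01,
        pab=h00,
        D=h11 * h00 - h10 * h01,
        n_complete=int(em["n"][0]),
        em_iters=int(em["iters"][0]),
    )


def ld_pair(h: HaplotypeFreqs) -> tuple[float, float]:
    """Signed r and r2 from fitted two-locus frequencies."""
    var = h.pA * h.pa * h.pB * h.pb
    if var <= 0:
        raise MonomorphicPairError("zero allele-frequency variance: LD undefined")
    r = h.D / np.sqrt(var)
    r = float(np.clip(r, -1.0, 1.0))
    return r, r * r


def _window_pairs(
    pos: np.ndarray, max_dist_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i < j) with pos_j - pos_i <= max_dist_bp on one chromosome."""
    i_list, j_list = [], []
    hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
    for i in range(len(pos)):
        if hi[i] > i + 1:
            j = np.arange(i + 1, hi[i])
            i_list.append(np.full(j.size, i))
            j_list.append(j)
    if not i_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(i_list), np.concatenate(j_list)


def pairwise_ld(G: GenotypeMatrix, max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """All intra-chromosomal pairwise LD within a distance window.

    Returns a DataFrame with columns chrom, i_vid, j_vid, dist_bp, r, r2.
    Pairs with undefined LD (a monomorphic locus among complete samples) are
    skipped; co-located SNPs (distance 0) are excluded with a warning.  The
    skip counts are stored in ``result.attrs``.
    """
    frames = []
    n_undefined = 0
    n_colocated = 0
    for chrom, sub in G.variants.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        ii, jj = _window_pairs(pos, max_dist_bp)
        if ii.size == 0:
            continue
        dist = pos[jj] - pos[ii]
        keep = dist > 0
        n_colocated += int((~keep).sum())
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        if ii.size == 0:
            continue
        counts = _pair_counts(G.dosage, idx[ii], idx[jj])
        em = _em_from_counts(counts)
        r, r2, defined = _signed_r(em)
        n_undefined += int((~defined).sum())
        vids = sub["vid"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "i_vid": vids[ii[defined]],
                    "j_vid": vids[jj[defined]],
                    "dist_bp": dist[defined],
                    "r": r[defined],
                    "r2": r2[defined],
                }
            )
        )
    if n_colocated:
        warnings.warn(
            f"pairwise_ld: excluded {n_colocated} co-located SNP pair(s) "
            "(distance 0)",
            stacklevel=2,
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=LD_COLUMNS)
    )
    out.attrs["n_undefined"] = n_undefined
    out.attrs["n_colocated"] = n_colocated
    return out


def adjacent_r2_summary(G: GenotypeMatrix) -> pd.DataFrame:
    """Mean and sd of r2 between consecutive SNPs, per chromosome and overall.

    The sd is the population (divide-by-n) standard deviation, matching the
    mean +/- sd presentation of array-summary tables.  Chromosomes with fewer
    than two usable SNPs are reported with NaN statistics.  The overall row
    (chrom = "All") is the pair-weighted mean over chromosomes.
    """
    rows = []
    all_r2 = []
    for chrom, sub in G.variants.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            rows.append(
                {"chrom": chrom, "n_pairs": 0, "mean_r2": np.nan, "sd_r2": np.nan}
            )
            continue
        counts = _pair_counts(G.dosage, idx[:-1], idx[1:])
        em = _em_from_counts(counts)
        _, r2, defined = _signed_r(em)
        r2 = r2[defined]
        all_r2.append(r2)
        rows.append(
            {
                "chrom": chrom,
                "n_pairs": int(r2.size),
                "mean_r2": float(r2.mean()) if r2.size else np.nan,
                "sd_r2": float(r2.std()) if r2.size else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    pooled = np.concatenate(all_r2) if all_r2 else np.empty(0)
    out = pd.concat(
        [
            out,
            pd.DataFrame(
                [
                    {
                        "chrom": "All",
                        "n_pairs": int(pooled.size),
                        "mean_r2": float(pooled.mean()) if pooled.size else np.nan,
                        "sd_r2": float(pooled.std()) if pooled.size else np.nan,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    return out


def ld_decay(
    records: pd.DataFrame, bin_bp: int = 10_000, max_bp: int = 1_000_000
) -> pd.DataFrame:
    """Distance-binned LD decay curve.

    Half-open bins ``[k*bin_bp, (k+1)*bin_bp)`` tile ``[0, max_bp)``; each
    record lands in ``floor(dist/bin_bp)``.  Empty bins report NaN means.
    """
    n_bins = int(np.ceil(max_bp / bin_bp))
    lo = np.arange(n_bins) * bin_bp
    out = pd.DataFrame(
        {
            "lo_bp": lo,
            "hi_bp": lo + bin_bp,
            "n_pairs": 0,
            "mean_r2": np.nan,
            "sd_r2": np.nan,
        }
    )
    dist = records["dist_bp"].to_numpy()
    r2 = records["r2"].to_numpy()
    keep = dist < max_bp
    which = (dist[keep] // bin_bp).astype(np.int64)
    r2 = r2[keep]
    if which.size:
        n = np.bincount(which, minlength=n_bins)
        s = np.bincount(which, weights=r2, minlength=n_bins)
        ss = np.bincount(which, weights=r2 * r2, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            var = np.where(n > 0, ss / np.maximum(n, 1) - mean**2, np.nan)
        out["n_pairs"] = n
        out["mean_r2"] = mean
        out["sd_r2"] = np.sqrt(np.maximum(var, 0.0))
    return out


def proportion_above(records_or_r2, threshold: float) -> float:
    """Fraction of pairs with r2 strictly greater than ``threshold``."""
    if isinstance(records_or_r2, pd.DataFrame):
        r2 = records_or_r2["r2"].to_numpy()
    else:
        r2 = np.asarray(records_or_r2, dtype=float)
    if r2.size == 0:
        raise ValueError("proportion_above is undefined on an empty record set")
    return float((r2 > threshold).mean())


def maf_threshold_sweep(
    G: GenotypeMatrix,
    thresholds: tuple[float, ...] = (0.05, 0.1, 0.2),
    bin_bp: int = 10_000,
    max_bp: int = 1_000_000,
) -> dict[float, pd.DataFrame]:
    """LD decay curves after re-filtering variants at each minimum MAF.

    The retained variant sets are nested (higher threshold => subset), which
    is how the effect of low-frequency alleles on the r2 decay curve is
    usually displayed.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    freq = _maf(G)
    curves: dict[float, pd.DataFrame] = {}
    for t in thresholds:
        sub = G.select_variants(np.nan_to_num(freq, nan=-1.0) >= t)
        per_chrom = sub.variants.groupby("chrom").size()
        if len(per_chrom) == 0 or (per_chrom < 2).all():
            curves[t] = ld_decay(pd.DataFrame(columns=LD_COLUMNS), bin_bp, max_bp)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = pairwise_ld(sub, max_dist_bp=max_bp)
        curves[t] = ld_decay(records, bin_bp, max_bp)
    return curves


def subsample_ld_curves(
    G: GenotypeMatrix,
    sizes: tuple[int, ...] = (25, 45, 51, 55, 102, 205, 411),
    reps: int = 1000,
    seed: int = 0,
    bin_bp: int = 10_000,
    max_bp: int = 1_000_000,
    replacement: bool = False,
) -> dict[int, pd.DataFrame]:
    """Mean LD decay curve per subsample size, averaged over replicates.

    For each size, ``reps`` random individual subsets are drawn (without
    replacement by default; a size equal to the cohort is the identity and
    uses a single replicate) and the per-replicate decay curves are averaged
    bin-wise.  Reproducible given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for s in sizes:
        if s > G.n_samples:
            raise ValueError(
                f"subsample size {s} exceeds cohort size {G.n_samples}"
            )
    rng = np.random.default_rng(seed)
    out: dict[int, pd.DataFrame] = {}
    for size in sizes:
        identity = size == G.n_samples and not replacement
        n_reps = 1 if identity else reps
        acc_sum = None
        acc_cnt = None
        acc_pairs = None
        for _ in range(n_reps):
            if identity:
                sub = G
            elif replacement:
                sub = G.select_samples(rng.integers(0, G.n_samples, size))
            else:
                sub = G.select_samples(rng.permutation(G.n_samples)[:size])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = ld_decay(pairwise_ld(sub, max_bp), bin_bp, max_bp)
            mean = curve["mean_r2"].to_numpy()
            seen = ~np.isnan(mean)
            if acc_sum is None:
                acc_sum = np.zeros(len(curve))
                acc_cnt = np.zeros(len(curve))
                acc_pairs = np.zeros(len(curve))
                template = curve
            acc_sum[seen] += mean[seen]
            acc_cnt[seen] += 1
            acc_pairs += curve["n_pairs"].to_numpy() / n_reps
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(acc_cnt > 0, acc_sum / np.maximum(acc_cnt, 1), np.nan)
        out[size] = pd.DataFrame(
            {
                "lo_bp": template["lo_bp"],
                "hi_bp": template["hi_bp"],
                "n_pairs": acc_pairs,
                "mean_r2": avg,
            }
        )
    return out


def marker_density_requirement(
    genome_size_bp: float, ld_distance_bp: float
) -> tuple[float, int]:
    """Number of informative SNPs needed to tile a genome at a given LD horizon.

    One marker per ``ld_distance_bp`` (the distance out to which r2 stays
    above the target level) across ``genome_size_bp``.  Returns the exact
    quotient and its value rounded to the nearest 100.
    """
    if genome_size_bp <= 0 or ld_distance_bp <= 0:
        raise ValueError("genome size and LD distance must be positive")
    exact = genome_size_bp / ld_distance_bp
    return exact, int(round(exact / 100.0) * 100)
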