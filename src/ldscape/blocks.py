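"""Haplotype-block detection from D-prime confidence intervals.

Implements the confidence-interval block definition behind the default
PLINK/Haploview block caller: for every SNP pair within a 200 kb window a
90% likelihood-based confidence interval on |D'| is computed; a pair is in
"strong LD" when the interval lies high (ci_lo >= 0.70 and ci_hi >= 0.98)
and shows "strong recombination" when ci_hi < 0.90.  A run of SNPs is a
candidate block when at least 95% of its informative pairs are strong-LD;
the final block set is a greedy longest-first, leftmost-tie-break selection
of non-overlapping candidates.

Haploview's special-case distance-dependent cutoffs for 2-4 marker spans are
deliberately not applied, so block-count parity with PLINK's caller is
approximate; the core CI rule is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .ld import MonomorphicPairError, _em_from_counts, _pair_counts, _window_pairs


@dataclass
class DPrimeCI:
    """|D'| point estimate with likelihood-based confidence bounds."""

    dprime: float
    ci_lo: float
    ci_hi: float


@dataclass
class HaploBlock:
    chrom: int
    start_bp: int
    end_bp: int
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class BlockSummary:
    """Genome-wide haploblock statistics (lengths in kb, coverage in Mb)."""

    n_blocks: int
    mean_len_kb: float
    max_len_kb: float
    coverage_mb: float
    n_snps_in_blocks: int
    pct_snps_in_blocks: float
    mean_snps_per_block: float
    max_snps_per_block: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _cell_log_probs(h00, h01, h10, h11):
    """Log-probabilities of the 9 genotype cells given haplotype frequencies.

    Cell (gi, gj) collects every compatible unordered haplotype pair; the
    double heterozygote mixes the coupling and repulsion phases.
    Inputs broadcast; output has shape (..., 3, 3).
    """
    tiny = 1e-300
    p = np.empty(np.broadcast(h00, h11).shape + (3, 3))
    p[..., 0, 0] = h00**2
    p[..., 0, 1] = 2 * h00 * h01
    p[..., 0, 2] = h01**2
    p[..., 1, 0] = 2 * h00 * h10
    p[..., 1, 1] = 2 * h00 * h11 + 2 * h01 * h10
    p[..., 1, 2] = 2 * h01 * h11
    p[..., 2, 0] = h10**2
    p[..., 2, 1] = 2 * h10 * h11
    p[..., 2, 2] = h11**2
    return np.log(np.maximum(p, tiny))


def _dprime_ci_batch(
    counts: np.ndarray, grid: float = 0.001, ci: float = 0.90, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised |D'| and likelihood CI for a batch of 3x3 genotype tables.

    Allele frequencies are fixed at their EM estimates; the genotype-table
    likelihood is evaluated on a |D'| grid (D carrying the sign of the EM
    estimate) and normalised over the grid.  ci_lo is the smallest grid value
    with at least (1-ci)/2 cumulative likelihood at or below it; ci_hi the
    largest with at least (1-ci)/2 at or above it.  Returns
    (dprime, ci_lo, ci_hi, defined-mask).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 2:
        counts = counts[None]
    if counts.shape[0] > chunk:  # bound the (pairs x grid x 9) workspace
        parts = [
            _dprime_ci_batch(counts[k : k + chunk], grid=grid, ci=ci, chunk=chunk)
            for k in range(0, counts.shape[0], chunk)
        ]
        return tuple(np.concatenate(list(p)) for p in zip(*parts))
    em = _em_from_counts(counts)
    p1, p2 = em["p_i"], em["p_j"]
    D = em["h11"] * em["h00"] - em["h10"] * em["h01"]
    defined = (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1)

    q1, q2 = 1 - p1, 1 - p2
    d_max = np.where(
        D >= 0,
        np.minimum(p1 * q2, q1 * p2),
        np.minimum(p1 * p2, q1 * q2),
    )
    d_max = np.where(d_max > 0, d_max, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.abs(D) / d_max
    dprime = np.clip(dprime, 0.0, 1.0)

    n_grid = int(round(1.0 / grid)) + 1
    dgrid = np.linspace(0.0, 1.0, n_grid)
    sign = np.where(D >= 0, 1.0, -1.0)
    # Haplotype frequencies at each grid |D'| value: h11 = p1*p2 + sign*d'*Dmax.
    Dg = sign[:, None] * dgrid[None, :] * d_max[:, None]
    h11 = p1[:, None] * p2[:, None] + Dg
    h10 = p1[:, None] * q2[:, None] - Dg
    h01 = q1[:, None] * p2[:, None] - Dg
    h00 = q1[:, None] * q2[:, None] + Dg
    loglik = np.einsum(
        "pgh,pdgh->pd", counts, _cell_log_probs(h00, h01, h10, h11)
    )
    loglik = np.where(np.isnan(loglik), -np.inf, loglik)
    peak = np.max(loglik, axis=1, keepdims=True)
    loglik -= np.where(np.isfinite(peak), peak, 0.0)
    w = np.exp(loglik)
    w /= np.maximum(w.sum(axis=1, keepdims=True), 1e-300)

    alpha = (1.0 - ci) / 2.0
    cum_lo = np.cumsum(w, axis=1)
    cum_hi = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    lo_idx = np.argmax(cum_lo >= alpha, axis=1)
    hi_idx = n_grid - 1 - np.argmax((cum_hi >= alpha)[:, ::-1], axis=1)
    return dprime, dgrid[lo_idx], dgrid[hi_idx], defined


def dprime_ci(g_i, g_j, grid: float = 0.001, ci: float = 0.90) -> DPrimeCI:
    """|D'| with a likelihood confidence interval for one SNP pair."""
    from .genotype_io import MISSING

    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(g_i[ok], g_j[ok]):
        counts[a, b] += 1
    dp, lo, hi, defined = _dprime_ci_batch(counts[None], grid=grid, ci=ci)
    if not defined[0]:
        raise MonomorphicPairError("D' undefined: a locus is monomorphic")
    return DPrimeCI(float(dp[0]), float(lo[0]), float(hi[0]))


def find_blocks(
    G: GenotypeMatrix,
    window_bp: int = 200_000,
    strong_lo: float = 0.70,
    strong_hi: float = 0.98,
    recomb_hi: float = 0.90,
    min_strong_frac: float = 0.95,
    grid: float = 0.001,
    ci: float = 0.90,
) -> list[HaploBlock]:
    """Detect CI-rule haplotype blocks per chromosome.

    Pairs within ``window_bp`` are classified strong-LD / strong-recombination
    from their |D'| CI; every SNP run whose informative pairs are at least
    ``min_strong_frac`` strong-LD is a candidate, and candidates are accepted
    greedily longest-first (leftmost wins ties) without overlap.
    """
    blocks: list[HaploBlock] = []
    for chrom, sub in G.variants.groupby("chrom", sort=True):
        col_idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        vids = sub["vid"].to_numpy()
        m = len(pos)
        if m < 2:
            continue
        ii, jj = _window_pairs(pos, window_bp)
        if ii.size == 0:
            continue
        counts = _pair_counts(G.dosage, col_idx[ii], col_idx[jj])
        dp, lo, hi, defined = _dprime_ci_batch(counts, grid=grid, ci=ci)
        strong = defined & (lo >= strong_lo) & (hi >= strong_hi)
        recomb = defined & (hi < recomb_hi)
        informative = strong | recomb

        # Dense lookup tables over the (banded) pair set.
        strong_m = np.zeros((m, m), dtype=bool)
        info_m = np.zeros((m, m), dtype=bool)
        strong_m[ii, jj] = strong
        info_m[ii, jj] = informative

        candidates: list[tuple[int, int, int]] = []  # (length_bp, a, b)
        for a in range(m - 1):
            b_max = np.searchsorted(pos, pos[a] + window_bp, side="right") - 1
            for b in range(a + 1, b_max + 1):
                n_info = int(info_m[a : b + 1, a : b + 1].sum())
                if n_info == 0:
                    continue
                n_strong = int(strong_m[a : b + 1, a : b + 1].sum())
                if n_strong / n_info >= min_strong_frac:
                    candidates.append((int(pos[b] - pos[a]), a, b))

        # Greedy: longest span first, leftmost start on ties.
        candidates.sort(key=lambda t: (-t[0], t[1]))
        used = np.zeros(m, dtype=bool)
        chosen = []
        for length, a, b in candidates:
            if used[a : b + 1].any():
                continue
            used[a : b + 1] = True
            chosen.append((a, b))
        for a, b in sorted(chosen):
            blocks.append(
                HaploBlock(
                    chrom=int(chrom),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    snp_ids=list(vids[a : b + 1]),
                )
            )
    return blocks


def block_summary(blocks: list[HaploBlock], G: GenotypeMatrix) -> BlockSummary:
    """Genome-wide block statistics relative to the QC-passed SNP set in ``G``."""
    n = len(blocks)
    if n == 0:
        return BlockSummary(0, np.nan, np.nan, 0.0, 0, 0.0, np.nan, 0)
    lens_kb = np.array([b.length_bp / 1e3 for b in blocks])
    snps = np.array([b.n_snps for b in blocks])
    n_in = int(snps.sum())
    return BlockSummary(
        n_blocks=n,
        mean_len_kb=float(lens_kb.mean()),
        max_len_kb=float(lens_kb.max()),
        coverage_mb=float(lens_kb.sum() / 1e3),
        n_snps_in_blocks=n_in,
        pct_snps_in_blocks=100.0 * n_in / G.n_variants if G.n_variants else np.nan,
        mean_snps_per_block=float(snps.mean()),
        max_snps_per_block=int(snps.max()),
    )


def blocks_to_frame(blocks: list[HaploBlock]) -> pd.DataFrame:
    """Blocks as a ``.blocks.det``-style table (one row per block)."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start_bp": [b.start_bp for b in blocks],
            "end_bp": [b.end_bp for b in blocks],
            "kb": [b.length_bp / 1e3 for b in blocks],
            "nsnps": [b.n_snps for b in blocks],
            "snps": ["|".join(b.snp_ids) for b in blocks],
        }
    )
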