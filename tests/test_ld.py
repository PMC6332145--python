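"""EM haplotype frequencies, r2, decay binning, subsampling, marker density."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ldscape import (
    HaplotypeFreqs,
    MonomorphicPairError,
    em_haplotype_freqs,
    ld_decay,
    ld_pair,
    maf_threshold_sweep,
    marker_density_requirement,
    pairwise_ld,
    proportion_above,
    subsample_ld_curves,
    adjacent_r2_summary,
)
from ldscape.ld import _em_from_counts

from conftest import make_genotypes


def _grid_loglik(gi, gj, pAB, pA, pB):
    pAb = pA - pAB
    paB = pB - pAB
    pab = 1.0 - pA - pB + pAB
    cell = np.zeros((3, 3, pAB.size))
    cell[0, 0] = pab**2
    cell[0, 1] = 2 * pab * paB
    cell[0, 2] = paB**2
    cell[1, 0] = 2 * pab * pAb
    cell[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    cell[1, 2] = 2 * pAB * paB
    cell[2, 0] = pAb**2
    cell[2, 1] = 2 * pAB * pAb
    cell[2, 2] = pAB**2
    counts = np.zeros((3, 3))
    for a, b in zip(gi, gj):
        counts[a, b] += 1
    return (counts[..., None] * np.log(np.maximum(cell, 1e-300))).sum(axis=(0, 1))


def grid_likelihood_oracle(g_i, g_j, resolution=1e-5):
    """Brute-force maximisation of the two-locus multinomial likelihood.

    Profiles the likelihood of the 3x3 genotype table over pAB on a grid
    within its Frechet bounds (allele frequencies fixed at their observed
    values), then refines around the coarse argmax.  Independent of the EM
    code path.
    """
    g_i, g_j = np.asarray(g_i), np.asarray(g_j)
    ok = (g_i >= 0) & (g_j >= 0)
    gi, gj = g_i[ok], g_j[ok]
    n = len(gi)
    pA = gi.sum() / (2 * n)
    pB = gj.sum() / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    grid = np.arange(lo, hi + resolution, resolution)
    best = grid[np.argmax(_grid_loglik(gi, gj, grid, pA, pB))]
    fine = np.linspace(
        max(lo, best - resolution), min(hi, best + resolution), 401
    )
    best = fine[np.argmax(_grid_loglik(gi, gj, fine, pA, pB))]
    D = best - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return best, D, D * D / denom


def test_em_of_locus_with_itself_is_perfect_ld():
    g = np.array([0, 0, 1, 2, 2])
    h = em_haplotype_freqs(g, g)
    assert h.pAB == pytest.approx(h.pA, abs=1e-9)
    assert h.D == pytest.approx(h.pA * h.pa, abs=1e-9)
    assert ld_pair(h)[1] == pytest.approx(1.0, abs=1e-9)


def test_em_without_double_heterozygotes_is_direct_gamete_counting():
    # 5 samples, no (1,1) cell: haplotypes resolve deterministically.
    g_i = np.array([0, 2, 1, 0, 2])
    g_j = np.array([0, 2, 2, 1, 1])
    # Hand gamete count (A/B = allele2): pairs per sample:
    # (0,0)->ab,ab ; (2,2)->AB,AB ; (1,2)->AB,aB ; (0,1)->ab,aB ; (2,1)->AB,Ab
    # totals over 10 gametes: AB=4, Ab=1, aB=2, ab=3
    h = em_haplotype_freqs(g_i, g_j)
    assert h.em_iters == 1
    assert (h.pAB, h.pAb, h.paB, h.pab) == pytest.approx(
        (0.4, 0.1, 0.2, 0.3), abs=1e-12
    )


def test_em_matches_grid_likelihood_oracle_on_double_het_table():
    rng = np.random.default_rng(42)
    hap_freqs = np.array([0.35, 0.15, 0.1, 0.4])  # AB, Ab, aB, ab
    haps = rng.choice(4, size=(20, 2), p=hap_freqs)
    carries_A = np.isin(haps, [0, 1]).sum(axis=1)
    carries_B = np.isin(haps, [0, 2]).sum(axis=1)
    assert ((carries_A == 1) & (carries_B == 1)).any()  # double hets present
    h = em_haplotype_freqs(carries_A, carries_B)
    pAB_star, _, r2_star = grid_likelihood_oracle(carries_A, carries_B)
    assert h.pAB == pytest.approx(pAB_star, abs=1e-4)
    assert ld_pair(h)[1] == pytest.approx(r2_star, abs=1e-4)


def test_em_loglikelihood_nondecreasing_and_matches_oracle_on_random_tables():
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(60):
        n = rng.integers(5, 51)
        pA, pB = rng.uniform(0.15, 0.85, 2)
        d_lo = max(-pA * pB, -(1 - pA) * (1 - pB))
        d_hi = min(pA * (1 - pB), (1 - pA) * pB)
        D = rng.uniform(d_lo, d_hi)
        p = np.array(
            [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D]
        )
        haps = rng.choice(4, size=(n, 2), p=p)
        gi = np.isin(haps, [0, 1]).sum(axis=1)
        gj = np.isin(haps, [0, 2]).sum(axis=1)
        try:
            h = em_haplotype_freqs(gi, gj)
        except MonomorphicPairError:
            continue
        pAB_star, _, r2_star = grid_likelihood_oracle(gi, gj)
        assert ld_pair(h)[1] == pytest.approx(r2_star, abs=1e-4)
        checked += 1
    assert checked >= 30


def test_em_monomorphic_locus_raises():
    with pytest.raises(MonomorphicPairError):
        em_haplotype_freqs(np.array([0, 0, 0, 0]), np.array([0, 1, 2, 1]))


def test_ld_pair_closed_form_cases():
    perfect = HaplotypeFreqs(0.5, 0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.5, 0.25, 10, 1)
    assert ld_pair(perfect) == pytest.approx((1.0, 1.0))
    indep = HaplotypeFreqs(0.4, 0.6, 0.5, 0.5, 0.2, 0.2, 0.3, 0.3, 0.0, 10, 1)
    assert ld_pair(indep) == pytest.approx((0.0, 0.0))
    mixed = HaplotypeFreqs(0.5, 0.5, 0.5, 0.5, 0.4, 0.1, 0.1, 0.4, 0.15, 10, 1)
    r, r2 = ld_pair(mixed)
    assert (r, r2) == pytest.approx((0.6, 0.36))


def test_pairwise_ld_window_and_combinatorial_count():
    rng = np.random.default_rng(1)
    # 6 SNPs mutually within 1 Mb -> 15 pairs
    dosage = rng.choice([0, 1, 2], size=(40, 6))
    G = make_genotypes(dosage, positions=np.arange(6) * 100_000 + 1)
    rec = pairwise_ld(G)
    assert len(rec) == 15

    far = make_genotypes(rng.choice([0, 1, 2], size=(40, 2)), positions=[1, 1_200_001])
    assert len(pairwise_ld(far, max_dist_bp=1_000_000)) == 0


def test_pairwise_ld_allele_relabel_flips_r_keeps_r2():
    rng = np.random.default_rng(2)
    dosage = rng.choice([0, 1, 2], size=(50, 4))
    G = make_genotypes(dosage)
    flipped = dosage.copy()
    flipped[:, 1] = 2 - flipped[:, 1]
    Gf = make_genotypes(flipped)
    a = pairwise_ld(G).set_index(["i_vid", "j_vid"])
    b = pairwise_ld(Gf).set_index(["i_vid", "j_vid"])
    assert a["r2"].values == pytest.approx(b["r2"].values, abs=1e-12)
    touches = ["v1" in idx for idx in a.index]
    sign = np.where(touches, -1.0, 1.0)
    assert a["r"].values == pytest.approx(sign * b["r"].values, abs=1e-12)


def test_adjacent_r2_summary_hand_arithmetic():
    # Build three loci where both adjacent r2 values are hand-computable via
    # direct gamete counting (no double heterozygotes).
    g0 = np.array([0, 2, 1, 0, 2] * 8)
    g1 = np.array([0, 2, 2, 1, 1] * 8)  # vs g0: r2 = 0.36 / 0.24 ... computed below
    G = make_genotypes(np.stack([g0, g1, g0], axis=1))
    out = adjacent_r2_summary(G)
    h01 = em_haplotype_freqs(g0, g1)
    r2_01 = ld_pair(h01)[1]
    overall = out[out["chrom"] == "All"].iloc[0]
    assert overall["n_pairs"] == 2
    assert overall["mean_r2"] == pytest.approx(r2_01)  # both pairs identical
    assert overall["sd_r2"] == pytest.approx(0.0, abs=1e-12)


def test_adjacent_summary_pair_weighted_overall(wf_cohort):
    Gq, _ = wf_cohort
    out = adjacent_r2_summary(Gq)
    per = out[out["chrom"] != "All"].dropna(subset=["mean_r2"])
    overall = out[out["chrom"] == "All"].iloc[0]
    weighted = (per["mean_r2"] * per["n_pairs"]).sum() / per["n_pairs"].sum()
    assert overall["mean_r2"] == pytest.approx(weighted)


def test_ld_decay_half_open_binning_and_groupby_oracle():
    records = pd.DataFrame(
        {
            "chrom": 1,
            "i_vid": "a",
            "j_vid": "b",
            "dist_bp": [5_000, 9_999, 10_000, 25_000, 5_000, 10_001,
                        999_999, 500, 10_000, 19_999],
            "r": 0.0,
            "r2": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        }
    )
    curve = ld_decay(records)
    by_hand = records.groupby(records["dist_bp"] // 10_000)["r2"].agg(["mean", "size"])
    for k, row in by_hand.iterrows():
        assert curve.loc[k, "mean_r2"] == pytest.approx(row["mean"])
        assert curve.loc[k, "n_pairs"] == row["size"]
    # boundary: 10,000 bp lands in [10 kb, 20 kb)
    assert curve.loc[1, "n_pairs"] == 4
    assert curve.loc[0, "n_pairs"] == 4


def test_proportion_above_counts_strictly_greater():
    assert proportion_above(np.array([0.1, 0.25, 0.35]), 0.2) == pytest.approx(2 / 3)
    assert proportion_above(np.ones(5), 0.3) == 1.0
    assert proportion_above(np.ones(5), 1.0) == 0.0
    with pytest.raises(ValueError):
        proportion_above(np.empty(0), 0.2)


def test_maf_sweep_nested_sets_and_short_range_monotonicity(wf_cohort):
    Gq, _ = wf_cohort
    from ldscape import maf as maf_fn

    f = maf_fn(Gq)
    n_by_t = {t: int((f >= t).sum()) for t in (0.05, 0.1, 0.2)}
    assert n_by_t[0.2] <= n_by_t[0.1] <= n_by_t[0.05]

    curves = maf_threshold_sweep(Gq)
    base = pairwise_ld(Gq)
    baseline = ld_decay(base)
    pd.testing.assert_frame_equal(curves[0.05], baseline)
    # short-distance mean r2 non-decreasing in the MAF threshold
    short = {
        t: np.nansum(c["mean_r2"].to_numpy()[:10] * c["n_pairs"].to_numpy()[:10])
        / max(c["n_pairs"].to_numpy()[:10].sum(), 1)
        for t, c in curves.items()
    }
    assert short[0.1] >= short[0.05] - 1e-9
    assert short[0.2] >= short[0.1] - 1e-9


def test_subsample_identity_and_determinism(wf_cohort):
    Gq, _ = wf_cohort
    n = Gq.n_samples
    full = ld_decay(pairwise_ld(Gq))
    a = subsample_ld_curves(Gq, sizes=(n,), reps=3, seed=9)
    assert a[n]["mean_r2"].to_numpy() == pytest.approx(
        full["mean_r2"].to_numpy(), nan_ok=True
    )
    b1 = subsample_ld_curves(Gq, sizes=(25,), reps=3, seed=9)
    b2 = subsample_ld_curves(Gq, sizes=(25,), reps=3, seed=9)
    pd.testing.assert_frame_equal(b1[25], b2[25])
    with pytest.raises(ValueError):
        subsample_ld_curves(Gq, sizes=(n + 1,), reps=1, seed=0)


def test_small_subsample_inflates_long_range_r2(wf_cohort):
    """Finite-sample inflation ~ 1/n: size 25 curves sit above size 100."""
    Gq, _ = wf_cohort
    curves = subsample_ld_curves(Gq, sizes=(25, 100), reps=20, seed=3)
    tail25 = np.nanmean(curves[25]["mean_r2"].to_numpy()[50:])
    tail100 = np.nanmean(curves[100]["mean_r2"].to_numpy()[50:])
    assert tail25 > tail100


@pytest.mark.parametrize(
    "genome,distance,expected_exact,expected_rounded",
    [
        (2.87e9, 100e3, 28_700.0, 28_700),
        (2.83e9, 60e3, 47_166.666_666_666_664, 47_200),
        (1e9, 1e6, 1_000.0, 1_000),
    ],
)
def test_marker_density_requirement(genome, distance, expected_exact, expected_rounded):
    exact, rounded = marker_density_requirement(genome, distance)
    assert exact == pytest.approx(expected_exact)
    assert rounded == expected_rounded
    with pytest.raises(ValueError):
        marker_density_requirement(-1, 100)
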