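"""D' confidence intervals and CI-rule haplotype blocks."""

import numpy as np
import pytest

from ldscape import (
    MonomorphicPairError,
    BlockSummary,
    HaploBlock,
    block_summary,
    dprime_ci,
    find_blocks,
)
from ldscape.blocks import _dprime_ci_batch

from conftest import make_genotypes


def likelihood_ci_oracle(counts, grid=0.001, ci=0.90):
    """Direct likelihood tabulation over the |D'| grid (independent path)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p1 = float((2 * counts[2].sum() + counts[1].sum()) / (2 * n))
    p2 = float((2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n))
    # sign of D from the EM-free composite covariance (sufficient for the CI)
    from ldscape.ld import _em_from_counts

    em = _em_from_counts(counts)
    D = float((em["h11"] * em["h00"] - em["h10"] * em["h01"])[0])
    q1, q2 = 1 - p1, 1 - p2
    d_max = min(p1 * q2, q1 * p2) if D >= 0 else min(p1 * p2, q1 * q2)
    sign = 1.0 if D >= 0 else -1.0
    dgrid = np.linspace(0, 1, int(round(1 / grid)) + 1)
    liks = []
    for dp in dgrid:
        Dg = sign * dp * d_max
        h11 = p1 * p2 + Dg
        h10 = p1 * q2 - Dg
        h01 = q1 * p2 - Dg
        h00 = q1 * q2 + Dg
        cell = np.array(
            [
                [h00**2, 2 * h00 * h01, h01**2],
                [2 * h00 * h10, 2 * h00 * h11 + 2 * h01 * h10, 2 * h01 * h11],
                [h10**2, 2 * h10 * h11, h11**2],
            ]
        )
        liks.append((counts * np.log(np.maximum(cell, 1e-300))).sum())
    w = np.exp(np.array(liks) - max(liks))
    w /= w.sum()
    alpha = (1 - ci) / 2
    lo = dgrid[np.argmax(np.cumsum(w) >= alpha)]
    hi = dgrid[::-1][np.argmax(np.cumsum(w[::-1]) >= alpha)]
    return lo, hi


def test_dprime_perfect_ld_hits_upper_bound():
    g = np.repeat([0, 2], 50)
    out = dprime_ci(g, g)
    assert out.dprime == pytest.approx(1.0)
    assert out.ci_hi == pytest.approx(1.0)
    assert out.ci_lo > 0.9  # n = 100 in perfect LD pins the interval high


def test_dprime_zero_when_d_is_zero():
    # Independent loci with D exactly 0 by construction (no double hets).
    g_i = np.array([0, 0, 2, 2] * 10)
    g_j = np.array([0, 2, 0, 2] * 10)
    out = dprime_ci(g_i, g_j)
    assert out.dprime == pytest.approx(0.0, abs=1e-9)


def test_dprime_monomorphic_raises():
    with pytest.raises(MonomorphicPairError):
        dprime_ci(np.zeros(20, dtype=int), np.array([0, 1, 2, 1] * 5))


def test_dprime_ci_matches_direct_likelihood_tabulation():
    rng = np.random.default_rng(30)
    for _ in range(10):
        haps = rng.choice(4, size=(30, 2), p=[0.4, 0.15, 0.1, 0.35])
        gi = np.isin(haps, [0, 1]).sum(axis=1)
        gj = np.isin(haps, [0, 2]).sum(axis=1)
        counts = np.zeros((3, 3))
        for a, b in zip(gi, gj):
            counts[a, b] += 1
        if not ((0 < gi.mean() < 4) and (0 < gj.mean() < 4)):
            continue
        out = dprime_ci(gi, gj)
        lo, hi = likelihood_ci_oracle(counts)
        assert out.ci_lo == pytest.approx(lo, abs=0.001 + 1e-12)
        assert out.ci_hi == pytest.approx(hi, abs=0.001 + 1e-12)
        assert out.ci_lo <= out.dprime + 0.001
        assert out.dprime <= out.ci_hi + 0.001


def _complete_ld_cohort(n_snps, n=120, spacing=10_000):
    """SNPs in complete LD: two haplotypes only (all-0 and all-2 rows)."""
    rows = [[0] * n_snps] * (n // 2) + [[2] * n_snps] * (n - n // 2)
    return make_genotypes(
        np.array(rows), positions=(np.arange(n_snps) + 1) * spacing
    )


def test_three_tightly_linked_snps_form_one_block():
    G = _complete_ld_cohort(3)
    blocks = find_blocks(G)
    assert len(blocks) == 1
    assert blocks[0].snp_ids == ["v0", "v1", "v2"]


def test_distant_snps_form_no_blocks():
    G = _complete_ld_cohort(4, spacing=300_000)  # pairwise > 200 kb apart
    assert find_blocks(G) == []


def test_recombinant_splits_block():
    """An engineered recombination hotspot in the middle yields two blocks."""
    rng = np.random.default_rng(8)
    n = 200
    left = rng.random(n) < 0.5  # haplotype indicator, loci 0-2
    right = rng.random(n) < 0.5  # independent indicator, loci 3-4
    dosage = np.zeros((n, 5), dtype=np.int8)
    for j in range(3):
        dosage[:, j] = 2 * left
    for j in range(3, 5):
        dosage[:, j] = 2 * right
    G = make_genotypes(dosage, positions=(np.arange(5) + 1) * 20_000)
    blocks = find_blocks(G)
    assert [b.snp_ids for b in blocks] == [["v0", "v1", "v2"], ["v3", "v4"]]


def test_blocks_do_not_overlap_or_span_chromosomes(wf_cohort):
    Gq, _ = wf_cohort
    blocks = find_blocks(Gq)
    by_chrom: dict[int, list] = {}
    for b in blocks:
        assert b.end_bp > b.start_bp and b.n_snps >= 2
        chrom_pos = set(
            Gq.variants.loc[Gq.variants["chrom"] == b.chrom, "vid"]
        )
        assert set(b.snp_ids) <= chrom_pos  # never spans chromosomes
        by_chrom.setdefault(b.chrom, []).append((b.start_bp, b.end_bp))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # disjoint


def test_raising_strong_fraction_never_adds_blocks(wf_cohort):
    Gq, _ = wf_cohort
    n_loose = sum(b.n_snps for b in find_blocks(Gq, min_strong_frac=0.80))
    n_tight = sum(b.n_snps for b in find_blocks(Gq, min_strong_frac=1.0))
    assert n_tight <= n_loose


def test_free_recombination_yields_no_blocks():
    rng = np.random.default_rng(9)
    dosage = rng.choice([0, 1, 2], size=(150, 10), p=[0.25, 0.5, 0.25])
    G = make_genotypes(dosage, positions=(np.arange(10) + 1) * 20_000)
    assert len(find_blocks(G)) == 0


def test_block_summary_arithmetic():
    blocks = [
        HaploBlock(1, 100_000, 200_000, ["a", "b"]),
        HaploBlock(1, 300_000, 340_000, ["c", "d", "e", "f"]),
    ]
    G = make_genotypes(np.zeros((2, 12), dtype=np.int8))
    s = block_summary(blocks, G)
    assert s.n_blocks == 2
    assert s.mean_snps_per_block == pytest.approx(3.0)
    assert s.max_snps_per_block == 4
    assert s.coverage_mb == pytest.approx(0.14)
    assert s.mean_len_kb == pytest.approx(70.0)
    assert s.pct_snps_in_blocks == pytest.approx(100 * 6 / 12)


def test_block_summary_single_block_and_empty():
    G = make_genotypes(np.zeros((2, 2), dtype=np.int8))
    one = block_summary([HaploBlock(1, 50_000, 150_000, ["a", "b"])], G)
    assert one.coverage_mb == pytest.approx(0.1)
    assert one.pct_snps_in_blocks == pytest.approx(100.0)
    empty = block_summary([], G)
    assert empty.n_blocks == 0 and np.isnan(empty.mean_len_kb)
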