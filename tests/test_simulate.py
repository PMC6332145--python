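"""Wright-Fisher simulator: determinism, truth identities, drift behaviour."""

import numpy as np
import pytest

from ldscape import (
    MISSING,
    SimConfig,
    add_missingness,
    simulate_admixture,
    simulate_population,
)
from ldscape.simulate import _wf_generation, _switch_probs


SMALL = dict(N=30, n_chrom=2, n_sites=20, chrom_length_bp=500_000, generations=40)


def test_same_seed_reproduces_genotypes_exactly():
    a, _ = simulate_population(SimConfig(seed=77, **SMALL))
    b, _ = simulate_population(SimConfig(seed=77, **SMALL))
    assert np.array_equal(a.dosage, b.dosage)
    c, _ = simulate_population(SimConfig(seed=78, **SMALL))
    assert not np.array_equal(a.dosage, c.dosage)


def test_no_recombination_no_mutation_preserves_complete_ld():
    """Two sites starting in complete LD stay in complete LD without c or mu."""
    rng = np.random.default_rng(0)
    H = np.zeros((60, 2), dtype=bool)
    carrier = rng.random(60) < 0.4
    H[carrier] = True  # haplotypes either (1,1) or (0,0): r2 = 1
    q = _switch_probs(np.array([1, 400_000]), rec_rate=0.0)
    for _ in range(80):
        H = _wf_generation(H, q, 0.0, rng)
    f = H.mean(axis=0)
    if 0 < f[0] < 1:  # only defined while both segregate
        assert np.array_equal(H[:, 0], H[:, 1])


def test_truth_r2_equals_direct_haplotype_frequency_formula():
    """Pool r2 matches D = pAB*pab - pAb*paB pushed through the r formula."""
    _, truth = simulate_population(SimConfig(seed=5, **SMALL))
    rec = truth.pairwise_r2(1_000_000)
    pool = truth.pools[0]
    sub = truth.variants[truth.variants["chrom"] == 1]
    pos_of = dict(zip(sub["vid"], range(len(sub))))
    checked = 0
    for row in rec[rec["chrom"] == 1].head(40).itertuples():
        i, j = pos_of[row.i_vid], pos_of[row.j_vid]
        a, b = pool[:, i], pool[:, j]
        pAB = np.mean(a & b)
        pAb = np.mean(a & ~b)
        paB = np.mean(~a & b)
        pab = np.mean(~a & ~b)
        D = pAB * pab - pAb * paB
        pA, pB = pAB + pAb, pAB + paB
        r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
        assert row.r2 == pytest.approx(r2, abs=1e-12)
        checked += 1
    assert checked > 10


def test_allele_frequency_is_a_martingale_under_pure_drift():
    """Mean frequency change per generation ~ 0 across replicate populations."""
    rng = np.random.default_rng(1)
    q = _switch_probs(np.array([1, 200_000, 400_000]), rec_rate=1e-8)
    deltas = []
    for _ in range(200):
        p0 = rng.uniform(0.2, 0.5, 3)
        H = rng.random((40, 3)) < p0
        start = H.mean(axis=0)
        H = _wf_generation(H, q, 0.0, rng)
        deltas.append(H.mean(axis=0) - start)
    mean_delta = np.mean(deltas)
    # 600 site-replicates, per-site sd ~ sqrt(p q / 2N) ~ 0.077
    assert abs(mean_delta) < 4 * 0.077 / np.sqrt(600)


def test_sample_r2_converges_to_truth_with_sample_size():
    cfg = SimConfig(N=150, n_chrom=3, n_sites=25, chrom_length_bp=1_000_000,
                    generations=150, seed=42)
    _, truth = simulate_population(cfg)
    tru = truth.pairwise_r2(1_000_000).set_index(["i_vid", "j_vid"])["r2"]
    from ldscape import pairwise_ld
    from ldscape.simulate import sample_pool

    rmse = {}
    for k, n_s in enumerate((25, 50, 140)):
        rng = np.random.default_rng(100 + k)
        G = sample_pool(truth.pools, truth.variants, n_s, rng, "s")
        rec = pairwise_ld(G).set_index(["i_vid", "j_vid"])["r2"]
        common = tru.index.intersection(rec.index)
        rmse[n_s] = float(np.sqrt(np.mean((rec[common] - tru[common]) ** 2)))
    assert rmse[140] < rmse[25]


def test_admixture_generation_zero_haplotypes_are_unmixed():
    """With no crossing rounds each gamete is wholly from one source pool."""
    base = dict(N=40, n_chrom=1, n_sites=12, chrom_length_bp=500_000,
                generations=0)
    _, tA = simulate_population(SimConfig(seed=1, site_init=(0.95, 0.99), **base))
    _, tB = simulate_population(SimConfig(seed=2, site_init=(0.01, 0.05), **base))
    # Pools are nearly fixed for opposite alleles, so origin is identifiable.
    _, t_mix = simulate_admixture(tA, tB, founder_prop=0.5,
                                  cross_generations=0, sample_n=20, seed=3)
    frac_alt = t_mix.pools[0].mean(axis=1)
    # unmixed haplotypes are bimodal: none sits in the central band
    assert not ((frac_alt > 0.35) & (frac_alt < 0.65)).any()
    assert (frac_alt > 0.5).any() and (frac_alt < 0.5).any()


def test_admixture_requires_matching_variant_maps():
    _, tA = simulate_population(SimConfig(seed=1, **SMALL))
    other = dict(SMALL, n_sites=SMALL["n_sites"] + 1)
    _, tB = simulate_population(SimConfig(seed=2, **other))
    with pytest.raises(ValueError, match="variant map"):
        simulate_admixture(tA, tB)


def test_founder_prop_one_keeps_pool_a_allele_content():
    base = dict(N=40, n_chrom=1, n_sites=12, chrom_length_bp=500_000,
                generations=0)
    _, tA = simulate_population(SimConfig(seed=1, site_init=(0.9, 0.95), **base))
    _, tB = simulate_population(SimConfig(seed=2, site_init=(0.05, 0.1), **base))
    _, t_mix = simulate_admixture(tA, tB, founder_prop=1.0,
                                  cross_generations=2, sample_n=20, seed=3)
    # All material from pool A (high-frequency sites) - pool B never drawn.
    assert t_mix.pools[0].mean() > 0.7


def test_add_missingness_rate_zero_is_identity_and_seeded():
    G, _ = simulate_population(SimConfig(seed=10, **SMALL))
    same = add_missingness(G, 0.0, seed=1)
    assert np.array_equal(same.dosage, G.dosage)
    a = add_missingness(G, 0.5, seed=2)
    b = add_missingness(G, 0.5, seed=2)
    assert np.array_equal(a.dosage == MISSING, b.dosage == MISSING)
    n_cells = a.dosage.size
    frac = (a.dosage == MISSING).mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_cells)
    with pytest.raises(ValueError):
        add_missingness(G, 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(N=1)
    with pytest.raises(ValueError):
        SimConfig(n_sites=1)
    with pytest.raises(ValueError):
        SimConfig(rec_rate=-1e-8)
    with pytest.raises(ValueError):
        SimConfig(N=10, sample_n=11)
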