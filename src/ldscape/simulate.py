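"""Forward Wright-Fisher genotype simulation with known truth.

Populations of 2N haplotypes evolve by random union of gametes with
recombination and optional symmetric mutation over a fixed biallelic site
list.  Sites are initialised at linkage equilibrium with allele frequencies
drawn uniformly from a configurable band, so burn-in generations let drift
and recombination build the equilibrium LD structure E[r2] ~ 1/(1 + 4Nc)
that the LD-based Ne machinery assumes.  Chromosomes are simulated
independently (no inter-chromosomal LD, which no downstream stage uses).

Recombination is implemented as the crossover process restricted to the
observed sites: a gamete switches parental haplotype between adjacent sites
with probability (1 - exp(-2*rec*d))/2, the probability of an odd crossover
count in an interval of d bp under a Poisson crossover process of intensity
``rec`` per bp -- marginally identical to drawing Poisson crossover counts
at uniform positions, and vectorisable.

An admixture operation crosses two source haplotype pools for a configurable
number of generations to emulate a crossbred cohort, and a missingness
operation exercises the call-rate QC filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Wright-Fisher simulation settings.

    N: diploid population size; generations: burn-in length (default 4N);
    chrom_length_bp / n_sites: map geometry (sites evenly spaced);
    site_init: (lo, hi) band for initial allele frequencies; rec_rate:
    Morgans per bp per generation (1e-8 = 1 cM/Mb); mu: per-site flip
    probability per generation; sample_n: sampled diploids (default N);
    n_chrom: independently simulated chromosomes.
    """

    N: int = 100
    generations: int | None = None
    chrom_length_bp: int = 2_000_000
    n_sites: int = 45
    site_init: tuple[float, float] = (0.05, 0.5)
    rec_rate: float = 1e-8
    mu: float = 0.0
    sample_n: int | None = None
    n_chrom: int = 24
    seed: int = 0
    population: str = "sim"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.rec_rate < 0:
            raise ValueError("rec_rate must be >= 0")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must be in [0, 1)")
        if self.sample_n is not None and self.sample_n > self.N:
            raise ValueError("sample_n cannot exceed N")
        if self.generations is not None and self.generations < 0:
            raise ValueError("generations must be >= 0")

    @property
    def burn_in(self) -> int:
        return 4 * self.N if self.generations is None else self.generations

    @property
    def n_sampled(self) -> int:
        return self.N if self.sample_n is None else self.sample_n


@dataclass
class TruthTable:
    """Exact per-population truth from the full 2N-haplotype pool.

    ``pools[k]`` is the (2N, n_sites) boolean haplotype array of chromosome
    k+1 (True = allele2); ``variants`` is the shared variant table.
    """

    variants: pd.DataFrame
    pools: list[np.ndarray] = field(repr=False)
    rec_rate: float = 1e-8

    def allele_freq(self) -> np.ndarray:
        """True allele2 frequency per site, in variant-table order."""
        return np.concatenate([pool.mean(axis=0) for pool in self.pools])

    def pairwise_r2(self, max_dist_bp: int = 1_000_000) -> pd.DataFrame:
        """Exact r (signed) and r2 per intra-chromosomal pair from pool counts.

        Haplotype frequencies are counted exactly from the pool and pushed
        through D = pAB*pab - pAb*paB, r = D/sqrt(pA*pa*pB*pb); monomorphic
        loci give undefined LD and are skipped.
        """
        from .ld import _window_pairs

        frames = []
        for k, pool in enumerate(self.pools):
            sub = self.variants[self.variants["chrom"] == k + 1]
            pos = sub["pos"].to_numpy()
            vids = sub["vid"].to_numpy()
            ii, jj = _window_pairs(pos, max_dist_bp)
            if ii.size == 0:
                continue
            two_n = pool.shape[0]
            hap = pool.astype(np.float64)
            pAB = (hap[:, ii] * hap[:, jj]).sum(axis=0) / two_n
            pA = hap[:, ii].mean(axis=0)
            pB = hap[:, jj].mean(axis=0)
            D = pAB - pA * pB  # equals pAB*pab - pAb*paB
            var = pA * (1 - pA) * pB * (1 - pB)
            ok = var > 0
            r = D[ok] / np.sqrt(var[ok])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": k + 1,
                        "i_vid": vids[ii[ok]],
                        "j_vid": vids[jj[ok]],
                        "dist_bp": (pos[jj] - pos[ii])[ok],
                        "r": r,
                        "r2": r * r,
                    }
                )
            )
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "i_vid", "j_vid", "dist_bp", "r", "r2"])
        )


def _switch_probs(pos: np.ndarray, rec_rate: float) -> np.ndarray:
    """Per-interval parental-switch probabilities (odd crossover count)."""
    d = np.diff(pos).astype(float)
    return 0.5 * (1.0 - np.exp(-2.0 * rec_rate * d))


def _wf_generation(
    H: np.ndarray, q_switch: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """One generation: every offspring haplotype is a recombinant gamete of
    two uniformly chosen parental haplotypes, then mutated."""
    n_hap, n_sites = H.shape
    pa = rng.integers(0, n_hap, n_hap)
    pb = rng.integers(0, n_hap, n_hap)
    take_a = np.empty((n_hap, n_sites), dtype=bool)
    take_a[:, 0] = rng.random(n_hap) < 0.5
    if n_sites > 1:
        take_a[:, 1:] = rng.random((n_hap, n_sites - 1)) < q_switch
        np.logical_xor.accumulate(take_a, axis=1, out=take_a)
    child = np.where(take_a, H[pa], H[pb])
    if mu > 0:
        child ^= rng.random((n_hap, n_sites)) < mu
    return child


def _chrom_positions(config: SimConfig) -> np.ndarray:
    return np.round(np.linspace(1, config.chrom_length_bp, config.n_sites)).astype(
        np.int64
    )


def _variant_table(config: SimConfig) -> pd.DataFrame:
    pos = _chrom_positions(config)
    rows = []
    for chrom in range(1, config.n_chrom + 1):
        for k, p in enumerate(pos):
            rows.append((chrom, int(p), f"c{chrom}s{k}", "A", "B"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "vid", "allele1", "allele2"])


def sample_pool(
    pools: list[np.ndarray],
    variants: pd.DataFrame,
    sample_n: int,
    rng: np.random.Generator,
    population: str,
) -> GenotypeMatrix:
    """Form ``sample_n`` diploids from 2*sample_n haplotypes drawn without
    replacement from each chromosome pool."""
    cols = []
    for pool in pools:
        idx = rng.permutation(pool.shape[0])[: 2 * sample_n]
        cols.append(pool[idx[0::2]].astype(np.int8) + pool[idx[1::2]].astype(np.int8))
    dosage = np.concatenate(cols, axis=1)
    samples = pd.DataFrame(
        {
            "iid": [f"{population}_{i}" for i in range(sample_n)],
            "population": population,
        }
    )
    return GenotypeMatrix(samples, variants.copy(), dosage)


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Burn in a constant-N Wright-Fisher population and sample genotypes.

    Returns the sampled :class:`GenotypeMatrix` and the :class:`TruthTable`
    holding the full post-burn-in haplotype pools.  Fully reproducible from
    ``config.seed``.  Sites fixed during burn-in are retained (the MAF filter
    removes them downstream, exercising QC realistically).
    """
    variants = _variant_table(config)
    pos = _chrom_positions(config)
    q_switch = _switch_probs(pos, config.rec_rate)
    root = np.random.SeedSequence(config.seed)
    chrom_seeds = root.spawn(config.n_chrom + 1)

    pools = []
    for k in range(config.n_chrom):
        rng = np.random.default_rng(chrom_seeds[k])
        p0 = rng.uniform(*config.site_init, config.n_sites)
        H = rng.random((2 * config.N, config.n_sites)) < p0
        for _ in range(config.burn_in):
            H = _wf_generation(H, q_switch, config.mu, rng)
        pools.append(H)

    truth = TruthTable(variants=variants, pools=pools, rec_rate=config.rec_rate)
    sample_rng = np.random.default_rng(chrom_seeds[-1])
    G = sample_pool(pools, variants, config.n_sampled, sample_rng, config.population)
    return G, truth


def simulate_admixture(
    truth_A: TruthTable,
    truth_B: TruthTable,
    founder_prop: float = 0.5,
    cross_generations: int = 3,
    sample_n: int = 45,
    seed: int = 0,
    population: str = "crossbred",
    founder_haplotypes: int | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Cross two source pools into an admixed cohort.

    Each founder haplotype is drawn from pool A with probability
    ``founder_prop``, else from pool B (so at ``cross_generations = 0`` every
    sampled haplotype is wholly A or wholly B); the founder population
    (``founder_haplotypes`` haplotypes, default the pool-A size) then mates
    randomly with recombination for ``cross_generations`` rounds.  Both
    sources must share the variant map.
    """
    if not truth_A.variants[["chrom", "pos", "vid"]].equals(
        truth_B.variants[["chrom", "pos", "vid"]]
    ):
        raise ValueError("source pools must share an identical variant map")
    if not 0.0 <= founder_prop <= 1.0:
        raise ValueError("founder_prop must be in [0, 1]")

    root = np.random.SeedSequence(seed)
    chrom_seeds = root.spawn(len(truth_A.pools) + 1)
    pools = []
    for k, (pool_a, pool_b) in enumerate(zip(truth_A.pools, truth_B.pools)):
        rng = np.random.default_rng(chrom_seeds[k])
        sub = truth_A.variants[truth_A.variants["chrom"] == k + 1]
        q_switch = _switch_probs(sub["pos"].to_numpy(), truth_A.rec_rate)
        n_hap = founder_haplotypes if founder_haplotypes else pool_a.shape[0]
        from_a = rng.random(n_hap) < founder_prop
        H = np.where(
            from_a[:, None],
            pool_a[rng.integers(0, pool_a.shape[0], n_hap)],
            pool_b[rng.integers(0, pool_b.shape[0], n_hap)],
        )
        for _ in range(cross_generations):
            H = _wf_generation(H, q_switch, 0.0, rng)
        pools.append(H)

    truth = TruthTable(
        variants=truth_A.variants.copy(), pools=pools, rec_rate=truth_A.rec_rate
    )
    sample_rng = np.random.default_rng(chrom_seeds[-1])
    G = sample_pool(pools, truth.variants, sample_n, sample_rng, population)
    return G, truth


def add_missingness(G: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each genotype to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return GenotypeMatrix(G.samples.copy(), G.variants.copy(), G.dosage.copy())
    rng = np.random.default_rng(seed)
    dosage = G.dosage.copy()
    dosage[rng.random(dosage.shape) < rate] = MISSING
    return GenotypeMatrix(G.samples.copy(), G.variants.copy(), dosage)


def paper_shaped_fixture(seed: int = 0, n_chrom: int = 24) -> dict:
    """The default two-population study-shaped fixture.

    A "purebred" cohort (N = 200, burn-in 4N) and a "crossbred" cohort formed
    by admixing a descendant of the purebred pool with an independent N = 100
    population (founder proportion 0.5, three crossing generations, 45
    sampled individuals), on 24 chromosomes of 2 Mb with 45 evenly spaced
    SNPs (~45 kb spacing), 1 cM/Mb, recurrent symmetric mutation (1e-4 per
    site per generation) to keep the MAF spectrum populated through the
    burn-in, plus 2% random missingness.  The shared
    purebred ancestry of one source pool gives the two cohorts an ancestral
    LD phase that decays with inter-marker distance.
    """
    ss = np.random.SeedSequence(seed)
    s_pure, s_desc, s_indep, s_cross, s_miss1, s_miss2 = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    )
    pure_cfg = SimConfig(
        N=200, n_chrom=n_chrom, seed=s_pure, population="purebred", mu=1e-4
    )
    G_pure, truth_pure = simulate_population(pure_cfg)

    # Source pool 1: an N = 100 descendant of the purebred population.
    _, truth_source1 = simulate_admixture(
        truth_pure,
        truth_pure,
        founder_prop=1.0,
        cross_generations=20,
        sample_n=2,
        seed=s_desc,
        population="sourceA",
        founder_haplotypes=200,
    )
    # Source pool 2: an independent N = 100 population.
    indep_cfg = SimConfig(
        N=100, n_chrom=n_chrom, seed=s_indep, population="sourceB", mu=1e-4
    )
    _, truth_source2 = simulate_population(indep_cfg)

    G_cross, truth_cross = simulate_admixture(
        truth_source1,
        truth_source2,
        founder_prop=0.5,
        cross_generations=3,
        sample_n=45,
        seed=s_cross,
        population="crossbred",
    )

    return {
        "purebred": add_missingness(G_pure, 0.02, seed=s_miss1),
        "crossbred": add_missingness(G_cross, 0.02, seed=s_miss2),
        "truth_purebred": truth_pure,
        "truth_crossbred": truth_cross,
    }
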