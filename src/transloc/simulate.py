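"""Forward simulator for source populations, founder draws and
post-translocation drift.

Source genotypes are drawn under Hardy-Weinberg from per-locus symmetric
Dirichlet frequencies; MHC variation is generated as a small set of
duplicated diploid loci with overlapping allele pools whose union per
individual is observed as a zygosity-free allele set; translocations are
discrete Wright-Fisher generations with deterministic logistic-style growth
N_{t+1} = min(K, round(lambda * N_t)).  No mutation, no migration.

The ``warbler`` preset is calibrated to a low-diversity source: 30 loci,
expected heterozygosity near 0.49, about 2.9 alleles per locus, 10 MHC
alleles over 4 duplicated loci with 2-8 alleles per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .popdata import GenotypeTable, MhcProfileSet, SampleFrame

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_source: int = 163
    allele_counts: tuple[int, ...] = tuple([2] * 14 + [3] * 9 + [4] * 4 + [5] * 2 + [6])
    dirichlet_alpha: float = 1.5
    missing_rate: float = 0.0
    source_pop: str = "source"
    source_year: int = 2011
    mhc_universe: int = 10
    mhc_loci: int = 4
    mhc_seq_len: int = 255
    mhc_mutations_per_allele: int = 10
    mhc_dirichlet_alpha: float = 1.0
    mhc_pools: tuple[tuple[int, ...], ...] | None = None  # allele indices per locus

    def __post_init__(self):
        if self.n_source < 2 or not self.allele_counts:
            raise SimulationError("invalid source size or locus list")
        if any(k < 1 for k in self.allele_counts):
            raise SimulationError("allele counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.mhc_loci < 1 or self.mhc_universe < 1:
            raise SimulationError("need at least one MHC locus and allele")
        if self.mhc_pools is not None:
            if len(self.mhc_pools) != self.mhc_loci:
                raise SimulationError("mhc_pools must give one pool per locus")
            for pool in self.mhc_pools:
                if not pool or any(not 0 <= a < self.mhc_universe for a in pool):
                    raise SimulationError("mhc_pools entries must index the universe")
        elif self.mhc_universe < self.mhc_loci:
            raise SimulationError("default pools need universe >= loci")


def warbler_preset(seed: int = 0) -> SimConfig:
    """Defaults tuned to the low-diversity source described above."""
    return SimConfig(seed=seed)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeTable
    frame: SampleFrame
    mhc: MhcProfileSet | None = None
    truth: dict = field(default_factory=dict)


def _ids(pop: str, year: int, n: int) -> list[str]:
    return [f"{pop}_{year}_{i:04d}" for i in range(n)]


def _hwe_genotypes(rng, freqs: list[np.ndarray], labels: list[np.ndarray], n: int):
    calls = np.zeros((n, len(freqs), 2), dtype=np.int64)
    for j, (f, lab) in enumerate(zip(freqs, labels)):
        calls[:, j, :] = rng.choice(lab, size=(n, 2), p=f)
    return calls


def simulate_source(config: SimConfig) -> SimulatedDataset:
    """Source population under HWE with Dirichlet allele frequencies."""
    rng = np.random.default_rng(config.seed)
    L = len(config.allele_counts)
    loci = tuple(f"loc{j + 1:02d}" for j in range(L))
    labels = [100 + 2 * np.arange(k) for k in config.allele_counts]
    freqs = [
        rng.dirichlet(np.full(k, config.dirichlet_alpha))
        for k in config.allele_counts
    ]
    n = config.n_source
    calls = _hwe_genotypes(rng, freqs, labels, n)
    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        calls[miss] = 0
    ids = _ids(config.source_pop, config.source_year, n)
    table = GenotypeTable(tuple(ids), loci, calls)
    frame = SampleFrame({i: (config.source_pop, config.source_year) for i in ids})
    truth = {
        "config": config,
        "frequencies": {
            loci[j]: {int(a): float(p) for a, p in zip(labels[j], freqs[j])}
            for j in range(L)
        },
    }
    return SimulatedDataset(table, frame, None, truth)


def _default_pools(universe: int, n_loci: int) -> list[np.ndarray]:
    """Overlapping sliding-window pools with empty global intersection."""
    size = max(2, universe // n_loci + 1)
    starts = np.linspace(0, universe, n_loci, endpoint=False).astype(int)
    return [np.arange(s, s + size) % universe for s in starts]


def simulate_mhc(config: SimConfig, dataset: SimulatedDataset) -> SimulatedDataset:
    """Attach MHC profiles: duplicated diploid loci, observed as allele sets.

    Allele sequences are generated by mutating a random root sequence at a
    fixed number of positions per allele, so pairwise differences are
    roughly twice that number.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    U = config.mhc_universe
    names = tuple(f"A{i + 1:02d}" for i in range(U))
    root = rng.choice(_BASES, size=config.mhc_seq_len)
    sequences = {}
    for name in names:
        seq = root.copy()
        pos = rng.choice(config.mhc_seq_len, size=config.mhc_mutations_per_allele,
                         replace=False)
        for p in pos:
            choices = _BASES[_BASES != seq[p]]
            seq[p] = rng.choice(choices)
        sequences[name] = "".join(seq)

    if config.mhc_pools is not None:
        pools = [np.array(pool, dtype=int) for pool in config.mhc_pools]
    else:
        pools = _default_pools(U, config.mhc_loci)
    pool_freqs = [
        rng.dirichlet(np.full(len(pool), config.mhc_dirichlet_alpha))
        for pool in pools
    ]
    inds = dataset.genotypes.individuals
    n = len(inds)
    latent = np.zeros((n, config.mhc_loci, 2), dtype=np.int64)
    for j, (pool, f) in enumerate(zip(pools, pool_freqs)):
        latent[:, j, :] = rng.choice(pool, size=(n, 2), p=f)
    profiles = {
        ind: frozenset(names[a] for a in latent[i].ravel())
        for i, ind in enumerate(inds)
    }
    mhc = MhcProfileSet(profiles, names, sequences)
    truth = dict(dataset.truth)
    truth["mhc_latent"] = {ind: latent[i].copy() for i, ind in enumerate(inds)}
    truth["mhc_pools"] = [pool.tolist() for pool in pools]
    truth["mhc_pool_frequencies"] = [f.tolist() for f in pool_freqs]
    return SimulatedDataset(dataset.genotypes, dataset.frame, mhc, truth)


def _impute_missing(calls: np.ndarray, rng) -> np.ndarray:
    """Replace missing founder calls by draws from the founder gene pool."""
    out = calls.copy()
    for j in range(calls.shape[1]):
        col = out[:, j, :]
        miss = col == 0
        if not miss.any():
            continue
        pool = col[col != 0]
        if len(pool) == 0:
            raise SimulationError(f"locus column {j} entirely missing among founders")
        col[miss] = rng.choice(pool, size=int(miss.sum()))
    return out


def _wf_generation(rng, geno: np.ndarray, n_next: int) -> np.ndarray:
    """One discrete generation: each offspring unites two random gametes."""
    n, L, _ = geno.shape
    mothers = rng.integers(0, n, size=n_next)
    fathers = rng.integers(0, n, size=n_next)
    pick_m = rng.integers(0, 2, size=(n_next, L))
    pick_f = rng.integers(0, 2, size=(n_next, L))
    child = np.empty((n_next, L, 2), dtype=geno.dtype)
    cols = np.arange(L)
    child[:, :, 0] = geno[mothers[:, None], cols[None, :], pick_m]
    child[:, :, 1] = geno[fathers[:, None], cols[None, :], pick_f]
    return child


def simulate_translocation(
    dataset: SimulatedDataset,
    n_founders: int,
    generations: int,
    growth_rate: float = 2.0,
    carrying_capacity: int = 300,
    seed: int | None = None,
    pop: str = "new",
    base_year: int = 2012,
    snapshot_generations: tuple[int, ...] | None = None,
    sample_size: int | None = None,
    source_pop: str | None = None,
) -> SimulatedDataset:
    """Found a new population from the source and let it drift.

    Founders are drawn uniformly without replacement from the source
    population; generation t maps to catch year ``base_year + t``.
    Snapshots (default: the final generation only; generation 0 is the
    founder cohort itself) are appended to the dataset as new individuals
    with their own strata.  Alleles absent among founders can never
    reappear (no mutation).
    """
    if growth_rate < 1:
        raise SimulationError("growth_rate must be >= 1")
    rng = np.random.default_rng(seed)
    src_pop = source_pop or dataset.truth["config"].source_pop
    source_ids = dataset.frame.population_individuals(src_pop)
    if n_founders > len(source_ids):
        raise SimulationError("more founders than source individuals")
    founder_ids = list(
        rng.choice(np.array(source_ids, dtype=object), size=n_founders, replace=False)
    )
    table = dataset.genotypes
    idx = [table.individuals.index(i) for i in founder_ids]
    geno = _impute_missing(table.calls[idx], rng)
    mhc_latent = None
    if dataset.mhc is not None:
        mhc_latent = np.stack(
            [dataset.truth["mhc_latent"][i] for i in founder_ids]
        )

    if snapshot_generations is None:
        snapshot_generations = (generations,)
    snaps = sorted(set(int(g) for g in snapshot_generations))
    if any(g < 0 or g > generations for g in snaps):
        raise SimulationError("snapshot generations outside [0, generations]")

    new_inds: list[str] = []
    new_calls: list[np.ndarray] = []
    new_assign: dict[str, tuple[str, int]] = {}
    new_profiles: dict[str, frozenset] = {}
    new_latent: dict[str, np.ndarray] = {}
    traj = [n_founders]

    def take_snapshot(gen: int, geno_now, latent_now):
        year = base_year + gen
        n_now = geno_now.shape[0]
        if sample_size is not None and sample_size < n_now:
            keep = rng.choice(n_now, size=sample_size, replace=False)
        else:
            keep = np.arange(n_now)
        ids = _ids(pop, year, len(keep))
        new_inds.extend(ids)
        new_calls.append(geno_now[keep])
        for i in ids:
            new_assign[i] = (pop, year)
        if latent_now is not None:
            names = dataset.mhc.universe
            for row, i in zip(keep, ids):
                new_latent[i] = latent_now[row].copy()
                new_profiles[i] = frozenset(
                    names[a] for a in latent_now[row].ravel()
                )

    if 0 in snaps:
        take_snapshot(0, geno, mhc_latent)
    n_now = n_founders
    for gen in range(1, generations + 1):
        n_next = min(carrying_capacity, int(round(growth_rate * n_now)))
        seeds = rng.integers(0, 2 ** 31, size=2)
        geno = _wf_generation(np.random.default_rng(seeds[0]), geno, n_next)
        if mhc_latent is not None:
            mhc_latent = _wf_generation(
                np.random.default_rng(seeds[1]), mhc_latent, n_next
            )
        n_now = n_next
        traj.append(n_now)
        if gen in snaps:
            take_snapshot(gen, geno, mhc_latent)

    merged_calls = np.concatenate([table.calls] + new_calls, axis=0)
    merged = GenotypeTable(
        table.individuals + tuple(new_inds), table.loci, merged_calls
    )
    assignments = dict(dataset.frame.assignments)
    assignments.update(new_assign)
    mhc = dataset.mhc
    truth = dict(dataset.truth)
    if mhc is not None:
        profiles = dict(mhc.profiles)
        profiles.update(new_profiles)
        mhc = MhcProfileSet(profiles, mhc.universe, mhc.sequences, mhc.size_range)
        latents = dict(truth["mhc_latent"])
        latents.update(new_latent)
        truth["mhc_latent"] = latents
    founders_key = f"founders_{pop}"
    truth[founders_key] = founder_ids
    truth[f"trajectory_{pop}"] = traj
    return SimulatedDataset(merged, SampleFrame(assignments), mhc, truth)


def constant_size_run(
    config: SimConfig,
    n: int,
    generations: int,
    seed: int | None = None,
    pop: str = "wf",
) -> SimulatedDataset:
    """Convenience: found a constant-size WF population of size n from a
    fresh source and return the dataset with snapshots at the last
    generation."""
    cfg = replace(config, n_source=max(n, config.n_source))
    src = simulate_source(cfg)
    return simulate_translocation(
        src, n_founders=n, generations=generations, growth_rate=1.0,
        carrying_capacity=n, seed=seed, pop=pop,
    )
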