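"""Differentiation statistics among population x year strata.

Pairwise F_ST uses the Weir & Cockerham (1984) theta estimator (variance
components a, b, c; ratio of sums across loci and alleles) for diploid
microsatellite data, and its haploid analogue on MHC carrier counts.
Jost's D uses Nei-Chesser-corrected H_S / H_T.  The global test of identical
allele distributions across strata is a permutation G-test, and matrix
correspondence is assessed with a Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np

from .popdata import MISSING, GenotypeTable, MhcProfileSet, PopDataError, subset

__all__ = [
    "weir_cockerham_theta",
    "pairwise_fst",
    "jost_d",
    "pairwise_dest",
    "global_exact_test",
    "mantel",
    "pairwise_matrix",
    "DistanceMatrix",
]


class DifferentiationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _locus_pop_stats(tables: list[GenotypeTable], locus: str):
    """Per-population sample sizes, allele frequencies and het frequencies."""
    alleles = sorted({a for t in tables for a in t.allele_counts(locus)})
    if len(alleles) < 2:
        return None
    ns, freqs, hets = [], [], []
    for t in tables:
        j = t.locus_index(locus)
        col = t.calls[:, j, :]
        mask = col[:, 0] != MISSING
        ni = int(mask.sum())
        if ni == 0:
            return None
        pairs = col[mask]
        ns.append(ni)
        counts = np.array(
            [(pairs == a).sum() for a in alleles], dtype=float
        )
        freqs.append(counts / (2 * ni))
        het = np.array(
            [((pairs[:, 0] == a) ^ (pairs[:, 1] == a)).sum() for a in alleles],
            dtype=float,
        )
        hets.append(het / ni)
    return np.array(ns, float), np.vstack(freqs), np.vstack(hets)


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per allele.

    n: (r,) sample sizes (individuals for diploid, gene copies for haploid);
    p: (r, k) allele frequencies; h: (r, k) observed heterozygote
    frequencies, or None for the haploid analogue (h == 0, c == 0).
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    if h is None:
        hbar = np.zeros_like(pbar)
    else:
        hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def weir_cockerham_theta(tables: list[GenotypeTable]) -> float:
    """Multi-locus WC84 theta across the given per-stratum genotype tables.

    Ratio of sums of the a component over a+b+c, pooled across loci and
    alleles; loci monomorphic over all strata are skipped.
    """
    if len(tables) < 2:
        raise DifferentiationError("need >= 2 strata")
    for t in tables:
        if t.n_individuals < 2:
            raise DifferentiationError("each stratum needs >= 2 individuals")
    loci = tables[0].loci
    num = den = 0.0
    informative = False
    for locus in loci:
        stats = _locus_pop_stats(tables, locus)
        if stats is None:
            continue
        n, p, h = stats
        if (n < 2).any():
            continue
        a, b, c = _wc_components(n, p, h)
        num += a.sum()
        den += (a + b + c).sum()
        informative = True
    if not informative or den == 0:
        raise DifferentiationError("no informative (polymorphic) locus")
    return float(num / den)


def _mhc_haploid_theta(sets: list[MhcProfileSet]) -> float:
    """Haploid-analogue WC theta on carrier counts (one gene copy per carrier)."""
    universe = sets[0].universe
    counts = np.array(
        [[s.carrier_counts()[a] for a in universe] for s in sets], dtype=float
    )
    n = counts.sum(axis=1)
    if (n < 2).any():
        raise DifferentiationError("each stratum needs >= 2 carrier observations")
    p = counts / n[:, None]
    poly = (counts.sum(axis=0) > 0).sum() >= 2
    if not poly:
        raise DifferentiationError("no informative (polymorphic) allele")
    a, b, _ = _wc_components(n, p, None)
    den = (a + b).sum()
    if den == 0:
        raise DifferentiationError("degenerate carrier counts")
    return float(a.sum() / den)


def _theta_of(samples) -> float:
    if isinstance(samples[0], GenotypeTable):
        return weir_cockerham_theta(samples)
    return _mhc_haploid_theta(samples)


def _split_like(pooled, sizes: list[int], order: np.ndarray):
    """Re-partition pooled individuals into pseudo-strata of the given sizes."""
    if isinstance(pooled, GenotypeTable):
        inds = np.array(pooled.individuals, dtype=object)
    else:
        inds = np.array(list(pooled.profiles), dtype=object)
    out, start = [], 0
    for s in sizes:
        ids = list(inds[order[start:start + s]])
        out.append(pooled.subset(ids))
        start += s
    return out


def _pool(samples):
    if isinstance(samples[0], GenotypeTable):
        loci = samples[0].loci
        for t in samples[1:]:
            if t.loci != loci:
                raise DifferentiationError("strata must share loci")
        return GenotypeTable(
            tuple(i for t in samples for i in t.individuals),
            loci,
            np.concatenate([t.calls for t in samples], axis=0),
        )
    universe = samples[0].universe
    profiles = {}
    for s in samples:
        if s.universe != universe:
            raise DifferentiationError("strata must share the allele universe")
        profiles.update(s.profiles)
    return MhcProfileSet(profiles, universe, samples[0].sequences, samples[0].size_range)


@dataclass(frozen=True)
class PairwiseResult:
    statistic: str
    value: float
    p_value: float | None
    permutations: int
    seed: int | None


def pairwise_fst(
    data,
    frame,
    strata_pair,
    permutations: int = 9_999,
    seed: int | None = None,
) -> PairwiseResult:
    """WC theta between two strata with a permutation P value.

    Individuals are permuted between the strata and theta recomputed;
    P = (1 + #{theta* >= theta_obs}) / (permutations + 1).
    """
    samples = [subset(data, frame, s) for s in strata_pair]
    if len(samples) != 2:
        raise DifferentiationError("strata_pair must name exactly two strata")
    theta = _theta_of(samples)
    if permutations <= 0:
        return PairwiseResult("fst", theta, None, 0, seed)
    pooled = _pool(samples)
    sizes = [
        s.n_individuals if isinstance(s, GenotypeTable) else len(s.profiles)
        for s in samples
    ]
    rng = np.random.default_rng(seed)
    total = sum(sizes)
    extreme = 0
    for _ in range(permutations):
        order = rng.permutation(total)
        try:
            t_star = _theta_of(_split_like(pooled, sizes, order))
        except DifferentiationError:
            t_star = np.inf  # degenerate shuffle counts as extreme
        if t_star >= theta:
            extreme += 1
    p = (1 + extreme) / (permutations + 1)
    return PairwiseResult("fst", theta, p, permutations, seed)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_d_from_frequencies(
    p: np.ndarray, n_individuals: np.ndarray, clamp: bool = True
) -> float:
    """Per-locus Jost's D for s strata with Nei-Chesser-corrected H_S, H_T.

    p: (s, k) allele frequencies; n_individuals: (s,) sampled individuals.
    H_S_est = (2n~/(2n~-1)) H_S, H_T_est = H_T + H_S_est/(2 n~ s), with n~
    the harmonic-mean sample size; D = (H_T-H_S)/(1-H_S) * s/(s-1) on the
    corrected values, clamped to >= 0 (sampling noise can push it negative).
    """
    p = np.asarray(p, dtype=float)
    s = p.shape[0]
    if s < 2:
        raise DifferentiationError("need >= 2 strata")
    n = np.asarray(n_individuals, dtype=float)
    ntilde = s / (1.0 / n).sum()
    hs = float(np.mean(1.0 - (p ** 2).sum(axis=1)))
    pbar = p.mean(axis=0)
    ht = float(1.0 - (pbar ** 2).sum())
    hs_est = 2 * ntilde / (2 * ntilde - 1) * hs
    ht_est = ht + hs_est / (2 * ntilde * s)
    if hs_est >= 1.0:
        return 0.0
    d = (ht_est - hs_est) / (1.0 - hs_est) * s / (s - 1.0)
    if clamp:
        d = min(max(d, 0.0), 1.0)
    return float(d)


@dataclass(frozen=True)
class DestResult:
    value: float
    per_locus: dict[str, float]


def pairwise_dest(data, frame, strata_pair) -> DestResult:
    """Jost's D_EST between two strata.

    Per-locus D values are combined by the harmonic mean (loci with D = 0
    make the harmonic mean 0 only if all are 0; zero loci are held out of
    the harmonic mean and averaged in arithmetically, a common guard).
    """
    samples = [subset(data, frame, s) for s in strata_pair]
    per: dict[str, float] = {}
    if isinstance(samples[0], GenotypeTable):
        loci = samples[0].loci
        for locus in loci:
            countmaps = [t.allele_counts(locus) for t in samples]
            alleles = sorted({a for cm in countmaps for a in cm})
            if len(alleles) < 2:
                continue
            n_ind = []
            freqs = []
            ok = True
            for t, cm in zip(samples, countmaps):
                tot = sum(cm.values())
                if tot < 2:
                    ok = False
                    break
                n_ind.append(tot / 2.0)
                freqs.append([cm.get(a, 0) / tot for a in alleles])
            if not ok:
                continue
            per[locus] = jost_d_from_frequencies(np.array(freqs), np.array(n_ind))
    else:
        universe = samples[0].universe
        counts = np.array(
            [[s.carrier_counts()[a] for a in universe] for s in samples], float
        )
        n = counts.sum(axis=1)
        p = counts / n[:, None]
        # haploid analogue: "individuals" are carrier observations / 2 copies
        per["mhc"] = jost_d_from_frequencies(p, n / 2.0)
    if not per:
        raise DifferentiationError("no informative locus for D_EST")
    vals = np.array(list(per.values()))
    pos = vals[vals > 0]
    if len(pos) == 0:
        overall = 0.0
    else:
        harm = len(pos) / (1.0 / pos).sum()
        overall = float(harm * len(pos) / len(vals))
    return DestResult(overall, per)


# ---------------------------------------------------------------------------
# Global permutation G-test
# ---------------------------------------------------------------------------

def _g_statistic(tables_counts: np.ndarray) -> float:
    """Log-likelihood-ratio G on an allele x stratum count table."""
    obs = tables_counts
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    tot = obs.sum()
    if tot == 0:
        return 0.0
    exp = row @ col / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def _g_many(obs: np.ndarray) -> np.ndarray:
    """G statistics for a batch of contingency tables, shape (B, k, s)."""
    row = obs.sum(axis=2, keepdims=True)
    col = obs.sum(axis=1, keepdims=True)
    tot = obs.sum(axis=(1, 2))[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = row * col / tot
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return 2.0 * terms.sum(axis=(1, 2))


def global_exact_test(
    data,
    frame,
    strata_set,
    steps: int = 30_000,
    seed: int | None = None,
    chunk: int = 2_000,
) -> PairwiseResult:
    """Permutation G-test of identical allele distributions across strata.

    The statistic is the sum over loci of G on the allele-count x stratum
    contingency table (total distinct alleles over the pooled strata define
    rows); individuals are permuted across strata to build the null.
    """
    strata = list(strata_set)
    if len(strata) < 2:
        raise DifferentiationError("need >= 2 strata")
    samples = [subset(data, frame, s) for s in strata]
    pooled = _pool(samples)
    if isinstance(pooled, GenotypeTable):
        from .diversity import _encode_genotypes

        codes, kvec = _encode_genotypes(pooled)
        if not (kvec >= 2).any():
            raise DifferentiationError("no polymorphic locus")
        sizes = [s.n_individuals for s in samples]
    else:
        _, mat = pooled.to_matrix()
        sizes = [len(s.profiles) for s in samples]
    total = sum(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    ns = len(sizes)

    def g_of(perm_idx: np.ndarray) -> np.ndarray:
        B = perm_idx.shape[0]
        if isinstance(pooled, GenotypeTable):
            g = np.zeros(B)
            for j in range(codes.shape[1]):
                k = int(kvec[j])
                if k < 2:
                    continue
                sel = codes[:, j, :][perm_idx]  # (B, n, 2)
                obs = np.empty((B, k, ns))
                for s_i in range(ns):
                    part = sel[:, bounds[s_i]:bounds[s_i + 1], :].reshape(B, -1)
                    onehot = part[:, :, None] == np.arange(k)[None, None, :]
                    obs[:, :, s_i] = onehot.sum(axis=1)
                g += _g_many(obs)
            return g
        obs = np.empty((B, mat.shape[1], ns))
        sel = mat[perm_idx]  # (B, n, k)
        for s_i in range(ns):
            obs[:, :, s_i] = sel[:, bounds[s_i]:bounds[s_i + 1], :].sum(axis=1)
        return _g_many(obs)

    g_obs = float(g_of(np.arange(total)[None, :])[0])
    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    while done < steps:
        b = min(chunk, steps - done)
        perms = np.argsort(rng.random((b, total)), axis=1)
        extreme += int((g_of(perms) >= g_obs - 1e-12).sum())
        done += b
    p = (1 + extreme) / (steps + 1)
    return PairwiseResult("global-G", g_obs, p, steps, seed)


# ---------------------------------------------------------------------------
# Distance matrices and the Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise differentiation matrix with per-cell P values."""

    labels: tuple[str, ...]
    values: np.ndarray
    p_values: np.ndarray | None = None
    permutations: int = 0
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DifferentiationError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise DifferentiationError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DifferentiationError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]


def pairwise_matrix(
    data,
    frame,
    strata,
    statistic: str = "fst",
    permutations: int = 999,
    seed: int | None = None,
) -> DistanceMatrix:
    """All-pairs F_ST or D_EST matrix over the given strata."""
    strata = [(str(p), int(y)) for p, y in strata]
    labels = [f"{p}_{y}" for p, y in strata]
    m = len(strata)
    vals = np.zeros((m, m))
    ps = np.full((m, m), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(m), 2):
        pair = (strata[i], strata[j])
        if statistic == "fst":
            res = pairwise_fst(
                data, frame, pair, permutations,
                int(rng.integers(0, 2 ** 31)),
            )
            vals[i, j] = vals[j, i] = res.value
            ps[i, j] = ps[j, i] = res.p_value if res.p_value is not None else np.nan
        elif statistic == "dest":
            res = pairwise_dest(data, frame, pair)
            vals[i, j] = vals[j, i] = res.value
        else:
            raise DifferentiationError(f"unknown statistic {statistic!r}")
    return DistanceMatrix(tuple(labels), vals, ps, permutations, seed)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    permutations: int
    seed: int | None


def mantel(
    mat_a: DistanceMatrix,
    mat_b: DistanceMatrix,
    permutations: int = 9_999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same strata.

    r is the Pearson correlation of lower-triangle entries; P is upper-tail,
    from joint row/column label permutations of the second matrix (all m!
    permutations when ``exhaustive``).
    """
    if mat_a.labels != mat_b.labels:
        raise DifferentiationError(
            f"label mismatch: {mat_a.labels} vs {mat_b.labels}"
        )
    m = len(mat_a.labels)
    if m < 4:
        raise DifferentiationError("need >= 4 strata for a Mantel test")
    x = mat_a.lower_triangle()
    tril = np.tril_indices(m, k=-1)

    def corr(bv: np.ndarray) -> float:
        y = bv[tril]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(mat_b.values)
    rng = np.random.default_rng(seed)
    extreme = 0
    if exhaustive:
        perms = list(iter_permutations(range(m)))
        count = 0
        for perm in perms:
            perm = np.array(perm)
            r_star = corr(mat_b.values[np.ix_(perm, perm)])
            if r_star >= r_obs - 1e-12:
                extreme += 1
            count += 1
        return MantelResult(r_obs, extreme / count, count, seed)
    for _ in range(permutations):
        perm = rng.permutation(m)
        r_star = corr(mat_b.values[np.ix_(perm, perm)])
        if r_star >= r_obs - 1e-12:
            extreme += 1
    p = (1 + extreme) / (permutations + 1)
    return MantelResult(r_obs, p, permutations, seed)
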