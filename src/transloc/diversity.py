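"""Diversity statistics and the pooled randomization test of temporal change.

Microsatellite measures: unbiased expected heterozygosity and rarefied
allelic richness (exact hypergeometric expectation).  MHC measures computed
from carrier counts treated as haplotype frequencies: total alleles k, mean
alleles per individual, nucleotide diversity Pi (per amplicon) and the
Ewens sampling-formula allelic-richness index theta_K.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .popdata import MISSING, GenotypeTable, MhcProfileSet, PopDataError

logger = logging.getLogger(__name__)

STATISTICS = ("he", "richness", "mhc-ind", "pi", "thetak")


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class LocusFrequencySpectrum:
    """Gene-copy allele counts at one locus (complete calls only)."""

    locus: str
    counts: dict[int, int]

    def __post_init__(self):
        if any(c <= 0 for c in self.counts.values()):
            raise DiversityError(f"non-positive allele count at {self.locus!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return len(self.counts)


def spectra(table: GenotypeTable) -> list[LocusFrequencySpectrum]:
    """Per-locus frequency spectra; loci with zero complete calls are dropped
    with a warning."""
    out = []
    for locus in table.loci:
        counts = table.allele_counts(locus)
        if not counts:
            logger.warning("locus %r has no complete calls, excluded", locus)
            continue
        out.append(LocusFrequencySpectrum(locus, counts))
    return out


@dataclass(frozen=True)
class LocusMeanResult:
    per_locus: dict[str, float]
    mean: float
    se: float


def _mean_se(values: dict[str, float]) -> LocusMeanResult:
    arr = np.array(list(values.values()), dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return LocusMeanResult(values, float(arr.mean()), se)


def heterozygosity_from_counts(counts: dict[int, int] | np.ndarray) -> float:
    """Unbiased expected heterozygosity [Ng/(Ng-1)](1 - sum p_i^2)."""
    arr = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    ng = arr.sum()
    if ng < 2:
        raise DiversityError("need at least 2 gene copies for H_E")
    p = arr / ng
    return float(ng / (ng - 1.0) * (1.0 - (p ** 2).sum()))


def expected_heterozygosity(table: GenotypeTable) -> LocusMeanResult:
    """Per-locus unbiased H_E and the across-loci mean with its SE."""
    per = {}
    for spec in spectra(table):
        per[spec.locus] = heterozygosity_from_counts(spec.counts)
    if not per:
        raise DiversityError("no locus with complete calls")
    return _mean_se(per)


def rarefied_richness_from_counts(counts: dict[int, int] | np.ndarray, g: int) -> float:
    """Exact expected number of distinct alleles among g gene copies.

    A_g = sum_i [1 - C(N_g - N_i, g) / C(N_g, g)] (hypergeometric expectation).
    """
    arr = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    ng = arr.sum()
    if g < 1:
        raise DiversityError("rarefaction depth g must be >= 1")
    if g > ng:
        raise DiversityError(f"depth g={g} exceeds gene copies N_g={int(ng)}")
    # log C(ng-Ni, g) - log C(ng, g); C(m, g)=0 when m < g
    rem = ng - arr
    with np.errstate(invalid="ignore"):
        logratio = (
            gammaln(rem + 1) - gammaln(g + 1) - gammaln(rem - g + 1)
            - (gammaln(ng + 1) - gammaln(g + 1) - gammaln(ng - g + 1))
        )
    prob_absent = np.where(rem >= g, np.exp(logratio), 0.0)
    return float((1.0 - prob_absent).sum())


def rarefied_allelic_richness(table: GenotypeTable, g: int) -> LocusMeanResult:
    """Per-locus rarefied allelic richness at gene-copy depth g, with mean/SE.

    Raises if g exceeds any included locus's complete-call gene copies.
    """
    per = {}
    for spec in spectra(table):
        if g > spec.total:
            raise DiversityError(
                f"depth g={g} exceeds N_g={spec.total} at locus {spec.locus!r}"
            )
        per[spec.locus] = rarefied_richness_from_counts(spec.counts, g)
    if not per:
        raise DiversityError("no locus with complete calls")
    return _mean_se(per)


def default_depth(*tables: GenotypeTable) -> int:
    """Smallest complete-call gene-copy count across loci of all tables."""
    gs = []
    for t in tables:
        for spec in spectra(t):
            gs.append(spec.total)
    if not gs:
        raise DiversityError("no loci with complete calls")
    return int(min(gs))


# ---------------------------------------------------------------------------
# Ewens sampling formula theta_K
# ---------------------------------------------------------------------------

def ewens_expected_alleles(theta: float, n: int) -> float:
    """E[K] = sum_{m=0}^{n-1} theta / (theta + m) under the Ewens formula."""
    m = np.arange(n, dtype=float)
    return float((theta / (theta + m)).sum())


def ewens_theta_k(k: int, n: int) -> float:
    """Solve E[K] = k for theta given sample size n (monotone; by brentq).

    Returns 0 for k <= 1 and +inf (with a warning) when k == n, where the
    expectation only reaches k in the limit.
    """
    if n < 1 or k < 1 or k > n:
        raise DiversityError(f"need 1 <= k <= n, got k={k}, n={n}")
    if k == 1:
        return 0.0
    if k == n:
        warnings.warn("k equals n (all singletons): theta_K diverges", stacklevel=2)
        return float("inf")
    lo, hi = 1e-12, 1e3
    while ewens_expected_alleles(hi, n) < k:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for k < n
            return float("inf")
    return float(brentq(lambda t: ewens_expected_alleles(t, n) - k, lo, hi))


# ---------------------------------------------------------------------------
# MHC summaries
# ---------------------------------------------------------------------------

def pairwise_differences(sequences: dict[str, str], universe) -> np.ndarray:
    """Nucleotide-difference matrix between allele sequences (per amplicon)."""
    seqs = [np.frombuffer(sequences[a].encode(), dtype="S1") for a in universe]
    k = len(seqs)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = int((seqs[i] != seqs[j]).sum())
    return d


def nucleotide_diversity(carriers: np.ndarray, dmat: np.ndarray) -> float:
    """Pi = [n/(n-1)] sum_{i != j} q_i q_j d_ij with q from carrier counts."""
    c = np.asarray(carriers, dtype=float)
    n = c.sum()
    if n < 2:
        raise DiversityError("Pi needs >= 2 carrier observations")
    q = c / n
    return float(n / (n - 1.0) * q @ dmat @ q)


@dataclass(frozen=True)
class MhcSummary:
    n_individuals: int
    k: int
    mhc_per_ind: float
    pi: float | None
    theta_k: float


def mhc_summary(profiles: MhcProfileSet) -> MhcSummary:
    """k, mean alleles per individual, Pi (if sequences present) and theta_K.

    Carrier counts (individuals carrying each allele) are treated as
    haplotype counts: n = sum of carrier counts, q_i = c_i / n.
    """
    if profiles.n_individuals < 2:
        raise DiversityError("need >= 2 individuals")
    counts = profiles.carrier_counts()
    c = np.array([counts[a] for a in profiles.universe], dtype=int)
    k = int((c > 0).sum())
    n = int(c.sum())
    mhc_ind = n / profiles.n_individuals
    pi = None
    if profiles.sequences is not None:
        dmat = pairwise_differences(profiles.sequences, profiles.universe)
        pi = nucleotide_diversity(c, dmat)
    theta = ewens_theta_k(k, n)
    return MhcSummary(profiles.n_individuals, k, mhc_ind, pi, theta)


# ---------------------------------------------------------------------------
# Pooled randomization test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizationResult:
    statistic: str
    observed_diff: float
    iterations: int
    p_value: float
    seed: int | None
    tail: str
    redraws: int = 0


def _encode_genotypes(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Recode allele labels per locus to 0..k-1 (missing -> -1)."""
    n, L = table.n_individuals, table.n_loci
    codes = np.full((n, L, 2), -1, dtype=np.int32)
    kvec = np.zeros(L, dtype=np.int32)
    for j in range(L):
        col = table.calls[:, j, :]
        labels = np.unique(col[col != MISSING])
        kvec[j] = len(labels)
        if len(labels) == 0:
            continue
        lut = {int(a): i for i, a in enumerate(labels)}
        for a, i in lut.items():
            codes[:, j, :][col == a] = i
    return codes, kvec


def _counts_per_draw(sel: np.ndarray, k: int) -> np.ndarray:
    """Allele counts per draw: sel (B, m, 2) coded alleles -> (B, k)."""
    flat = sel.reshape(sel.shape[0], -1)
    onehot = flat[:, :, None] == np.arange(k)[None, None, :]
    return onehot.sum(axis=1).astype(float)


class _GenotypeStat:
    """Vectorized per-pseudo-sample statistic over a pooled genotype array."""

    def __init__(self, pool: GenotypeTable, name: str, g: int | None):
        self.codes, self.kvec = _encode_genotypes(pool)
        self.name = name
        self.g = g
        self.n_loci_used = int((self.kvec > 0).sum())
        if name == "richness" and g is None:
            raise DiversityError("richness statistic requires a depth g")

    def values(self, idx: np.ndarray) -> np.ndarray:
        B = idx.shape[0]
        acc = np.zeros(B)
        nloc = np.zeros(B)
        for j in range(self.codes.shape[1]):
            k = int(self.kvec[j])
            if k == 0:
                continue
            sel = self.codes[:, j, :][idx]  # (B, m, 2)
            counts = _counts_per_draw(sel, k)
            ng = counts.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                if self.name == "he":
                    p2 = (counts / ng[:, None]) ** 2
                    val = ng / (ng - 1.0) * (1.0 - np.nansum(p2, axis=1))
                    val = np.where(ng >= 2, val, np.nan)
                else:  # richness at depth g
                    g = float(self.g)
                    rem = ng[:, None] - counts
                    logratio = (
                        gammaln(rem + 1) - gammaln(rem - g + 1)
                        - gammaln(ng + 1)[:, None] + gammaln(ng - g + 1)[:, None]
                    )
                    absent = np.where(rem >= g, np.exp(logratio), 0.0)
                    present = np.where(counts > 0, 1.0 - absent, 0.0)
                    val = np.where(ng >= g, present.sum(axis=1), np.nan)
            ok = np.isfinite(val)
            acc[ok] += val[ok]
            nloc += ok
        with np.errstate(divide="ignore", invalid="ignore"):
            out = acc / nloc
        # a pseudo-sample is undefined if any locus was undefined for it
        out[nloc < self.n_loci_used] = np.nan
        return out


class _MhcStat:
    def __init__(self, pool_matrix: np.ndarray, name: str,
                 dmat: np.ndarray | None):
        self.mat = pool_matrix.astype(float)
        self.name = name
        self.dmat = dmat
        if name == "pi" and dmat is None:
            raise DiversityError("pi statistic requires allele sequences")

    def values(self, idx: np.ndarray) -> np.ndarray:
        sel = self.mat[idx]              # (B, m, k)
        counts = sel.sum(axis=1)         # carrier counts per draw
        ntot = counts.sum(axis=1)
        if self.name == "mhc-ind":
            return ntot / idx.shape[1]
        if self.name == "pi":
            q = counts / ntot[:, None]
            quad = np.einsum("bi,ij,bj->b", q, self.dmat, q)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(ntot >= 2, ntot / (ntot - 1.0) * quad, np.nan)
        # thetak
        out = np.empty(idx.shape[0])
        for b in range(idx.shape[0]):
            kk, nn = int((counts[b] > 0).sum()), int(ntot[b])
            out[b] = ewens_theta_k(kk, nn) if 1 <= kk <= nn else np.nan
        return out


def _build_stat(sample_a, sample_b, statistic: str, g: int | None):
    if isinstance(sample_a, GenotypeTable):
        if statistic not in ("he", "richness"):
            raise DiversityError(f"statistic {statistic!r} needs MHC profiles")
        overlap = set(sample_a.individuals) & set(sample_b.individuals)
        if overlap:
            raise PopDataError(f"samples overlap: {sorted(overlap)[:5]}")
        if sample_a.loci != sample_b.loci:
            raise DiversityError("samples must share the same loci")
        pool = GenotypeTable(
            tuple(sample_a.individuals) + tuple(sample_b.individuals),
            sample_a.loci,
            np.concatenate([sample_a.calls, sample_b.calls], axis=0),
        )
        stat = _GenotypeStat(pool, statistic, g)
        return stat, sample_a.n_individuals, sample_b.n_individuals
    if statistic not in ("mhc-ind", "pi", "thetak"):
        raise DiversityError(f"statistic {statistic!r} needs genotype tables")
    overlap = set(sample_a.profiles) & set(sample_b.profiles)
    if overlap:
        raise PopDataError(f"samples overlap: {sorted(overlap)[:5]}")
    if sample_a.universe != sample_b.universe:
        raise DiversityError("samples must share the same allele universe")
    _, mat_a = sample_a.to_matrix()
    _, mat_b = sample_b.to_matrix()
    pool = np.concatenate([mat_a, mat_b], axis=0)
    dmat = None
    if sample_a.sequences is not None:
        dmat = pairwise_differences(sample_a.sequences, sample_a.universe)
    stat = _MhcStat(pool, statistic, dmat)
    return stat, mat_a.shape[0], mat_b.shape[0]


def randomization_test(
    sample_a,
    sample_b,
    statistic: str = "he",
    iterations: int = 100_000,
    seed: int | None = None,
    tail: str = "two",
    g: int | None = None,
    chunk: int = 5_000,
) -> RandomizationResult:
    """Pooled resampling test of a difference in a per-sample diversity scalar.

    The two samples are pooled; ``iterations`` times two pseudo-samples of
    the original sizes are drawn with replacement from the pool and the
    statistic difference recomputed.  P = (1 + #{extreme}) / (iterations + 1)
    where "extreme" means |d*| >= |d_obs| (``tail='two'``) or d* >= d_obs
    (``tail='one'``).  Pseudo-samples on which the statistic is undefined
    are redrawn (counted and logged).
    """
    if statistic not in STATISTICS:
        raise DiversityError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if iterations < 100:
        raise DiversityError("iterations must be >= 100 for a stable estimator")
    if tail not in ("two", "one"):
        raise DiversityError("tail must be 'two' or 'one'")
    stat, n_a, n_b = _build_stat(sample_a, sample_b, statistic, g)
    n_pool = n_a + n_b
    idx_a_obs = np.arange(n_a)[None, :]
    idx_b_obs = np.arange(n_a, n_pool)[None, :]
    obs = float(stat.values(idx_a_obs)[0] - stat.values(idx_b_obs)[0])
    if not np.isfinite(obs):
        raise DiversityError("statistic undefined on an observed sample")

    rng = np.random.default_rng(seed)
    extreme = 0
    redraws = 0
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        ia = rng.integers(0, n_pool, size=(b, n_a))
        ib = rng.integers(0, n_pool, size=(b, n_b))
        diffs = stat.values(ia) - stat.values(ib)
        bad = ~np.isfinite(diffs)
        while bad.any():
            redraws += int(bad.sum())
            ia[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), n_a))
            ib[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), n_b))
            diffs[bad] = stat.values(ia[bad]) - stat.values(ib[bad])
            bad = ~np.isfinite(diffs)
        if tail == "two":
            extreme += int((np.abs(diffs) >= abs(obs)).sum())
        else:
            extreme += int((diffs >= obs).sum())
        done += b
    if redraws:
        logger.info("randomization_test: %d undefined pseudo-samples redrawn", redraws)
    p = (1 + extreme) / (iterations + 1)
    return RandomizationResult(statistic, obs, iterations, p, seed, tail, redraws)
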