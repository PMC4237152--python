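"""Genetic-capture rarefaction planner.

Monte-Carlo rarefaction of a source sample answers: how much of the
source's allelic diversity does a founder cohort of n individuals capture?
Curves are built by coupled subsampling (one shuffle per replicate yields
nested subsets for every n), so expected capture is monotone in n by
construction while each n keeps its exact marginal subsampling distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .popdata import MISSING, GenotypeTable, MhcProfileSet, PopDataError

MARKER_FILTERS = ("all", "diverse", "mhc")
DIVERSE_MIN_ALLELES = 4
RARE_FREQ = 0.01


class CaptureError(ValueError):
    pass


def _filter_loci(source: GenotypeTable, marker_filter: str) -> GenotypeTable:
    if marker_filter == "all":
        keep = [l for l in source.loci if source.allele_counts(l)]
    elif marker_filter == "diverse":
        keep = [
            l for l in source.loci
            if len(source.allele_counts(l)) >= DIVERSE_MIN_ALLELES
        ]
        if not keep:
            raise CaptureError(
                f"no locus with >= {DIVERSE_MIN_ALLELES} alleles under 'diverse' filter"
            )
    else:
        raise CaptureError(f"marker filter {marker_filter!r} invalid for genotypes")
    if not keep:
        raise CaptureError("no usable loci")
    return source.subset_loci(keep)


def observed_richness(source: GenotypeTable | MhcProfileSet, ids=None) -> float:
    """Capture statistic: mean over loci of distinct alleles (genotypes) or
    total distinct MHC alleles, over the given individuals (default: all)."""
    if ids is not None:
        source = source.subset(list(ids))
    if isinstance(source, GenotypeTable):
        return float(
            np.mean([len(source.allele_counts(l)) for l in source.loci])
        )
    counts = source.carrier_counts()
    return float(sum(1 for c in counts.values() if c > 0))


@dataclass(frozen=True)
class CaptureCurve:
    """Per-founder-number Monte-Carlo distribution of captured richness."""

    marker: str
    n_source: int
    replicates: int
    seed: int | None
    values: np.ndarray = field(repr=False)  # (n_source, replicates)
    full_value: float
    loci: tuple[str, ...] | None = None

    @property
    def ns(self) -> np.ndarray:
        return np.arange(1, self.n_source + 1)

    @property
    def means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def sds(self) -> np.ndarray:
        return self.values.std(axis=1, ddof=1)

    @property
    def ses(self) -> np.ndarray:
        return self.sds / math.sqrt(self.replicates)

    @property
    def pct5(self) -> np.ndarray:
        return np.percentile(self.values, 5, axis=1)

    @property
    def pct95(self) -> np.ndarray:
        return np.percentile(self.values, 95, axis=1)

    @property
    def captured_fraction(self) -> np.ndarray:
        return self.means / self.full_value

    def at(self, n: int) -> np.ndarray:
        """Replicate values for founder number n."""
        if not 1 <= n <= self.n_source:
            raise CaptureError(f"n={n} outside [1, {self.n_source}]")
        return self.values[n - 1]


def _genotype_first_positions(calls: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Mean-over-loci distinct-allele curve for one shuffled order.

    Returns an (N,) array whose entry n-1 is the capture statistic of the
    first n individuals in ``order``.
    """
    n, L, _ = calls.shape
    total = np.zeros(n)
    used = 0
    shuffled = calls[order]  # (n, L, 2)
    for j in range(L):
        col = shuffled[:, j, :]
        mask = col[:, 0] != MISSING
        if not mask.any():
            continue
        used += 1
        pos = np.repeat(np.arange(n), 2)[np.repeat(mask, 2)]
        alleles = col[mask].ravel()
        labels, codes = np.unique(alleles, return_inverse=True)
        first = np.full(len(labels), n)
        np.minimum.at(first, codes, pos)
        total += np.cumsum(np.bincount(first, minlength=n + 1)[:n])
    if used == 0:
        raise CaptureError("no usable loci")
    return total / used


def _mhc_curve(mat: np.ndarray, order: np.ndarray) -> np.ndarray:
    n, k = mat.shape
    shuffled = mat[order]
    first = np.where(
        shuffled.any(axis=0), shuffled.argmax(axis=0), n
    )
    return np.cumsum(np.bincount(first, minlength=n + 1)[:n]).astype(float)


def build_capture_curve(
    source: GenotypeTable | MhcProfileSet,
    marker_filter: str = "all",
    replicates: int = 1000,
    seed: int | None = None,
) -> CaptureCurve:
    """Monte-Carlo capture curve over founder numbers 1..N_source.

    For each replicate one random individual order is drawn; the first n
    individuals form the founder draw for every n (coupled subsets).  The
    statistic is the mean over included loci of distinct alleles present
    (microsatellites) or the total distinct MHC alleles.
    """
    if marker_filter not in MARKER_FILTERS:
        raise CaptureError(f"marker_filter must be one of {MARKER_FILTERS}")
    rng = np.random.default_rng(seed)
    if isinstance(source, GenotypeTable):
        if marker_filter == "mhc":
            raise CaptureError("'mhc' filter requires an MhcProfileSet source")
        filtered = _filter_loci(source, marker_filter)
        n = filtered.n_individuals
        if n < 2:
            raise CaptureError("source needs >= 2 individuals")
        values = np.empty((n, replicates))
        for r in range(replicates):
            order = rng.permutation(n)
            values[:, r] = _genotype_first_positions(filtered.calls, order)
        full = observed_richness(filtered)
        loci = filtered.loci
    else:
        _, mat = source.to_matrix()
        n = mat.shape[0]
        if n < 2:
            raise CaptureError("source needs >= 2 individuals")
        values = np.empty((n, replicates))
        for r in range(replicates):
            order = rng.permutation(n)
            values[:, r] = _mhc_curve(mat, order)
        full = observed_richness(source)
        loci = None
    marker = marker_filter if isinstance(source, GenotypeTable) else "mhc"
    return CaptureCurve(marker, n, replicates, seed, values, full, loci)


@dataclass(frozen=True)
class FounderRecommendation:
    n: int
    target_fraction: float
    attainable: bool
    expected_fraction: float


def min_founders(curve: CaptureCurve, target_fraction: float) -> FounderRecommendation:
    """Smallest founder number whose expected captured fraction meets the target.

    If no n reaches the target the recommendation is capped at N_source and
    flagged unattainable.
    """
    if not 0 < target_fraction <= 1:
        raise CaptureError("target_fraction must be in (0, 1]")
    frac = curve.captured_fraction
    meets = np.nonzero(frac >= target_fraction)[0]
    if len(meets) == 0:
        return FounderRecommendation(
            curve.n_source, target_fraction, False, float(frac[-1])
        )
    n = int(meets[0]) + 1
    return FounderRecommendation(n, target_fraction, True, float(frac[n - 1]))


@dataclass(frozen=True)
class LostAllele:
    locus: str | None
    allele: str
    source_frequency: float
    rare: bool


@dataclass(frozen=True)
class CaptureAssessment:
    founders: tuple[str, ...]
    n_founders: int
    observed: float
    expected_mean: float
    expected_se: float
    captured_fraction: float
    p_value: float
    alleles_lost: tuple[LostAllele, ...]


def _lost_alleles(source, founder_ids) -> list[LostAllele]:
    lost: list[LostAllele] = []
    if isinstance(source, GenotypeTable):
        founders = source.subset(list(founder_ids))
        for locus in source.loci:
            src = source.allele_counts(locus)
            if not src:
                continue
            total = sum(src.values())
            fnd = set(founders.allele_counts(locus))
            for allele, count in sorted(src.items()):
                if allele not in fnd:
                    freq = count / total
                    lost.append(
                        LostAllele(locus, str(allele), freq, freq < RARE_FREQ)
                    )
    else:
        counts = source.carrier_counts()
        total = sum(counts.values())
        founders = source.subset(list(founder_ids))
        fcounts = founders.carrier_counts()
        for allele in source.universe:
            if counts[allele] > 0 and fcounts[allele] == 0:
                freq = counts[allele] / total
                lost.append(LostAllele(None, allele, freq, freq < RARE_FREQ))
    return lost


def assess_founders(
    curve: CaptureCurve,
    source: GenotypeTable | MhcProfileSet,
    founder_ids,
) -> CaptureAssessment:
    """Observed-vs-expected capture test for an actual founder cohort.

    One-tailed (deficit) P = (1 + #{replicates at n <= observed}) / (R + 1):
    small values mean the cohort captured less than random draws of its size.
    """
    founder_ids = list(founder_ids)
    if isinstance(source, GenotypeTable):
        have = set(source.individuals)
        eval_source = (
            source.subset_loci(list(curve.loci)) if curve.loci is not None else source
        )
    else:
        have = set(source.profiles)
        eval_source = source
    unknown = [f for f in founder_ids if f not in have]
    if unknown:
        raise PopDataError(f"founder IDs not in source: {unknown[:5]}")
    n = len(founder_ids)
    reps = curve.at(n)
    observed = observed_richness(eval_source, founder_ids)
    p = (1 + int((reps <= observed).sum())) / (curve.replicates + 1)
    lost = _lost_alleles(eval_source, founder_ids)
    return CaptureAssessment(
        tuple(founder_ids),
        n,
        observed,
        float(reps.mean()),
        float(reps.std(ddof=1) / math.sqrt(curve.replicates)),
        observed / curve.full_value,
        p,
        tuple(lost),
    )


def allele_loss_probability(n_source: int, m_carriers: int, n_founders: int) -> float:
    """Exact probability that an allele carried by m of N individuals is
    absent from a uniform draw of n founders: C(N-m, n) / C(N, n)."""
    if not 0 < m_carriers <= n_source:
        raise CaptureError("need 0 < m <= N")
    if not 0 < n_founders <= n_source:
        raise CaptureError("need 0 < n <= N")
    if n_founders > n_source - m_carriers:
        return 0.0
    return math.comb(n_source - m_carriers, n_founders) / math.comb(
        n_source, n_founders
    )
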