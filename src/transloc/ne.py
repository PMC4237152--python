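"""Linkage-disequilibrium effective-population-size estimation.

Burrows composite disequilibrium between all pairs of loci, squared
composite correlations r^2, the random-mating sampling-bias correction and
the quadratic inversion to Ne.  Only the random-mating model is provided.
Missing data are handled per locus pair (complete-case S), and a
minor-allele-frequency floor excludes uninformative alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .popdata import MISSING, GenotypeTable, SampleFrame, subset


class NeError(ValueError):
    pass


@dataclass(frozen=True)
class NeEstimate:
    stratum: tuple[str, int] | None
    s_harmonic: float
    mean_r2: float
    r2_corrected: float
    ne: float
    ci_low: float
    ci_high: float
    maf_floor: float
    n_comparisons: int


def _expected_sample_r2(s: float) -> float:
    """E[r^2] from sampling alone under random mating (Waples 2006)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _invert_ne(r2p: float, s: float) -> float:
    """Solve the drift expectation for Ne given bias-corrected r2'."""
    if r2p <= 0:
        return float("inf")
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308 ** 2 - 2.08 * r2p
    if disc < 0:
        disc = 0.0
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def _dosage_columns(table: GenotypeTable, maf_floor: float):
    """Allele-dosage columns (NaN where missing) and their locus indices.

    Alleles with whole-sample frequency outside [floor, 1 - floor] are
    excluded; biallelic loci contribute a single column (their two allele
    comparisons are identical).
    """
    cols, locus_of = [], []
    for j, locus in enumerate(table.loci):
        col = table.calls[:, j, :]
        mask = col[:, 0] != MISSING
        if mask.sum() < 2:
            continue
        counts = table.allele_counts(locus)
        total = sum(counts.values())
        alleles = sorted(counts)
        passing = [
            a for a in alleles
            if maf_floor <= counts[a] / total <= 1 - maf_floor
        ]
        if len(alleles) == 2 and passing:
            passing = passing[:1]
        for a in passing:
            dose = (col == a).sum(axis=1).astype(float)
            dose[~mask] = np.nan
            cols.append(dose)
            locus_of.append(j)
    if not cols:
        return None
    return np.column_stack(cols), np.array(locus_of)


def ld_ne(
    table: GenotypeTable,
    frame: SampleFrame | None = None,
    stratum: tuple[str, int] | None = None,
    maf_floor: float = 0.02,
    min_s: int = 3,
) -> NeEstimate:
    """LD-based Ne for one sample (random-mating model).

    For every allele pair at distinct loci the Burrows composite
    disequilibrium Delta (with the S/(S-1) correction) is squared and scaled
    by composite variances (including homozygote excess) to give r^2.  The
    S-weighted mean r^2 minus the sampling expectation at the harmonic-mean
    S is inverted to Ne; the CI is parametric chi-square on the pooled r^2
    with the comparison count as degrees of freedom.
    """
    if not 0 <= maf_floor < 0.5:
        raise NeError("maf_floor must be in [0, 0.5)")
    if stratum is not None:
        if frame is None:
            raise NeError("stratum given without a sample frame")
        table = subset(table, frame, stratum)
    built = _dosage_columns(table, maf_floor)
    if built is None:
        raise NeError("no polymorphic locus passes the frequency floor")
    X, locus_of = built
    if len(np.unique(locus_of)) < 2:
        raise NeError("need >= 2 polymorphic loci after the frequency floor")

    A = np.nan_to_num(X)
    M = (~np.isnan(X)).astype(float)
    I2 = (A == 2).astype(float) * M

    S = M.T @ M
    Sx = A.T @ M
    Sy = Sx.T
    Sxy = A.T @ A
    S2x = I2.T @ M
    S2y = S2x.T

    with np.errstate(divide="ignore", invalid="ignore"):
        p = Sx / (2 * S)
        q = Sy / (2 * S)
        delta = (Sxy / (2 * S) - 2 * p * q) * (S / (S - 1))
        ha = S2x / S - p ** 2
        hb = S2y / S - q ** 2
        den = (p * (1 - p) + ha) * (q * (1 - q) + hb)
        r2 = delta ** 2 / den

    iu, ju = np.triu_indices(X.shape[1], k=1)
    cross = locus_of[iu] != locus_of[ju]
    valid = (
        cross
        & (S[iu, ju] >= min_s)
        & np.isfinite(r2[iu, ju])
        & (p[iu, ju] >= maf_floor) & (p[iu, ju] <= 1 - maf_floor)
        & (q[iu, ju] >= maf_floor) & (q[iu, ju] <= 1 - maf_floor)
        & (den[iu, ju] > 0)
    )
    if not valid.any():
        raise NeError("no usable locus-pair comparison")
    r2v = r2[iu, ju][valid]
    sv = S[iu, ju][valid]
    w = sv
    mean_r2 = float((w * r2v).sum() / w.sum())
    n_comp = int(valid.sum())
    s_harm = float(n_comp / (1.0 / sv).sum())

    r2p = mean_r2 - _expected_sample_r2(s_harm)
    ne = _invert_ne(r2p, s_harm)

    df = n_comp
    lo_r2 = mean_r2 * df / chi2.ppf(0.975, df)
    hi_r2 = mean_r2 * df / chi2.ppf(0.025, df)
    ci_high = _invert_ne(lo_r2 - _expected_sample_r2(s_harm), s_harm)
    ci_low = _invert_ne(hi_r2 - _expected_sample_r2(s_harm), s_harm)

    return NeEstimate(
        stratum, s_harm, mean_r2, r2p, ne, ci_low, ci_high, maf_floor, n_comp
    )
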