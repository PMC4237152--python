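"""Genotype and MHC-profile data model, sampling strata, and file I/O.

Codominant diploid microsatellite genotypes are held in a
:class:`GenotypeTable`; multilocus MHC "presence" profiles (allele sets per
individual, locus zygosity unresolved) in an :class:`MhcProfileSet`; and the
population x catch-year stratification in a :class:`SampleFrame`.

Supported formats: GenePop (2- and 3-digit diploid codes), a long CSV
genotype dialect (``ind,pop,year,locus,a1,a2``), MHC presence CSV (wide 0/1
matrix or long two-column), and FASTA for MHC allele sequences.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel allele code for a missing call (GenePop convention).
MISSING = 0

_STRATUM_ID_RE = re.compile(r"^(?P<pop>.+)_(?P<year>\d{4})_\d+$")


class PopDataError(ValueError):
    """Raised for malformed input data or contract violations."""


class GenepopParseError(PopDataError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid multi-locus genotypes with a missing-data sentinel.

    Parameters
    ----------
    individuals : ordered individual IDs (unique).
    loci : ordered locus IDs (unique).
    calls : int array of shape (n_individuals, n_loci, 2); allele labels are
        positive integers, ``MISSING`` (0) marks an absent call.  A call is
        wholly present or wholly missing — half-calls are rejected.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "individuals", tuple(self.individuals))
        object.__setattr__(self, "loci", tuple(self.loci))
        calls = np.asarray(self.calls, dtype=np.int64)
        object.__setattr__(self, "calls", calls)
        if len(set(self.individuals)) != len(self.individuals):
            raise PopDataError("duplicate individual IDs")
        if len(set(self.loci)) != len(self.loci):
            raise PopDataError("duplicate locus IDs")
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise PopDataError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if (calls < 0).any():
            raise PopDataError("allele labels must be positive (0 = missing)")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise PopDataError(
                f"half-call at individual {self.individuals[i]!r}, "
                f"locus {self.loci[j]!r}: calls are wholly present or wholly missing"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def _ind_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise PopDataError(f"unknown individual ID {exc.args[0]!r}") from None

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise PopDataError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def allele_counts(self, locus: str) -> dict[int, int]:
        """Gene-copy counts per allele label at ``locus`` (complete calls only)."""
        j = self.locus_index(locus)
        flat = self.calls[:, j, :].ravel()
        flat = flat[flat != MISSING]
        labels, counts = np.unique(flat, return_counts=True)
        return {int(a): int(c) for a, c in zip(labels, counts)}

    def complete_calls(self, locus: str) -> int:
        j = self.locus_index(locus)
        return int((self.calls[:, j, 0] != MISSING).sum())

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        idx = self._ind_index(ids)
        return GenotypeTable(tuple(ids), self.loci, self.calls[idx])

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(self.individuals, tuple(loci), self.calls[:, idx, :])


@dataclass(frozen=True)
class MhcProfileSet:
    """Per-individual sets of MHC allele IDs, with optional sequences.

    Zygosity across duplicated loci is unobservable, so each individual's
    data is a plain allele set.  ``universe`` is the ordered catalogue of
    allele IDs; ``sequences`` (if given) maps every universe allele to an
    equal-length A/C/G/T nucleotide sequence.
    """

    profiles: dict[str, frozenset[str]]
    universe: tuple[str, ...]
    sequences: dict[str, str] | None = None
    size_range: tuple[int, int] = (1, 10)

    def __post_init__(self):
        object.__setattr__(
            self, "profiles", {k: frozenset(v) for k, v in self.profiles.items()}
        )
        object.__setattr__(self, "universe", tuple(self.universe))
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise PopDataError("duplicate allele IDs in universe")
        lo, hi = self.size_range
        for ind, prof in self.profiles.items():
            if not prof:
                raise PopDataError(f"individual {ind!r} has an empty allele set")
            if not prof <= uni:
                missing = sorted(prof - uni)
                raise PopDataError(
                    f"individual {ind!r} carries alleles outside the universe: {missing}"
                )
            if not lo <= len(prof) <= hi:
                raise PopDataError(
                    f"individual {ind!r} carries {len(prof)} alleles, outside "
                    f"plausibility range [{lo}, {hi}]"
                )
        if self.sequences is not None:
            seqs = dict(self.sequences)
            object.__setattr__(self, "sequences", seqs)
            absent = [a for a in self.universe if a not in seqs]
            if absent:
                raise PopDataError(f"sequences missing for universe alleles: {absent}")
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise PopDataError(f"unequal sequence lengths: {sorted(lengths)}")
            bad = {a for a, s in seqs.items() if set(s.upper()) - set("ACGT")}
            if bad:
                raise PopDataError(f"non-ACGT characters in sequences: {sorted(bad)}")

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    @property
    def n_individuals(self) -> int:
        return len(self.profiles)

    def carrier_counts(self) -> dict[str, int]:
        """Number of individuals carrying each universe allele (zeros kept)."""
        counts = dict.fromkeys(self.universe, 0)
        for prof in self.profiles.values():
            for a in prof:
                counts[a] += 1
        return counts

    def to_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        """(individual IDs, boolean presence matrix individuals x universe)."""
        inds = self.individuals
        col = {a: j for j, a in enumerate(self.universe)}
        mat = np.zeros((len(inds), len(self.universe)), dtype=bool)
        for i, ind in enumerate(inds):
            for a in self.profiles[ind]:
                mat[i, col[a]] = True
        return inds, mat

    def subset(self, ids: Sequence[str]) -> "MhcProfileSet":
        missing = [i for i in ids if i not in self.profiles]
        if missing:
            raise PopDataError(f"unknown individual IDs: {missing}")
        return MhcProfileSet(
            {i: self.profiles[i] for i in ids},
            self.universe,
            self.sequences,
            self.size_range,
        )


@dataclass(frozen=True)
class SampleFrame:
    """Registry assigning individuals to (population, catch-year) strata."""

    assignments: dict[str, tuple[str, int]]

    def __post_init__(self):
        object.__setattr__(
            self,
            "assignments",
            {k: (str(p), int(y)) for k, (p, y) in self.assignments.items()},
        )

    def strata(self) -> list[tuple[str, int]]:
        return sorted(set(self.assignments.values()))

    def individuals_in(self, stratum: tuple[str, int]) -> list[str]:
        pop, year = str(stratum[0]), int(stratum[1])
        ids = [i for i, s in self.assignments.items() if s == (pop, year)]
        if not ids:
            raise PopDataError(f"stratum {(pop, year)!r} is empty or unknown")
        return ids

    def population_individuals(self, pop: str) -> list[str]:
        ids = [i for i, (p, _) in self.assignments.items() if p == pop]
        if not ids:
            raise PopDataError(f"population {pop!r} is empty or unknown")
        return ids


@dataclass(frozen=True)
class CohortSelection:
    """Resolved individuals for one or more strata, with missing-data accounting."""

    strata: tuple[tuple[str, int], ...]
    individuals: dict[tuple[str, int], tuple[str, ...]]
    complete_calls: dict[tuple[str, int], dict[str, int]] = field(default_factory=dict)

    def n(self, stratum: tuple[str, int]) -> int:
        return len(self.individuals[stratum])


def select_cohorts(
    data: GenotypeTable | MhcProfileSet,
    frame: SampleFrame,
    strata: Sequence[tuple[str, int]],
) -> CohortSelection:
    """Resolve strata to individual lists present in ``data``; disjointness enforced."""
    have = set(
        data.individuals if isinstance(data, GenotypeTable) else data.profiles
    )
    resolved: dict[tuple[str, int], tuple[str, ...]] = {}
    seen: set[str] = set()
    complete: dict[tuple[str, int], dict[str, int]] = {}
    for stratum in strata:
        key = (str(stratum[0]), int(stratum[1]))
        ids = [i for i in frame.individuals_in(key) if i in have]
        if not ids:
            raise PopDataError(f"no individuals of stratum {key!r} present in data")
        overlap = seen & set(ids)
        if overlap:
            raise PopDataError(f"strata overlap on individuals: {sorted(overlap)[:5]}")
        seen |= set(ids)
        resolved[key] = tuple(ids)
        if isinstance(data, GenotypeTable):
            sub = data.subset(ids)
            complete[key] = {l: sub.complete_calls(l) for l in sub.loci}
    return CohortSelection(tuple(resolved), resolved, complete)


def subset(
    data: GenotypeTable | MhcProfileSet,
    frame: SampleFrame,
    stratum: tuple[str, int],
) -> GenotypeTable | MhcProfileSet:
    """Restrict ``data`` to the individuals of one (population, year) stratum.

    Individuals of the stratum absent from ``data`` are dropped with a
    warning; individuals in ``data`` but not in the frame are ignored.
    """
    ids = frame.individuals_in(stratum)
    if isinstance(data, GenotypeTable):
        have = set(data.individuals)
    else:
        have = set(data.profiles)
    keep = [i for i in ids if i in have]
    dropped = len(ids) - len(keep)
    if dropped:
        logger.warning(
            "stratum %r: %d assigned individuals absent from data, dropped",
            stratum, dropped,
        )
    if not keep:
        raise PopDataError(f"no individuals of stratum {stratum!r} present in data")
    return data.subset(keep)


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

def _parse_stratum_from_id(ind_id: str, block: int) -> tuple[str, int]:
    m = _STRATUM_ID_RE.match(ind_id)
    if m:
        return m.group("pop"), int(m.group("year"))
    return f"pop{block}", 0


def read_genepop(
    path, strata: Mapping[str, tuple[str, int]] | None = None
) -> tuple[GenotypeTable, SampleFrame]:
    """Read a GenePop file (2- or 3-digit diploid codes).

    Population and catch year come from a ``pop_year`` naming convention on
    individual IDs (``<pop>_<year>_<n>``) or, failing that, from an optional
    ``strata`` side table mapping individual ID -> (population, year); IDs
    matching neither fall back to ``popK`` block labels with year 0.
    Allele code 0 maps to :data:`MISSING`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP block found", len(lines))
    if not loci:
        raise GenepopParseError("no locus names before first POP", i + 1)
    if len(set(loci)) != len(loci):
        raise GenepopParseError("duplicate locus names", i + 1)

    individuals: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    assignments: dict[str, tuple[str, int]] = {}
    block = 0
    width: int | None = None
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            block += 1
            i += 1
            continue
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError("missing ',' between ID and genotypes", i + 1)
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        if ind_id in assignments:
            raise GenepopParseError(f"duplicate individual ID {ind_id!r}", i + 1)
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"{len(codes)} genotype codes for {len(loci)} loci", i + 1
            )
        row: list[tuple[int, int]] = []
        for code in codes:
            if not code.isdigit() or len(code) not in (4, 6):
                raise GenepopParseError(
                    f"malformed diploid code {code!r} (need 4 or 6 digits)", i + 1
                )
            w = len(code) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"inconsistent code width in {code!r} (file uses {2 * width}-digit codes)",
                    i + 1,
                )
            a1, a2 = int(code[:w]), int(code[w:])
            if (a1 == 0) != (a2 == 0):
                raise GenepopParseError(
                    f"half-missing call {code!r} is not allowed", i + 1
                )
            row.append((a1, a2))
        individuals.append(ind_id)
        rows.append(row)
        if strata is not None and ind_id in strata:
            pop, year = strata[ind_id]
            assignments[ind_id] = (str(pop), int(year))
        else:
            assignments[ind_id] = _parse_stratum_from_id(ind_id, block)
        i += 1

    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    table = GenotypeTable(tuple(individuals), tuple(loci), calls)
    return table, SampleFrame(assignments)


def write_genepop(
    table: GenotypeTable,
    path,
    frame: SampleFrame | None = None,
    title: str = "transloc genotypes",
    digits: int = 3,
) -> None:
    """Write a GenePop file (3-digit codes by default).

    If ``frame`` is given, individuals are grouped into POP blocks by
    stratum (sorted); otherwise all go into one block.
    """
    if digits not in (2, 3):
        raise PopDataError("digits must be 2 or 3")
    if table.calls.max(initial=0) >= 10 ** digits:
        raise PopDataError(f"allele label too large for {digits}-digit codes")
    if frame is None:
        blocks = [list(table.individuals)]
    else:
        by_stratum: dict[tuple[str, int], list[str]] = {}
        for ind in table.individuals:
            if ind not in frame.assignments:
                logger.warning("individual %r missing from frame, dropped on write", ind)
                continue
            by_stratum.setdefault(frame.assignments[ind], []).append(ind)
        blocks = [by_stratum[k] for k in sorted(by_stratum)]
    idx = {ind: i for i, ind in enumerate(table.individuals)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for members in blocks:
            fh.write("POP\n")
            for ind in members:
                row = table.calls[idx[ind]]
                codes = " ".join(
                    f"{a1:0{digits}d}{a2:0{digits}d}" for a1, a2 in row
                )
                fh.write(f"{ind} , {codes}\n")


# ---------------------------------------------------------------------------
# CSV genotype dialect
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> tuple[GenotypeTable, SampleFrame]:
    """Read the long CSV genotype dialect ``ind,pop,year,locus,a1,a2``."""
    inds: list[str] = []
    loci: list[str] = []
    seen_calls: dict[tuple[str, str], tuple[int, int]] = {}
    assignments: dict[str, tuple[str, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"ind", "pop", "year", "locus", "a1", "a2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PopDataError(f"genotype CSV must have columns {sorted(required)}")
        for row in reader:
            ind, locus = row["ind"], row["locus"]
            if ind not in assignments:
                inds.append(ind)
                assignments[ind] = (row["pop"], int(row["year"]))
            if locus not in loci:
                loci.append(locus)
            if (ind, locus) in seen_calls:
                raise PopDataError(f"duplicate call for ({ind!r}, {locus!r})")
            seen_calls[(ind, locus)] = (int(row["a1"]), int(row["a2"]))
    calls = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    for (ind, locus), pair in seen_calls.items():
        calls[inds.index(ind), loci.index(locus)] = pair
    return GenotypeTable(tuple(inds), tuple(loci), calls), SampleFrame(assignments)


# ---------------------------------------------------------------------------
# MHC profiles
# ---------------------------------------------------------------------------

def read_mhc_profiles(path, fasta=None, size_range=(1, 10)) -> MhcProfileSet:
    """Read MHC presence profiles from CSV, optionally attaching FASTA sequences.

    Two CSV layouts are accepted: a wide 0/1 presence matrix (first column
    individual ID, remaining columns allele IDs) or a long two-column
    ``ind,allele`` table with one row per carried allele.  The universe is
    the union of observed alleles and any FASTA-only alleles.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise PopDataError("MHC CSV has no data rows")
    header, body = rows[0], rows[1:]

    def _is_binary(v: str) -> bool:
        return v.strip() in {"0", "1"}

    wide = len(header) > 2 or (
        len(header) >= 2 and all(_is_binary(r[1]) for r in body)
    )
    profiles: dict[str, set[str]] = {}
    observed: list[str] = []
    if wide:
        alleles = [h.strip() for h in header[1:]]
        observed = list(alleles)
        for r in body:
            ind = r[0].strip()
            if len(r) != len(header):
                raise PopDataError(f"row for {ind!r} has wrong column count")
            bad = [v for v in r[1:] if not _is_binary(v)]
            if bad:
                raise PopDataError(
                    f"non-binary presence values for {ind!r}: {bad[:3]}"
                )
            profiles[ind] = {a for a, v in zip(alleles, r[1:]) if v.strip() == "1"}
    else:
        for r in body:
            ind, allele = r[0].strip(), r[1].strip()
            profiles.setdefault(ind, set()).add(allele)
            if allele not in observed:
                observed.append(allele)

    empty = sorted(i for i, p in profiles.items() if not p)
    if empty:
        raise PopDataError(f"individuals with empty allele sets: {empty}")

    sequences = None
    universe = list(observed)
    if fasta is not None:
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        missing = sorted(set(observed) - set(sequences))
        if missing:
            raise PopDataError(
                f"alleles in CSV but absent from FASTA: {missing}"
            )
        for a in sequences:
            if a not in universe:
                universe.append(a)
    return MhcProfileSet(
        {i: frozenset(p) for i, p in profiles.items()},
        tuple(universe),
        sequences,
        size_range,
    )


def write_mhc_profiles(profiles: MhcProfileSet, path) -> None:
    """Write profiles as a wide 0/1 presence matrix CSV."""
    inds, mat = profiles.to_matrix()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ind", *profiles.universe])
        for ind, row in zip(inds, mat):
            writer.writerow([ind, *(int(v) for v in row)])


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
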