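import numpy as np
import pytest

from transloc.popdata import GenotypeTable, MhcProfileSet, SampleFrame
from transloc.simulate import SimConfig, simulate_mhc, simulate_source, warbler_preset


def make_table(rows, loci=None, prefix="ind"):
    """Build a GenotypeTable from a list of per-individual locus call lists.

    rows: list of lists of (a1, a2) tuples; (0, 0) marks a missing call.
    """
    n = len(rows)
    n_loci = len(rows[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    calls = np.array(rows, dtype=np.int64).reshape(n, n_loci, 2)
    inds = tuple(f"{prefix}{i + 1}" for i in range(n))
    return GenotypeTable(inds, tuple(loci), calls)


@pytest.fixture(scope="session")
def warbler_dataset():
    cfg = warbler_preset(seed=11)
    return simulate_mhc(cfg, simulate_source(cfg))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimConfig(
        seed=5, n_source=40,
        allele_counts=(2, 2, 3, 3, 4, 5),
        dirichlet_alpha=2.0,
        source_pop="src", source_year=2000,
    )
    return simulate_mhc(cfg, simulate_source(cfg))


@pytest.fixture
def two_pop_frame():
    def build(table, split):
        return SampleFrame({
            ind: ("A", 2000) if i < split else ("B", 2000)
            for i, ind in enumerate(table.individuals)
        })
    return build


@pytest.fixture
def toy_mhc():
    seqs = {
        "A01": "ACGT" * 4,
        "A02": "ACGA" * 4,
        "A03": "TCGT" * 4,
    }
    profiles = {
        "i1": frozenset({"A01", "A02"}),
        "i2": frozenset({"A01"}),
        "i3": frozenset({"A02", "A03"}),
        "i4": frozenset({"A01", "A03"}),
    }
    return MhcProfileSet(profiles, ("A01", "A02", "A03"), seqs)
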