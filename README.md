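# transloc

Population-genetic analysis toolkit for conservation translocations:
diversity estimation on codominant microsatellite genotypes and multilocus
MHC "presence" profiles, randomization tests of temporal change, a
Monte-Carlo genetic-capture rarefaction planner for founder numbers,
differentiation statistics (Weir–Cockerham F_ST, Jost's D_EST, permutation
G-test, Mantel), linkage-disequilibrium effective-population-size
estimation, and a forward Wright–Fisher simulator so the whole pipeline is
exercisable offline on synthetic data.

## Library overview

| Module | Contents |
| --- | --- |
| `transloc.popdata` | `GenotypeTable`, `MhcProfileSet`, `SampleFrame`; GenePop (2/3-digit) and CSV readers/writers, MHC presence CSV + FASTA |
| `transloc.diversity` | unbiased expected heterozygosity, exact hypergeometric rarefied allelic richness, MHC summaries (k, alleles/individual, nucleotide diversity Pi per amplicon, Ewens theta-K), pooled randomization test |
| `transloc.capture` | capture curves (coupled subsampling, 1000 replicates default), founder-size recommendations, observed-vs-expected founder assessment, exact allele-loss probabilities |
| `transloc.differentiation` | Weir–Cockerham theta (diploid + haploid carrier-count analogue) with permutation P, Jost's D with Nei–Chesser correction, global permutation G-test, Mantel test |
| `transloc.ne` | LD-based Ne (Burrows composite r², random-mating bias correction, MAF floor, parametric chi-square CI) |
| `transloc.simulate` | Dirichlet/HWE source populations, duplicated-locus MHC profiles with sequences, founder draws and Wright–Fisher drift with logistic growth; `warbler` preset tuned to a low-diversity source (H_E ≈ 0.49, richness ≈ 2.9, 10 MHC alleles, 2–8 per individual) |
| `transloc.pipeline` | YAML-driven end-to-end orchestration with per-stage seeded substreams |

## CLI

All stages are standalone subcommands of `transloc` (see `--help` on each):

```bash
# generate a synthetic study
transloc simulate --seed 1 --out-prefix demo/study \
    --translocation isleA:29:6 --translocation isleB:59:3

# per-stratum diversity table (one row per population x catch year)
transloc diversity --genepop demo/study.gen --mhc demo/study_mhc.csv \
    --fasta demo/study_mhc.fasta --out demo/diversity.csv

# randomization test of temporal change within one population
transloc temporal-test --genepop demo/study.gen --population isleA \
    --stat he --iterations 100000 --seed 1 --tail two

# genetic-capture planning
transloc capture --genepop demo/study.gen --source-stratum source:2011 \
    --filter all --replicates 1000 --target 0.95 --out demo/curve.csv

# differentiation and Mantel
transloc fst --genepop demo/study.gen --marker msat --permutations 9999 \
    --seed 1 --out demo/fst.csv --matrix-out demo/fst_mat.csv
transloc mantel demo/fst_mat.csv demo/fst_mhc_mat.csv

# LD-based Ne
transloc ne --genepop demo/study.gen --maf 0.02 --out demo/ne.csv

# everything from one config
transloc run --config study.yaml
```

A minimal `study.yaml`:

```yaml
genepop: demo/study.gen
mhc_csv: demo/study_mhc.csv
mhc_fasta: demo/study_mhc.fasta
output_dir: demo/out
seed: 1
capture_source: [source, 2011]
```

## Conventions and caveats

- Allele labels are opaque positive integers (no fragment-size arithmetic);
  allele code 0 is missing; half-calls are rejected.
- MHC locus zygosity is never inferred: profiles are allele sets, and
  carrier counts are treated as haplotype counts for Pi, theta-K, F_ST and
  D_EST.
- Rarefaction depth is in gene copies with a single global default (the
  minimum complete-call count across compared strata).
- Randomization P values use the two-sided (1+extreme)/(B+1) estimator;
  `--tail one` gives the upper-tail variant.
- Negative theta estimates are reported as computed; pipeline summary
  tables add a floored display column.
- Only the random-mating LD-Ne model is implemented; CIs are parametric
  chi-square (no jackknife).
- The simulator uses non-overlapping generations and no mutation/migration.
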