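"""End-to-end orchestration of the translocation genetics analyses.

One YAML config drives: per-stratum diversity tables, earliest-vs-latest
randomization tests per population, capture curves and founder assessments,
pairwise differentiation matrices, the Mantel comparison of microsatellite
vs MHC structure, and LD-based Ne — each stage on its own seeded random
substream so results are reproducible and stage-order independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import capture as cap
from . import differentiation as diff
from . import diversity as div
from . import ne as ne_mod
from .popdata import (
    GenotypeTable,
    MhcProfileSet,
    PopDataError,
    SampleFrame,
    read_genepop,
    read_mhc_profiles,
    subset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed: adding stages never perturbs others."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2 ** 63)


@dataclass
class PipelineConfig:
    genepop: str
    output_dir: str
    seed: int = 0
    mhc_csv: str | None = None
    mhc_fasta: str | None = None
    depth: int | None = None
    iterations: int = 10_000
    permutations: int = 999
    exact_steps: int = 30_000
    replicates: int = 1000
    capture_source: tuple[str, int] | None = None
    capture_targets: tuple[float, ...] = (0.95, 0.99)
    founder_counts: tuple[int, ...] = ()
    maf_floor: float = 0.02
    temporal_statistics: tuple[str, ...] = ("he", "richness")
    stages: tuple[str, ...] = (
        "diversity", "temporal", "capture", "differentiation", "mantel", "ne",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "capture_source" in raw and raw["capture_source"] is not None:
            raw["capture_source"] = tuple(raw["capture_source"])
        for key in ("capture_targets", "founder_counts", "temporal_statistics",
                    "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if not Path(cfg.genepop).exists():
            raise PipelineError(f"genepop file not found: {cfg.genepop}")
        return cfg


@dataclass
class PipelineResult:
    output_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _load(config: PipelineConfig):
    table, frame = read_genepop(config.genepop)
    mhc = None
    if config.mhc_csv:
        mhc = read_mhc_profiles(config.mhc_csv, config.mhc_fasta)
    return table, frame, mhc


def _diversity_stage(table, frame, mhc, config) -> pd.DataFrame:
    rows = []
    strata = frame.strata()
    depth = config.depth
    if depth is None:
        depth = min(
            div.default_depth(subset(table, frame, s)) for s in strata
        )
        logger.info("diversity: using global rarefaction depth g=%d", depth)
    for stratum in strata:
        sub = subset(table, frame, stratum)
        he = div.expected_heterozygosity(sub)
        rich = div.rarefied_allelic_richness(sub, depth)
        row = {
            "population": stratum[0],
            "year": stratum[1],
            "n_msat": sub.n_individuals,
            "he_mean": he.mean,
            "he_se": he.se,
            "richness_mean": rich.mean,
            "richness_se": rich.se,
            "depth_g": depth,
        }
        if mhc is not None:
            try:
                msub = subset(mhc, frame, stratum)
                summ = div.mhc_summary(msub)
                row.update(
                    n_mhc=summ.n_individuals,
                    mhc_alleles=summ.k,
                    mhc_per_ind=summ.mhc_per_ind,
                    pi=summ.pi,
                    theta_k=summ.theta_k,
                )
            except PopDataError:
                logger.warning("no MHC data for stratum %r", stratum)
        rows.append(row)
    return pd.DataFrame(rows)


def _temporal_stage(table, frame, mhc, config, seed) -> pd.DataFrame:
    rows = []
    by_pop: dict[str, list[int]] = {}
    for pop, year in frame.strata():
        by_pop.setdefault(pop, []).append(year)
    for i, (pop, years) in enumerate(sorted(by_pop.items())):
        if len(years) < 2:
            continue
        first, last = min(years), max(years)
        a = subset(table, frame, (pop, first))
        b = subset(table, frame, (pop, last))
        g = min(div.default_depth(a), div.default_depth(b))
        for stat in config.temporal_statistics:
            if stat in ("he", "richness"):
                sa, sb = a, b
            else:
                if mhc is None:
                    continue
                sa = subset(mhc, frame, (pop, first))
                sb = subset(mhc, frame, (pop, last))
            res = div.randomization_test(
                sa, sb, stat, iterations=config.iterations,
                seed=seed + i, g=g,
            )
            rows.append({
                "population": pop, "first_year": first, "last_year": last,
                "statistic": stat, "observed_diff": res.observed_diff,
                "iterations": res.iterations, "p_value": res.p_value,
            })
    return pd.DataFrame(rows)


def _capture_stage(table, frame, mhc, config, seed):
    stratum = config.capture_source
    if stratum is None:
        # latest year of the first population by name
        strata = frame.strata()
        pops = sorted({p for p, _ in strata})
        years = [y for p, y in strata if p == pops[0]]
        stratum = (pops[0], max(years))
        logger.info("capture: defaulting to source stratum %r", stratum)
    src = subset(table, frame, stratum)
    curves = {}
    curve_rows = []
    specs = [("all", src), ("diverse", src)]
    if mhc is not None:
        try:
            specs.append(("mhc", subset(mhc, frame, stratum)))
        except PopDataError:
            pass
    for k, (marker, source) in enumerate(specs):
        try:
            curve = cap.build_capture_curve(
                source, marker if marker != "mhc" else "mhc",
                replicates=config.replicates, seed=seed + k,
            )
        except cap.CaptureError as exc:
            logger.warning("capture: skipping %s (%s)", marker, exc)
            continue
        curves[marker] = curve
        for n, mean, sd, se, lo, hi in zip(
            curve.ns, curve.means, curve.sds, curve.ses, curve.pct5, curve.pct95
        ):
            curve_rows.append({
                "marker": marker, "n_founders": n, "mean": mean, "sd": sd,
                "se": se, "pct5": lo, "pct95": hi,
                "captured_fraction": mean / curve.full_value,
            })
    assess_rows = []
    rng_seed = seed + 101
    for marker, curve in curves.items():
        for target in config.capture_targets:
            rec = cap.min_founders(curve, target)
            assess_rows.append({
                "marker": marker, "kind": "recommendation",
                "target_fraction": target, "n_founders": rec.n,
                "attainable": rec.attainable,
                "expected_fraction": rec.expected_fraction,
                "observed": None, "p_value": None,
            })
        source = specs[[m for m, _ in specs].index(marker)][1]
        import numpy as _np
        rng = _np.random.default_rng(rng_seed)
        ids = (
            source.individuals
            if isinstance(source, GenotypeTable)
            else tuple(source.profiles)
        )
        for n_f in config.founder_counts:
            if n_f > len(ids):
                continue
            founders = list(
                rng.choice(_np.array(ids, dtype=object), size=n_f, replace=False)
            )
            res = cap.assess_founders(curve, source, founders)
            assess_rows.append({
                "marker": marker, "kind": "assessment",
                "target_fraction": None, "n_founders": n_f,
                "attainable": None,
                "expected_fraction": res.expected_mean / curve.full_value,
                "observed": res.observed, "p_value": res.p_value,
            })
    return pd.DataFrame(curve_rows), pd.DataFrame(assess_rows)


def _differentiation_stage(table, frame, mhc, config, seed):
    strata = frame.strata()
    out = {}
    mats = {}
    for marker, data in (("msat", table), ("mhc", mhc)):
        if data is None:
            continue
        usable = []
        for s in strata:
            try:
                sub = subset(data, frame, s)
            except PopDataError:
                continue
            n = (
                sub.n_individuals
                if isinstance(sub, GenotypeTable)
                else len(sub.profiles)
            )
            if n >= 2:
                usable.append(s)
        if len(usable) < 2:
            continue
        fst = diff.pairwise_matrix(
            data, frame, usable, "fst",
            permutations=config.permutations, seed=seed,
        )
        dest = diff.pairwise_matrix(data, frame, usable, "dest", permutations=0)
        mats[marker] = (fst, dest, usable)
        rows = []
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                rows.append({
                    "stratum_a": fst.labels[i], "stratum_b": fst.labels[j],
                    "fst": fst.values[i, j], "fst_p": fst.p_values[i, j],
                    "fst_displayed": max(fst.values[i, j], 0.0),
                    "dest": dest.values[i, j],
                })
        out[marker] = pd.DataFrame(rows)
    return out, mats


def _exact_stage(table, frame, config, seed) -> pd.DataFrame:
    rows = []
    by_pop: dict[str, list[int]] = {}
    for pop, year in frame.strata():
        by_pop.setdefault(pop, []).append(year)
    for pop, years in sorted(by_pop.items()):
        if len(years) < 2:
            continue
        strata = [(pop, y) for y in sorted(years)]
        res = diff.global_exact_test(
            table, frame, strata, steps=config.exact_steps, seed=seed,
        )
        rows.append({
            "population": pop, "years": ",".join(str(y) for y in sorted(years)),
            "g_statistic": res.value, "steps": res.permutations,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def _ne_stage(table, frame, config) -> pd.DataFrame:
    rows = []
    for stratum in frame.strata():
        try:
            est = ne_mod.ld_ne(table, frame, stratum, maf_floor=config.maf_floor)
        except ne_mod.NeError as exc:
            logger.warning("ne: skipping %r (%s)", stratum, exc)
            continue
        rows.append({
            "population": stratum[0], "year": stratum[1],
            "s_harmonic": est.s_harmonic, "mean_r2": est.mean_r2,
            "r2_corrected": est.r2_corrected, "ne": est.ne,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "maf_floor": est.maf_floor, "n_comparisons": est.n_comparisons,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all configured stages; outputs land in ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("transloc")
    root.addHandler(handler)
    result = PipelineResult(outdir)
    try:
        table, frame, mhc = _load(config)
        logger.info("loaded %d individuals, %d loci, seed=%d",
                    table.n_individuals, table.n_loci, config.seed)
        stage_errors: list[str] = []

        def run_stage(name, fn):
            try:
                return fn()
            except Exception as exc:
                stage_errors.append(name)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        if "diversity" in config.stages:
            df = run_stage(
                "diversity", lambda: _diversity_stage(table, frame, mhc, config)
            )
            df.to_csv(outdir / "diversity.csv", index=False)
            result.tables["diversity"] = df
        if "temporal" in config.stages:
            df = run_stage("temporal", lambda: _temporal_stage(
                table, frame, mhc, config, stage_seed(config.seed, "temporal")))
            df.to_csv(outdir / "temporal_tests.csv", index=False)
            result.tables["temporal"] = df
        if "capture" in config.stages:
            curves, assessments = run_stage("capture", lambda: _capture_stage(
                table, frame, mhc, config, stage_seed(config.seed, "capture")))
            curves.to_csv(outdir / "capture_curves.csv", index=False)
            assessments.to_csv(outdir / "assessments.csv", index=False)
            result.tables["capture_curves"] = curves
            result.tables["assessments"] = assessments
        if "differentiation" in config.stages:
            tables, mats = run_stage(
                "differentiation", lambda: _differentiation_stage(
                    table, frame, mhc, config,
                    stage_seed(config.seed, "differentiation")))
            for marker, df in tables.items():
                df.to_csv(outdir / f"fst_{marker}.csv", index=False)
                result.tables[f"fst_{marker}"] = df
            exact = run_stage("exact", lambda: _exact_stage(
                table, frame, config, stage_seed(config.seed, "exact")))
            exact.to_csv(outdir / "exact_tests.csv", index=False)
            result.tables["exact"] = exact
            result.tables["_matrices"] = mats
        if "mantel" in config.stages:
            mats = result.tables.get("_matrices", {})
            if "msat" in mats and "mhc" in mats:
                fst_m, _, strata_m = mats["msat"]
                fst_h, _, strata_h = mats["mhc"]
                common = [s for s in strata_m if s in strata_h]
                if len(common) >= 4:
                    def reindex(mat, strata):
                        import numpy as _np
                        pos = [strata.index(s) for s in common]
                        labels = tuple(mat.labels[p] for p in pos)
                        return diff.DistanceMatrix(
                            labels, mat.values[_np.ix_(pos, pos)]
                        )
                    res = diff.mantel(
                        reindex(fst_m, strata_m), reindex(fst_h, strata_h),
                        permutations=config.permutations,
                        seed=stage_seed(config.seed, "mantel"),
                    )
                    (outdir / "mantel.txt").write_text(
                        f"r_M = {res.r:.4f}\nP = {res.p_value:.5f}\n"
                        f"permutations = {res.permutations}\n"
                    )
                    result.tables["mantel"] = pd.DataFrame(
                        [{"r": res.r, "p_value": res.p_value}]
                    )
                else:
                    logger.warning("mantel: fewer than 4 shared strata, skipped")
            else:
                logger.warning("mantel: needs both msat and mhc matrices, skipped")
        if "ne" in config.stages:
            df = run_stage("ne", lambda: _ne_stage(table, frame, config))
            df.to_csv(outdir / "ne.csv", index=False)
            result.tables["ne"] = df

        manifest = {
            "seed": config.seed,
            "stages": list(config.stages),
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in ("temporal", "capture", "differentiation", "exact", "mantel")
            },
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    result.tables.pop("_matrices", None)
    return result
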