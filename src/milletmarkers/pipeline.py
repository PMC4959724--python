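"""Configuration and the umbrella pipeline tying the stages together.

A run is described by a flat ``key = value`` config (unknown keys are
rejected) and executes, in order: synthetic-data generation, SSR
mining, homeolog-aware SNP filtering, per-locus diversity statistics,
and distance/UPGMA plus admixture-MCMC population structure.  Every
intermediate is written to the output directory together with a
parameter log, and a given (config, seed) pair reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .diversity import locus_summary, qc_filter
from .popstruct import (align_runs, best_k, delta_k, gibbs_admixture,
                        ibs_distance, lnpd, upgma)
from .ssr import SSRParams, find_ssrs, summarize_ssrs
from .synthetic import (plant_ssrs, random_ssr_specs,
                        simulate_allotetraploid_variants,
                        simulate_genotype_matrix)
from .variants import (filter_sites, homeolog_positions, subtract_homeologs,
                       summarize_variants)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("milletmarkers")


@dataclass
class PipelineConfig:
    """All pipeline stages and thresholds, with the study defaults."""

    outdir: str = "millet_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    mine_ssr: bool = True
    filter_snps: bool = True
    diversity: bool = True
    structure: bool = True
    # synthetic data
    n_contigs: int = 5
    contig_length: int = 20_000
    n_ssrs: int = 20
    variant_bp: int = 100_000
    n_genotypes: int = 2
    homeolog_rate: float = 1.0 / 657.0
    allelic_rate: float = 1.0 / 3306.0
    sim_k: int = 2
    n_per_pop: int = 15
    n_loci: int = 60
    divergence: float = 0.6
    sim_alpha: float = 0.1
    selfing: float = 0.9
    missing_rate: float = 0.02
    # SSR mining
    min_repeats: int = 5
    min_length: int = 10
    # SNP filtering
    min_quality: float = 30.0
    max_alleles: int = 2
    min_depth: int = 3
    # diversity QC
    max_sample_missing: float = 0.80
    max_locus_missing: float = 0.90
    # structure
    k_min: int = 1
    k_max: int = 3
    runs: int = 2
    burnin: int = 200
    reps: int = 800
    alpha: float = 1.0
    outgroup: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cls, key, None)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return run
    return wrap


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, out: Path, artifacts: dict) -> None:
    specs = random_ssr_specs(cfg.n_ssrs, cfg.n_contigs, cfg.contig_length,
                             seed=cfg.seed)
    contigs, ssr_truths = plant_ssrs(cfg.n_contigs, cfg.contig_length,
                                     specs, seed=cfg.seed)
    mio.write_fasta(contigs, out / "contigs.fasta")
    pd.DataFrame([dataclasses.asdict(t) for t in ssr_truths]).to_csv(
        out / "ssr_truth.tsv", sep="\t", index=False)
    artifacts["contigs"] = out / "contigs.fasta"
    artifacts["ssr_truth"] = out / "ssr_truth.tsv"

    self_sets, combined, var_truths = simulate_allotetraploid_variants(
        cfg.variant_bp, cfg.n_genotypes, cfg.homeolog_rate, cfg.allelic_rate,
        seed=cfg.seed + 1)
    for g, sites in self_sets.items():
        mio.write_vcf(sites, out / f"self_{g}.vcf")
        artifacts[f"self_{g}"] = out / f"self_{g}.vcf"
    mio.write_vcf(combined, out / "combined.vcf")
    pd.DataFrame([dataclasses.asdict(t) for t in var_truths]).to_csv(
        out / "variant_truth.tsv", sep="\t", index=False)
    artifacts["combined"] = out / "combined.vcf"
    artifacts["variant_truth"] = out / "variant_truth.tsv"

    matrix, pop_truth = simulate_genotype_matrix(
        cfg.sim_k, cfg.n_per_pop, cfg.n_loci, cfg.divergence, cfg.sim_alpha,
        cfg.selfing, cfg.missing_rate, seed=cfg.seed + 2)
    mio.write_genotype_csv(matrix, out / "genotypes.csv")
    mio.write_groups_csv(matrix.groups, out / "groups.csv")
    (out / "population_truth.json").write_text(json.dumps({
        "K": pop_truth.K,
        "Q_true": pop_truth.Q_true.tolist(),
        "P_true": pop_truth.P_true.tolist(),
        "selfing": pop_truth.selfing,
    }, indent=1))
    artifacts["genotypes"] = out / "genotypes.csv"
    artifacts["groups"] = out / "groups.csv"
    artifacts["population_truth"] = out / "population_truth.json"


@_stage("mine_ssr")
def _run_mine_ssr(cfg: PipelineConfig, out: Path, artifacts: dict) -> None:
    records = mio.read_fasta(artifacts.get("contigs", out / "contigs.fasta"))
    params = SSRParams(min_repeats=cfg.min_repeats, min_length=cfg.min_length)
    loci = [l for name, seq in records for l in find_ssrs(name, seq, params)]
    pd.DataFrame([{
        "contig": l.contig_id, "start": l.start, "end": l.end,
        "motif": l.motif, "class": l.canonical_class,
        "repeats": l.n_repeats, "length": l.length,
    } for l in loci]).to_csv(out / "ssr_loci.tsv", sep="\t", index=False)
    total_bp = sum(len(seq) for _, seq in records)
    summary = summarize_ssrs(loci, total_bp)
    rows = [{"category": "ALL", "count": summary.total,
             "frequency": summary.frequency["ALL"]}]
    rows += [{"category": f"unit{u}", "count": c,
              "frequency": summary.frequency[f"unit{u}"]}
             for u, c in summary.by_unit.items()]
    rows += [{"category": cls, "count": c, "frequency": summary.frequency[cls]}
             for cls, c in summary.by_class.items()]
    pd.DataFrame(rows).to_csv(out / "ssr_summary.tsv", sep="\t", index=False)
    artifacts["ssr_loci"] = out / "ssr_loci.tsv"
    artifacts["ssr_summary"] = out / "ssr_summary.tsv"


@_stage("filter_snps")
def _run_filter_snps(cfg: PipelineConfig, out: Path, artifacts: dict) -> None:
    from .variants import HomeologSet
    self_paths = sorted(p for k, p in artifacts.items() if k.startswith("self_"))
    if not self_paths:
        self_paths = sorted(out.glob("self_*.vcf"))
    self_sets = []
    for path in self_paths:
        sites, _ = mio.read_vcf(path)
        self_sets.append(HomeologSet(Path(path).stem.removeprefix("self_"),
                                     {s.key for s in sites}))
    combined, _ = mio.read_vcf(artifacts.get("combined", out / "combined.vcf"))
    passed = filter_sites(combined, cfg.min_quality, cfg.max_alleles,
                          cfg.min_depth)
    retained = subtract_homeologs(passed, homeolog_positions(self_sets))
    mio.write_vcf(retained, out / "retained_snps.vcf")
    summary = summarize_variants(retained, cfg.variant_bp)
    pd.DataFrame([{
        "n_retained": len(retained),
        "n_transitions": summary.n_transitions,
        "n_transversions": summary.n_transversions,
        "tstv": round(summary.tstv, 1),
        "frequency": summary.frequency,
        **{f"frac_{k}": v for k, v in summary.spectrum.items()},
    }]).to_csv(out / "snp_summary.tsv", sep="\t", index=False)
    artifacts["retained_snps"] = out / "retained_snps.vcf"
    artifacts["snp_summary"] = out / "snp_summary.tsv"


@_stage("diversity")
def _run_diversity(cfg: PipelineConfig, out: Path, artifacts: dict) -> None:
    groups = mio.read_groups_csv(artifacts.get("groups", out / "groups.csv"))
    matrix = mio.read_genotype_csv(artifacts.get("genotypes",
                                                 out / "genotypes.csv"),
                                   groups=groups)
    filtered, report = qc_filter(matrix, cfg.max_sample_missing,
                                 cfg.max_locus_missing)
    report.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    table = locus_summary(filtered,
                          group_labels=tuple(sorted(set(groups.values()))))
    table.to_csv(out / "locus_stats.tsv", sep="\t")
    artifacts["qc_exclusions"] = out / "qc_exclusions.tsv"
    artifacts["locus_stats"] = out / "locus_stats.tsv"
    artifacts["_qc_matrix"] = filtered


@_stage("structure")
def _run_structure(cfg: PipelineConfig, out: Path, artifacts: dict) -> None:
    matrix = artifacts.get("_qc_matrix")
    if matrix is None:
        groups = mio.read_groups_csv(artifacts.get("groups", out / "groups.csv"))
        matrix, _ = qc_filter(
            mio.read_genotype_csv(artifacts.get("genotypes",
                                                out / "genotypes.csv"),
                                  groups=groups),
            cfg.max_sample_missing, cfg.max_locus_missing)
    dm = ibs_distance(matrix)
    tree = upgma(dm)
    tree.write(str(out / "upgma.nwk"))
    artifacts["upgma"] = out / "upgma.nwk"

    lnpd_by_k: dict[int, list[float]] = {}
    for K in range(cfg.k_min, cfg.k_max + 1):
        runs = []
        for r in range(cfg.runs):
            run = gibbs_admixture(matrix, K, cfg.burnin, cfg.reps, cfg.alpha,
                                  seed=cfg.seed + 1000 * K + r)
            runs.append(run)
            pd.DataFrame(run.Q, index=matrix.sample_ids).to_csv(
                out / f"Q_K{K}_run{r + 1}.csv")
        lnpd_by_k[K] = [lnpd(r) for r in runs]
        avg = align_runs(runs)
        pd.DataFrame(avg, index=matrix.sample_ids).to_csv(out / f"Q_K{K}.csv")
        artifacts[f"Q_K{K}"] = out / f"Q_K{K}.csv"
    if cfg.k_max - cfg.k_min >= 2 and cfg.runs >= 2:
        table = delta_k(lnpd_by_k)
        table.to_csv(out / "delta_k.tsv", sep="\t")
        artifacts["delta_k"] = out / "delta_k.tsv"
        try:
            logger.info("delta-K optimum at K=%d", best_k(table))
        except ValueError:
            logger.info("delta-K undefined at every K")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns the artifact paths."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    np.random.seed(cfg.seed % (2 ** 31))  # legacy consumers only; stages use Generators
    artifacts: dict[str, Path] = {}
    cfg.to_file(out / "run_params.log")
    if cfg.simulate:
        _run_simulate(cfg, out, artifacts)
    if cfg.mine_ssr:
        _run_mine_ssr(cfg, out, artifacts)
    if cfg.filter_snps:
        _run_filter_snps(cfg, out, artifacts)
    if cfg.diversity:
        _run_diversity(cfg, out, artifacts)
    if cfg.structure:
        _run_structure(cfg, out, artifacts)
    artifacts.pop("_qc_matrix", None)
    artifacts["run_params"] = out / "run_params.log"
    return artifacts
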