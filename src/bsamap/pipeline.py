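"""End-to-end orchestration: simulate -> bulk -> call/filter -> associate ->
cluster -> annotate -> report, with a persisted run manifest.

Every stage parameter defaults to the published value where one exists
(bulk caller 20/20/90%, parent caller 5/5/100%, phred >= 30, alpha 0.05,
HAB frequency cutoff 90%, 10-member bulks from 100 progeny, bulk depths
53x/59x, 4.76 cM/Mbp).  The configuration round-trips through YAML and a
``--set key=value`` override mechanism so a run is fully described by its
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import classify_candidates, coverage_report
from .bulking import bulk_table, select_bulks
from .cds_annot import annotate_substitutions
from .clustering import cluster_candidates, regions_bed, regions_table
from .coexpress import screen_guides
from .genome import DEFAULT_CM_PER_MBP, default_rice_genome
from .io import (read_expression_matrix, read_gene_list, read_tsv, write_tsv,
                 write_pileup_vcf)
from .simulate import (DONOR, RECURRENT, PhredModel, QtlModel, assign_phenotypes,
                       breed_bc2f8, founder, genotype_table, phenotype_table,
                       simulate_cohort_pileup)
from .variant_filter import (BULK_PARAMS, PARENT_PARAMS, CallParams, call_cohort,
                             parent_genotypes, run_cascade)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # simulation
    seed: int = 1
    n_progeny: int = 100
    site_spacing: int = 50_000
    cm_per_mbp: float = DEFAULT_CM_PER_MBP
    baseline_ac: float = 23.2
    qtl_effects: list = field(default_factory=lambda: [
        ["chr06", 1_769_686, +2.5],
        ["chr11", 18_288_616, +0.75],
        ["chr01", 30_038_502, -2.25],
    ])
    env_sd: float = 0.8
    hab_depth: float = 53.0
    lab_depth: float = 59.0
    parent_depth: float = 30.0
    error_rate: float = 0.005
    phred_value: float = 40.0
    phred_degraded_fraction: float = 0.0
    phred_degraded_value: float = 20.0
    # bulking
    n_per_bulk: int = 10
    # calling / filtering
    bulk_min_coverage: int = 20
    bulk_min_count: int = 20
    bulk_min_freq: float = 0.90
    parent_min_coverage: int = 5
    parent_min_count: int = 5
    parent_min_freq: float = 1.00
    min_phred: float = 30.0
    noise_floor: int = 2
    # association
    alpha: float = 0.05
    hab_freq_cutoff: float = 0.90
    direction: bool = True
    bonferroni: bool = False
    expected_min_coverage: int = 20
    # clustering
    max_gap: int = 1_000_000
    # optional real-data / annotation inputs
    cds_substitutions: str | None = None   # TSV: position, ref, alt, ref_aa
    expression_matrix: str | None = None   # TSV genes x samples
    guide_genes: str | None = None         # text file, one gene per line
    coexpress_cutoff: float = 0.6
    write_vcf: bool = True

    @property
    def bulk_params(self) -> CallParams:
        return CallParams(self.bulk_min_coverage, self.bulk_min_count,
                          self.bulk_min_freq)

    @property
    def parent_params(self) -> CallParams:
        return CallParams(self.parent_min_coverage, self.parent_min_count,
                          self.parent_min_freq)

    @property
    def qtl_model(self) -> QtlModel:
        effects = [(c, int(p), float(e)) for c, p, e in self.qtl_effects]
        return QtlModel(self.baseline_ac, effects, self.env_sd)

    @property
    def phred_model(self) -> PhredModel:
        return PhredModel(self.phred_value, self.phred_degraded_fraction,
                          self.phred_degraded_value)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def apply_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` overrides (values parsed as YAML scalars)."""
        cfg = dataclasses.replace(self)
        valid = {f.name for f in dataclasses.fields(cfg)}
        for item in overrides:
            key, _, raw = item.partition("=")
            if key not in valid:
                raise KeyError(f"unknown config key {key!r}")
            setattr(cfg, key, yaml.safe_load(raw))
        return cfg


@dataclass
class RunResult:
    config: PipelineConfig
    outdir: Path
    phenotypes: pd.DataFrame
    bulks: pd.DataFrame
    filter_ledger: pd.DataFrame
    results: pd.DataFrame            # every evaluated site
    candidates: pd.DataFrame         # passing sites only
    regions: pd.DataFrame
    cds_annotation: pd.DataFrame | None = None
    coexpression: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 make_figure: bool = True) -> RunResult:
    """Execute the full synthetic-mode pipeline and persist every stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        genome = default_rice_genome(config.site_spacing, config.cm_per_mbp)
        qtl = config.qtl_model
        qtl.validate_sites(genome)
        ss = np.random.SeedSequence(config.seed)
        s_breed, s_pheno, s_hab, s_lab, s_p1, s_p2 = ss.spawn(6)
        population = breed_bc2f8(genome, config.n_progeny, s_breed)
        assign_phenotypes(population, qtl, np.random.default_rng(s_pheno))
        phenos = phenotype_table(population)
        write_tsv(phenos, outdir / "phenotypes.tsv")
        write_tsv(genotype_table(population, genome), outdir / "genotypes.tsv")

        stage = "select_bulks"
        hab_def, lab_def = select_bulks(phenos, config.n_per_bulk)
        bulks = bulk_table(hab_def, lab_def)
        write_tsv(bulks, outdir / "bulks.tsv")
        by_id = {ind.id: ind for ind in population}
        hab_members = [by_id[m] for m in hab_def.members]
        lab_members = [by_id[m] for m in lab_def.members]

        stage = "sequence"
        pm = config.phred_model
        hab_pile = simulate_cohort_pileup(hab_members, genome, config.hab_depth,
                                          config.error_rate,
                                          np.random.default_rng(s_hab), pm, "HAB")
        lab_pile = simulate_cohort_pileup(lab_members, genome, config.lab_depth,
                                          config.error_rate,
                                          np.random.default_rng(s_lab), pm, "LAB")
        donor_pile = simulate_cohort_pileup([founder(genome, DONOR)], genome,
                                            config.parent_depth, config.error_rate,
                                            np.random.default_rng(s_p1), pm, "donor")
        recur_pile = simulate_cohort_pileup([founder(genome, RECURRENT)], genome,
                                            config.parent_depth, config.error_rate,
                                            np.random.default_rng(s_p2), pm,
                                            "recurrent")
        if config.write_vcf:
            write_pileup_vcf(outdir / "pileups.vcf", genome,
                             {"HAB": hab_pile, "LAB": lab_pile,
                              "donor": donor_pile, "recurrent": recur_pile})

        stage = "call_filter"
        ref = genome.sites.rename(columns={"recurrent": "ref"})
        hab_calls = call_cohort(hab_pile, config.bulk_params, ref)
        lab_calls = call_cohort(lab_pile, config.bulk_params, ref)
        donor_geno = parent_genotypes(donor_pile, config.parent_params)
        recur_geno = parent_genotypes(recur_pile, config.parent_params)
        hab_f, lab_f, ledger = run_cascade(
            hab_calls, lab_calls,
            [hab_pile, lab_pile, donor_pile, recur_pile],
            donor_geno, recur_geno,
            min_phred=config.min_phred, noise_floor=config.noise_floor)
        write_tsv(ledger, outdir / "filter_ledger.tsv")
        write_tsv(hab_f, outdir / "hab_calls.tsv")
        write_tsv(lab_f, outdir / "lab_calls.tsv")

        stage = "associate"
        results = classify_candidates(
            hab_f, lab_f, hab_pile, lab_pile, donor_geno, recur_geno,
            alpha=config.alpha, hab_freq_cutoff=config.hab_freq_cutoff,
            direction=config.direction, bonferroni=config.bonferroni)
        results = coverage_report(results, config.expected_min_coverage)
        write_tsv(results, outdir / "association.tsv")
        candidates = results[results["passed"]].reset_index(drop=True)
        write_tsv(candidates, outdir / "candidates.tsv")

        stage = "cluster"
        regions = cluster_candidates(candidates, config.max_gap, config.cm_per_mbp)
        write_tsv(regions_table(regions), outdir / "regions.tsv")
        write_tsv(regions_bed(regions), outdir / "regions.bed")

        stage = "annotate"
        cds_out = None
        if config.cds_substitutions:
            cds_out = annotate_substitutions(read_tsv(config.cds_substitutions))
            write_tsv(cds_out, outdir / "cds_annotation.tsv")

        stage = "coexpress"
        coex_out = None
        if config.expression_matrix and config.guide_genes:
            matrix = read_expression_matrix(config.expression_matrix)
            guides = read_gene_list(config.guide_genes)
            cand_genes = [g for g in matrix.index if g not in guides]
            coex_out = screen_guides(matrix, guides, cand_genes,
                                     config.coexpress_cutoff)
            write_tsv(coex_out, outdir / "coexpression.tsv")

        stage = "report"
        if make_figure:
            from .plotting import plot_allele_frequency
            plot_allele_frequency(results, regions, genome,
                                  outdir / "allele_frequency.png")
        _write_manifest(config, outdir, ledger, results, regions)
    except Exception as exc:
        logger.exception("pipeline failed at stage %r (partial outputs in %s)",
                         stage, outdir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunResult(config, outdir, phenos, bulks, ledger, results,
                     candidates, regions_table(regions), cds_out, coex_out)


def _write_manifest(config: PipelineConfig, outdir: Path, ledger: pd.DataFrame,
                    results: pd.DataFrame, regions) -> None:
    import scipy
    manifest = {
        "bsamap_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config": dataclasses.asdict(config),
        "counts": {
            "filter_ledger": ledger.to_dict(orient="records"),
            "evaluated_sites": int(len(results)),
            "candidates": int(results["passed"].sum()) if len(results) else 0,
            "regions": len(regions),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
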