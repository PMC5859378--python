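"""End-to-end orchestration: QC -> parentage -> relationship matrices ->
variance components -> GWAS -> cross-validation.

Stage order mirrors a genomic-evaluation workflow for a factorial cross
with initially unknown family structure.  Every stage writes its artifact
under the output directory, and a provenance log records inputs,
parameters, the seed, and record counts entering/leaving each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio

from .parentage import assign_parents, validate_pedigree

from .predict import density_scenarios, make_folds, scenario_table
from .qc import filter_genotypes
from .relmat import condition_matrix, pedigree_numerator_matrix, vanraden_grm
from .gwas import mixed_model_gwas
from .varcomp import ModelSpec, bivariate_reml_fit, reml_fit

log = logging.getLogger("carpgs")


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters; round-trips through YAML."""

    genotypes: str = ""
    genotype_format: str | None = None
    phenotypes: str = ""
    pedigree: str | None = None
    parents: list[str] = field(default_factory=list)
    out_dir: str = "out"
    # stage toggles
    do_qc: bool = True
    do_parentage: bool = True
    do_varcomp: bool = True
    do_gwas: bool = True
    do_cv: bool = True
    # stage parameters
    maf_min: float = 0.01
    locus_miss_max: float = 0.25
    hwe_p_min: float = 1e-06
    sample_miss_max: float = 0.25
    parentage_tolerance: float = 0.04
    parentage_margin: float = 0.01
    trait: str = "length_mm"
    second_trait: str = "weight_g"
    fixed: str = "cross"
    panels: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.45])
    n_folds: int = 5
    n_repeats: int = 10
    cv_components: str = "per-fold"
    blend_alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the provenance log.

    A failing stage raises, leaving the log written up to that point with
    the name of the stage to rerun.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    prov: dict = {"seed": cfg.seed, "config_hash": chash, "stages": {}}
    prov_path = out / "provenance.json"

    def checkpoint(stage: str, info: dict) -> None:
        prov["stages"][stage] = info
        prov_path.write_text(json.dumps(prov, indent=2, default=str))
        log.info("stage %s: %s", stage, info)

    geno = cio.read_genotypes(cfg.genotypes, cfg.genotype_format)
    phenos = cio.read_phenotypes(cfg.phenotypes)
    parents = [str(p) for p in cfg.parents]
    if not parents and cfg.pedigree:
        parents = list(cio.read_pedigree(cfg.pedigree).founders())
    checkpoint("load", {"n_samples": geno.n_samples, "n_loci": geno.n_loci,
                        "n_phenotyped": len(phenos), "n_parents": len(parents)})

    if cfg.do_qc:
        geno, report = filter_genotypes(
            geno, parents, maf_min=cfg.maf_min, locus_miss_max=cfg.locus_miss_max,
            hwe_p_min=cfg.hwe_p_min, sample_miss_max=cfg.sample_miss_max,
        )
        cio.write_table_with_provenance(report.locus_table, out / "qc_loci.tsv", cfg.seed, chash)
        cio.write_table_with_provenance(report.sample_table, out / "qc_samples.tsv", cfg.seed, chash)
        (out / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2))
        checkpoint("qc", report.summary())

    if cfg.do_parentage:
        if not parents:
            raise RuntimeError("parentage stage needs --parents or a pedigree with founders")
        sires = [p for p in parents if p.startswith("S")]
        dams = [p for p in parents if p.startswith("D")]
        if not sires or not dams:
            half = len(parents) // 2
            sires, dams = parents[:half], parents[half:]
        offspring_ids = [s for s in geno.samples if s not in set(parents)]
        result = assign_parents(
            geno.subset_samples(offspring_ids), geno.subset_samples(sires),
            geno.subset_samples(dams), tolerance=cfg.parentage_tolerance,
            margin=cfg.parentage_margin,
        )
        cio.write_table_with_provenance(result.table, out / "parentage.tsv", cfg.seed, chash)
        pedigree = result.to_pedigree()
        flags = validate_pedigree(pedigree, geno, threshold=cfg.parentage_tolerance)
        cio.write_table_with_provenance(flags, out / "parentage_validation.tsv", cfg.seed, chash)
        cio.write_pedigree(pedigree, out / "pedigree_assigned.csv")
        checkpoint("parentage", {**result.family_summary(),
                                 "n_flagged_links": int(flags["flagged"].sum())})
    elif cfg.pedigree:
        pedigree = cio.read_pedigree(cfg.pedigree)
        checkpoint("parentage", {"skipped": True, "pedigree": cfg.pedigree})
    else:
        pedigree = None

    analysis_ids = [i for i in phenos["id"] if i in set(geno.samples)]
    if pedigree is not None:
        in_ped = set(pedigree.ids)
        analysis_ids = [i for i in analysis_ids if i in in_ped]
    phenos_a = phenos.set_index("id", drop=False).loc[analysis_ids].reset_index(drop=True)
    geno_a = geno.subset_samples(analysis_ids)
    grm = condition_matrix(vanraden_grm(geno_a), cfg.blend_alpha)
    amat = pedigree_numerator_matrix(pedigree) if pedigree is not None else None
    grm.to_tsv(out / "grm.tsv")
    checkpoint("relmat", {"n_analysis": len(analysis_ids), "grm_markers": geno_a.n_loci})

    spec = ModelSpec(traits=(cfg.trait,), fixed=cfg.fixed)
    if cfg.do_varcomp:
        comps = {"G": reml_fit(phenos_a, spec, grm).to_dict()}
        if amat is not None:
            comps["A"] = reml_fit(phenos_a, spec, amat).to_dict()
        if cfg.second_trait in phenos_a.columns:
            bspec = ModelSpec(traits=(cfg.second_trait, cfg.trait), fixed=cfg.fixed)
            comps["bivariate_G"] = bivariate_reml_fit(phenos_a, bspec, grm).to_dict()
        (out / "varcomp.json").write_text(json.dumps(comps, indent=2))
        checkpoint("varcomp", {k: {"h2": v["h2"], "rg": v["rg"]} for k, v in comps.items()})

    if cfg.do_gwas:
        res = mixed_model_gwas(phenos_a, geno_a, grm, spec)
        cio.write_table_with_provenance(res.table, out / "gwas.tsv", cfg.seed, chash)
        checkpoint("gwas", {"n_tested": res.n_tested, "threshold": res.threshold,
                            "n_significant": int(len(res.significant())),
                            "lambda_gc": res.lambda_gc()})

    if cfg.do_cv:
        scheme = make_folds(analysis_ids, n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
                            seed=cfg.seed)
        results = density_scenarios(
            phenos_a, geno_a, scheme, thresholds=cfg.panels, pedigree=pedigree,
            spec=spec, components=cfg.cv_components, blend_alpha=cfg.blend_alpha,
        )
        table = scenario_table(results)
        with open(out / "cv_table.tsv", "w") as fh:
            fh.write(f"# carpgs seed={cfg.seed} config_hash={chash}\n")
            table.to_csv(fh, sep="\t")
        (out / "cv_summary.json").write_text(
            json.dumps({k: v.summary() for k, v in results.items()}, indent=2)
        )
        checkpoint("cv", {k: round(v.mean_accuracy, 4) for k, v in results.items()})

    return prov
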