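"""End-to-end replication of the genomic-evaluation study on simulated data.

One call simulates the partial factorial cross with the genome template and
trait parameters of the study, applies SNP quality control, reconstructs
the pedigree from the SNPs, subsamples the assigned offspring to the
study's cross-validation cohort size (1,214 by default, giving the printed
972/242 fivefold split), and runs the paired GBLUP / PBLUP cross-validation
over marker-density scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .parentage import AssignmentResult, assign_parents
from .pedigree import Pedigree
from .predict import CVResult, CVScheme, density_scenarios, make_folds
from .qc import QCReport, filter_genotypes
from .simdata import SimConfig, TruePopulation, simulate_population
from .varcomp import ModelSpec


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one base seed."""
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class StudyReplicate:
    """Everything produced by one simulated pass through the study."""

    population: TruePopulation
    qc_report: QCReport
    assignment: AssignmentResult
    pedigree: Pedigree            # assigned pedigree, restricted to the cohort
    cohort_ids: list              # offspring entering cross-validation
    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix     # QC-passing genotypes of the cohort
    scheme: CVScheme
    cv_results: dict[str, CVResult]

    def assignment_correct_fraction(self) -> float:
        truth = self.population.pedigree.table.set_index("id")
        a = self.assignment.assigned()
        if a.empty:
            return 0.0
        ok = sum((truth.loc[r.offspring_id, "sire"] == r.sire_id)
                 and (truth.loc[r.offspring_id, "dam"] == r.dam_id)
                 for r in a.itertuples())
        return ok / len(a)


def replicate_study(seed: int, cfg: SimConfig | None = None,
                    n_repeats: int = 10, thresholds=(0.45,),
                    cohort_size: int = 1214, components: str = "full",
                    spec: ModelSpec | None = None) -> StudyReplicate:
    """Run the full simulated study once.

    ``components="full"`` estimates variance components once per scenario
    relationship matrix on the whole cohort (components and the accuracy
    denominator h shared across folds); ``"per-fold"`` re-estimates them on
    every training fold.
    """
    s_sim, s_sub, s_folds = _spawn_seeds(seed, 3)
    if cfg is None:
        cfg = SimConfig(seed=s_sim)
    pop = simulate_population(cfg)
    spec = spec or ModelSpec()

    geno_qc, report = filter_genotypes(pop.genotypes_observed, pop.parent_ids)
    parent_set = set(pop.parent_ids)
    offspring = [s for s in geno_qc.samples if s not in parent_set]
    sires = [p for p in pop.parent_ids if p.startswith("S")]
    dams = [p for p in pop.parent_ids if p.startswith("D")]
    assignment = assign_parents(
        geno_qc.subset_samples(offspring), geno_qc.subset_samples(sires),
        geno_qc.subset_samples(dams), tolerance=0.04,
    )

    assigned_ids = assignment.assigned()["offspring_id"].to_numpy()
    rng = np.random.default_rng(s_sub)
    cohort = list(rng.permutation(assigned_ids)[:cohort_size])
    phenos = pop.phenotypes.set_index("id", drop=False).loc[cohort].reset_index(drop=True)

    ped = assignment.to_pedigree()
    keep = set(cohort) | set(ped.founders())
    ped = Pedigree(ped.table[ped.table["id"].isin(keep)].reset_index(drop=True))

    geno_cohort = geno_qc.subset_samples(cohort)
    scheme = make_folds(cohort, n_folds=5, n_repeats=n_repeats, seed=s_folds)
    results = density_scenarios(
        phenos, geno_cohort, scheme, thresholds=thresholds, pedigree=ped,
        spec=spec, components=components,
    )
    return StudyReplicate(
        population=pop, qc_report=report, assignment=assignment, pedigree=ped,
        cohort_ids=cohort, phenotypes=phenos, genotypes=geno_cohort,
        scheme=scheme, cv_results=results,
    )


def summarize_replicates(replicates: list[StudyReplicate]) -> dict[str, dict]:
    """Average scenario accuracies and biases over replicate simulations."""
    out: dict[str, dict] = {}
    keys = replicates[0].cv_results.keys()
    for k in keys:
        accs = [r.cv_results[k].mean_accuracy for r in replicates if k in r.cv_results]
        biases = [r.cv_results[k].mean_bias for r in replicates if k in r.cv_results]
        out[k] = {
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "mean_bias": float(np.mean(biases)),
            "n_replicates": len(accs),
        }
    return out
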