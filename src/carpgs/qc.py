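"""SNP- and sample-level quality control and MAF-threshold marker panels.

Filters mirror a standard RAD-seq genotyping pipeline for a family-based
mapping population: samples with excessive missingness are dropped first,
then loci by minor allele frequency, locus missingness, and departure from
Hardy-Weinberg proportions among the parental samples (parents are the only
group expected to be in HWE — offspring of a factorial cross are not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor allele frequency min(p, 1-p).

    p is the counted-allele frequency among non-missing genotypes.  Loci
    with no genotyped individual get NaN.
    """
    if g.n_loci == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    d = g.dosage_float()
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))
    return np.minimum(p, 1.0 - p)


def locus_missingness(g: GenotypeMatrix) -> np.ndarray:
    return g.missing_mask().mean(axis=0)


def sample_missingness(g: GenotypeMatrix) -> np.ndarray:
    return g.missing_mask().mean(axis=1)


def hwe_test(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus 1-df chi-square goodness-of-fit p-value for HW proportions.

    Expected genotype counts use the observed allele frequency; monomorphic
    loci return p = 1 and loci with fewer than two genotyped individuals
    return NaN.
    """
    d = g.dosages
    n0 = (d == 0).sum(axis=0).astype(float)
    n1 = (d == 1).sum(axis=0).astype(float)
    n2 = (d == 2).sum(axis=0).astype(float)
    return hwe_pvalues_from_counts(n0, n1, n2)


def hwe_pvalues_from_counts(n0, n1, n2) -> np.ndarray:
    """Chi-square HWE p-values from (hom-ref, het, hom-alt) count arrays."""
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    n2 = np.atleast_1d(np.asarray(n2, dtype=float))
    n = n0 + n1 + n2
    p = np.full(n.shape, np.nan)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (2 * n2 + n1) / (2 * n)  # counted-allele frequency
        e0, e1, e2 = n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q ** 2
        chi2 = np.zeros(n.shape)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 = chi2 + term
    mono = ok & ((q == 0) | (q == 1))
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    p[mono] = 1.0
    return p


def hwe_test_parents(g: GenotypeMatrix, parent_ids) -> np.ndarray:
    """HWE test restricted to the parental samples."""
    return hwe_test(g.subset_samples(parent_ids))


@dataclass
class QCReport:
    """Per-locus and per-sample QC metrics plus surviving counts per step."""

    locus_table: pd.DataFrame
    sample_table: pd.DataFrame
    steps: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_samples_in": int(len(self.sample_table)),
            "n_samples_kept": int(self.sample_table["keep"].sum()),
            "n_loci_in": int(len(self.locus_table)),
            "n_loci_kept": int(self.locus_table["keep"].sum()),
            "steps": self.steps.to_dict(orient="records"),
        }


def filter_genotypes(g: GenotypeMatrix, parent_ids, maf_min: float = 0.01,
                     locus_miss_max: float = 0.25, hwe_p_min: float = 1e-06,
                     sample_miss_max: float = 0.25
                     ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full QC cascade and report what each step removed.

    Order: samples by missingness first, then loci by MAF, locus
    missingness, and parental HWE.  All locus statistics are computed on the
    sample-filtered matrix; MAF uses every retained animal.
    """
    for name, v in (("maf_min", maf_min), ("locus_miss_max", locus_miss_max),
                    ("hwe_p_min", hwe_p_min), ("sample_miss_max", sample_miss_max)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    parent_ids = [str(p) for p in parent_ids]
    missing_ids = set(parent_ids) - set(map(str, g.samples))
    if missing_ids:
        raise ValueError(f"parent ids absent from genotype matrix: {sorted(missing_ids)[:5]}")

    smiss = sample_missingness(g)
    keep_sample = smiss <= sample_miss_max
    sample_table = pd.DataFrame({"id": g.samples, "missing_frac": smiss, "keep": keep_sample})
    g1 = GenotypeMatrix(g.dosages[keep_sample], g.samples[keep_sample], g.markers)

    kept_parents = [p for p in parent_ids if p in set(map(str, g1.samples))]
    maf = compute_maf(g1)
    lmiss = locus_missingness(g1)
    hwe_p = hwe_test_parents(g1, kept_parents) if kept_parents else np.full(g1.n_loci, np.nan)

    fail_maf = ~(maf >= maf_min)  # NaN MAF (all-missing locus) also fails
    fail_miss = lmiss > locus_miss_max
    fail_hwe = np.where(np.isnan(hwe_p), False, hwe_p < hwe_p_min)

    reasons = np.array(["" for _ in range(g1.n_loci)], dtype=object)
    keep = np.ones(g1.n_loci, dtype=bool)
    steps = [("samples", int(g.n_samples), int(g1.n_samples))]
    for name, fail in (("maf", fail_maf), ("missingness", fail_miss), ("hwe_parents", fail_hwe)):
        newly = keep & fail
        reasons[newly] = np.where(reasons[newly] == "", name, reasons[newly])
        before = int(keep.sum())
        keep &= ~fail
        steps.append((name, before, int(keep.sum())))

    locus_table = g1.markers.copy()
    locus_table["maf"] = maf
    locus_table["missing_frac"] = lmiss
    locus_table["hwe_p_parents"] = hwe_p
    locus_table["keep"] = keep
    locus_table["fail_reason"] = reasons

    report = QCReport(
        locus_table=locus_table,
        sample_table=sample_table,
        steps=pd.DataFrame(steps, columns=["step", "n_before", "n_after"]),
    )
    return g1.subset_loci(keep), report


def maf_threshold_subsets(g: GenotypeMatrix, thresholds) -> dict[float, GenotypeMatrix]:
    """Marker panels of loci with MAF strictly above each threshold.

    Higher-threshold panels are nested inside lower ones by construction.
    """
    thresholds = list(thresholds)
    for t in thresholds:
        if not 0 <= t < 0.5:
            raise ValueError("MAF thresholds must lie in [0, 0.5)")
    maf = compute_maf(g)
    return {t: g.subset_loci(maf > t) for t in thresholds}
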