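"""BLUP breeding values and repeated cross-validated prediction accuracy.

Breeding values solve Henderson's mixed-model equations for the animal
model; validation animals, whose phenotypes are masked, receive (G)EBVs
through their relationship ties to the training set.  Accuracy is
approximated as cor(EBV, y) / h over validation animals (h the square root
of heritability) and dispersion bias as the ordinary-least-squares slope of
phenotype on EBV, the standard benchmarking pair in breeding-program
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .qc import maf_threshold_subsets
from .relmat import RelationshipMatrix, condition_matrix, pedigree_numerator_matrix, vanraden_grm
from .varcomp import ModelSpec, VarianceEstimates, fixed_design, reml_fit


@dataclass
class CVScheme:
    """Fold memberships for n_folds x n_repeats cross-validation.

    ``memberships`` holds one integer array per repeat: entry i is the
    validation-fold index of individual i, or -1 for remainder individuals
    that stay in the training side of every fold (this reproduces the
    972/242 convention of a 1,214-animal fivefold split).
    """

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    ids: np.ndarray | None = None
    memberships: list[np.ndarray] = field(default_factory=list)


def make_folds(ids, scheme: CVScheme | None = None, n_folds: int = 5,
               n_repeats: int = 10, seed: int = 0) -> CVScheme:
    """Randomly permute ids, then cut contiguous validation blocks.

    Each of the ``n_folds`` validation folds has exactly floor(n / n_folds)
    individuals; the n mod n_folds remainder individuals are appended to the
    training side of every fold.  Memberships are reproducible from seed.
    """
    if scheme is None:
        scheme = CVScheme(n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    ids = np.asarray(ids, dtype=object)
    n = ids.size
    if n < scheme.n_folds:
        raise ValueError("fewer individuals than folds")
    fold_size = n // scheme.n_folds
    rng = np.random.default_rng(scheme.seed)
    memberships = []
    for _ in range(scheme.n_repeats):
        perm = rng.permutation(n)
        m = np.full(n, -1, dtype=int)
        for k in range(scheme.n_folds):
            m[perm[k * fold_size:(k + 1) * fold_size]] = k
        memberships.append(m)
    return replace(scheme, ids=ids, memberships=memberships)


def solve_mme(phenotypes_train: pd.DataFrame, spec: ModelSpec,
              relmat: RelationshipMatrix, components: VarianceEstimates,
              k_inv: np.ndarray | None = None) -> pd.Series:
    """Solve Henderson's mixed-model equations; EBVs for every individual.

    ``phenotypes_train`` carries the records used for fitting (columns
    ``id``, trait, fixed factor); every individual in ``relmat`` gets an
    EBV, phenotyped or not.  ``k_inv`` may supply a precomputed inverse of
    the relationship matrix (it does not depend on the training split).
    """
    trait = spec.traits[0]
    ph = phenotypes_train.dropna(subset=[trait]).reset_index(drop=True)
    if ph["id"].duplicated().any():
        raise ValueError("repeated records per individual are not supported")
    lam = components.lambda_ratio
    n_all = relmat.n
    train_idx = relmat.index_of(ph["id"])  # raises if a training id is absent
    y = ph[trait].to_numpy(dtype=float)
    x = fixed_design(ph, spec.fixed)
    p = x.shape[1]

    if k_inv is None:
        k_inv = np.linalg.inv(relmat.values)
    c = np.zeros((p + n_all, p + n_all))
    c[:p, :p] = x.T @ x
    zx = np.zeros((n_all, p))
    zx[train_idx] = x
    c[:p, p:] = zx.T
    c[p:, :p] = zx
    c[p:, p:] = lam * k_inv
    c[p + train_idx, p + train_idx] += 1.0
    rhs = np.zeros(p + n_all)
    rhs[:p] = x.T @ y
    rhs[p + train_idx] = y
    sol = linalg.solve(c, rhs, assume_a="sym")
    return pd.Series(sol[p:], index=relmat.ids, name="ebv")


def accuracy_and_bias(ebv: np.ndarray, y: np.ndarray, h: float) -> tuple[float, float]:
    """Validation-set accuracy cor(EBV, y)/h and bias slope of y on EBV."""
    ebv = np.asarray(ebv, dtype=float)
    y = np.asarray(y, dtype=float)
    if ebv.size < 3 or np.std(ebv) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    acc = float(np.corrcoef(ebv, y)[0, 1]) / h
    bias = float(np.cov(ebv, y, ddof=1)[0, 1] / np.var(ebv, ddof=1))
    return acc, bias


@dataclass
class CVResult:
    """Per-fold accuracies/biases plus scenario-level summaries."""

    folds: pd.DataFrame  # repeat, fold, n_train, n_val, accuracy, bias
    method: str
    scenario: str
    n_markers: int | None = None
    h2_source: str = "per-fold"

    @property
    def mean_accuracy(self) -> float:
        return float(self.repeat_means()["accuracy"].mean())

    @property
    def se_accuracy(self) -> float:
        """SD of the repeat means (the repeat-to-repeat precision)."""
        return float(self.repeat_means()["accuracy"].std(ddof=1))

    @property
    def mean_bias(self) -> float:
        return float(self.repeat_means()["bias"].mean())

    def repeat_means(self) -> pd.DataFrame:
        return self.folds.groupby("repeat")[["accuracy", "bias"]].mean()

    def summary(self) -> dict:
        return {
            "method": self.method,
            "scenario": self.scenario,
            "n_markers": self.n_markers,
            "mean_accuracy": self.mean_accuracy,
            "se_accuracy": self.se_accuracy,
            "mean_bias": self.mean_bias,
            "h2_source": self.h2_source,
        }


def cross_validate(phenotypes: pd.DataFrame, relmat: RelationshipMatrix,
                   scheme: CVScheme, spec: ModelSpec | None = None,
                   components: VarianceEstimates | str = "per-fold",
                   method: str = "GBLUP", scenario: str = "FD",
                   n_markers: int | None = None,
                   h_value: float | None = None) -> CVResult:
    """Repeated k-fold cross-validation of (G/P)BLUP prediction.

    ``components`` is either "per-fold" (REML re-estimated on each training
    set; its h used for that fold's accuracy), "full" (one REML fit on all
    phenotyped animals, shared), or a ready ``VarianceEstimates``.
    ``h_value`` optionally fixes the accuracy denominator h (so that
    scenarios compared side by side all divide by the same heritability,
    as when one study-wide h2 estimate is used); the components still set
    the mixed-model shrinkage.  Fold memberships come from ``scheme`` and
    can be shared across scenarios for paired comparisons.
    """
    spec = spec or ModelSpec()
    trait = spec.traits[0]
    ph = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    if scheme.ids is None or not scheme.memberships:
        raise ValueError("scheme has no fold memberships; call make_folds first")
    if not set(scheme.ids).issubset(set(ph["id"])):
        raise ValueError("scheme ids must all be phenotyped")
    ph = ph.set_index("id", drop=False).loc[scheme.ids].reset_index(drop=True)

    h2_source = components if isinstance(components, str) else "fixed"
    fixed_comp: VarianceEstimates | None = None
    if isinstance(components, VarianceEstimates):
        fixed_comp = components
    elif components == "full":
        fixed_comp = reml_fit(ph, spec, relmat)
    elif components != "per-fold":
        raise ValueError("components must be 'per-fold', 'full' or a VarianceEstimates")

    k_inv = np.linalg.inv(relmat.values)
    rows = []
    for rep, member in enumerate(scheme.memberships, start=1):
        for fold in range(scheme.n_folds):
            val_mask = member == fold
            train = ph.loc[~val_mask]
            comp = fixed_comp if fixed_comp is not None else reml_fit(train, spec, relmat)
            h = h_value if h_value is not None else float(np.sqrt(comp.h2[0]))
            ebv = solve_mme(train, spec, relmat, comp, k_inv=k_inv)
            val = ph.loc[val_mask]
            acc, bias = accuracy_and_bias(
                ebv.loc[val["id"]].to_numpy(), val[trait].to_numpy(), h
            )
            if np.isnan(acc):
                warnings.warn(f"repeat {rep} fold {fold}: degenerate EBV/phenotype variance")
            rows.append((rep, fold + 1, len(train), len(val), acc, bias))
    folds = pd.DataFrame(rows, columns=["repeat", "fold", "n_train", "n_val", "accuracy", "bias"])
    return CVResult(folds, method=method, scenario=scenario, n_markers=n_markers,
                    h2_source=h2_source)


def density_scenarios(phenotypes: pd.DataFrame, g: GenotypeMatrix,
                      scheme: CVScheme, thresholds=(0.1, 0.2, 0.3, 0.4, 0.45),
                      pedigree: Pedigree | None = None,
                      spec: ModelSpec | None = None,
                      components: str = "per-fold", blend_alpha: float = 0.01,
                      shared_h: bool = True) -> dict[str, CVResult]:
    """GBLUP across MAF-threshold marker panels, plus a PBLUP baseline.

    All scenarios share the fold memberships in ``scheme`` (paired
    comparison).  With ``shared_h`` (default) one study-wide heritability
    supplies the accuracy denominator for every scenario -- the
    pedigree-based REML estimate when a pedigree is available (the
    classical anchor for the trait heritability), otherwise the
    full-density genomic estimate -- so scenario accuracies differ only
    through cor(EBV, y).  Otherwise each scenario divides by its own
    estimate.  Panels that end up empty are skipped with a warning.
    Keys: "FD", "MAF>t" per threshold, and "PBLUP" when a pedigree is
    given.
    """
    spec = spec or ModelSpec()
    results: dict[str, CVResult] = {}
    panels: dict[str, GenotypeMatrix] = {"FD": g}
    for t, sub in maf_threshold_subsets(g, thresholds).items():
        panels[f"MAF>{t:g}"] = sub

    trait = spec.traits[0]
    ph = phenotypes.dropna(subset=[trait]).set_index("id", drop=False)
    ph = ph.loc[scheme.ids].reset_index(drop=True)
    a = pedigree_numerator_matrix(pedigree) if pedigree is not None else None
    h_value = None
    if shared_h:
        if a is not None:
            h_value = float(np.sqrt(reml_fit(ph, spec, a).h2[0]))
        else:
            grm_fd = condition_matrix(vanraden_grm(g.subset_samples(scheme.ids)), blend_alpha)
            h_value = float(np.sqrt(reml_fit(ph, spec, grm_fd).h2[0]))

    for name, panel in panels.items():
        if panel.n_loci == 0:
            warnings.warn(f"scenario {name}: empty marker panel, skipped")
            continue
        grm = condition_matrix(vanraden_grm(panel.subset_samples(scheme.ids)), blend_alpha)
        results[name] = cross_validate(
            phenotypes, grm, scheme, spec, components=components,
            method="GBLUP", scenario=name, n_markers=panel.n_loci,
            h_value=h_value,
        )
    if a is not None:
        results["PBLUP"] = cross_validate(
            phenotypes, a, scheme, spec, components=components,
            method="PBLUP", scenario="PBLUP", n_markers=None,
            h_value=h_value,
        )
    return results


def scenario_table(results: dict[str, CVResult]) -> pd.DataFrame:
    """Repeats x scenarios table with "accuracy (bias)" cells plus a mean row."""
    cols = {}
    for name, res in results.items():
        rm = res.repeat_means()
        cells = [f"{a:.2f} ({b:.2f})" for a, b in zip(rm["accuracy"], rm["bias"])]
        cells.append(f"{res.mean_accuracy:.2f} ({res.mean_bias:.2f})")
        cols[name] = cells
    index = [str(i + 1) for i in range(len(next(iter(results.values())).repeat_means()))] + ["Mean"]
    return pd.DataFrame(cols, index=pd.Index(index, name="repeat"))
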