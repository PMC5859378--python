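"""BLUP solving, fold construction, and cross-validated accuracy/bias."""

import numpy as np
import pandas as pd
import pytest

from carpgs.pedigree import Pedigree
from carpgs.predict import (
    CVScheme,
    accuracy_and_bias,
    cross_validate,
    density_scenarios,
    make_folds,
    solve_mme,
)
from carpgs.relmat import (
    RelationshipMatrix,
    condition_matrix,
    pedigree_numerator_matrix,
    vanraden_grm,
)
from carpgs.varcomp import ModelSpec, VarianceEstimates


def _components(sg2, se2):
    return VarianceEstimates(
        traits=("y",), sigma_g2=np.array([[sg2]]), sigma_e2=np.array([[se2]]),
        h2=np.array([sg2 / (sg2 + se2)]), se_h2=np.array([np.nan]),
        rg=None, se_rg=None, loglik=0.0, iterations=0, converged=True,
    )


class TestMakeFolds:
    def test_study_convention_242(self):
        ids = [f"i{k}" for k in range(1214)]
        scheme = make_folds(ids, n_folds=5, n_repeats=10, seed=3)
        for m in scheme.memberships:
            sizes = [int((m == k).sum()) for k in range(5)]
            assert sizes == [242] * 5
            assert int((m == -1).sum()) == 1214 - 5 * 242  # remainder stays in training

    def test_small_n(self):
        scheme = make_folds([f"i{k}" for k in range(10)], n_folds=5, n_repeats=2, seed=0)
        for m in scheme.memberships:
            assert sorted(np.bincount(m[m >= 0]).tolist()) == [2] * 5

    def test_deterministic_and_exhaustive(self):
        ids = [f"i{k}" for k in range(53)]
        a = make_folds(ids, n_folds=5, n_repeats=3, seed=11)
        b = make_folds(ids, n_folds=5, n_repeats=3, seed=11)
        for ma, mb in zip(a.memberships, b.memberships):
            assert np.array_equal(ma, mb)
            covered = set(np.flatnonzero(ma >= 0)) | set(np.flatnonzero(ma == -1))
            assert covered == set(range(53))

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], n_folds=5)


class TestSolveMME:
    def test_single_record_regression_to_mean(self):
        """One animal, no fixed effects: EBV = h2 * y in the single-record
        closed form sigma_g2/(sigma_g2+sigma_e2) * deviation."""
        relmat = RelationshipMatrix(np.array([[1.0]]), np.array(["a"], dtype=object),
                                    "pedigree_A")
        ph = pd.DataFrame({"id": ["a"], "y": [3.0]})
        comp = _components(sg2=1.0, se2=2.0)  # h2 = 1/3
        spec = ModelSpec(traits=("y",), fixed="none")
        ebv = solve_mme(ph, spec, relmat, comp)
        assert ebv["a"] == pytest.approx(3.0 / 3.0)

    def test_three_individual_toy_matches_direct_solve(self):
        """Parent with a record, two offspring without; lambda = 2."""
        ped = Pedigree(pd.DataFrame(
            [("p", "0", "0"), ("m", "0", "0"), ("c1", "p", "m"), ("c2", "p", "m")],
            columns=["id", "sire", "dam"]))
        a = pedigree_numerator_matrix(ped)
        ph = pd.DataFrame({"id": ["p"], "y": [10.0]})
        comp = _components(sg2=1.0, se2=2.0)
        spec = ModelSpec(traits=("y",), fixed="none")
        ebv = solve_mme(ph, spec, a, comp)

        # independent oracle: assemble and invert the MME directly
        a_inv = np.linalg.inv(a.values)
        z = np.zeros((1, 4))
        z[0, a.index_of(["p"])[0]] = 1.0
        lhs = z.T @ z + 2.0 * a_inv
        rhs = z.T @ np.array([10.0])
        u = np.linalg.solve(lhs, rhs)
        assert np.allclose(ebv.to_numpy(), u)
        # offspring get half the parent EBV through the relationship
        assert ebv["c1"] == pytest.approx(ebv["c2"])

    def test_validation_animals_predicted_through_ties(self, le_pop):
        ph = le_pop.phenotypes.rename(columns={"length_mm": "y"})
        a = pedigree_numerator_matrix(le_pop.pedigree)
        train = ph.iloc[:200]
        comp = _components(sg2=0.33 * 7.1 ** 2, se2=0.67 * 7.1 ** 2)
        ebv = solve_mme(train, ModelSpec(traits=("y",)), a, comp)
        assert len(ebv) == a.n
        masked = ph.iloc[200:]
        tbv = le_pop.true_breeding_values.set_index("id")
        r = np.corrcoef(ebv.loc[masked["id"]], tbv.loc[masked["id"], "length_mm"])[0, 1]
        assert r > 0.3

    def test_unknown_training_id_rejected(self):
        relmat = RelationshipMatrix(np.eye(2), np.array(["a", "b"], dtype=object),
                                    "pedigree_A")
        ph = pd.DataFrame({"id": ["zz"], "y": [1.0]})
        with pytest.raises(KeyError):
            solve_mme(ph, ModelSpec(traits=("y",), fixed="none"), relmat,
                      _components(1.0, 1.0))


class TestAccuracyBias:
    def test_true_breeding_values_give_accuracy_one(self):
        """cor(u, y) = h when y = u + e, so cor/h hits 1 for a perfect EBV.
        Block effects are switched off so no extra variance enters y."""
        from carpgs.simdata import SimConfig, simulate_population

        cfg = SimConfig(n_blocks=2, n_offspring=400, n_qtl=150,
                        block_effect_sd_frac=0.0, seed=19)
        pop = simulate_population(cfg, n_markers=300)
        tbv = pop.true_breeding_values.set_index("id")
        ph = pop.phenotypes
        u = tbv.loc[ph["id"], "length_mm"].to_numpy()
        acc, _ = accuracy_and_bias(u, ph["length_mm"].to_numpy(),
                                   np.sqrt(cfg.h2_length))
        assert acc == pytest.approx(1.0, abs=0.1)

    def test_permuted_predictor_is_null(self, small_pop):
        rng = np.random.default_rng(5)
        tbv = small_pop.true_breeding_values.set_index("id")
        ph = small_pop.phenotypes
        u = rng.permutation(tbv.loc[ph["id"], "length_mm"].to_numpy())
        acc, bias = accuracy_and_bias(u, ph["length_mm"].to_numpy(),
                                      np.sqrt(small_pop.config.h2_length))
        assert abs(acc) < 0.15 and abs(bias) < 0.3

    def test_translation_and_scaling_behavior(self):
        rng = np.random.default_rng(9)
        ebv = rng.normal(size=300)
        y = ebv + rng.normal(size=300)
        acc, bias = accuracy_and_bias(ebv, y, h=0.5)
        acc2, bias2 = accuracy_and_bias(ebv, y + 50.0, h=0.5)
        assert (acc2, bias2) == (pytest.approx(acc), pytest.approx(bias))
        acc3, bias3 = accuracy_and_bias(3.0 * ebv, y, h=0.5)
        assert acc3 == pytest.approx(acc)
        assert bias3 == pytest.approx(bias / 3.0)

    def test_degenerate_inputs_are_nan(self):
        acc, bias = accuracy_and_bias(np.ones(10), np.arange(10.0), h=0.5)
        assert np.isnan(acc) and np.isnan(bias)


@pytest.fixture(scope="module")
def cv_setup(small_pop):
    ids = list(small_pop.offspring_ids)
    ph = small_pop.phenotypes
    g = small_pop.genotypes_clean.subset_samples(ids)
    grm = condition_matrix(vanraden_grm(g))
    scheme = make_folds(ids, n_folds=5, n_repeats=3, seed=17)
    return ids, ph, g, grm, scheme


class TestCrossValidate:
    def test_no_masking_beats_masked_folds(self, cv_setup):
        ids, ph, g, grm, scheme = cv_setup
        comp = _components(0.33 * 7.1 ** 2, 0.67 * 7.1 ** 2)
        spec = ModelSpec()
        masked = cross_validate(ph, grm, scheme, spec, components=comp)
        ebv_full = solve_mme(ph.set_index("id", drop=False).loc[ids].reset_index(drop=True),
                             spec, grm, comp)
        y = ph.set_index("id").loc[ids, "length_mm"].to_numpy()
        acc_full, _ = accuracy_and_bias(ebv_full.loc[ids].to_numpy(), y,
                                        np.sqrt(comp.h2[0]))
        assert acc_full > masked.mean_accuracy

    def test_result_reproducible_from_seed(self, cv_setup):
        ids, ph, g, grm, scheme = cv_setup
        comp = _components(0.33 * 7.1 ** 2, 0.67 * 7.1 ** 2)
        r1 = cross_validate(ph, grm, scheme, components=comp)
        r2 = cross_validate(ph, grm, scheme, components=comp)
        assert r1.folds["accuracy"].equals(r2.folds["accuracy"])

    def test_repeat_summary_shapes(self, cv_setup):
        ids, ph, g, grm, scheme = cv_setup
        r = cross_validate(ph, grm, scheme,
                           components=_components(16.0, 32.0))
        assert len(r.folds) == scheme.n_folds * scheme.n_repeats
        assert len(r.repeat_means()) == scheme.n_repeats
        assert r.se_accuracy >= 0


class TestDensityScenarios:
    def test_scenarios_share_folds_and_report_panels(self, small_pop, cv_setup):
        ids, ph, g, grm, scheme = cv_setup
        results = density_scenarios(ph, g, scheme, thresholds=[0.3, 0.45],
                                    pedigree=small_pop.pedigree, components="full")
        assert set(results) == {"FD", "MAF>0.3", "MAF>0.45", "PBLUP"}
        assert results["MAF>0.45"].n_markers <= results["MAF>0.3"].n_markers
        assert results["FD"].n_markers == g.n_loci
        # paired: identical fold layout in every scenario
        for r in results.values():
            assert r.folds[["repeat", "fold", "n_val"]].equals(
                results["FD"].folds[["repeat", "fold", "n_val"]])

    def test_empty_threshold_list(self, small_pop, cv_setup):
        ids, ph, g, grm, scheme = cv_setup
        results = density_scenarios(ph, g, scheme, thresholds=[],
                                    pedigree=small_pop.pedigree, components="full")
        assert set(results) == {"FD", "PBLUP"}

    def test_gblup_shrinkage_beats_raw_phenotype(self, cv_setup, small_pop):
        """All-records GBLUP EBVs track true breeding values better than the
        raw phenotype does (pooling of relatives' information)."""
        ids, ph, g, grm, scheme = cv_setup
        comp = _components(0.33 * 7.1 ** 2, 0.67 * 7.1 ** 2)
        spec = ModelSpec()
        phx = ph.set_index("id", drop=False).loc[ids].reset_index(drop=True)
        ebv = solve_mme(phx, spec, grm, comp)
        tbv = small_pop.true_breeding_values.set_index("id")["length_mm"]
        u = tbv.loc[ids].to_numpy()
        assert (np.corrcoef(ebv.loc[ids], u)[0, 1]
                > np.corrcoef(phx["length_mm"], u)[0, 1] + 0.05)
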