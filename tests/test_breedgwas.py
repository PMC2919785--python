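import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breedmap.breedgwas import (
    BreedPhenotypes,
    KinshipMatrix,
    breed_average_kinship,
    breed_averages,
    breed_frequencies,
    ibs_kinship,
    lmm_assoc,
    naive_assoc,
    weighted_bootstrap_assoc,
)
from breedmap.io_formats import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable

from oracles import reml_loglik_direct


def pheno_table(rows):
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["individual_id", "breed", "trait", "value", "age_years"])
    )


class TestBreedAverages:
    def test_transform_then_average(self):
        t = pheno_table(
            [("d1", "A", "w", 10.0, 3.0), ("d2", "A", "w", 20.0, 4.0)]
        )
        out = breed_averages(t, "w", transform="log")
        assert out.values["A"] == pytest.approx((np.log(10) + np.log(20)) / 2)

    def test_single_dog_breed_dropped(self):
        t = pheno_table(
            [("d1", "A", "w", 10.0, 3.0), ("d2", "A", "w", 20.0, 4.0),
             ("d3", "B", "w", 5.0, 3.0)]
        )
        out = breed_averages(t, "w")
        assert "B" not in out.values.index

    def test_young_dog_excluded(self):
        t = pheno_table(
            [("d1", "A", "w", 10.0, 0.5), ("d2", "A", "w", 20.0, 3.0),
             ("d3", "A", "w", 30.0, 2.0)]
        )
        out = breed_averages(t, "w")
        assert out.values["A"] == pytest.approx(25.0)
        assert out.n_measured["A"] == 2

    def test_unknown_age_kept(self):
        t = pheno_table(
            [("d1", "A", "w", 10.0, np.nan), ("d2", "A", "w", 20.0, 3.0)]
        )
        out = breed_averages(t, "w")
        assert out.values["A"] == pytest.approx(15.0)

    def test_no_breed_passes_raises(self):
        t = pheno_table([("d1", "A", "w", 10.0, 3.0)])
        with pytest.raises(ValueError, match="no breed"):
            breed_averages(t, "w")


class TestIbsKinship:
    def build(self, rows, breeds=None):
        rows = np.asarray(rows, dtype=np.int8)
        n, m = rows.shape
        mm = MarkerMap(
            marker_id=[f"m{j}" for j in range(m)],
            chromosome=["chr1"] * m,
            position_bp=[(j + 1) * 1000 for j in range(m)],
        )
        return GenotypeMatrix(
            genotypes=rows,
            individual_ids=[f"d{i}" for i in range(n)],
            breed_labels=breeds if breeds is not None else ["B"] * n,
            map=mm,
        )

    def test_identical_vectors_ibs_one(self):
        g = self.build([[0, 1, 2], [0, 1, 2]])
        K = ibs_kinship(g)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_ibs_zero(self):
        g = self.build([[0, 0, 0], [2, 2, 2]])
        assert ibs_kinship(g).values[0, 1] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        g = self.build([[0, 1, 2], [2, 1, 0]])
        # per-marker shares: 0, 1, 0 of 2 alleles -> mean 1/3
        assert ibs_kinship(g).values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_missing_markers_complete_case(self):
        g = self.build([[0, 1, MISSING], [0, 1, 2]])
        assert ibs_kinship(g).values[0, 1] == pytest.approx(1.0)

    def test_no_shared_markers_raises(self):
        g = self.build([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="share no genotyped marker"):
            ibs_kinship(g)

    def test_breed_average_excludes_self_pairs(self):
        g = self.build(
            [[0, 0, 0], [2, 2, 2], [0, 0, 0], [0, 0, 0]],
            breeds=["A", "A", "B", "B"],
        )
        K = ibs_kinship(g)
        Kb = breed_average_kinship(K, g.breed_labels)
        # breed A: single cross pair d1-d2 with IBS 0 (diagonal, self excluded)
        assert Kb.values[0, 0] == pytest.approx(0.0)
        assert Kb.values[1, 1] == pytest.approx(1.0)
        # cross-breed: mean of 4 pairs: d1-d3 (1), d1-d4 (1), d2-d3 (0), d2-d4 (0)
        assert Kb.values[0, 1] == pytest.approx(0.5)


class TestLmmAssoc:
    def random_inputs(self, seed, nb=20, M=30):
        rng = np.random.default_rng(seed)
        F = pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(nb, M)),
            index=[f"b{i}" for i in range(nb)],
            columns=[f"s{j}" for j in range(M)],
        )
        y = pd.Series(rng.normal(size=nb), index=F.index)
        return F, y

    def test_identity_kinship_equals_ols(self):
        F, y = self.random_inputs(0)
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        lmm = lmm_assoc(F, y, K)
        ols = naive_assoc(F, y)
        np.testing.assert_allclose(
            lmm.table["p_value"].to_numpy(), ols.table["p_value"].to_numpy(), atol=1e-8
        )

    def test_constant_phenotype_p_one(self):
        F, y = self.random_inputs(1)
        y[:] = 3.0
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        lmm = lmm_assoc(F, y, K)
        assert (lmm.table["p_value"] == 1.0).all()

    def test_monomorphic_marker_skipped(self):
        F, y = self.random_inputs(2)
        F["s0"] = 0.4
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        lmm = lmm_assoc(F, y, K)
        assert "s0" in set(lmm.skipped["marker_id"])
        assert "s0" not in set(lmm.table["marker_id"])

    def test_reml_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            nb = 15
            A = rng.normal(size=(nb, nb))
            K = A @ A.T / nb + np.eye(nb)
            d = np.sqrt(np.diag(K))
            K = K / np.outer(d, d)
            F = pd.DataFrame(
                rng.uniform(0.1, 0.9, size=(nb, 1)),
                index=[f"b{i}" for i in range(nb)],
                columns=["s0"],
            )
            y = pd.Series(
                np.linalg.cholesky(K + 0.5 * np.eye(nb)) @ rng.normal(size=nb),
                index=F.index,
            )
            res = lmm_assoc(F, y, KinshipMatrix(F.index.to_numpy(dtype=object), K))
            delta_hat = res.table["delta"].iloc[0]
            X = np.column_stack([np.ones(nb), F["s0"].to_numpy()])
            grid = np.exp(np.linspace(-10, 10, 4001))
            lls = [reml_loglik_direct(dl, K, X, y.to_numpy()) for dl in grid]
            ll_hat = reml_loglik_direct(delta_hat, K, X, y.to_numpy())
            assert ll_hat >= max(lls) - 1e-4 * abs(max(lls)) - 1e-9

    def test_allele_relabeling_flips_beta_not_p(self):
        F, y = self.random_inputs(4)
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        r1 = lmm_assoc(F, y, K)
        r2 = lmm_assoc(1.0 - F, y, K)
        np.testing.assert_allclose(
            r1.table["p_value"].to_numpy(), r2.table["p_value"].to_numpy(), atol=1e-8
        )
        np.testing.assert_allclose(
            r1.table["beta"].to_numpy(), -r2.table["beta"].to_numpy(), atol=1e-8
        )

    def test_covariate_consumed(self):
        F, y = self.random_inputs(5)
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        cov = pd.DataFrame({"logbw": np.log(np.abs(y) + 1.0)})
        cov.index = y.index
        res = lmm_assoc(F, y, K, covariates=cov)
        assert res.covariates == ["logbw"]
        assert len(res.table) == len(F.columns)

    def test_too_few_breeds_raises(self):
        F, y = self.random_inputs(6, nb=5)
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        with pytest.raises(ValueError, match="breeds"):
            lmm_assoc(F, y, K)

    def test_bonferroni_threshold_recorded(self):
        F, y = self.random_inputs(7)
        K = KinshipMatrix(F.index.to_numpy(dtype=object), np.eye(len(y)))
        res = lmm_assoc(F, y, K)
        assert res.bonferroni_alpha == pytest.approx(0.05 / len(F.columns))


class TestNaiveAssoc:
    def test_exact_linear_phenotype(self):
        rng = np.random.default_rng(8)
        F = pd.DataFrame(
            rng.uniform(0.1, 0.9, size=(15, 3)),
            index=[f"b{i}" for i in range(15)],
            columns=["s0", "s1", "s2"],
        )
        y = pd.Series(2.0 + 3.0 * F["s0"], index=F.index)
        res = naive_assoc(F, y)
        assert res.table.set_index("marker_id").loc["s0", "p_value"] < 1e-20

    def test_zero_variance_marker_skipped(self):
        rng = np.random.default_rng(9)
        F = pd.DataFrame(
            np.column_stack([np.full(12, 0.5), rng.uniform(0.1, 0.9, 12)]),
            index=[f"b{i}" for i in range(12)],
            columns=["s0", "s1"],
        )
        y = pd.Series(rng.normal(size=12), index=F.index)
        res = naive_assoc(F, y)
        assert list(res.table["marker_id"]) == ["s1"]


class TestWeightedBootstrap:
    def setup_cohort(self, nb=10, dpb=8, M=30, seed=0):
        rng = np.random.default_rng(seed)
        breeds = np.repeat([f"b{i}" for i in range(nb)], dpb)
        F = pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(nb, M)),
            index=[f"b{i}" for i in range(nb)],
            columns=[f"s{j}" for j in range(M)],
        )
        n = nb * dpb
        K = KinshipMatrix(
            np.array([f"i{k}" for k in range(n)], dtype=object), np.full((n, n), 0.7)
        )
        return breeds, F, K, rng

    def test_perfect_separation_minimal_p(self):
        breeds, F, K, rng = self.setup_cohort()
        F["s0"] = [1.0] * 5 + [0.0] * 5
        y = np.repeat([1.0] * 5 + [0.0] * 5, 8)
        res = weighted_bootstrap_assoc(F, y, breeds, K, B=500, seed=1)
        p0 = res.table.set_index("marker_id").loc["s0", "p_value"]
        assert p0 == pytest.approx(1.0 / 501.0)

    def test_constant_phenotype_p_one(self):
        breeds, F, K, rng = self.setup_cohort()
        y = np.ones(80)
        res = weighted_bootstrap_assoc(F, y, breeds, K, B=200, seed=2)
        assert (res.table["p_value"] == 1.0).all()

    def test_small_B_rejected(self):
        breeds, F, K, rng = self.setup_cohort()
        y = rng.integers(0, 2, 80).astype(float)
        with pytest.raises(ValueError, match="at least 100"):
            weighted_bootstrap_assoc(F, y, breeds, K, B=50)

    def test_plain_count_formula_recovered(self):
        breeds, F, K, rng = self.setup_cohort()
        y = rng.integers(0, 2, 80).astype(float)
        r1 = weighted_bootstrap_assoc(F, y, breeds, K, B=200, seed=3)
        r2 = weighted_bootstrap_assoc(
            F, y, breeds, K, B=200, seed=3, plus_one_correction=False
        )
        p1 = r1.table["p_value"].to_numpy()
        p2 = r2.table["p_value"].to_numpy()
        np.testing.assert_allclose(p1, (p2 * 200 + 1) / 201, atol=1e-12)

    def test_statistic_invariant_to_allele_relabeling(self):
        breeds, F, K, rng = self.setup_cohort()
        y = rng.integers(0, 2, 80).astype(float)
        r1 = weighted_bootstrap_assoc(F, y, breeds, K, B=300, seed=4)
        r2 = weighted_bootstrap_assoc(1.0 - F, y, breeds, K, B=300, seed=4)
        np.testing.assert_allclose(
            r1.table["stat"].to_numpy(), r2.table["stat"].to_numpy(), atol=1e-12
        )


class TestBreedFrequencies:
    def test_matches_subset_frequency(self, small_cohort):
        cfg, truth, panel, genotypes = small_cohort
        F = breed_frequencies(genotypes)
        sub = genotypes.subset_individuals(
            np.flatnonzero(genotypes.breed_labels == "breed03")
        )
        np.testing.assert_allclose(
            F.loc["breed03"].to_numpy(), sub.allele_frequencies(), atol=1e-12
        )
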