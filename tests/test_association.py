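"""Genotype encoding, the covariate-adjusted OLS test, BH correction and
the full association scan."""

import numpy as np
import pandas as pd
import pytest

from varlinks import association as assoc
from varlinks.datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix


def make_covariates(n, rng):
    return CovariateTable(pd.DataFrame(
        {
            "age": rng.uniform(20, 80, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "pc1": rng.normal(0, 1, n),
            "pc2": rng.normal(0, 1, n),
            "pc3": rng.normal(0, 1, n),
        },
        index=[f"S{i}" for i in range(n)],
    ))


def normal_equations_oracle(y, X):
    """Closed-form OLS via normal equations with classic t-test on beta1."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se1 = np.sqrt(cov[1, 1])
    from scipy import stats
    t = beta[1] / se1
    p = 2 * stats.t.sf(abs(t), df)
    return beta[1], se1, p


class TestEncode:
    def test_dominant_encoding(self):
        design, classes = assoc.encode_genotype(np.array([0, 0, 1, 1, 2, 2.0]),
                                                "dominant")
        np.testing.assert_array_equal(design, [0, 0, 1, 1, 1, 1])
        assert classes == {0: 2, 1: 4}

    def test_recessive_encoding(self):
        design, classes = assoc.encode_genotype(np.array([0, 0, 1, 1, 2, 2.0]),
                                                "recessive")
        np.testing.assert_array_equal(design, [0, 0, 0, 0, 1, 1])
        assert classes == {0: 4, 1: 2}

    def test_additive_keeps_dosage_and_missing(self):
        codes = np.array([0, 1, 2, np.nan])
        design, classes = assoc.encode_genotype(codes, "additive")
        assert np.isnan(design[3])
        assert classes == {0: 1, 1: 1, 2: 1}

    def test_random_codes_match_brute_force(self, rng):
        codes = rng.choice([0.0, 1.0, 2.0, np.nan], size=200,
                           p=[0.4, 0.3, 0.2, 0.1])
        for model in assoc.MODELS:
            _, classes = assoc.encode_genotype(codes, model)
            if model == "additive":
                expected = {k: int(np.nansum(codes == k)) for k in (0, 1, 2)}
            elif model == "dominant":
                expected = {0: int(np.nansum(codes == 0)),
                            1: int(np.nansum(codes >= 1))}
            else:
                expected = {0: int(np.nansum(codes <= 1)),
                            1: int(np.nansum(codes == 2))}
            assert classes == expected


class TestSingleFit:
    def test_planted_effect_recovered(self, rng):
        n = 300
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
        y = 1.0 + 0.5 * codes + rng.normal(0, 0.1, n)
        cov = make_covariates(n, rng)
        res = assoc.test_association(y, codes, cov.design_columns(cov.sample_ids),
                                     assoc.AssociationModelSpec("additive"))
        assert 0.45 <= res.beta1 <= 0.55
        assert res.p < 1e-10
        assert res.direction == "increase"

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = 60
            codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.4, 0.4, 0.2])
            if min((codes == k).sum() for k in (0, 1, 2)) < 3:
                continue
            cov = make_covariates(n, rng)
            C = cov.design_columns(cov.sample_ids)
            y = rng.normal(0, 1, n) + 0.3 * codes
            res = assoc.test_association(y, codes, C)
            X = np.column_stack([np.ones(n), codes, C])
            b1, se1, p = normal_equations_oracle(y, X)
            assert res.beta1 == pytest.approx(b1, rel=1e-8)
            assert res.se == pytest.approx(se1, rel=1e-8)
            assert res.p == pytest.approx(p, rel=1e-8)

    def test_small_class_is_skipped(self, rng):
        codes = np.array([0.0] * 50 + [1.0] * 10 + [2.0] * 2)
        cov = make_covariates(len(codes), rng)
        y = rng.normal(0, 1, len(codes))
        res = assoc.test_association(y, codes, cov.design_columns(cov.sample_ids),
                                     assoc.AssociationModelSpec("additive"))
        assert res is None
        # dominant pools {1,2}: classes are 50 and 12, so it is eligible
        res2 = assoc.test_association(y, codes, cov.design_columns(cov.sample_ids),
                                      assoc.AssociationModelSpec("dominant"))
        assert res2 is not None

    def test_type_one_error_calibrated(self, rng):
        """Fraction of null fits with p < 0.05 stays in the binomial band."""
        n = 120
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
        cov = make_covariates(n, rng)
        C = cov.design_columns(cov.sample_ids)
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            res = assoc.test_association(y, codes, C)
            hits += res.p < 0.05
        assert abs(hits / reps - 0.05) <= 0.012

    def test_constant_covariate_dropped_with_warning(self, rng):
        n = 100
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.3, 0.4, 0.3])
        cov = make_covariates(n, rng)
        table = cov.table.copy()
        table["sex"] = 1.0  # single-sex cohort
        y = rng.normal(0, 1, n) + 0.2 * codes
        with pytest.warns(UserWarning, match="constant"):
            res = assoc.test_association(
                y, codes, CovariateTable(table).design_columns(list(table.index)))
        assert res is not None and np.isfinite(res.p)

    def test_orthogonal_covariates_reduce_to_simple_regression(self, rng):
        # with all covariates zero-variance-free but orthogonal to G and y
        n = 200
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
        C = np.zeros((n, 5))
        C[:, 0] = 50.0  # constant age: dropped
        C[:, 1] = np.tile([0, 1], n // 2)
        # make remaining columns exactly orthogonal to [1, G]
        for j in (1, 2, 3, 4):
            if j > 1:
                C[:, j] = rng.normal(0, 1, n)
            X0 = np.column_stack([np.ones(n), codes])
            C[:, j] -= X0 @ np.linalg.lstsq(X0, C[:, j], rcond=None)[0]
        y = 0.4 * codes + rng.normal(0, 1, n)
        with pytest.warns(UserWarning):
            res = assoc.test_association(y, codes, C)
        X_simple = np.column_stack([np.ones(n), codes])
        beta_simple = np.linalg.lstsq(X_simple, y, rcond=None)[0]
        assert res.beta1 == pytest.approx(beta_simple[1], rel=1e-8)


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        np.testing.assert_allclose(assoc.bh_adjust([0.5]), [0.5])

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=1000)
        got = assoc.bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(got, adj, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.bh_adjust([0.5, 1.5])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        adj = assoc.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def build_scan_fixture(rng, n=400, n_variants=6, n_genes=40, beta=1.0):
    codes = rng.choice([0.0, 1.0, 2.0], size=(n, n_variants), p=[0.25, 0.5, 0.25])
    genotypes = GenotypeMatrix([f"S{i}" for i in range(n)],
                               [f"v{j}" for j in range(n_variants)], codes)
    cov = make_covariates(n, rng)
    E = rng.normal(0, 0.5, size=(n, n_genes))
    E[:, 0] += beta * codes[:, 0]  # planted: v0 -> g0, additive
    expression = ExpressionMatrix([f"S{i}" for i in range(n)],
                                  [f"g{j}" for j in range(n_genes)], E)
    return genotypes, expression, cov


class TestScan:
    def test_planted_association_survives_and_nulls_do_not(self, rng):
        genotypes, expression, cov = build_scan_fixture(rng)
        results = assoc.run_association_scan(genotypes, expression, cov)
        surviving = {(r.variant_id, r.gene_id) for r in results}
        assert ("v0", "g0") in surviving
        # encodings are correlated so dominant/recessive may co-fire on g0,
        # but no other gene should survive
        assert {g for _, g in surviving} == {"g0"}

    def test_all_null_fixture_rarely_survives(self, rng):
        genotypes, expression, cov = build_scan_fixture(rng, n=300,
                                                        n_variants=10,
                                                        n_genes=100, beta=0.0)
        results = assoc.run_association_scan(genotypes, expression, cov)
        assert len(results) <= 2  # expected ~0 at alpha 0.005 after BH

    def test_empty_variant_list(self, rng):
        genotypes, expression, cov = build_scan_fixture(rng, n=50)
        empty = GenotypeMatrix(genotypes.sample_ids, [], np.zeros((50, 0)))
        assert assoc.run_association_scan(empty, expression, cov) == []

    def test_no_shared_samples_errors(self, rng):
        genotypes, expression, cov = build_scan_fixture(rng, n=50)
        other = GenotypeMatrix([f"X{i}" for i in range(50)],
                               genotypes.variant_ids, genotypes.codes)
        with pytest.raises(ValueError, match="shared"):
            assoc.run_association_scan(other, expression, cov)

    def test_sample_permutation_invariance(self, rng):
        genotypes, expression, cov = build_scan_fixture(rng, n=200, n_genes=20)
        base = assoc.results_to_frame(
            assoc.run_association_scan(genotypes, expression, cov, keep_all=True))
        perm = rng.permutation(200)
        g2 = GenotypeMatrix([genotypes.sample_ids[i] for i in perm],
                            genotypes.variant_ids, genotypes.codes[perm])
        e2 = ExpressionMatrix([expression.sample_ids[i] for i in perm],
                              expression.gene_ids, expression.values[perm])
        shuffled = assoc.results_to_frame(
            assoc.run_association_scan(g2, e2, cov, keep_all=True))
        key = ["variant_id", "gene_id", "model"]
        merged = base.merge(shuffled, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_allclose(merged["beta1_a"], merged["beta1_b"],
                                   rtol=1e-9)
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], rtol=1e-7)

    def test_parameter_recovery_unbiased(self, rng):
        """Mean estimation error over repeated simulations is within 2 SE."""
        errors = []
        for _ in range(200):
            n = 120
            codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
            beta = rng.normal(0, 0.3)
            cov = make_covariates(n, rng)
            y = beta * codes + rng.normal(0, 0.5, n)
            res = assoc.test_association(y, codes,
                                         cov.design_columns(cov.sample_ids))
            if res is not None:
                errors.append(res.beta1 - beta)
        errors = np.asarray(errors)
        se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) <= 2 * se + 1e-12

    def test_cis_trans_labelling(self):
        r = assoc.AssociationResult("v", "g", "additive", 1.0, 0.1, 1e-5)
        assoc.label_cis_trans([r], {"v": ("chr1", 500_000)},
                              {"g": ("chr1", 1_000_000, 1_010_000)})
        assert r.cis_trans == "cis"
        assoc.label_cis_trans([r], {"v": ("chr2", 500_000)},
                              {"g": ("chr1", 1_000_000, 1_010_000)})
        assert r.cis_trans == "trans"
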