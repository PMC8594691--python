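import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epiewas.association_models import (
    DesignMatrix,
    ScanConfig,
    bh_fdr,
    emodel_scan,
    gmodel_scan,
    gxe_scan,
    merge_chunked,
    residualize,
)
from epiewas.containers import GenotypeMatrix, SampleFrame

from conftest import make_matrix


def make_design(n, covariates=None):
    sf = SampleFrame(
        sample_ids=[f"S{j+1}" for j in range(n)],
        env=np.arange(n, dtype=float),
        covariates=covariates,
    )
    return DesignMatrix.from_sample_frame(sf)


def make_genotypes(codes, starts=None, chrom="chr1"):
    codes = np.asarray(codes, dtype=float)
    n_var, n_samp = codes.shape
    if starts is None:
        starts = np.arange(n_var) * 10 + 12
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(starts) + 1, "start": starts,
        "ref": "A", "alt": "G", "qual": 60.0,
    })
    return GenotypeMatrix(variants=variants, samples=[f"S{j+1}" for j in range(n_samp)],
                          codes=codes)


# ---------------------------------------------------------------------------
# residualize / design
# ---------------------------------------------------------------------------

class TestResidualize:
    def test_intercept_only_centers(self):
        d = make_design(3)
        np.testing.assert_allclose(residualize(np.array([1.0, 2.0, 3.0]), d),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_on_orthogonal_input(self):
        d = make_design(4)
        y = np.array([-1.5, -0.5, 0.5, 1.5])  # already centered
        np.testing.assert_allclose(residualize(y, d), y, atol=1e-12)

    def test_output_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"cov1": rng.normal(size=50),
                            "cov2": [f"g{i % 3}" for i in range(50)]})
        d = make_design(50, cov)
        y = rng.normal(size=50)
        r = residualize(y, d)
        assert np.max(np.abs(d.X.T @ r)) < 1e-8 * np.linalg.norm(y)

    def test_matches_dense_ols_residuals(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        d = DesignMatrix(X=X, columns=["intercept", "a", "b", "c"])
        for _ in range(5):
            y = rng.normal(size=50)
            expected = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(residualize(y, d), expected, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X=X, columns=["intercept", "dup"])

    def test_categorical_covariate_one_hot_first_level_dropped(self):
        cov = pd.DataFrame({"cov1": ["a", "b", "c", "a", "b", "c"]})
        d = make_design(6, cov)
        assert d.columns == ["intercept", "cov1_b", "cov1_c"]


# ---------------------------------------------------------------------------
# Emodel
# ---------------------------------------------------------------------------

class TestEmodel:
    def test_closed_form_slope(self):
        sf = SampleFrame(sample_ids=["A", "B", "C"], env=np.array([1.0, 2.0, 3.0]))
        m = make_matrix([[0.1, 0.2, 0.4]])
        out = emodel_scan(m, sf)
        assert out["beta"].iloc[0] == pytest.approx(0.15)  # Sxy/Sxx = 0.3/2

    def test_exact_fit_dropped_as_nonfinite(self):
        sf = SampleFrame(sample_ids=list("ABCD"), env=np.array([1.0, 2.0, 3.0, 4.0]))
        m = make_matrix([[0.1, 0.2, 0.3, 0.4], [0.3, 0.1, 0.4, 0.1]], starts=[10, 20])
        out = emodel_scan(m, sf)
        assert out["id"].tolist() == ["chr1:20-21"]

    def test_env_scaling_equivariance(self):
        rng = np.random.default_rng(2)
        vals = rng.random((10, 20))
        env = rng.normal(size=20)
        sf1 = SampleFrame(sample_ids=[f"S{j}" for j in range(20)], env=env)
        sf2 = SampleFrame(sample_ids=[f"S{j}" for j in range(20)], env=env * 4.0)
        m = make_matrix(vals)
        a, b = emodel_scan(m, sf1), emodel_scan(m, sf2)
        np.testing.assert_allclose(b["beta"], a["beta"] / 4.0, rtol=1e-10)
        np.testing.assert_allclose(b["stat"], a["stat"], rtol=1e-10)
        np.testing.assert_allclose(b["pvalue"], a["pvalue"], rtol=1e-10)

    def test_stat_equals_pearson_t_without_covariates(self):
        rng = np.random.default_rng(3)
        n = 30
        vals = rng.random((5, n))
        env = rng.normal(size=n)
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)], env=env)
        out = emodel_scan(make_matrix(vals), sf)
        for i in range(5):
            r = np.corrcoef(vals[i], env)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            assert out["stat"].iloc[i] == pytest.approx(t, rel=1e-10)

    def test_constant_env_rejected(self):
        sf = SampleFrame(sample_ids=list("ABC"), env=np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="constant"):
            emodel_scan(make_matrix([[0.1, 0.2, 0.3]]), sf)

    def test_incomplete_matrix_rejected(self):
        sf = SampleFrame(sample_ids=list("ABC"), env=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="missing"):
            emodel_scan(make_matrix([[0.1, np.nan, 0.3]]), sf)

    def test_null_pvalues_uniform(self):
        """Under the null the p-value distribution is uniform (KS check)."""
        rng = np.random.default_rng(4)
        n = 30
        vals = rng.random((5000, n))
        env = rng.normal(size=n)
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)], env=env)
        out = emodel_scan(make_matrix(vals, starts=np.arange(5000) * 2 + 2), sf)
        assert stats.kstest(out["pvalue"], "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Gmodel
# ---------------------------------------------------------------------------

class TestGmodel:
    def test_exact_additive_effect(self):
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(6)],
                         env=np.arange(6, dtype=float))
        d = DesignMatrix.from_sample_frame(sf)
        m = make_matrix([[0.1, 0.1, 0.2, 0.2, 0.3, 0.35]], starts=[10])
        g = make_genotypes([[1, 1, 2, 2, 3, 3]], starts=[12])
        out = gmodel_scan(m, g, d)
        # exact OLS slope on the constructed data
        gg = np.array([1, 1, 2, 2, 3, 3], float)
        mm = m.values[0]
        slope = np.cov(gg, mm, ddof=1)[0, 1] / np.var(gg, ddof=1)
        assert out["beta"].iloc[0] == pytest.approx(slope, rel=1e-10)

    def test_distant_snp_not_tested(self):
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(6)],
                         env=np.arange(6, dtype=float))
        d = DesignMatrix.from_sample_frame(sf)
        m = make_matrix([[0.1, 0.3, 0.2, 0.4, 0.3, 0.5]], starts=[10])
        g = make_genotypes([[1, 1, 2, 2, 3, 3]], starts=[3010])
        with pytest.warns(UserWarning, match="no .*pair"):
            out = gmodel_scan(m, g, d, ScanConfig(distance=2000))
        assert len(out) == 0

    def test_constant_variant_skipped(self):
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(6)],
                         env=np.arange(6, dtype=float))
        d = DesignMatrix.from_sample_frame(sf)
        m = make_matrix([[0.1, 0.3, 0.2, 0.4, 0.3, 0.5]], starts=[10])
        g = make_genotypes([[2, 2, 2, 2, 2, 2]], starts=[12])
        with pytest.warns(UserWarning):
            out = gmodel_scan(m, g, d)
        assert len(out) == 0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 20
        vals = rng.random((4, n))
        codes = rng.integers(1, 4, size=(2, n)).astype(float)
        env = rng.normal(size=n)
        cov = pd.DataFrame({"cov1": rng.normal(size=n)})
        perm = rng.permutation(n)

        def scan(order):
            sf = SampleFrame(sample_ids=[f"S{j}" for j in order], env=env[order],
                             covariates=cov.iloc[order].reset_index(drop=True))
            d = DesignMatrix.from_sample_frame(sf)
            m = make_matrix(vals[:, order],
                            samples=[f"S{j}" for j in order])
            g = make_genotypes(codes[:, order], starts=[12, 22])
            g.samples = [f"S{j}" for j in order]
            return gmodel_scan(m, g, d)

        a, b = scan(np.arange(n)), scan(perm)
        np.testing.assert_allclose(a["stat"], b["stat"], rtol=1e-9)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-9)


# ---------------------------------------------------------------------------
# GxE
# ---------------------------------------------------------------------------

class TestGxE:
    def test_single_genotype_class_absent_from_output(self):
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(6)],
                         env=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        d = DesignMatrix.from_sample_frame(sf)
        m = make_matrix([[0.1, 0.3, 0.2, 0.4, 0.3, 0.5]], starts=[10])
        g = make_genotypes([[1, 1, 1, 1, 1, 1]], starts=[12])
        with pytest.warns(UserWarning):
            out = gxe_scan(m, g, sf, d)
        assert len(out) == 0

    def test_interaction_coefficient_recovered(self):
        rng = np.random.default_rng(6)
        n = 60
        env = rng.normal(size=n)
        codes = rng.integers(1, 4, size=n).astype(float)
        y = 0.3 + 0.02 * codes + 0.01 * env + 0.05 * codes * env \
            + rng.normal(0, 0.01, size=n)
        y = np.clip(y, 0, 1)
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)], env=env)
        d = DesignMatrix.from_sample_frame(sf)
        m = make_matrix([y], starts=[10])
        g = make_genotypes([codes], starts=[12])
        out = gxe_scan(m, g, sf, d)
        assert out["beta"].iloc[0] == pytest.approx(0.05, abs=0.01)
        assert out["pvalue"].iloc[0] < 1e-6

    def test_no_interaction_gives_large_pvalue_on_exact_data(self):
        n = 12
        env = np.arange(n, dtype=float)
        codes = np.tile([1.0, 2.0, 3.0], 4)
        rng = np.random.default_rng(7)
        y = np.clip(0.3 + 0.05 * codes + 0.01 * env + rng.normal(0, 0.02, n), 0, 1)
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)], env=env)
        d = DesignMatrix.from_sample_frame(sf)
        out = gxe_scan(make_matrix([y], starts=[10]), make_genotypes([codes], starts=[12]),
                       sf, d)
        assert out["pvalue"].iloc[0] > 0.05


# ---------------------------------------------------------------------------
# full-OLS oracle equivalence for all three scans
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(8)
    n, k = 50, 40
    env = rng.normal(size=n)
    cov = pd.DataFrame({
        "cov1": rng.normal(size=n),
        "cov2": rng.normal(size=n),
        "cov3": [f"s{i % 3}" for i in range(n)],
    })
    sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)], env=env, covariates=cov)
    d = DesignMatrix.from_sample_frame(sf)
    vals = rng.random((k, n))
    codes = rng.integers(1, 4, size=(3, n)).astype(float)
    m = make_matrix(vals, starts=np.arange(k) * 10 + 10)
    g = make_genotypes(codes, starts=[15, 105, 255])
    return sf, d, m, g


class TestOlsOracle:
    def test_emodel_matches_statsmodels(self, instance):
        sf, d, m, g = instance
        out = emodel_scan(m, sf, d)
        for i in range(m.n_positions):
            X = sm.add_constant(np.column_stack([d.X[:, 1:], sf.env]))
            fit = sm.OLS(m.values[i], X).fit()
            assert out["beta"].iloc[i] == pytest.approx(fit.params[-1], rel=1e-8)
            assert out["stat"].iloc[i] == pytest.approx(fit.tvalues[-1], rel=1e-8)
            assert out["pvalue"].iloc[i] == pytest.approx(fit.pvalues[-1], rel=1e-8)

    def test_gmodel_matches_statsmodels(self, instance):
        sf, d, m, g = instance
        out = gmodel_scan(m, g, d, ScanConfig(all_pairs=True))
        snp_ids = g.snp_ids().tolist()
        ids = m.row_ids().tolist()
        for row in out.itertuples(index=False):
            i, j = ids.index(row.id), snp_ids.index(row.snp)
            X = sm.add_constant(np.column_stack([d.X[:, 1:], g.codes[j]]))
            fit = sm.OLS(m.values[i], X).fit()
            assert row.beta == pytest.approx(fit.params[-1], rel=1e-8)
            assert row.stat == pytest.approx(fit.tvalues[-1], rel=1e-8)

    def test_gxe_matches_statsmodels(self, instance):
        sf, d, m, g = instance
        out = gxe_scan(m, g, sf, d, ScanConfig(all_pairs=True))
        snp_ids = g.snp_ids().tolist()
        ids = m.row_ids().tolist()
        for row in out.itertuples(index=False):
            i, j = ids.index(row.id), snp_ids.index(row.snp)
            X = sm.add_constant(np.column_stack(
                [d.X[:, 1:], g.codes[j], sf.env, g.codes[j] * sf.env]))
            fit = sm.OLS(m.values[i], X).fit()
            assert row.beta == pytest.approx(fit.params[-1], rel=1e-8)
            assert row.stat == pytest.approx(fit.tvalues[-1], rel=1e-8)
            assert row.pvalue == pytest.approx(fit.pvalues[-1], rel=1e-8)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_step_up(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)
        # step-up property: q non-decreasing in p order
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# chunk merging
# ---------------------------------------------------------------------------

class TestMergeChunked:
    def _scan(self, n_rows=40, n=20, seed=9):
        rng = np.random.default_rng(seed)
        sf = SampleFrame(sample_ids=[f"S{j}" for j in range(n)],
                         env=rng.normal(size=n))
        m = make_matrix(rng.random((n_rows, n)), starts=np.arange(n_rows) * 5 + 5)
        return sf, m

    def test_chunked_equals_unchunked_bitwise(self):
        sf, m = self._scan()
        full = emodel_scan(m, sf)
        chunks = [emodel_scan(m.take_rows(np.arange(lo, lo + 10)), sf)
                  for lo in range(0, 40, 10)]
        merged = merge_chunked(chunks)
        assert merged["id"].tolist() == full["id"].tolist()
        assert (merged["fdr"].to_numpy() == full["fdr"].to_numpy()).all()

    def test_single_chunk_identity_plus_fdr(self):
        sf, m = self._scan()
        full = emodel_scan(m, sf)
        merged = merge_chunked([full.drop(columns=["fdr"])])
        assert (merged["fdr"].to_numpy() == full["fdr"].to_numpy()).all()

    def test_duplicate_keys_rejected(self):
        sf, m = self._scan(n_rows=4)
        t = emodel_scan(m, sf)
        with pytest.raises(ValueError, match="duplicate"):
            merge_chunked([t, t])
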