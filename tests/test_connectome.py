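"""Connectivity construction, thresholding, standardization, residualization."""

import numpy as np
import pandas as pd
import pytest

from connpool.connectome import (
    CohortDataset,
    ConnectivityMatrix,
    DegenerateSeriesError,
    TimeSeriesMatrix,
    build_design_matrix,
    load_cohort,
    pearson_connectivity,
    proportional_threshold,
    residualize_covariates,
    retained_edge_target,
    save_cohort,
    standardize_matrix,
    tikhonov_connectivity,
)
from connpool.synth import SimulationConfig, simulate_cohort

from conftest import processed_matrix, random_symmetric


def make_ts(values, sid="s1"):
    values = np.asarray(values, float)
    return TimeSeriesMatrix(values, [f"r{i}" for i in range(values.shape[1])], sid)


class TestPearson:
    def test_identical_and_anticorrelated_columns(self):
        ts = make_ts(np.column_stack([[1, 2, 3], [1, 2, 3], [3, 2, 1]]))
        c = pearson_connectivity(ts).values
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_matches_per_pair_formula_oracle(self, rng):
        ts = make_ts(rng.standard_normal((20, 4)))
        c = pearson_connectivity(ts).values
        x = ts.values
        for i in range(4):
            for j in range(4):
                ti = x[:, i] - x[:, i].mean()
                tj = x[:, j] - x[:, j].mean()
                expect = (ti @ tj) / np.sqrt((ti @ ti) * (tj @ tj))
                assert abs(c[i, j] - expect) < 1e-12

    def test_affine_invariance_and_range(self, rng):
        ts = make_ts(rng.standard_normal((30, 5)))
        c1 = pearson_connectivity(ts).values
        scaled = ts.values.copy()
        scaled[:, 2] = 4.2 * scaled[:, 2] - 7.0
        c2 = pearson_connectivity(make_ts(scaled)).values
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        assert np.all(np.abs(c1) <= 1.0)

    def test_zero_variance_roi_raises_naming_roi(self):
        ts = make_ts(np.column_stack([[1, 2, 3], [5, 5, 5]]))
        with pytest.raises(DegenerateSeriesError, match="r1"):
            pearson_connectivity(ts)


class TestTikhonov:
    def test_identity_covariance_closed_form(self, rng):
        # series whose empirical covariance (1/T convention) is the identity
        t, n = 40, 3
        x = rng.standard_normal((t, n))
        x -= x.mean(axis=0)
        # orthogonalize and rescale columns to exact unit 1/T-covariance
        q, _ = np.linalg.qr(x)
        x = q * np.sqrt(t)
        p = tikhonov_connectivity(make_ts(x), rho=0.1).values
        np.testing.assert_allclose(p, np.eye(n) / 1.1, atol=1e-10)

    def test_2x2_closed_form(self):
        # build a series with covariance [[1, .5], [.5, 1]]
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        chol = np.linalg.cholesky(cov)
        t = 50
        rng = np.random.default_rng(0)
        z = rng.standard_normal((t, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        x = q * np.sqrt(t) @ chol.T
        p = tikhonov_connectivity(make_ts(x), rho=0.1).values
        expect = np.array([[1.145833, -0.520833], [-0.520833, 1.145833]])
        np.testing.assert_allclose(p, expect, atol=1e-5)

    def test_rho_zero_is_plain_inverse_and_inverse_identity(self, rng):
        x = rng.standard_normal((60, 4))
        ts = make_ts(x)
        xc = x - x.mean(axis=0)
        c = xc.T @ xc / 60
        p0 = tikhonov_connectivity(ts, rho=0.0).values
        np.testing.assert_allclose(p0, np.linalg.inv(c), atol=1e-8)
        p = tikhonov_connectivity(ts, rho=0.3).values
        np.testing.assert_allclose((c + 0.3 * np.eye(4)) @ p, np.eye(4), atol=1e-8)


class TestProportionalThreshold:
    @pytest.mark.parametrize("n", [5, 30, 90, 173, 400])
    def test_retained_count_matches_floor_formula(self, n, rng):
        cm = ConnectivityMatrix(random_symmetric(rng, n),
                                [str(i) for i in range(n)], "s")
        out = proportional_threshold(cm, 0.05)
        expect = int(np.floor(0.05 * n * (n - 1) / 2))
        assert out.retained_edge_count() == expect
        if n == 90:
            assert expect == 200

    def test_keeps_top_magnitudes_per_sort_oracle(self, rng):
        n = 12
        cm = ConnectivityMatrix(random_symmetric(rng, n),
                                [str(i) for i in range(n)], "s")
        out = proportional_threshold(cm, 0.2)
        iu, ju = np.triu_indices(n, k=1)
        vals = cm.values[iu, ju]
        m = retained_edge_target(n, 0.2)
        top = set(np.argsort(-np.abs(vals), kind="stable")[:m])
        kept = set(np.flatnonzero(out.values[iu, ju] != 0))
        assert kept == top
        # retained entries keep their signed weights
        for k in kept:
            assert out.values[iu[k], ju[k]] == vals[k]

    def test_idempotent_and_zero_matrix(self, rng):
        cm = processed_matrix(rng, 10, sparsity=0.3)
        again = proportional_threshold(cm, 0.3)
        np.testing.assert_array_equal(again.values, cm.values)
        zeros = ConnectivityMatrix(np.zeros((6, 6)), list("abcdef"), "z")
        assert proportional_threshold(zeros, 0.5).retained_edge_count() == 0

    def test_rejects_bad_sparsity(self, rng):
        cm = ConnectivityMatrix(random_symmetric(rng, 5), list("abcde"), "s")
        for bad in (0.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                proportional_threshold(cm, bad)


class TestStandardize:
    def test_two_values_population_sd(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[0, 2] = m[2, 0] = 3.0
        cm = ConnectivityMatrix(m, list("abc"), "s", is_thresholded=True)
        z = standardize_matrix(cm).values
        assert z[0, 1] == pytest.approx(-1.0)  # population sd of {1,3} is 1
        assert z[0, 2] == pytest.approx(+1.0)

    def test_moments_and_zero_preservation(self, rng):
        cm = processed_matrix(rng, 14, sparsity=0.25)
        iu = np.triu_indices(14, k=1)
        vals = cm.values[iu]
        retained = vals[vals != 0]
        assert abs(retained.mean()) < 1e-12
        assert abs(retained.std() - 1.0) < 1e-12
        raw = ConnectivityMatrix(random_symmetric(rng, 14),
                                 [str(i) for i in range(14)], "s")
        thr = proportional_threshold(raw, 0.25)
        std = standardize_matrix(thr)
        assert np.count_nonzero(std.values) == np.count_nonzero(thr.values)
        assert np.allclose(std.values, std.values.T)

    def test_constant_retained_values_raise(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 2.0
        m[0, 2] = m[2, 0] = 2.0
        cm = ConnectivityMatrix(m, list("abc"), "s", is_thresholded=True)
        with pytest.raises(ValueError, match="variance"):
            standardize_matrix(cm)


class TestResidualize:
    @staticmethod
    def _cohort_with_edge_effect(rng, n_subj=200, n=8, age_beta=0.0):
        mats, rows = [], []
        for k in range(n_subj):
            age = rng.uniform(7, 30)
            site = f"site{k % 2}"
            m = random_symmetric(rng, n)
            m[0, 1] = m[1, 0] = 2.0 * age_beta * age + rng.normal(0, 1)
            cm = ConnectivityMatrix(m, [str(i) for i in range(n)], f"s{k:03d}",
                                    is_thresholded=True)
            mats.append(cm)
            rows.append({"subject_id": f"s{k:03d}", "site": site, "age": age,
                         "sex": "M" if k % 3 else "F", "score": rng.normal()})
        return CohortDataset(mats, pd.DataFrame(rows), "score")

    def test_planted_age_effect_removed(self, rng):
        ds = self._cohort_with_edge_effect(rng, n_subj=500, age_beta=1.0)
        out = residualize_covariates(ds, ("site", "age", "sex"))
        edge = np.array([cm.values[0, 1] for cm in out.matrices])
        ages = ds.phenotypes["age"].to_numpy()
        r = np.corrcoef(edge, ages)[0, 1]
        assert abs(r) < 0.05

    def test_residuals_orthogonal_to_design(self, rng):
        ds = self._cohort_with_edge_effect(rng, n_subj=60)
        out = residualize_covariates(ds, ("site", "age", "sex"))
        x, _ = build_design_matrix(ds.phenotypes, ("site", "age", "sex"))
        resid = np.array([cm.values[0, 1] for cm in out.matrices])
        assert np.all(np.abs(x.T @ resid) < 1e-8)

    def test_no_covariates_single_site_mean_centers(self, rng):
        mats, rows = [], []
        for k in range(12):
            cm = ConnectivityMatrix(random_symmetric(rng, 5),
                                    [str(i) for i in range(5)], f"s{k}",
                                    is_thresholded=True)
            mats.append(cm)
            rows.append({"subject_id": f"s{k}", "site": "A", "age": 10.0,
                         "sex": "M", "score": float(k)})
        ds = CohortDataset(mats, pd.DataFrame(rows), "score")
        out = residualize_covariates(ds, ())
        stack_in = ds.stacked()
        stack_out = out.stacked()
        np.testing.assert_allclose(stack_out, stack_in - stack_in.mean(axis=0),
                                   atol=1e-12)

    def test_rank_deficient_design_raises(self, rng):
        ds = self._cohort_with_edge_effect(rng, n_subj=20)
        pheno = ds.phenotypes.copy()
        # make the site indicator a copy of the sex indicator -> collinear
        pheno["site"] = np.where(pheno["sex"] == "M", "siteB", "siteA")
        ds2 = CohortDataset(ds.matrices, pheno, "score")
        with pytest.raises(ValueError, match="collinear"):
            residualize_covariates(ds2, ("site", "sex"))


class TestCohortIO:
    def test_round_trip_bitwise(self, tmp_path):
        cfg = SimulationConfig(n_subjects=3, n_rois=6, support_size=2, sparsity=0.4, seed=1)
        ds, _ = simulate_cohort(cfg)
        save_cohort(ds, tmp_path)
        mats = sorted(p for p in tmp_path.glob("*.tsv"))
        back = load_cohort(matrix_paths=mats,
                           phenotype_path=tmp_path / "phenotypes.csv",
                           target_name="severity")
        assert back.n_subjects == 3
        for a, b in zip(ds.matrices, back.matrices):
            assert np.array_equal(a.values, b.values)

    def test_missing_matrix_names_subject(self, tmp_path):
        cfg = SimulationConfig(n_subjects=3, n_rois=6, support_size=2, sparsity=0.4, seed=1)
        ds, _ = simulate_cohort(cfg)
        save_cohort(ds, tmp_path)
        (tmp_path / "sub-0001.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="sub-0001"):
            load_cohort(matrix_paths=sorted(tmp_path.glob("*.tsv")),
                        phenotype_path=tmp_path / "phenotypes.csv",
                        target_name="severity")
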