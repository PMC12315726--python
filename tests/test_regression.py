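import numpy as np
import pytest

import netsift as ns
from netsift.regression import DesignError, build_design, quadratic_rule


class TestVectorizedFitMatchesReference:
    def test_fifty_random_edges(self, planted_cohort, planted_fits):
        stack, subjects, _ = planted_cohort
        rng = np.random.default_rng(0)
        edges = rng.choice(stack.n_edges, size=50, replace=False)
        for e in edges:
            params, t_ref, p_ref = ns.fit_single_edge_reference(stack, subjects, int(e))
            assert np.allclose(planted_fits.beta[e], params, atol=1e-8)
            assert planted_fits.t_age[e] == pytest.approx(t_ref, abs=1e-8)
            assert planted_fits.p_age[e] == pytest.approx(p_ref, abs=1e-8)

    def test_reference_agrees_with_quadratic_design(self, planted_cohort):
        stack, subjects, _ = planted_cohort
        fits = ns.fit_edges(stack, subjects, include_quadratic="always")
        params, t_ref, p_ref = ns.fit_single_edge_reference(
            stack, subjects, 7, include_quadratic=True
        )
        assert np.allclose(fits.beta[7], params, atol=1e-8)
        assert fits.t_age[7] == pytest.approx(t_ref, abs=1e-8)


class TestFitEdgesContracts:
    def test_requires_imputed_stack(self, planted_cohort):
        stack, subjects, _ = planted_cohort
        vals = stack.values.copy()
        missing = np.zeros_like(vals, bool)
        missing[0, 0] = True
        dirty = ns.ConnectomeStack(stack.subject_ids, stack.n_nodes, vals, missing)
        with pytest.raises(ValueError, match="missing"):
            ns.fit_edges(dirty, subjects)

    def test_constant_edge_degenerate_contract(self, planted_cohort):
        stack, subjects, _ = planted_cohort
        vals = stack.values.copy()
        vals[:, 5] = 0.42
        const_stack = ns.ConnectomeStack(stack.subject_ids, stack.n_nodes, vals)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            fits = ns.fit_edges(const_stack, subjects)
        assert fits.t_age[5] == 0.0
        assert fits.p_age[5] == 1.0

    def test_rank_deficient_design_named(self, planted_cohort):
        stack, subjects, _ = planted_cohort
        df = subjects.df.copy()
        df["pos_y"] = df["pos_x"]  # duplicate confound column
        with pytest.raises(DesignError, match="pos"):
            ns.fit_edges(stack, ns.SubjectTable(df))

    def test_type_one_error_calibrated(self, null_fits):
        frac = (null_fits.p_age < 0.05).mean()
        n = len(null_fits.p_age)
        band = 2.58 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < band + 0.005

    def test_planted_edges_show_negative_t(self):
        spec = ns.CohortSpec(
            n_subjects=300,
            n_nodes=30,
            planted=[ns.PlantedSubnetworkSpec(nodes=range(12), beta_age=-0.003)],
            noise_sd=0.3,
            seed=31,
        )
        stack, subjects, _ = ns.generate_cohort(spec)
        fits = ns.fit_edges(stack, subjects)
        cols = [stack.edge_index.index_of(i, j) for i in range(12) for j in range(i + 1, 12)]
        # theoretical noncentrality: beta * sqrt(sum(age_c^2)) / noise_sd
        age_c = subjects.age - subjects.age.mean()
        expected_t = -0.003 * np.sqrt((age_c**2).sum()) / 0.3
        mean_t = fits.t_age[cols].mean()
        assert mean_t < -1.5
        assert mean_t == pytest.approx(expected_t, abs=3 / np.sqrt(len(cols)))

    def test_subject_reordering_invariance(self, planted_cohort, planted_fits):
        stack, subjects, _ = planted_cohort
        rng = np.random.default_rng(5)
        perm = rng.permutation(stack.n_subjects)
        stack_p = stack.subset(perm)
        subjects_p = subjects.subset(perm)
        fits_p = ns.fit_edges(stack_p, subjects_p)
        assert np.allclose(fits_p.t_age, planted_fits.t_age, atol=1e-10)
        W1 = ns.build_inference_matrix(planted_fits)
        W2 = ns.build_inference_matrix(fits_p)
        assert np.allclose(W1.w, W2.w, atol=1e-10)


class TestQuadraticRule:
    def _cohort_with_quadratic(self, beta_sq, seed=41, noise=0.1):
        spec = ns.CohortSpec(
            n_subjects=400,
            n_nodes=12,
            planted=[
                ns.PlantedSubnetworkSpec(
                    nodes=range(12), beta_age=-0.002, beta_age_sq=beta_sq
                )
            ],
            noise_sd=noise,
            seed=seed,
        )
        return ns.generate_cohort(spec)[:2]

    def test_linear_data_rejects_quadratic(self):
        stack, subjects = self._cohort_with_quadratic(0.0)
        fits = ns.fit_edges(stack, subjects, include_quadratic="auto")
        assert fits.used_quadratic is False
        assert "age_c_sq" not in fits.columns

    def test_strong_quadratic_retained(self):
        # beta_age_sq large enough for partial r^2 well above 1%
        stack, subjects = self._cohort_with_quadratic(-0.0008, noise=0.05)
        fits = ns.fit_edges(stack, subjects, include_quadratic="auto")
        assert fits.used_quadratic is True
        assert np.median(fits.partial_r2_agesq) >= 0.01

    def test_unreachable_threshold_always_false(self):
        stack, subjects = self._cohort_with_quadratic(-0.0008, noise=0.05)
        fit_w = ns.fit_edges(stack, subjects, include_quadratic="always")
        fit_wo = ns.fit_edges(stack, subjects, include_quadratic="never")
        assert quadratic_rule(fit_w, fit_wo, r2_min=1.0) is False

    def test_per_edge_scope_returns_mask(self):
        stack, subjects = self._cohort_with_quadratic(-0.0008, noise=0.05)
        fit_w = ns.fit_edges(stack, subjects, include_quadratic="always")
        fit_wo = ns.fit_edges(stack, subjects, include_quadratic="never")
        mask = quadratic_rule(fit_w, fit_wo, scope="per_edge")
        assert mask.shape == (stack.n_edges,)
        assert mask.any()


class TestInferenceMatrix:
    def test_known_transforms(self, null_fits):
        W = ns.build_inference_matrix(null_fits, direction="both")
        e = 11
        i, j = null_fits_pairs(null_fits)[e]
        assert W.w[i, j] == pytest.approx(-np.log10(null_fits.p_age[e]))
        assert W.w[i, j] == W.w[j, i]
        assert np.all(np.diag(W.w) == 0)

    def test_point_values(self):
        W = ns.build_inference_matrix(
            _tiny_fits(p=np.array([0.05]), t=np.array([-2.0]), n_nodes=2), "both"
        )
        assert W.w[0, 1] == pytest.approx(1.30103, abs=1e-5)
        W1 = ns.build_inference_matrix(
            _tiny_fits(p=np.array([1.0]), t=np.array([0.5]), n_nodes=2), "both"
        )
        assert W1.w[0, 1] == 0.0

    def test_direction_mask_halves_null(self, null_fits):
        Wn = ns.build_inference_matrix(null_fits, direction="negative")
        Wb = ns.build_inference_matrix(null_fits, direction="both")
        iu = np.triu_indices(Wn.n_nodes, 1)
        frac_zeroed = (Wn.w[iu] == 0).mean() - (Wb.w[iu] == 0).mean()
        assert frac_zeroed == pytest.approx(0.5, abs=0.05)
        # sign matrix retained regardless of masking
        assert np.array_equal(Wn.sign, Wb.sign)

    def test_null_mean_weight(self, null_fits):
        Wb = ns.build_inference_matrix(null_fits, direction="both")
        iu = np.triu_indices(Wb.n_nodes, 1)
        mean_w = Wb.w[iu].mean()
        se = np.sqrt(1 / np.log(10) ** 2 / len(iu[0]))
        assert abs(mean_w - np.log10(np.e)) < 3 * se

    def test_underflow_capped(self):
        with pytest.warns(RuntimeWarning, match="underflow"):
            W = ns.build_inference_matrix(
                _tiny_fits(p=np.array([0.0]), t=np.array([-30.0]), n_nodes=2), "both",
                w_max=50.0,
            )
        assert W.w[0, 1] == 50.0


def _tiny_fits(p, t, n_nodes):
    beta = np.zeros((len(p), 8))
    beta[:, 1] = np.sign(t)
    return ns.EdgeFitTable(
        n_nodes=n_nodes,
        columns=["const", "age_c", "sex"] + list(ns.SubjectTable.CONFOUNDS),
        beta=beta,
        t_age=t,
        p_age=p,
        rss=np.ones(len(p)),
        df_resid=100,
    )


def null_fits_pairs(fits):
    return ns.EdgeIndex(fits.n_nodes).pairs
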