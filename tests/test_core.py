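import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netsift as ns
from netsift.core import EmptyCohortError, UnimputableEdgeError


class TestEdgeCount:
    @pytest.mark.parametrize("n,expected", [(246, 30135), (2, 1), (10, 45), (1, 0)])
    def test_values(self, n, expected):
        assert ns.edge_count(n) == expected

    @pytest.mark.parametrize("bad", [0, -3])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            ns.edge_count(bad)

    @pytest.mark.parametrize("bad", [2.5, "ten", None, True])
    def test_rejects_non_integer(self, bad):
        with pytest.raises(TypeError):
            ns.edge_count(bad)

    def test_matches_edge_index_length(self):
        for n in range(2, 301, 37):
            assert ns.edge_count(n) == len(ns.EdgeIndex(n).pairs)


class TestFisherZ:
    def test_known_values(self):
        assert ns.fisher_z(0.0) == 0.0
        assert ns.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        assert ns.fisher_z(-0.5) == pytest.approx(-0.549306, abs=1e-6)

    def test_clipping_keeps_finite(self):
        z1 = ns.fisher_z(1.0)
        assert np.isfinite(z1) and z1 == pytest.approx(np.arctanh(1 - 1e-7))
        assert ns.fisher_z(-1.5) == -z1

    def test_rejects_non_numeric(self):
        with pytest.raises(TypeError):
            ns.fisher_z("strong")

    @given(st.floats(min_value=-5, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_with_tanh(self, z):
        assert ns.fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-12)

    @given(st.floats(min_value=0.001, max_value=0.999))
    @settings(max_examples=30, deadline=None)
    def test_odd_and_increasing(self, r):
        assert ns.fisher_z(-r) == pytest.approx(-ns.fisher_z(r), abs=1e-12)
        assert ns.fisher_z(r) > ns.fisher_z(r - 1e-3)


class TestEdgeIndex:
    def test_lexicographic_order(self):
        pairs = ns.EdgeIndex(4).pairs
        assert pairs.tolist() == [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]

    @given(st.integers(min_value=2, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_bijection(self, n):
        idx = ns.EdgeIndex(n)
        pairs = idx.pairs
        cols = [idx.index_of(i, j) for i, j in pairs]
        assert cols == list(range(len(pairs)))
        assert idx.index_of(1, 0) == idx.index_of(0, 1)

    def test_invalid_pairs(self):
        idx = ns.EdgeIndex(5)
        for i, j in [(2, 2), (-1, 3), (0, 5)]:
            with pytest.raises(ValueError):
                idx.index_of(i, j)


class TestVectorizeMatrixize:
    @given(st.integers(min_value=2, max_value=25), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((n, n))
        m = m + m.T
        vec = ns.vectorize_matrix(m)
        back = ns.matrixize_vector(vec, n)
        iu = np.triu_indices(n, 1)
        assert np.allclose(back[iu], m[iu])
        assert np.allclose(back, back.T, equal_nan=True)
        assert np.isnan(np.diag(back)).all()

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ns.vectorize_matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            ns.matrixize_vector(np.zeros(5), 4)


class TestTimeseriesToConnectome:
    def test_identical_columns_clip_high(self, rng):
        t = rng.standard_normal(50)
        ts = np.column_stack([t, t, rng.standard_normal(50)])
        z = ns.timeseries_to_connectome(ts)
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_negated_column_clips_low(self, rng):
        t = rng.standard_normal(50)
        ts = np.column_stack([t, -t])
        z = ns.timeseries_to_connectome(ts)
        assert z[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_independent_noise_near_zero(self, rng):
        T = 2000
        ts = rng.standard_normal((T, 2))
        z = ns.timeseries_to_connectome(ts)
        assert abs(z[0, 1]) < 4 / np.sqrt(T)

    def test_zero_variance_column_flagged_missing(self, rng):
        ts = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        z = ns.timeseries_to_connectome(ts)
        assert np.isnan(z[0, 1]) and np.isnan(z[0, 2])
        assert np.isfinite(z[1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ns.timeseries_to_connectome(np.zeros((2, 4)))


def _stack(values, n_nodes, missing=None, ids=None):
    ids = ids or [f"s{k}" for k in range(len(values))]
    return ns.ConnectomeStack(ids, n_nodes, np.asarray(values, float), missing)


class TestQCFilter:
    def test_clean_stack_is_noop(self, rng):
        stack = _stack(rng.normal(0, 0.3, (5, ns.edge_count(6))), 6)
        out = ns.qc_filter(stack, 0.1, (0.01, 10))
        assert out.subject_ids == stack.subject_ids

    def test_high_missing_subject_removed(self, rng):
        vals = rng.normal(0, 0.3, (3, ns.edge_count(6)))
        missing = np.zeros_like(vals, bool)
        missing[1, : vals.shape[1] // 2] = True
        out = ns.qc_filter(_stack(vals, 6, missing), 0.1, (0.001, 10))
        assert out.subject_ids == ["s0", "s2"]

    def test_constant_subject_removed(self, rng):
        vals = rng.normal(0, 0.3, (3, ns.edge_count(6)))
        vals[2] = 0.7
        out = ns.qc_filter(_stack(vals, 6), 0.1, (0.01, 10))
        assert out.subject_ids == ["s0", "s1"]

    def test_all_removed_raises(self):
        vals = np.full((2, ns.edge_count(5)), 0.3)
        with pytest.raises(EmptyCohortError):
            ns.qc_filter(_stack(vals, 5), 0.1, (0.01, 10))

    def test_bad_arguments(self, rng):
        stack = _stack(rng.normal(0, 0.3, (2, 10)), 5)
        with pytest.raises(ValueError):
            ns.qc_filter(stack, -0.1, (0.01, 10))
        with pytest.raises(ValueError):
            ns.qc_filter(stack, 0.1, (np.inf, 10))


class TestImputeMissing:
    def test_no_missing_identity(self, rng):
        stack = _stack(rng.normal(0, 0.3, (4, 10)), 5)
        assert ns.impute_missing(stack) is stack

    def test_mean_fill(self):
        vals = np.array([[1.0, 0.2, 0.1], [3.0, 0.2, 0.1], [0.0, 0.2, 0.1]])
        missing = np.zeros((3, 3), dtype=bool)
        missing[2, 0] = True
        out = ns.impute_missing(_stack(vals, 3, missing))
        assert out.values[2, 0] == pytest.approx(2.0)
        assert not out.missing.any()

    def test_mean_is_fixed_point(self, rng):
        vals = rng.normal(0, 0.3, (60, ns.edge_count(8)))
        missing = rng.random(vals.shape) < 0.05
        stack = _stack(vals, 8, missing)
        obs_means = np.where(missing, np.nan, vals)
        obs_means = np.nanmean(obs_means, axis=0)
        out = ns.impute_missing(stack)
        assert np.allclose(out.values.mean(axis=0), obs_means, atol=1e-12)

    def test_fully_missing_edge_raises(self):
        vals = np.zeros((2, ns.edge_count(4)))
        missing = np.zeros_like(vals, bool)
        missing[:, 3] = True
        with pytest.raises(UnimputableEdgeError) as exc:
            ns.impute_missing(_stack(vals, 4, missing))
        assert 3 in exc.value.edges

    def test_qc_then_impute_leaves_complete_stack(self, rng):
        vals = rng.normal(0, 0.3, (30, ns.edge_count(10)))
        missing = rng.random(vals.shape) < 0.03
        out = ns.impute_missing(ns.qc_filter(_stack(vals, 10, missing)))
        assert not out.missing.any()
        assert np.isfinite(out.values.mean(axis=0)).all()


class TestTables:
    def test_subject_table_validation(self):
        base = {
            "subject_id": ["a"],
            "age": [50.0],
            "sex": [1],
            **{c: [0.0] for c in ns.SubjectTable.CONFOUNDS},
        }
        t = ns.SubjectTable(pd.DataFrame(base))
        assert t.age_sq[0] == 2500.0
        with pytest.raises(ValueError):
            ns.SubjectTable(pd.DataFrame({**base, "age": [-1.0]}))
        with pytest.raises(ValueError):
            ns.SubjectTable(pd.DataFrame({**base, "sex": [2]}))
        with pytest.raises(ValueError):
            ns.SubjectTable(pd.DataFrame({k: v for k, v in base.items() if k != "age"}))

    def test_parcellation_validation(self):
        good = ns.default_parcellation(14)
        assert good.n_nodes == 14 and len(good.networks) == 7
        df = good.df.copy()
        df.loc[3, "node_id"] = 99
        with pytest.raises(ValueError):
            ns.ParcellationInfo(df)
        df2 = good.df.copy()
        df2.loc[0, "network"] = ""
        with pytest.raises(ValueError):
            ns.ParcellationInfo(df2)

    def test_alignment_check(self, planted_cohort):
        stack, subjects, _ = planted_cohort
        subjects.check_aligned(stack)
        with pytest.raises(ValueError):
            subjects.subset(np.arange(len(subjects) - 1)).check_aligned(stack)
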