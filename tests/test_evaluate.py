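"""Correlation tables, assignment, and the delta / zeta summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberdemix.camera import VideoStack
from fiberdemix.evaluate import (
    CorrelationTable,
    assign_and_sort,
    crosstalk_summary,
    diagonal_summary,
    ensemble_trace,
    fingerprint_match,
    pearson_table,
)


class TestPearsonTable:
    def test_self_correlation_is_one(self):
        t = [np.array([0.0, 1.0, 3.0, 2.0])]
        table = pearson_table(t, t)
        assert table.values[0, 0] == pytest.approx(1.0)

    def test_perfect_linear_relation(self):
        table = pearson_table([np.array([0.0, 1.0, 2.0])], [np.array([0.0, 2.0, 4.0])])
        assert table.values[0, 0] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3,4), y=(2,1,4,3): covariance 3, variances 5 -> r = 0.6
        table = pearson_table([np.array([1.0, 2, 3, 4])], [np.array([2.0, 1, 4, 3])])
        assert table.values[0, 0] == pytest.approx(0.6)

    def test_constant_trace_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            table = pearson_table([np.ones(5)], [np.arange(5.0)])
        assert table.values[0, 0] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pearson_table([np.ones(5)], [np.ones(6)])


class TestAssignment:
    def test_dominant_diagonal(self):
        table = CorrelationTable(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assignment, order = assign_and_sort(table)
        assert assignment == {0: 0, 1: 1}
        assert order == [0, 1]

    def test_tie_broken_by_lowest_row_col(self):
        table = CorrelationTable(np.array([[0.9, 0.85], [0.9, 0.1]]))
        assignment, order = assign_and_sort(table)
        assert assignment == {0: 0, 1: 1}
        assert order == [0, 1]
        assert table.values[1, assignment[1]] == pytest.approx(0.1)

    def test_assignment_inverts_component_permutation(self, three_source_scene):
        # permuting the "components" of a well-separated scene is undone
        traces = three_source_scene.traces
        perm = [2, 0, 1]
        table = pearson_table(traces, [traces[j] for j in perm])
        assignment, _ = assign_and_sort(table)
        assert assignment == {i: perm.index(i) for i in range(3)}

    def test_more_sources_than_components_leaves_unassigned(self):
        table = CorrelationTable(np.array([[0.9], [0.5]]))
        assignment, order = assign_and_sort(table)
        assert assignment == {0: 0}
        assert order == [0]


class TestDiagonalSummary:
    def table(self):
        return CorrelationTable(np.diag([0.9, 0.8, 0.7]))

    def test_mean(self):
        s = diagonal_summary(self.table(), {0: 0, 1: 1, 2: 2})
        assert s.delta_avg == pytest.approx(0.8)

    def test_population_std(self):
        s = diagonal_summary(self.table(), {0: 0, 1: 1, 2: 2})
        assert s.sigma_delta == pytest.approx(0.081649658, rel=1e-6)

    def test_single_source_zero_spread(self):
        s = diagonal_summary(self.table(), {0: 0, 1: 1, 2: 2}, subset=[1])
        assert s.sigma_delta == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            diagonal_summary(self.table(), {0: 0}, subset=[])


class TestCrosstalkSummary:
    def test_identical_tables_zero_crosstalk(self):
        nu = CorrelationTable(np.array([[1.0, 0.3], [0.2, 1.0]]))
        s = crosstalk_summary(nu, nu, [0, 1])
        assert s.zeta_avg == 0.0
        assert s.sigma_zeta == 0.0

    def test_hand_computed_case(self):
        # off-diagonals nu={0.3, 0.2}, gamma={0.1, 0.1}: AE={0.2, 0.1}, mean 0.15
        nu = CorrelationTable(np.array([[1.0, 0.3], [0.2, 1.0]]))
        ga = CorrelationTable(np.array([[1.0, 0.1], [0.1, 1.0]]))
        s = crosstalk_summary(nu, ga, [0, 1])
        assert sorted(s.ae_matrix[~np.eye(2, dtype=bool)]) == pytest.approx([0.1, 0.2])
        assert s.zeta_avg == pytest.approx(0.15)

    def test_printed_prefactor_variant(self):
        nu = CorrelationTable(np.array([[1.0, 0.3], [0.2, 1.0]]))
        ga = CorrelationTable(np.array([[1.0, 0.1], [0.1, 1.0]]))
        s = crosstalk_summary(nu, ga, [0, 1], printed_prefactor=True)
        assert s.zeta_avg == pytest.approx(0.3 / 2)  # sum/(2(N-1)) with N=2

    def test_subset_of_one_rejected(self):
        nu = CorrelationTable(np.eye(2))
        with pytest.raises(ValueError):
            crosstalk_summary(nu, nu, [0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crosstalk_summary(CorrelationTable(np.eye(2)), CorrelationTable(np.eye(3)), [0, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_relabel_invariance(self, perm):
        # zeta statistics cannot depend on how sources are numbered
        rng = np.random.default_rng(3)
        nu = rng.uniform(-1, 1, (4, 4))
        ga = rng.uniform(-1, 1, (4, 4))
        base = crosstalk_summary(CorrelationTable(nu), CorrelationTable(ga), list(range(4)))
        p = list(perm)
        rel = crosstalk_summary(
            CorrelationTable(nu[np.ix_(p, p)]), CorrelationTable(ga[np.ix_(p, p)]), list(range(4))
        )
        assert rel.zeta_avg == pytest.approx(base.zeta_avg)
        assert rel.sigma_zeta == pytest.approx(base.sigma_zeta)

    def test_percent_scale_consistency(self):
        # evaluating on fraction scale and multiplying by 100 reproduces
        # percent-scale statistics exactly
        rng = np.random.default_rng(5)
        nu = rng.uniform(-1, 1, (3, 3))
        ga = rng.uniform(-1, 1, (3, 3))
        frac = crosstalk_summary(CorrelationTable(nu), CorrelationTable(ga), [0, 1, 2])
        pct_ae = np.abs(nu * 100 - ga * 100)
        off = pct_ae[~np.eye(3, dtype=bool)]
        assert frac.zeta_avg * 100 == pytest.approx(off.mean())
        assert frac.sigma_zeta * 100 == pytest.approx(off.std())


class TestFingerprintMatch:
    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        same = fingerprint_match([img], [img], {0: 0})
        doubled = fingerprint_match([img], [2.0 * img], {0: 0})
        assert same[0] == pytest.approx(1.0)
        assert doubled[0] == pytest.approx(1.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            fingerprint_match([np.ones((8, 8))], [np.ones((6, 6))], {0: 0})


class TestEnsembleTrace:
    def test_matches_linear_superposition(self, three_source_scene):
        from fiberdemix.camera import render_video

        video = render_video(three_source_scene, camera=None)
        trace = ensemble_trace(video)
        W_sums = np.array([fp.image.sum() for fp in three_source_scene.fingerprints])
        expected = W_sums @ three_source_scene.trace_matrix()
        np.testing.assert_allclose(trace, expected, rtol=1e-10)

    def test_zero_video(self):
        video = VideoStack(frames=np.zeros((5, 4, 4)))
        assert np.array_equal(ensemble_trace(video), np.zeros(5))

    def test_added_source_increases_trace(self, three_source_scene):
        from fiberdemix.camera import SourceSet, render_video

        sub = SourceSet(
            three_source_scene.fingerprints[:2],
            three_source_scene.traces[:2],
            three_source_scene.positions[:2],
            three_source_scene.roles[:2],
        )
        t_sub = ensemble_trace(render_video(sub, camera=None))
        t_full = ensemble_trace(render_video(three_source_scene, camera=None))
        extra = three_source_scene.traces[2]
        assert (t_full[extra > 0] > t_sub[extra > 0]).all()
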