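"""Correlation communities, modularity, aggregated conditioning (PCGC^t)."""

import numpy as np
import pytest

from pcgc import (
    HierPartition,
    TimeSeriesSet,
    build_conditioning_set,
    build_hier_partition,
    conditional_gc,
    correlation_matrix,
    group_average_abs,
    louvain_partition,
    modularity_q,
    pcgc_t,
    pcgc_t_matrix,
)


def two_cliques(size=5):
    w = np.zeros((2 * size, 2 * size))
    w[:size, :size] = 1.0
    w[size:, size:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w


def planted_blocks(n_blocks=4, block=25, within=1.0, between=0.05):
    n = n_blocks * block
    w = np.full((n, n), between)
    for b in range(n_blocks):
        s = slice(b * block, (b + 1) * block)
        w[s, s] = within
    np.fill_diagonal(w, 0.0)
    return w


def same_partition(a, b):
    """Partition equality up to relabeling."""
    a, b = np.asarray(a), np.asarray(b)
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestCorrelationMatrix:
    def test_textbook_hand_computation(self):
        data = np.array([[1.0, 2, 0], [2, 4, 1], [3, 6, 0], [4, 8, 1]])
        r = correlation_matrix(TimeSeriesSet(data))
        assert r[0, 1] == pytest.approx(1.0)
        # hand computation of r(col0, col2): cov = 0.25/..., explicitly:
        x, y = data[:, 0], data[:, 2]
        expect = ((x - x.mean()) @ (y - y.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert r[0, 2] == pytest.approx(expect)
        assert np.allclose(np.diag(r), 1.0)

    def test_zero_variance_column_named(self):
        data = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="v2"):
            correlation_matrix(TimeSeriesSet(data))


class TestGroupAverageAbs:
    def test_average_precedes_abs(self):
        a = np.array([[0.0, 0.5], [0.5, 0.0]])
        b = np.array([[0.0, -0.5], [-0.5, 0.0]])
        w = group_average_abs([a, b])
        assert w[0, 1] == 0.0

    def test_single_matrix_and_diagonal(self):
        a = np.array([[1.0, -0.3], [-0.3, 1.0]])
        w = group_average_abs([a])
        assert w[0, 1] == pytest.approx(0.3)
        assert w[0, 0] == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average_abs([])


class TestModularityQ:
    def test_two_cliques_closed_form(self):
        w = two_cliques(5)
        q = modularity_q(w, np.array([0] * 5 + [1] * 5))
        assert q == pytest.approx(0.5)

    def test_single_community_zero(self):
        assert modularity_q(two_cliques(4), np.zeros(8, int)) == pytest.approx(0.0)

    def test_relabeling_invariance(self, rng):
        w = planted_blocks(3, 5, between=0.2)
        a = np.repeat([0, 1, 2], 5)
        b = np.repeat([7, 2, 5], 5)
        assert modularity_q(w, a) == pytest.approx(modularity_q(w, b))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            modularity_q(np.zeros((4, 4)), np.zeros(4, int))


class TestLouvain:
    def test_two_cliques_exact_split(self):
        assignment, q = louvain_partition(two_cliques(5), restarts=5, seed=0)
        assert q == pytest.approx(0.5)
        assert same_partition(assignment, [0] * 5 + [1] * 5)

    def test_planted_four_blocks_recovered(self):
        w = planted_blocks()
        truth = np.repeat(np.arange(4), 25)
        hits = 0
        for seed in range(20):
            assignment, _ = louvain_partition(w, restarts=10, seed=seed)
            hits += same_partition(assignment, truth)
        assert hits >= 19

    def test_more_restarts_never_worse(self, rng):
        w = np.abs(rng.standard_normal((30, 30)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        _, q1 = louvain_partition(w, restarts=1, seed=42)
        _, q50 = louvain_partition(w, restarts=50, seed=42)
        assert q50 >= q1 - 1e-12

    def test_reported_q_matches_assignment(self):
        w = planted_blocks(3, 10, between=0.3)
        assignment, q = louvain_partition(w, restarts=3, seed=1)
        assert q == modularity_q(w, assignment)
        assert q >= 0.0  # never below the trivial one-community Q


class TestHierPartition:
    def test_nested_two_by_two_blocks_recovered(self):
        # 2 systems of 2 subsystems each: strong within-subsystem weight,
        # medium within-system, weak between systems
        n_sub, size = 4, 10
        w = np.full((n_sub * size, n_sub * size), 0.02)
        for s in range(n_sub):
            sl = slice(s * size, (s + 1) * size)
            w[sl, sl] = 1.0
        w[:20, :20] = np.maximum(w[:20, :20], 0.4)
        w[20:, 20:] = np.maximum(w[20:, 20:], 0.4)
        for s in range(n_sub):
            sl = slice(s * size, (s + 1) * size)
            w[sl, sl] = 1.0
        np.fill_diagonal(w, 0.0)
        hier = build_hier_partition(w, restarts=10, seed=0)
        assert same_partition(hier.system_of, np.repeat([0, 1], 20))
        assert same_partition(hier.subsystem_of, np.repeat([0, 1, 2, 3], 10))

    def test_unstructured_matrix_still_well_formed(self, rng):
        w = np.abs(rng.standard_normal((12, 12)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        hier = build_hier_partition(w, restarts=5, seed=3)
        assert hier.n_vars == 12  # invariants enforced in __post_init__

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError, match="spans"):
            HierPartition(
                system_of=np.array([0, 0, 1, 1]),
                subsystem_of=np.array([0, 1, 1, 2]),
                q_top=0.3,
            )


class TestConditioningSet:
    @pytest.fixture
    def hier(self):
        # 3 systems; system 0 has 4 subsystems
        system_of = np.array([0] * 8 + [1] * 3 + [2] * 3)
        subsystem_of = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 4, 5, 5, 5])
        return HierPartition(system_of=system_of, subsystem_of=subsystem_of, q_top=0.4)

    def test_aggregate_count_fine_plus_coarse(self, hier):
        cs = build_conditioning_set(hier, driver=0, target=9, mode="t")
        assert len(cs.aggregates) == 4 + 2
        assert cs.provenance.count("subsystem-of-driver-system") == 4
        assert cs.provenance.count("other-system") == 2

    def test_modes_differ_only_in_driver_membership(self, hier):
        cs_t = build_conditioning_set(hier, 0, 9, mode="t")
        cs_ti = build_conditioning_set(hier, 0, 9, mode="ti")
        flat_t = sorted(v for agg in cs_t.aggregates for v in agg)
        flat_ti = sorted(v for agg in cs_ti.aggregates for v in agg)
        assert set(flat_ti) - set(flat_t) == {0}
        assert cs_t.aggregates[1:] == cs_ti.aggregates[1:]

    def test_every_non_driver_in_exactly_one_aggregate(self, hier):
        cs = build_conditioning_set(hier, 5, 2, mode="t")
        flat = [v for agg in cs.aggregates for v in agg]
        assert sorted(flat) == [v for v in range(14) if v != 5]
        assert len(flat) == len(set(flat))


class TestPcgcT:
    def test_singleton_limit_equals_full_conditional(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((300, 6)))
        hier = HierPartition.singletons(6)
        for (i, j) in [(0, 3), (2, 5), (4, 1)]:
            full = conditional_gc(ts, i, j, [k for k in range(6) if k not in (i, j)])
            agg = pcgc_t(ts, hier, i, j)
            assert agg.gc == pytest.approx(full.gc, abs=1e-12)
            assert agg.p_value == pytest.approx(full.p_value, abs=1e-12)

    def test_matrix_matches_per_pair_calls(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((250, 8)))
        system_of = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        subsystem_of = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        hier = HierPartition(system_of=system_of, subsystem_of=subsystem_of, q_top=0.2)
        for mode in ("t", "ti"):
            m = pcgc_t_matrix(ts, hier, mode=mode)
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    res = pcgc_t(ts, hier, i, j, mode=mode)
                    assert m.gc[i, j] == pytest.approx(res.gc, abs=1e-9)
                    assert m.p_value[i, j] == pytest.approx(res.p_value, abs=1e-8)

    def test_aggregation_equals_equal_coefficient_constraint(self, rng):
        # regressing on a group mean == constraining the members' AR
        # coefficients to share one weight
        t = 300
        data = rng.standard_normal((t, 4))
        ts = TimeSeriesSet(data)
        hier = HierPartition(
            system_of=np.array([0, 0, 1, 1]),
            subsystem_of=np.array([0, 0, 1, 1]),
            q_top=0.1,
        )
        res = pcgc_t(ts, hier, 2, 3, mode="t")
        # oracle: constrained least squares — members 0,1 share one weight,
        # implemented by regressing on their (scaled) sum; the {2,3} system
        # aggregate reduces to subsets of {driver, target} and is dropped
        y = data[1:, 3]
        shared = (data[:-1, 0] + data[:-1, 1]) / 2.0
        x_r = np.column_stack([np.ones(t - 1), data[:-1, 3], shared])
        x_u = np.column_stack([x_r, data[:-1, 2]])
        rss = []
        for x in (x_r, x_u):
            beta = np.linalg.lstsq(x, y, rcond=None)[0]
            r = y - x @ beta
            rss.append(r @ r)
        assert res.gc == pytest.approx(np.log(rss[0] / rss[1]), abs=1e-10)

    def test_ti_vs_t_highly_correlated_on_redundant_data(self, rng):
        # modules of redundant signals: removing one driver from a large
        # aggregate barely changes it, so modes t and ti nearly coincide
        t, per = 400, 10
        latents = rng.standard_normal((t, 4))
        cols = [
            latents[:, m] + 0.6 * rng.standard_normal(t)
            for m in range(4)
            for _ in range(per)
        ]
        ts = TimeSeriesSet(np.column_stack(cols))
        w = np.abs(correlation_matrix(ts))
        np.fill_diagonal(w, 0.0)
        hier = build_hier_partition(w, restarts=10, seed=0)
        pairs = [(0, 15), (3, 38), (12, 27), (21, 5), (33, 9)]
        vals_t = [pcgc_t(ts, hier, i, j, mode="t").gc for i, j in pairs]
        vals_ti = [pcgc_t(ts, hier, i, j, mode="ti").gc for i, j in pairs]
        r = np.corrcoef(vals_t, vals_ti)[0, 1]
        assert r > 0.99


class TestLabelExport:
    def test_round_trip_through_voxel_space(self):
        from pcgc.community import communities_to_label_volume
        from pcgc.io import VolumeMask

        flat_mask = np.zeros(64, dtype=bool)
        flat_mask[[2, 7, 9, 30]] = True
        mask = VolumeMask(grid=flat_mask.reshape((4, 4, 4), order="F"))
        hier = HierPartition(
            system_of=np.array([0, 0, 1, 1]),
            subsystem_of=np.array([0, 0, 1, 1]),
            q_top=0.2,
        )
        vol = communities_to_label_volume(hier, mask)
        flat = vol.grid.ravel(order="F")
        np.testing.assert_array_equal(flat[[2, 7, 9, 30]], [1, 1, 2, 2])
        assert (flat == 0).sum() == 60
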