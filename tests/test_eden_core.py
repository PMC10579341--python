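"""Unit and property tests for the lattice model and its two engines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from edensat.eden_core import (
    GROWTH,
    JUMP,
    LatticeState,
    SimParams,
    classify_populations,
    draw_waiting_time,
    empty_neighbor_count,
    growth_event,
    growth_probability,
    jump_event,
    run,
    run_naive_oracle,
    select_event,
    total_event_rate,
)

from conftest import cube_sites, make_state


class TestEmptyNeighborCount:
    def test_isolated_cell_has_six_empty_neighbors(self):
        state = make_state([(10, 10, 10)])
        assert empty_neighbor_count(state, (10, 10, 10)) == 6

    def test_enclosed_center_of_block_has_none(self):
        state = make_state(cube_sites((9, 9, 9), 3))
        assert empty_neighbor_count(state, (10, 10, 10)) == 0

    def test_cube_corner_cell_has_three(self):
        state = make_state(cube_sites((10, 10, 10), 2))
        assert empty_neighbor_count(state, (10, 10, 10)) == 3

    def test_lattice_wall_counts_as_blocked(self):
        state = make_state([(0, 0, 0)], L=5)
        assert empty_neighbor_count(state, (0, 0, 0)) == 3

    def test_site_outside_lattice_rejected(self):
        state = make_state([(1, 1, 1)], L=5)
        with pytest.raises(ValueError, match="outside"):
            empty_neighbor_count(state, (5, 0, 0))


class TestClassifyPopulations:
    def test_single_cell_is_jump_capable(self):
        part = classify_populations(make_state([(10, 10, 10)]))
        assert part.n1_cells == frozenset()
        assert part.n2_cells == frozenset({(10, 10, 10)})
        assert len(part.boundary_sites) == 6

    def test_two_cube_all_divide_only(self):
        part = classify_populations(make_state(cube_sites((10, 10, 10), 2)))
        assert part.n1 == 8 and part.n2 == 0

    def test_three_cube_partition_matches_enumeration(self):
        # brute-force enumeration of the 27 sites: the centre is enclosed,
        # the 6 face centres (1 empty), 12 edges (2) and 8 corners (3) are
        # all below the 4-empty-neighbour jump threshold
        part = classify_populations(make_state(cube_sites((9, 9, 9), 3)))
        assert part.n2 == 0
        assert part.n1 == 26
        assert (9 + 1, 9 + 1, 9 + 1) not in part.n1_cells

    def test_empty_lattice_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_populations(make_state([]))

    def test_threshold_three_reading_promotes_exposed_cells(self):
        # a cube corner has exactly 3 empty neighbours: N1 under the
        # default reading, N2 under the "three or more" reading
        state = make_state(cube_sites((10, 10, 10), 2))
        part3 = classify_populations(state, n2_min_empty=3)
        assert part3.n2 == 8 and part3.n1 == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(
            st.tuples(
                st.integers(0, 6), st.integers(0, 6), st.integers(0, 6)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_partition_agrees_with_per_site_recount(self, sites):
        """Independent recount: classify every site by empty_neighbor_count."""
        L = 7
        state = make_state(sites, L=L)
        part = classify_populations(state)
        boundary = set()
        weights = 0
        for s in sites:
            e = empty_neighbor_count(state, s)
            assert (s in part.n2_cells) == (e >= 4)
            assert (s in part.n1_cells) == (1 <= e <= 3)
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (s[0] + d[0], s[1] + d[1], s[2] + d[2])
                if all(0 <= c < L for c in nb) and nb not in sites:
                    boundary.add(nb)
                    weights += 1
        assert set(map(tuple, part.boundary_sites.tolist())) == boundary
        part_m = classify_populations(state, boundary_variant="multiplicity")
        assert len(part_m.boundary_sites) == weights


class TestRatesAndSelection:
    def test_total_rate_formula(self):
        params = SimParams(k=1.0, k_s=0.05, sigma=1.0, L=21)
        part = classify_populations(make_state(cube_sites((5, 5, 5), 2)))
        # 8 N1 cells, 0 N2
        assert total_event_rate(part, params) == pytest.approx(8.0)
        single = classify_populations(make_state([(10, 10, 10)]))
        assert total_event_rate(
            single, SimParams(k=1.0, k_s=0.2, sigma=1.0, L=21)
        ) == pytest.approx(1.2)

    def test_growth_probability_matches_rate_share(self):
        params = SimParams(k=1.0, k_s=0.05, sigma=1.0)
        assert growth_probability(3, 2, params) == pytest.approx(5.0 / 5.1)
        assert growth_probability(5, 0, SimParams(k_s=0.0)) == 1.0
        assert growth_probability(0, 1, SimParams(k=1.0, k_s=1.0, sigma=1.0)) == 0.5

    def test_waiting_time_closed_form(self):
        class FakeRng:
            def __init__(self, r):
                self.r = r

            def random(self):
                return self.r

        assert draw_waiting_time(1.0, FakeRng(math.exp(-1))) == pytest.approx(1.0)
        assert draw_waiting_time(4.0, FakeRng(math.exp(-2))) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            draw_waiting_time(0.0, FakeRng(0.5))

    def test_waiting_time_mean_matches_rate(self, rng):
        taus = np.array([draw_waiting_time(2.0, rng) for _ in range(100_000)])
        se = 0.5 / math.sqrt(len(taus))
        assert abs(taus.mean() - 0.5) < 3 * se

    def test_event_selection_frequency_matches_rate_share(self, rng):
        # 3 N1-like + 2 N2-like cells, k_s = 0.05: growth share 5/5.1
        params = SimParams(k=1.0, k_s=0.05, sigma=1.0)
        p = growth_probability(3, 2, params)
        n = 100_000
        draws = rng.random(n)
        frac = np.mean(draws <= p)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_pure_eden_always_grows(self, rng):
        params = SimParams(k_s=0.0)
        part = classify_populations(make_state([(10, 10, 10)], L=21))
        assert all(select_event(part, params, rng) == "growth" for _ in range(100))


class TestGrowthEvent:
    def test_second_cell_lands_face_adjacent(self, rng):
        state = make_state([(10, 10, 10)])
        part = classify_populations(state)
        rec = growth_event(state, part, rng)
        assert state.n_cells == 2
        assert sum(abs(a - b) for a, b in zip(rec.site_to, (10, 10, 10))) == 1

    def test_domino_boundary_uniform(self, rng):
        """Third cell lands uniformly on the 10 distinct empty neighbours."""
        base = [(10, 10, 10), (10, 10, 11)]
        part = classify_populations(make_state(base))
        assert len(part.boundary_sites) == 10
        counts = {}
        n = 10_000
        for _ in range(n):
            state = make_state(base)
            rec = growth_event(state, part, rng)
            counts[rec.site_to] = counts.get(rec.site_to, 0) + 1
        assert set(counts) == set(map(tuple, part.boundary_sites.tolist()))
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01

    def test_empty_boundary_rejected(self, rng):
        part = classify_populations(make_state([(10, 10, 10)]))
        empty = part.__class__(
            n1_cells=frozenset(),
            n2_cells=frozenset(),
            boundary_sites=np.empty((0, 3), dtype=np.int64),
        )
        state = make_state([(10, 10, 10)])
        with pytest.raises(ValueError, match="surface"):
            growth_event(state, empty, rng)


class TestJumpEvent:
    def test_jump_conserves_cell_count(self, rng):
        state = make_state([(10, 10, 10)], L=41)
        params = SimParams(k=1.0, k_s=0.1, sigma=3.0, L=41)
        rec = jump_event(state, (10, 10, 10), params, rng)
        assert rec.event_type == "jump"
        assert state.n_cells == 1
        assert (10, 10, 10) not in state.occupied
        assert rec.site_to in state.occupied

    def test_displacement_spread_matches_sigma(self, rng):
        """Accepted jumps have per-axis SD ~ sigma (rounding adds ~1/12)."""
        L, sigma = 201, 3.0
        params = SimParams(k=1.0, k_s=0.1, sigma=sigma, L=L)
        center = (100, 100, 100)
        disps = []
        state = make_state([center], L=L)
        for _ in range(30_000):
            rec = jump_event(state, center, params, rng)
            disps.append(np.array(rec.site_to) - np.array(rec.site_from))
            state.remove(rec.site_to)
            state.add(center)
        sd = np.array(disps, dtype=float).std(axis=0, ddof=1)
        assert np.all(np.abs(sd - sigma) < 0.1)

    def test_capped_redraws_abort_without_state_change(self, rng, caplog):
        # sigma far below one site: every draw rounds to the occupied origin
        state = make_state([(10, 10, 10)], L=21)
        params = SimParams(k=1.0, k_s=0.1, sigma=0.01, L=21, redraw_cap=50)
        with caplog.at_level("WARNING"):
            rec = jump_event(state, (10, 10, 10), params, rng)
        assert rec.event_type == "jump_aborted"
        assert state.occupied == {(10, 10, 10)}
        assert "abandoned" in caplog.text


class TestRun:
    def test_single_event_doubles_population(self):
        res = run(SimParams(k_s=0.0, L=21, max_events=1, seed=0))
        assert res.n_cells == 2

    def test_eden_run_counts_and_connectivity(self):
        res = run(SimParams(k_s=0.0, L=61, max_events=10_000, seed=5))
        assert res.n_cells == 10_001
        assert res.status == "completed"
        # growth only attaches to the surface: one face-connected cluster
        from scipy import ndimage

        from edensat.fixtures import lattice_to_stack

        stack = lattice_to_stack(res.state.sites_array)
        _, n = ndimage.label(stack.values)  # 6-connectivity structure
        assert n == 1

    def test_trajectory_invariants(self, small_jump_run):
        traj = small_jump_run.trajectory
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(np.diff(traj.populations) >= 0)
        growth_steps = np.diff(traj.populations, prepend=1)
        assert np.array_equal(growth_steps == 1, traj.event_types == GROWTH)
        assert np.all(growth_steps[traj.event_types == JUMP] == 0)

    def test_identical_seed_reproduces_bitwise(self):
        p = SimParams(k_s=0.05, sigma=4.0, L=61, max_events=2_000, seed=9)
        a, b = run(p), run(p)
        assert a.events.equals(b.events)
        assert np.array_equal(a.state.sites_array, b.state.sites_array)
        assert a.state.t == b.state.t

    def test_boundary_margin_truncates_cleanly(self):
        res = run(SimParams(k_s=0.0, L=13, max_events=5_000, seed=1))
        assert res.status == "truncated"
        assert res.n_cells == len(res.events) + 1
        sites = res.state.sites_array
        assert sites.min() >= 0 and sites.max() < 13

    def test_final_partition_matches_full_reclassification(self, small_jump_run):
        res = small_jump_run
        part = classify_populations(res.state, 4, "dedup")
        n1, n2, btot = res.final_partition_counts
        assert (part.n1, part.n2) == (n1, n2)
        assert len(part.boundary_sites) == btot

    def test_multiplicity_variant_partition_audit(self):
        res = run(
            SimParams(
                k_s=0.05, sigma=4.0, L=61, max_events=1_500, seed=3,
                boundary_variant="multiplicity",
            )
        )
        part = classify_populations(res.state, 4, "multiplicity")
        n1, n2, btot = res.final_partition_counts
        assert (part.n1, part.n2) == (n1, n2)
        assert len(part.boundary_sites) == btot


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_s": 0.0, "sigma": 0.0, "max_events": 500},
            {"k_s": 0.05, "sigma": 3.0, "max_events": 800},
            {"k_s": 0.1, "sigma": 5.0, "max_events": 600, "n2_min_empty": 3},
            {
                "k_s": 0.1,
                "sigma": 5.0,
                "max_events": 600,
                "boundary_variant": "multiplicity",
            },
        ],
        ids=["eden", "jumps", "threshold3", "multiplicity"],
    )
    def test_engines_agree_event_for_event(self, kwargs):
        p = SimParams(L=61, seed=42, **kwargs)
        fast = run(p)
        naive = run_naive_oracle(p)
        assert fast.events.equals(naive.events)
        assert np.array_equal(fast.state.sites_array, naive.state.sites_array)
        assert fast.status == naive.status

    def test_single_event_identical(self):
        p = SimParams(k_s=0.5, sigma=2.0, L=21, max_events=1, seed=7)
        fast, naive = run(p), run_naive_oracle(p)
        assert fast.events.equals(naive.events)


class TestParamsValidation:
    def test_all_violations_reported_together(self):
        with pytest.raises(ValueError) as err:
            SimParams(k=0.0, k_s=-1.0, L=2, max_events=0)
        msg = str(err.value)
        for frag in ("k must", "k_s must", "L must", "max_events"):
            assert frag in msg

    def test_jumps_require_positive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            SimParams(k_s=0.1, sigma=0.0)

    def test_default_margin_scales_with_sigma(self):
        assert SimParams(k_s=0.1, sigma=10.0).boundary_margin == 30
        assert SimParams(k_s=0.0, sigma=0.0).boundary_margin == 5
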