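"""The iteration engine: update buffers, time steps, dense and sparse
update rules, and the evolution loop."""

import numpy as np
import pytest

import levelkit as lk
from levelkit.adaptors import sparse_to_dense
from levelkit.domains import DomainPartition
from levelkit.errors import NumericalError
from levelkit.evolution import compute_updates
from levelkit.metrics import boundary_hausdorff, interior_mask_of, zero_level_radius
from levelkit.synthetic import disk_image


def propagation_system(single_system, shape=(41, 41), radius=8.0, weight=-1.0):
    center = tuple((s - 1) / 2 for s in shape)
    mask = lk.mask_from_seed(center, radius, shape)
    ls = lk.binary_to_dense(mask)
    return single_system(np.zeros(shape), ls, [lk.PropagationTerm(1.0, weight=weight)]), ls


class TestComputeUpdates:
    def test_propagation_buffer_near_interface(self, single_system):
        system, ls = propagation_system(single_system, weight=1.0)
        buffers = compute_updates(system)
        band = np.abs(ls.values) < 2
        # the adaptor's phi is only pixel-accurate near the interface, so
        # the one-sided norm scatters around 1 there
        assert np.median(buffers[1][band]) == pytest.approx(1.0, abs=0.05)
        assert np.all(buffers[1][band] > 0.3) and np.all(buffers[1][band] < 1.5)

    def test_pixels_outside_regions_never_evaluated(self, recording_term):
        region = lk.GridRegion((4, 4), (8, 8))
        mask = lk.mask_from_seed((3.5, 3.5), 2.5, (8, 8))
        ls = lk.binary_to_dense(mask, region)
        c = lk.LevelSetContainer()
        c.add_level_set(1, ls)
        term = recording_term()
        tc = lk.TermContainer(1)
        tc.add_term(term)
        eq = lk.EquationContainer()
        eq.add_equation(1, tc)
        system = lk.LevelSetSystem(np.zeros((20, 20)), c, eq)
        compute_updates(system)
        assert term.visited and all(region.contains(idx) for idx in term.visited)
        assert len(term.visited) == 64

    def test_non_overlapping_level_sets_are_isolated(self, recording_term):
        image = np.zeros((30, 30))

        def assemble(ids_regions):
            c = lk.LevelSetContainer()
            eq = lk.EquationContainer()
            part = DomainPartition(lk.GridRegion((0, 0), (30, 30)))
            for ls_id, region in ids_regions:
                mask = lk.mask_from_seed((5, 5), 3, region.shape)
                c.add_level_set(ls_id, lk.binary_to_dense(mask, region))
                tc = lk.TermContainer(ls_id)
                tc.add_term(lk.PropagationTerm(1.0, weight=-1.0))
                eq.add_equation(ls_id, tc)
                part.add_region(ls_id, region)
            return lk.LevelSetSystem(image, c, eq, part)

        r1 = lk.GridRegion((0, 0), (12, 12))
        r2 = lk.GridRegion((16, 16), (12, 12))
        both = compute_updates(assemble([(1, r1), (2, r2)]))
        alone = compute_updates(assemble([(1, r1)]))
        assert np.array_equal(both[1], alone[1])

    def test_independent_of_subdomain_visitation_order(self, single_system):
        system, _ = propagation_system(single_system)
        reference = compute_updates(system)
        # reverse the subdomain iteration order
        dm = system.domain_map
        original = dm.iter_subdomains

        def reversed_iter():
            yield from reversed(list(original()))

        dm.iter_subdomains = reversed_iter
        permuted = compute_updates(system)
        assert np.array_equal(reference[1], permuted[1])


class TestTimeStep:
    def test_cfl_formula(self):
        buffers = {1: np.array([[2.0, -1.0]])}
        assert lk.compute_time_step(buffers) == pytest.approx(0.225, abs=1e-6)

    def test_zero_buffers_give_dt_max(self):
        assert lk.compute_time_step({1: np.zeros((3, 3))}) == 1.0

    def test_whitaker_never_skips_layers(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            buffers = {1: {(0, i): v for i, v in enumerate(rng.uniform(-9, 9, 12))}}
            dt = lk.compute_time_step(buffers, "whitaker")
            peak = max(abs(v) for v in buffers[1].values())
            assert dt * peak <= 0.5 + 1e-9

    def test_sign_driven_variants_ignore_dt(self):
        assert lk.compute_time_step({1: {(0, 0): 99.0}}, "shi") == 1.0
        assert lk.compute_time_step({1: {(0, 0): 99.0}}, "malcolm") == 1.0


class TestUpdateDense:
    def test_uniform_shift(self, circle_sdf):
        ls = circle_sdf()
        before = ls.values.copy()
        rms = lk.update_dense(ls, np.ones_like(before), 0.5)
        assert rms == pytest.approx(0.5)
        assert np.allclose(ls.values - before, 0.5)

    def test_zero_buffer(self, circle_sdf):
        ls = circle_sdf()
        assert lk.update_dense(ls, np.zeros_like(ls.values), 0.5) == 0.0

    def test_front_tracks_accumulated_time(self, single_system):
        x = np.arange(31.0)
        ls = lk.DenseLevelSet(lk.GridRegion((0, 0), (7, 31)), np.tile(x - 5.0, (7, 1)))
        system = single_system(np.zeros((7, 31)), ls, [lk.PropagationTerm(1.0, weight=-1.0)])
        engine = lk.LevelSetEvolution(system, lk.MaxIterations(10))
        history = engine.evolve()
        total_t = sum(s.dt for s in history)
        row = ls.values[3]
        i = int(np.where(np.diff(np.sign(row)))[0][0])
        crossing = i + row[i] / (row[i] - row[i + 1])
        assert crossing - 5.0 == pytest.approx(total_t, abs=0.1)

    def test_non_finite_updates_abort(self, single_system, recording_term):
        system, _ = propagation_system(single_system)
        tc = system.equations.get_equation(1)
        tc.add_term(recording_term(value=float("inf")))
        with pytest.raises(NumericalError):
            lk.LevelSetEvolution(system, lk.MaxIterations(2)).evolve()


class TestUpdateWhitaker:
    def test_zero_buffer_leaves_representation(self):
        ls = lk.binary_to_sparse(lk.mask_from_seed((10, 10), 5, (21, 21)), "whitaker")
        label_before = ls.label.copy()
        values_before = ls.values.copy()
        rms = lk.update_whitaker(ls, {}, 0.3)
        assert rms == 0.0
        assert np.array_equal(ls.label, label_before)
        assert np.array_equal(ls.values, values_before)

    def test_hand_traced_single_pixel_migration(self):
        ls = lk.binary_to_sparse(lk.mask_from_seed((10, 10), 5, (21, 21)), "whitaker")
        target = (5, 10)  # topmost zero-layer pixel
        assert ls.layer_of(target) == 0
        lk.update_whitaker(ls, {target: 0.6}, 1.0)
        ls.check_invariants()
        assert ls.layer_of(target) == 1
        # the inside neighbor surfaces into the zero layer
        assert ls.layer_of((6, 10)) == 0
        assert ls.value((6, 10)) == pytest.approx(-0.4)

    def test_growth_keeps_band_invariants(self, single_system):
        ls = lk.binary_to_sparse(lk.mask_from_seed((20, 20), 8, (41, 41)), "whitaker")
        system = single_system(np.zeros((41, 41)), ls, [lk.PropagationTerm(1.0, weight=-1.0)])
        lk.LevelSetEvolution(system, lk.MaxIterations(20)).evolve()
        ls.check_invariants()
        radius = zero_level_radius(sparse_to_dense(ls), (20, 20))
        assert radius > 10.0  # grew from 8

    def test_updates_notify_terms(self, single_system):
        ls = lk.binary_to_sparse(lk.mask_from_seed((10, 10), 5, (21, 21)), "whitaker")
        events = []
        lk.update_whitaker(
            ls, {idx: -0.3 for idx in ls.layers[0]}, 1.0,
            notify=lambda idx, old, new: events.append((idx, old, new)),
        )
        assert events and all(old != new for _, old, new in events)


class TestUpdateShiMalcolm:
    def test_zero_buffer_no_switches(self):
        for variant in ("shi", "malcolm"):
            ls = lk.binary_to_sparse(lk.mask_from_seed((10, 10), 5, (21, 21)), variant)
            fn = lk.update_shi if variant == "shi" else lk.update_malcolm
            switches, rms = fn(ls, {})
            assert switches == 0 and rms == 0.0

    def test_shi_interior_grows_monotonically(self, single_system):
        ls = lk.binary_to_sparse(lk.mask_from_seed((20, 20), 8, (41, 41)), "shi")
        system = single_system(np.zeros((41, 41)), ls, [lk.PropagationTerm(1.0, weight=-1.0)])
        counts = []
        engine = lk.LevelSetEvolution(system, lk.MaxIterations(8))
        engine.register_observer(lambda e: counts.append(int((ls.values < 0).sum())))
        engine.evolve()
        ls.check_invariants()
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_malcolm_layer_stays_thin_boundary(self, single_system):
        ls = lk.binary_to_sparse(lk.mask_from_seed((20, 20), 8, (41, 41)), "malcolm")
        system = single_system(np.zeros((41, 41)), ls, [lk.PropagationTerm(1.0, weight=-1.0)])
        lk.LevelSetEvolution(system, lk.MaxIterations(8)).evolve()
        ls.check_invariants()

    def test_cross_representation_consistency(self, single_system):
        """All four representations land within 2 px of each other after a
        short Chan-Vese flow toward a crisp disk."""
        image, _ = disk_image((48, 48), center=(24, 24), radius=10)
        masks = {}
        for rep in ("dense", "whitaker", "shi", "malcolm"):
            seed = lk.mask_from_seed((23, 25), 9, (48, 48))
            ls = (lk.binary_to_dense(seed) if rep == "dense"
                  else lk.binary_to_sparse(seed, rep))
            system = single_system(image, ls, lk.chan_vese_term_set(mu=0.5, level_set_id=1))
            lk.LevelSetEvolution(system, lk.MaxIterations(10)).evolve()
            masks[rep] = interior_mask_of(ls, (48, 48))
        import itertools

        for a, b in itertools.combinations(masks, 2):
            assert boundary_hausdorff(masks[a], masks[b]) <= 2.0


class TestEvolve:
    def test_history_length_matches_iteration_stop(self, single_system):
        system, _ = propagation_system(single_system)
        history = lk.LevelSetEvolution(system, lk.MaxIterations(5)).evolve()
        assert len(history) == 5
        assert [s.iteration for s in history] == [1, 2, 3, 4, 5]

    def test_bit_reproducible_histories(self, single_system):
        def run():
            system, _ = propagation_system(single_system)
            return lk.LevelSetEvolution(system, lk.MaxIterations(6)).evolve()

        a, b = run(), run()
        assert [(s.dt, s.rms_change) for s in a] == [(s.dt, s.rms_change) for s in b]

    def test_energy_tracked_only_for_pure_chan_vese(self, single_system):
        image, _ = disk_image((32, 32), center=(16, 16), radius=8)
        seed = lk.mask_from_seed((16, 16), 6, (32, 32))
        ls = lk.binary_to_dense(seed)
        system = single_system(image, ls, lk.chan_vese_term_set(level_set_id=1))
        history = lk.LevelSetEvolution(system, lk.MaxIterations(3)).evolve()
        assert all(s.total_energy is not None for s in history)
        assert history[-1].total_energy <= history[0].total_energy * 1.01

        ls2 = lk.binary_to_dense(seed)
        mixed = lk.chan_vese_term_set(level_set_id=1) + [lk.PropagationTerm(0.0)]
        system2 = single_system(image, ls2, mixed)
        history2 = lk.LevelSetEvolution(system2, lk.MaxIterations(2)).evolve()
        assert all(s.total_energy is None for s in history2)

    def test_hard_cap_flags_non_convergence(self, single_system):
        system, _ = propagation_system(single_system)
        engine = lk.LevelSetEvolution(system, lk.RmsChangeBelow(1e-12), hard_cap=4)
        history = engine.evolve()
        assert len(history) == 4 and engine.converged is False

    def test_dynamic_level_set_addition_rebuilds_domain_map(self, single_system):
        system, _ = propagation_system(single_system)
        labels_before = len(system.domain_map.table)
        region = lk.GridRegion((0, 0), (10, 10))
        ls2 = lk.binary_to_dense(lk.mask_from_seed((4, 4), 3, (10, 10)), region)
        tc = lk.TermContainer(2)
        tc.add_term(lk.PropagationTerm(1.0))
        system.add_level_set(2, ls2, tc, region)
        assert len(system.domain_map.table) > labels_before
        system.remove_level_set(2)
        assert len(system.domain_map.table) == labels_before
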