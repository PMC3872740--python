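"""Signed-distance reinitialization: Sussman relaxation, fast marching,
and the trigger policy."""

import numpy as np
import pytest

import levelkit as lk
from levelkit.errors import ConfigurationError, DegenerateInputError
from levelkit.metrics import zero_level_radius


def plane(shape=(11, 21), x0=5.0, scale=1.0):
    x = np.arange(shape[1], dtype=float)
    return lk.DenseLevelSet(
        lk.GridRegion((0, 0), shape), np.tile(scale * (x - x0), (shape[0], 1))
    )


def residual(ls):
    g = np.gradient(ls.values)
    return np.sqrt(g[0] ** 2 + g[1] ** 2) - 1.0


class TestPolicy:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            lk.ReinitPolicy(method="newton")
        with pytest.raises(ConfigurationError):
            lk.ReinitPolicy(every_k=0)
        with pytest.raises(ConfigurationError):
            lk.ReinitPolicy(dtau=0.7)


class TestSussman:
    def test_exact_signed_distance_is_fixed_point(self):
        ls = plane()
        out = lk.sussman_reinit(ls, inner_iterations=30)
        assert np.max(np.abs(out.values - ls.values)) < 1e-6

    def test_steepened_plane_restored(self):
        ls = plane(scale=3.0)
        out = lk.sussman_reinit(ls, inner_iterations=50)
        band = np.abs(out.values) < 3
        assert np.max(np.abs(residual(out)[band])) < 0.1
        # zero crossing still at x = 5 +- 0.5
        row = out.values[5]
        i = int(np.where(np.diff(np.sign(row)))[0][0])
        crossing = i + row[i] / (row[i] - row[i + 1])
        assert crossing == pytest.approx(5.0, abs=0.5)

    def test_odd_symmetry(self):
        ls = plane(scale=2.0)
        neg = lk.DenseLevelSet(ls.region, -ls.values)
        a = lk.sussman_reinit(ls, 30)
        b = lk.sussman_reinit(neg, 30)
        assert np.allclose(a.values, -b.values, atol=1e-12)

    def test_sign_preserved_away_from_interface(self, circle_sdf):
        ls = circle_sdf((41, 41), (20, 20), 10.0)
        steep = lk.DenseLevelSet(ls.region, 3.0 * ls.values)
        out = lk.sussman_reinit(steep, 50)
        far = np.abs(steep.values) > 1
        assert np.all(np.sign(out.values[far]) == np.sign(steep.values[far]))

    def test_unstable_dtau_rejected(self):
        with pytest.raises(ConfigurationError):
            lk.sussman_reinit(plane(), dtau=0.6)


class TestFastMarching:
    def test_plane_is_exact(self):
        ls = plane(scale=2.0)
        out = lk.fast_marching_reinit(ls)
        x = np.arange(21.0)
        assert np.max(np.abs(out.values - np.tile(x - 5.0, (11, 1)))) < 1e-9

    def test_disk_close_to_analytic(self):
        g = np.ogrid[0:31, 0:31]
        r = np.sqrt((g[0] - 15.0) ** 2 + (g[1] - 15.0) ** 2)
        ls = lk.DenseLevelSet(lk.GridRegion((0, 0), (31, 31)), 2.5 * (r - 6.0))
        out = lk.fast_marching_reinit(ls)
        assert np.max(np.abs(out.values - (r - 6.0))) < 1.0

    def test_signs_restored_from_input(self, circle_sdf):
        ls = circle_sdf((31, 31), (15, 15), 6.0)
        out = lk.fast_marching_reinit(ls)
        assert np.array_equal(np.sign(out.values), np.sign(ls.values))

    def test_no_sign_change_rejected(self):
        ls = lk.DenseLevelSet(lk.GridRegion((0, 0), (5, 5)), np.full((5, 5), 2.0))
        with pytest.raises(DegenerateInputError):
            lk.fast_marching_reinit(ls)


class TestInvariants:
    @pytest.mark.parametrize("method", [lk.sussman_reinit, lk.fast_marching_reinit])
    def test_zero_level_anchored(self, method, circle_sdf):
        ls = circle_sdf((41, 41), (20, 20), 8.0)
        steep = lk.DenseLevelSet(ls.region, 2.0 * ls.values)
        kwargs = {"inner_iterations": 60} if method is lk.sussman_reinit else {}
        out = method(steep, **kwargs)
        r_in = zero_level_radius(steep, (20, 20))
        r_out = zero_level_radius(out, (20, 20))
        assert abs(r_in - r_out) <= 0.5

    def test_eikonal_residual_in_band(self, circle_sdf):
        ls = circle_sdf((41, 41), (20, 20), 8.0)
        steep = lk.DenseLevelSet(ls.region, 3.0 * ls.values)
        out = lk.sussman_reinit(steep, inner_iterations=60)
        band = np.abs(out.values) < 5
        assert np.median(np.abs(residual(out)[band])) < 0.05

    @pytest.mark.parametrize("method", [lk.sussman_reinit, lk.fast_marching_reinit])
    def test_approximate_idempotence(self, method, circle_sdf):
        ls = circle_sdf((41, 41), (20, 20), 8.0)
        steep = lk.DenseLevelSet(ls.region, 2.0 * ls.values)
        kwargs = {"inner_iterations": 200} if method is lk.sussman_reinit else {}
        once = method(steep, **kwargs)
        twice = method(once, **kwargs)
        assert np.max(np.abs(twice.values - once.values)) < 1e-3


class TestApplyPolicy:
    def _system(self, single_system, circle_sdf):
        ls = circle_sdf((41, 41), (20, 20), 8.0)
        ls.values *= 3.0
        return single_system(np.zeros((41, 41)), ls, [lk.PropagationTerm(0.0)]), ls

    def test_none_leaves_phi_untouched(self, single_system, circle_sdf):
        system, ls = self._system(single_system, circle_sdf)
        before = ls.values.copy()
        state = lk.EvolutionState(iteration=5, dt=0.1, rms_change=0.0)
        lk.apply_policy(system, state, lk.ReinitPolicy(method="none"))
        assert np.array_equal(ls.values, before)

    def test_schedule_every_k(self, single_system, circle_sdf, monkeypatch):
        system, _ = self._system(single_system, circle_sdf)
        calls = []
        monkeypatch.setattr(
            "levelkit.reinit.sussman_reinit",
            lambda ls, *a, **k: calls.append(1) or ls.copy(),
        )
        policy = lk.ReinitPolicy(method="sussman", every_k=5)
        for it in range(1, 13):
            state = lk.EvolutionState(iteration=it, dt=0.1, rms_change=0.0)
            lk.apply_policy(system, state, policy)
        assert len(calls) == 2  # iterations 5 and 10

    def test_steepened_phi_restored_mid_run(self, single_system, circle_sdf):
        system, ls = self._system(single_system, circle_sdf)
        state = lk.EvolutionState(iteration=5, dt=0.1, rms_change=0.0)
        lk.apply_policy(
            system, state,
            lk.ReinitPolicy(method="sussman", every_k=5, inner_iterations=60),
        )
        band = np.abs(ls.values) < 3
        g = np.gradient(ls.values)
        gn = np.sqrt(g[0] ** 2 + g[1] ** 2)
        assert np.max(np.abs(gn[band] - 1)) < 0.1

    def test_sparse_level_sets_skipped(self, caplog):
        import logging

        mask = lk.mask_from_seed((10, 10), 5, (21, 21))
        ls = lk.binary_to_sparse(mask, "whitaker")
        c = lk.LevelSetContainer()
        c.add_level_set(1, ls)
        eq = lk.EquationContainer()
        tc = lk.TermContainer(1)
        tc.add_term(lk.PropagationTerm(0.0))
        eq.add_equation(1, tc)
        system = lk.LevelSetSystem(np.zeros((21, 21)), c, eq)
        before = ls.values.copy()
        with caplog.at_level(logging.INFO, logger="levelkit.reinit"):
            lk.apply_policy(
                system,
                lk.EvolutionState(iteration=5, dt=0.1, rms_change=0.0),
                lk.ReinitPolicy(method="sussman", every_k=5),
            )
        assert np.array_equal(ls.values, before)
        assert any("skipping" in r.message for r in caplog.records)
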