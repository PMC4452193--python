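"""The coupled-surface graph solver and the manual-correction hook."""

import numpy as np
import pytest

from octlayers import apply_manual_correction
from octlayers.classifier import BoundaryProbabilityMap
from octlayers.exceptions import InfeasibleConstraintsError, ManualCorrectionError
from octlayers.graph import (
    SurfaceConstraints,
    extract_surfaces,
    family_objective,
    solve_columns,
    solve_reference,
)


def random_instance(rng, k_surfaces=3):
    w = int(rng.integers(3, 7))
    d = int(rng.integers(8, 13))
    cost = np.log(rng.random((k_surfaces, w, d)) + 1e-9)
    cons = SurfaceConstraints(
        tuple(int(rng.integers(1, 3)) for _ in range(k_surfaces - 1)),
        tuple(int(rng.integers(4, 8)) for _ in range(k_surfaces - 1)),
        tuple(int(rng.integers(1, 3)) for _ in range(k_surfaces)),
    )
    return cost, cons


def random_feasible_family(rng, cost, cons):
    k, w, d = cost.shape
    lo = np.zeros(k, int)
    hi = np.full(k, d - 1, int)
    for i in range(1, k):
        lo[i] = lo[i - 1] + cons.min_sep[i - 1]
    for i in range(k - 2, -1, -1):
        hi[i] = hi[i + 1] - cons.min_sep[i]
    fam = np.zeros((k, w), int)
    for attempt in range(200):
        col = np.zeros(k, int)
        col[0] = rng.integers(lo[0], hi[0] + 1)
        ok = True
        for i in range(1, k):
            a = max(lo[i], col[i - 1] + cons.min_sep[i - 1])
            b = min(hi[i], col[i - 1] + cons.max_sep[i - 1])
            if a > b:
                ok = False
                break
            col[i] = rng.integers(a, b + 1)
        if ok:
            break
    fam[:, 0] = col
    for c in range(1, w):
        fam[:, c] = fam[:, c - 1]  # zero lateral change is always feasible
    return fam


class TestSolverExactness:
    def test_matches_enumeration_oracle_on_random_instances(self):
        """Min-cut solution == exhaustive DP optimum, 25 seeded instances."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            cost, cons = random_instance(rng)
            adj = [(c, c + 1) for c in range(cost.shape[1] - 1)]
            got = solve_columns(cost, cons, adj)
            ref = solve_reference(cost, cons)
            assert family_objective(cost, got) == pytest.approx(
                family_objective(cost, ref), abs=1e-6)
            np.testing.assert_array_equal(got, ref)

    def test_beats_random_feasible_families(self):
        rng = np.random.default_rng(7)
        cost, cons = random_instance(rng)
        adj = [(c, c + 1) for c in range(cost.shape[1] - 1)]
        best = family_objective(cost, solve_columns(cost, cons, adj))
        for _ in range(1000):
            fam = random_feasible_family(rng, cost, cons)
            assert family_objective(cost, fam) <= best + 1e-9

    def test_single_column_returns_argmax_when_separations_allow(self):
        rng = np.random.default_rng(3)
        cost = np.log(rng.random((3, 1, 30)) + 1e-9)
        # force well-separated argmaxes
        cost[0, 0, 5] = 1.0
        cost[1, 0, 15] = 1.0
        cost[2, 0, 25] = 1.0
        cons = SurfaceConstraints((1, 1), (29, 29), (2, 2, 2))
        got = solve_columns(cost, cons, [])
        np.testing.assert_array_equal(got[:, 0], [5, 15, 25])

    def test_output_satisfies_all_constraints(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            cost, cons = random_instance(rng)
            adj = [(c, c + 1) for c in range(cost.shape[1] - 1)]
            fam = solve_columns(cost, cons, adj)
            sep = np.diff(fam, axis=0)
            for i in range(fam.shape[0] - 1):
                assert sep[i].min() >= cons.min_sep[i]
                assert sep[i].max() <= cons.max_sep[i]
            for i in range(fam.shape[0]):
                assert np.abs(np.diff(fam[i])).max() <= cons.smoothness[i]

    def test_boosting_optimal_pixels_preserves_solution(self):
        """Extra probability mass on the optimum never dethrones it."""
        rng = np.random.default_rng(19)
        cost, cons = random_instance(rng)
        adj = [(c, c + 1) for c in range(cost.shape[1] - 1)]
        fam = solve_columns(cost, cons, adj)
        boosted = cost.copy()
        for k in range(fam.shape[0]):
            for c in range(fam.shape[1]):
                boosted[k, c, fam[k, c]] += 0.5
        fam2 = solve_columns(boosted, cons, adj)
        np.testing.assert_array_equal(fam2, fam)
        assert family_objective(boosted, fam2) >= family_objective(cost, fam)

    def test_infeasible_separations_raise(self):
        rng = np.random.default_rng(2)
        cost = np.log(rng.random((3, 4, 5)) + 1e-9)
        cons = SurfaceConstraints((3, 3), (4, 4), (1, 1, 1))  # needs depth >= 7
        with pytest.raises(InfeasibleConstraintsError):
            solve_columns(cost, cons, [(0, 1), (1, 2), (2, 3)])

    def test_full3d_adjacency_enforces_interbscan_smoothness(self):
        rng = np.random.default_rng(23)
        nb, nx, nz = 4, 6, 14
        cost = np.log(rng.random((3, nb * nx, nz)) + 1e-9)
        cons = SurfaceConstraints((1, 1), (8, 8), (2, 2, 2))
        adjacency = []
        for b in range(nb):
            for x in range(nx):
                c = b * nx + x
                if x + 1 < nx:
                    adjacency.append((c, c + 1))
                if b + 1 < nb:
                    adjacency.append((c, c + nx))
        fam = solve_columns(cost, cons, adjacency).reshape(3, nb, nx)
        for k in range(3):
            assert np.abs(np.diff(fam[k], axis=0)).max() <= 2
            assert np.abs(np.diff(fam[k], axis=1)).max() <= 2

    def test_extract_surfaces_full3d_on_nine_surface_map(self, profile):
        rng = np.random.default_rng(31)
        tiny = profile.with_overrides(n_ascans_per_bscan=5, n_bscans=3,
                                      n_depth=24, name="tiny9")
        p = rng.random((3, 5, 18, 10))
        p /= p.sum(axis=-1, keepdims=True)
        probs = BoundaryProbabilityMap(p, (3, 21))
        cons = SurfaceConstraints((1,) * 8, (16,) * 8, (2,) * 9)
        out = extract_surfaces(probs, cons, tiny, coupling="full3d")
        assert (np.diff(out.depths, axis=0) >= 1).all()
        assert out.depths.min() >= 3 and out.depths.max() <= 21


class TestManualCorrection:
    @pytest.fixture()
    def surfaces(self, clean_spec, profile):
        from octlayers import simulate_surfaces
        return simulate_surfaces(clean_spec, profile, seed=0)

    def test_empty_edit_list_is_identity(self, surfaces):
        out = apply_manual_correction(surfaces, [])
        np.testing.assert_array_equal(out.depths, surfaces.depths)

    def test_single_edit_is_local_to_one_surface(self, surfaces, profile):
        k, y, x = 3, 5, 40
        new_depth = surfaces.depths[k, y, x] + 3.0
        out = apply_manual_correction(surfaces, [(k, y, x, new_depth)],
                                      window=8)
        assert out.depths[k, y, x] == pytest.approx(new_depth)
        others = [j for j in range(9) if j != k]
        np.testing.assert_array_equal(out.depths[others],
                                      surfaces.depths[others])
        changed = np.abs(out.depths[k] - surfaces.depths[k]) > 1e-9
        ys, xs = np.nonzero(changed)
        assert set(ys) == {y}
        assert xs.min() >= x - 8 and xs.max() <= x + 8

    def test_ordering_breaking_edit_rejected(self, surfaces):
        k, y, x = 3, 5, 40
        below = surfaces.depths[k + 1, y, x] + 5.0
        with pytest.raises(ManualCorrectionError, match=r"\(3, 4\)"):
            apply_manual_correction(surfaces, [(k, y, x, below)])

    def test_out_of_grid_edit_rejected(self, surfaces, profile):
        with pytest.raises(ManualCorrectionError):
            apply_manual_correction(surfaces, [(0, 0, 0, profile.n_depth + 5)])
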