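"""String geometry, binless WHAM, PMF/barrier extraction, TS picking."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import logsumexp

from unbindkit.benchmarks import pocket_system
from unbindkit.engine import LangevinParams, simulate
from unbindkit.potentials import BiasTerm, CoordinateCV, DoubleWell, SingleWell
from unbindkit.string_fes import (
    PMFProfile,
    StringPath,
    WHAMResult,
    binless_wham,
    check_convergence,
    pick_ts_candidates_from_profile,
    pmf_and_barrier,
    refit_string,
    run_string,
    sample_windows,
    seed_string,
    string_umbrella_energies,
)


class TestSeedString:
    def test_straight_line_equal_spacing(self):
        t = np.linspace(0, 1, 500)[:, None]
        series = np.hstack([3 * t, -2 * t])  # straight line in 2 CVs
        path = seed_string(series, n_windows=10, smooth=1)
        gaps = np.linalg.norm(np.diff(path.nodes, axis=0), axis=1)
        assert np.allclose(gaps, gaps[0], rtol=1e-6)
        # nodes stay on the line cv2 = -2/3 cv1
        assert np.allclose(path.nodes[:, 1], -2 / 3 * path.nodes[:, 0], atol=1e-9)

    def test_two_windows_are_endpoints(self):
        series = np.column_stack([np.linspace(0, 5, 100)])
        path = seed_string(series, n_windows=2, smooth=1)
        assert np.allclose(path.nodes[:, 0], [0.0, 5.0])

    def test_noisy_arc_spacing_matches_arc_length_oracle(self, rng):
        t = np.linspace(0, np.pi, 2000)
        series = np.column_stack([np.cos(t), np.sin(t)])
        series += 0.002 * rng.standard_normal(series.shape)
        path = seed_string(series, n_windows=25)
        gaps = np.linalg.norm(np.diff(path.nodes, axis=0), axis=1)
        # chord gaps of an equal-arc sampling of a semicircle are constant
        assert gaps.std() / gaps.mean() < 0.05
        # total length ~ pi (the arc-length integral of the unit semicircle)
        assert gaps.sum() == pytest.approx(np.pi, rel=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            seed_string(np.ones((50, 2)), n_windows=5)


class TestRefitString:
    def _line_path(self, n=20):
        nodes = np.column_stack([np.linspace(0, 4, n), np.linspace(0, 2, n)])
        return StringPath(nodes=nodes)

    def test_straight_means_reproduce_line(self):
        path = self._line_path()
        refit = refit_string(path, path.nodes, order=8)
        assert np.allclose(refit.nodes, path.nodes, atol=1e-8)
        assert refit.iteration == path.iteration + 1

    def test_cubic_means_interpolated_exactly(self):
        # seed path straight in cv1, so its arc parameter equals t and the
        # window means are polynomial in the fit abscissa
        t = np.linspace(0, 1, 30)
        path = StringPath(nodes=np.column_stack([t, np.zeros_like(t)]))
        means = np.column_stack([t, t**3 - 0.5 * t])
        refit = refit_string(path, means, order=8)
        # refitted nodes must lie on the cubic curve cv2 = cv1^3 - cv1/2
        assert np.allclose(refit.nodes[:, 1],
                           refit.nodes[:, 0] ** 3 - 0.5 * refit.nodes[:, 0],
                           atol=1e-6)

    def test_matches_normal_equations_least_squares(self, rng):
        """Independent LS oracle: Vandermonde normal-equations solve."""
        n, order = 40, 8
        t = np.linspace(0, 1, n)
        means = np.column_stack([t + 0.05 * np.sin(6 * t),
                                 0.3 * np.sin(2 * np.pi * t)])
        path = StringPath(nodes=np.column_stack([t, np.zeros(n)]))
        arc = path.arc_parameter
        refit = refit_string(path, means, order=order, dense=4001)

        V = np.vander(arc, order + 1, increasing=True)
        coeffs = np.linalg.solve(V.T @ V, V.T @ means)
        t_dense = np.linspace(0, 1, 4001)
        oracle_curve = np.vander(t_dense, order + 1, increasing=True) @ coeffs
        # every refitted node must lie on the oracle curve
        d = np.min(
            np.linalg.norm(refit.nodes[:, None, :] - oracle_curve[None, :, :],
                           axis=-1), axis=1)
        assert d.max() < 1e-3

    def test_order_must_be_below_n_windows(self):
        path = self._line_path(n=8)
        with pytest.raises(ValueError, match="order"):
            refit_string(path, path.nodes, order=8)


class TestCheckConvergence:
    def _path(self, nodes):
        return StringPath(nodes=np.asarray(nodes, dtype=float))

    def test_identical_paths_converged_with_zero_change(self):
        nodes = np.column_stack([np.linspace(0, 10, 5), np.zeros(5)])
        ok, delta = check_convergence(self._path(nodes), self._path(nodes))
        assert ok and np.allclose(delta, 0.0)

    def test_small_absolute_move_converges_on_wide_range(self):
        nodes = np.column_stack([np.linspace(0, 10, 5)])
        moved = nodes.copy()
        moved[2, 0] += 0.2  # 2% of range and below 0.3 Å
        ok, delta = check_convergence(self._path(nodes), self._path(moved))
        assert ok and delta[0] == pytest.approx(0.2)

    def test_large_move_fails_both_rules(self):
        nodes = np.column_stack([np.linspace(0, 10, 5)])
        moved = nodes.copy()
        moved[2, 0] += 1.0  # 10% of range and above 0.3 Å
        ok, _ = check_convergence(self._path(nodes), self._path(moved))
        assert not ok


def _harmonic_bias_energies(centers, k, samples, kT=1.0):
    return 0.5 * k * (samples[None, :] - np.asarray(centers)[:, None]) ** 2


class TestBinlessWham:
    def test_single_unbiased_window_uniform_weights(self):
        samples = np.linspace(-1, 1, 50)
        u = np.zeros((1, 50))
        res = binless_wham(u, counts=[50], kT=1.0)
        assert np.allclose(res.weights, 1 / 50)
        assert res.window_free_energies[0] == 0.0

    def test_identical_windows_share_free_energy(self, rng):
        samples = rng.normal(size=200)
        u = _harmonic_bias_energies([0.0, 0.0], 2.0, samples)
        res = binless_wham(u, counts=[100, 100], kT=1.0)
        assert res.window_free_energies[1] == pytest.approx(0.0, abs=1e-9)

    def test_gauge_invariance_under_energy_shift(self, rng):
        samples = np.concatenate([rng.normal(-1, 0.5, 100),
                                  rng.normal(1, 0.5, 100)])
        u = _harmonic_bias_energies([-1.0, 1.0], 4.0, samples)
        a = binless_wham(u, counts=[100, 100], kT=1.0)
        b = binless_wham(u + 7.3, counts=[100, 100], kT=1.0)
        assert np.allclose(a.weights, b.weights, atol=1e-10)

    def test_two_window_gaussian_closed_form(self):
        """Quadrature samples: Delta f must equal (kT/2) ln(k1/k2) to 1e-3 kT."""
        kT, k1, k2 = 1.0, 4.0, 1.0
        grid = np.linspace(-8, 8, 4001)
        n1, n2 = 1.0, 1.0
        p1 = np.exp(-0.5 * k1 * grid**2 / kT)
        p2 = np.exp(-0.5 * k2 * grid**2 / kT)
        mult = n1 * p1 / p1.sum() + n2 * p2 / p2.sum()
        u = np.vstack([0.5 * k1 * grid**2, 0.5 * k2 * grid**2])
        res = binless_wham(u, counts=[1, 1], kT=kT, multiplicities=mult,
                           tol=1e-12)
        # f_i = -kT ln sqrt(2 pi kT / k_i), so f2 - f1 = (kT/2) ln(k2/k1)
        expected = kT / 2 * np.log(k2 / k1)
        assert res.window_free_energies[1] == pytest.approx(expected, abs=1e-3)

    def test_direct_likelihood_matches_self_consistent(self, rng):
        samples = np.concatenate([rng.normal(-1, 0.6, 150),
                                  rng.normal(0.5, 0.6, 150)])
        u = _harmonic_bias_energies([-1.0, 0.5], 3.0, samples)
        scf = binless_wham(u, counts=[150, 150], kT=1.0, method="scf")
        ml = binless_wham(u, counts=[150, 150], kT=1.0, method="ml")
        assert np.allclose(scf.window_free_energies, ml.window_free_energies,
                           atol=1e-6)

    def test_nonoverlapping_windows_raise_with_diagnostics(self):
        samples = np.concatenate([np.full(50, -50.0), np.full(50, 50.0)])
        u = _harmonic_bias_energies([-50.0, 50.0], 100.0, samples)
        with pytest.raises(RuntimeError, match="overlap"):
            binless_wham(u, counts=[50, 50], kT=1.0, max_iterations=200)


def _umbrella_pmf(potential, centers, k_umb, kT, n_steps, seed, n_bins=40,
                  step_size=0.002, n_replicas=6):
    """Umbrella-sample a 1D potential and reconstruct its PMF on a grid.

    All windows are propagated as one batch via the string sampler (a
    one-CV string whose nodes are the umbrella centres, replicated
    ``n_replicas`` times for independent samples that beat the stitching
    noise).  The small step keeps the Euler-Maruyama
    stationary-distribution bias (O(k dt)) below the tolerance.
    """
    centers = np.asarray(centers, dtype=float)
    tiled = np.tile(centers, n_replicas)
    path = StringPath(nodes=tiled[:, None], force_constant=k_umb)
    params = LangevinParams(step_size=step_size, kT=kT, n_steps=n_steps, seed=seed)
    ensembles = [e[:, 0] for e in sample_windows(potential, path, params,
                                                 equilibration_fraction=0.25,
                                                 subsample=20)]
    # replicated windows share a bias: pool their samples per centre
    pooled = [np.concatenate([ensembles[r * len(centers) + i]
                              for r in range(n_replicas)])
              for i in range(len(centers))]
    samples = np.concatenate(pooled)
    counts = [len(e) for e in pooled]
    u = _harmonic_bias_energies(centers, k_umb, samples, kT)
    res = binless_wham(u, counts, kT=kT)

    lo, hi = centers[0], centers[-1]
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[1:] + edges[:-1])
    idx = np.digitize(samples, edges) - 1
    inside = (idx >= 0) & (idx < n_bins)  # discard out-of-range tails
    mass = np.bincount(idx[inside], weights=res.weights[inside],
                       minlength=n_bins)
    good = mass > 1e-4
    fe = np.full(n_bins, np.nan)
    fe[good] = -kT * np.log(mass[good])
    return mids, fe, good


@pytest.mark.parametrize(
    "potential,x_max",
    [(SingleWell(stiffness=2.0), 2.0),
     (DoubleWell(barrier_height=3.0, half_width=1.0), 1.4)],
    ids=["harmonic", "double_well"],
)
def test_umbrella_sampling_reconstructs_analytic_pmf(potential, x_max):
    """Windows span the physically relevant range (both wells + crest for
    the double well); the reconstruction must match V(x) within 0.2 kT."""
    kT = 1.0
    centers = np.linspace(-x_max, x_max, 21)
    mids, fe, good = _umbrella_pmf(potential, centers, k_umb=20.0, kT=kT,
                                   n_steps=12000, seed=42)
    analytic = potential.energy(mids[good, None])
    # free energy along x includes the bin-width constant: compare shapes
    resid = (fe[good] - analytic) - np.mean(fe[good] - analytic)
    assert np.max(np.abs(resid)) < 0.2


class TestPmfAndBarrier:
    def test_flat_weights_flat_pmf_zero_barrier(self):
        n = 200
        wham = WHAMResult(window_free_energies=np.zeros(1),
                          weights=np.full(n, 1 / n), n_iterations=1,
                          converged=True, max_residual=0.0)
        arcs = np.linspace(0, 1, n)
        profile = pmf_and_barrier(wham, arcs, n_bins=10, kT=1.0)
        assert profile.barrier == pytest.approx(0.0, abs=0.15)
        assert profile.free_energy.min() == pytest.approx(0.0)

    def test_symmetric_double_well_minima_equal(self, rng):
        # weights from the exact Boltzmann density of a symmetric double well
        dw = DoubleWell(barrier_height=3.0)
        # domain ends below the crest energy, so the interior crest is the
        # profile's maximum
        x = np.linspace(-1.35, 1.35, 2001)
        w = np.exp(-dw.energy(x[:, None]))
        w /= w.sum()
        wham = WHAMResult(window_free_energies=np.zeros(1), weights=w,
                          n_iterations=1, converged=True, max_residual=0.0)
        arcs = (x - x[0]) / (x[-1] - x[0])
        profile = pmf_and_barrier(wham, arcs, n_bins=41, kT=1.0)
        fe = profile.free_energy
        left = np.nanmin(fe[: len(fe) // 2])
        right = np.nanmin(fe[len(fe) // 2 :])
        assert left == pytest.approx(right, abs=0.05)
        assert profile.barrier == pytest.approx(3.0, abs=0.3)


class TestPickTs:
    def test_single_sharp_peak_contiguous_block(self):
        fe = np.zeros(100)
        fe[40] = 5.0
        fe[38:43] += [1.0, 2.0, 0.0, 2.0, 1.0]  # symmetric shoulders
        assert list(pick_ts_candidates_from_profile(fe, n=5)) == [38, 39, 40, 41, 42]

    def test_flat_profile_lowest_indices(self):
        assert list(pick_ts_candidates_from_profile(np.zeros(50), n=5)) == [
            0, 1, 2, 3, 4]

    def test_two_equal_peaks_bound_side_wins(self):
        fe = np.zeros(60)
        fe[20] = fe[45] = 4.0
        chosen = pick_ts_candidates_from_profile(fe, n=3)
        # exhaustive scan oracle: the first global maximum is at 20
        assert int(np.argmax(fe)) == 20
        assert 20 in chosen and 45 not in chosen

    def test_n_larger_than_profile_rejected(self):
        with pytest.raises(ValueError):
            pick_ts_candidates_from_profile(np.zeros(4), n=5)


class TestStringOnPocket:
    def test_fixed_point_on_minimum_energy_path(self):
        """Seeded on the y=0 MEP, one iteration satisfies convergence."""
        fx = pocket_system("string")
        xs = np.linspace(fx.bound_x, fx.mep_x_range[1], 40)
        path = StringPath(nodes=np.column_stack([xs, np.zeros_like(xs)]))
        params = LangevinParams(step_size=0.005, kT=1.0, n_steps=2000)
        ensembles = sample_windows(fx.potential, path, params)
        means = np.array([e.mean(axis=0) for e in ensembles])
        new_path = refit_string(path, means)
        ok, delta = check_convergence(path, new_path)
        assert ok, f"per-CV changes {delta}"

    def test_off_path_string_converges_to_mep(self):
        fx = pocket_system("string")
        xs = np.linspace(fx.bound_x, fx.mep_x_range[1], 40)
        offset = 0.6 * np.sin(np.linspace(0, np.pi, 40))  # bowed off the MEP
        path = StringPath(nodes=np.column_stack([xs, offset]))
        params = LangevinParams(step_size=0.005, kT=1.0, n_steps=2000)
        final, history = run_string(fx.potential, path, params,
                                    max_iterations=25, seed=11)
        assert history[-1]["converged"]
        # MEP is y = 0: every node within 3 node-widths of it
        assert np.max(np.abs(final.nodes[:, 1])) < 3 * final.node_spacing


def test_string_wham_pipeline_recovers_pocket_barrier():
    """End-to-end: string sampling + WHAM PMF vs the known 1D profile."""
    fx = pocket_system("string")
    xs = np.linspace(fx.bound_x, fx.mep_x_range[1], 60)
    path = StringPath(nodes=np.column_stack([xs, np.zeros_like(xs)]))
    params = LangevinParams(step_size=0.005, kT=1.0, n_steps=3000)
    ensembles = sample_windows(fx.potential, path, params, subsample=3)
    path.ensembles = ensembles
    u, counts, samples = string_umbrella_energies(path, kT=1.0)
    res = binless_wham(u, counts, kT=1.0)
    from unbindkit.string_fes import project_onto_path

    arcs = project_onto_path(path, samples)
    profile = pmf_and_barrier(res, arcs, n_bins=30, kT=1.0)
    # the pocket's profile along y=0 overstates the free-energy barrier by
    # ignoring transverse entropy; the PMF barrier must be close to the
    # 1D energy barrier at this channel stiffness
    assert profile.barrier == pytest.approx(fx.barrier, abs=1.0)
    ts_arc = profile.arc[profile.ts_windows].mean()
    barrier_arc = (fx.barrier_x - fx.bound_x) / (fx.mep_x_range[1] - fx.bound_x)
    assert ts_arc == pytest.approx(barrier_arc, abs=0.15)
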