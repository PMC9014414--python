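import numpy as np
import pytest

from torves import (
    CVTrajectory,
    FESGrid,
    compute_weights,
    estimate_fes_2d,
    global_barrier,
    marginal_profile,
    minimax_path_barrier,
    read_fes,
    write_fes,
)
from torves.constants import beta as beta_of, kt

BETA = beta_of(300.0)


def _traj(n=1000, bias=None, phi=None, psi=None):
    rng = np.random.default_rng(0)
    phi = rng.uniform(-np.pi, np.pi, n) if phi is None else phi
    psi = rng.uniform(-np.pi, np.pi, n) if psi is None else psi
    bias = np.zeros(n) if bias is None else bias
    return CVTrajectory(np.arange(n, dtype=float), {"phi": phi, "psi": psi}, bias)


def _grid_from_values(values, beta=BETA):
    values = np.asarray(values, dtype=float)
    ni, nj = values.shape
    return FESGrid(
        np.linspace(-np.pi, np.pi, ni + 1),
        np.linspace(-np.pi, np.pi, nj + 1),
        values,
        np.ones((ni, nj), dtype=int),
        beta,
    )


class TestComputeWeights:
    def test_zero_bias_gives_unit_weights(self):
        ws = compute_weights(_traj(), burn_in_fraction=0.0)
        assert np.all(ws.weights == 1.0)

    def test_weight_ratio_follows_boltzmann_factor(self):
        bias = np.array([0.0, np.log(2.0) / BETA])
        ws = compute_weights(_traj(n=2, bias=bias), burn_in_fraction=0.0)
        np.testing.assert_allclose(ws.weights, [0.5, 1.0], atol=1e-12)

    def test_burn_in_fraction_masks_leading_rows(self):
        ws = compute_weights(_traj(n=1000), burn_in_fraction=0.02)
        assert ws.n_unmasked() == 980
        assert not ws.mask[:20].any()

    def test_invalid_burn_in_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(_traj(), burn_in_fraction=1.0)
        with pytest.raises(ValueError):
            compute_weights(_traj(), burn_in_fraction=-0.1)

    def test_max_scaled_weight_is_one_even_for_deep_bias(self):
        bias = np.linspace(0, 500.0, 100)  # e^{beta*500} would overflow naive scaling
        ws = compute_weights(_traj(n=100, bias=bias), burn_in_fraction=0.0)
        assert ws.weights.max() == 1.0
        assert np.all(ws.weights > 0)


class TestEstimateFES:
    def test_uniform_samples_give_flat_landscape(self):
        n = 1_000_000
        nbins = 50
        ws = compute_weights(_traj(n=n), burn_in_fraction=0.0)
        fes = estimate_fes_2d(ws, nbins=nbins)
        # multinomial noise: sd(F) ~ kT/sqrt(n_bin) per bin; the largest of
        # 2500 near-Gaussian deviations sits around 3.4 sigma
        sigma = kt(300.0) / np.sqrt(n / nbins**2)
        values = fes.values[fes.finite_mask()]
        assert np.abs(values - values.mean()).max() <= 4.2 * sigma
        assert np.nanmin(fes.values) == 0.0

    def test_boltzmann_samples_recover_the_potential(self):
        # exact Boltzmann draw on a fine grid of a broad two-well surface
        from torves import make_four_state_potential

        p = make_four_state_potential(
            centers=[(0, 0), (np.pi, 0), (0, np.pi), (np.pi, np.pi)],
            depths=(8.0, 6.0, 5.0, 4.0),
            concentrations=1.0,
        )
        g = 400
        x = (np.arange(g) + 0.5) / g * 2 * np.pi - np.pi
        pp, qq = np.meshgrid(x, x, indexing="ij")
        u = p.energy(pp, qq)
        prob = np.exp(-BETA * u).ravel()
        prob /= prob.sum()
        rng = np.random.default_rng(1)
        idx = rng.choice(prob.size, size=1_000_000, p=prob)
        cell = 2 * np.pi / g
        phi = pp.ravel()[idx] + rng.uniform(-cell / 2, cell / 2, idx.size)
        psi = qq.ravel()[idx] + rng.uniform(-cell / 2, cell / 2, idx.size)
        ws = compute_weights(_traj(n=idx.size, phi=phi, psi=psi), burn_in_fraction=0.0)
        fes = estimate_fes_2d(ws, nbins=50)
        xc = fes.centers_phi
        cp, cq = np.meshgrid(xc, xc, indexing="ij")
        truth = p.energy(cp, cq)
        truth -= truth.min()
        mask = fes.finite_mask() & (fes.counts >= 100)
        # per-bin residuals normalized by the multinomial sd kT/sqrt(count)
        # behave like standard normals (plus the global min-pinning shift)
        resid = fes.values[mask] - truth[mask]
        resid -= resid.mean()
        z = resid / (kt(300.0) / np.sqrt(fes.counts[mask]))
        assert np.sqrt(np.mean(z**2)) < 1.3
        assert np.abs(z).max() < 4.5
        assert np.sqrt(np.mean(resid**2)) < 0.5

    def test_minimum_is_pinned_to_zero_exactly(self):
        ws = compute_weights(_traj(n=5000), burn_in_fraction=0.1)
        fes = estimate_fes_2d(ws, nbins=20)
        assert np.nanmin(fes.values) == 0.0


class TestMarginalProfile:
    def test_separable_landscape_marginalizes_to_each_factor(self):
        nb = 40
        x = np.linspace(-np.pi, np.pi, nb + 1)
        c = 0.5 * (x[:-1] + x[1:])
        f = 3.0 * (1 + np.cos(c))
        g = 1.5 * (1 - np.sin(2 * c))
        fes = _grid_from_values(f[:, None] + g[None, :])
        _, prof_phi = marginal_profile(fes, axis=0)
        _, prof_psi = marginal_profile(fes, axis=1)
        np.testing.assert_allclose(prof_phi, f - f.min(), atol=1e-9)
        np.testing.assert_allclose(prof_psi, g - g.min(), atol=1e-9)

    def test_flat_landscape_gives_flat_profile(self):
        fes = _grid_from_values(np.zeros((10, 10)))
        _, prof = marginal_profile(fes, axis=0)
        np.testing.assert_allclose(prof, 0.0, atol=1e-12)

    def test_single_finite_column_reduces_to_that_column(self):
        values = np.full((6, 6), np.nan)
        col = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        values[:, 2] = col
        fes = _grid_from_values(values)
        _, prof = marginal_profile(fes, axis=0)
        np.testing.assert_allclose(prof, col - col.min(), atol=1e-12)

    def test_consistency_with_direct_1d_estimate(self):
        rng = np.random.default_rng(3)
        n = 20_000
        phi = rng.vonmises(0.5, 1.0, n)
        psi = rng.vonmises(-1.0, 0.5, n)
        bias = rng.uniform(0, 2, n)
        ws = compute_weights(_traj(n=n, phi=phi, psi=psi, bias=bias), burn_in_fraction=0.0)
        fes = estimate_fes_2d(ws, nbins=30)
        _, prof = marginal_profile(fes, axis=0)
        edges = np.linspace(-np.pi, np.pi, 31)
        hist, _ = np.histogram(phi, bins=edges, weights=ws.weights)
        direct = -np.log(hist / hist.sum()) / ws.beta
        direct -= direct.min()
        np.testing.assert_allclose(prof, direct, atol=1e-9)


class TestBarriers:
    def test_global_barrier_reference_cases(self):
        assert global_barrier(_grid_from_values(np.zeros((5, 5)))) == 0.0
        nb = 64
        x = np.linspace(-np.pi, np.pi, nb + 1)
        c = 0.5 * (x[:-1] + x[1:])
        values = 20.0 * (1 - np.cos(c))[:, None] + np.zeros((nb, nb))
        barrier = global_barrier(_grid_from_values(values))
        # amplitude-40 cosine; bin centers straddle the crest
        assert barrier == pytest.approx(40.0, abs=0.1)
        values[3, 4] = np.nan
        assert np.isfinite(global_barrier(_grid_from_values(values)))

    def test_start_equals_end_is_zero(self):
        fes = _grid_from_values(np.arange(16.0).reshape(4, 4))
        assert minimax_path_barrier(fes, (2, 2), (2, 2)) == 0.0

    @staticmethod
    def _barrier_by_level_sweep(values, start, end):
        from .conftest import barrier_by_level_sweep

        return barrier_by_level_sweep(values, start, end)

    def test_minimax_matches_brute_force_path_enumeration_small_grid(self):
        """On a tiny grid, every simple path can be enumerated directly."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 10, size=(3, 4))

        ni, nj = values.shape
        best = [np.inf]

        def dfs(node, visited, running_max, end):
            if node == end:
                best[0] = min(best[0], running_max)
                return
            i, j = node
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = ((i + di) % ni, (j + dj) % nj)
                if nb not in visited:
                    dfs(nb, visited | {nb}, max(running_max, values[nb]), end)

        start, end = (0, 0), (2, 3)
        dfs(start, {start}, values[start], end)
        expected = best[0] - values[start]
        fes = _grid_from_values(values)
        assert minimax_path_barrier(fes, start, end) == pytest.approx(expected, abs=1e-12)
        assert self._barrier_by_level_sweep(values, start, end) == pytest.approx(
            expected, abs=1e-12
        )

    def test_minimax_agrees_with_level_sweep_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            values = rng.uniform(0, 50, size=(12, 12))
            values[rng.uniform(size=(12, 12)) < 0.1] = np.nan
            finite = np.argwhere(np.isfinite(values))
            start, end = map(tuple, finite[rng.choice(len(finite), 2, replace=False)])
            fes = _grid_from_values(values)
            try:
                expected = self._barrier_by_level_sweep(values, start, end)
            except ValueError:
                with pytest.raises(ValueError):
                    minimax_path_barrier(fes, start, end)
                continue
            assert minimax_path_barrier(fes, start, end) == pytest.approx(expected, abs=1e-12)

    def test_path_crosses_the_periodic_seam_through_a_gap(self):
        values = np.zeros((8, 8))
        values[:, 4] = np.nan  # solid wall
        values[:, 0] = np.nan  # boundary column blocked ...
        values[3, 0] = 7.5  # ... except one elevated gap next to the seam
        fes = _grid_from_values(values)
        # (1,2) -> (1,6) cannot pass column 4; the only route runs through
        # (3,0) and the periodic adjacency (3,0)-(3,7), i.e. across the seam
        assert minimax_path_barrier(fes, (1, 2), (1, 6)) == pytest.approx(7.5)

    def test_saddle_symmetry_of_directed_barriers(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0, 30, size=(10, 10))
        fes = _grid_from_values(values)
        a, b = (0, 0), (7, 4)
        fwd = minimax_path_barrier(fes, a, b)
        rev = minimax_path_barrier(fes, b, a)
        assert fwd + values[a] == pytest.approx(rev + values[b], abs=1e-12)


def test_reweighting_consistency_under_known_bias():
    """Samples drawn from exp(-beta(U+V)) reweighted by e^{beta V}
    recover U as well as unbiased Boltzmann samples do."""
    from torves import BiasModel, make_four_state_potential
    from torves.basis import n_axis_functions

    p = make_four_state_potential(depths=(8.0, 6.0, 5.0, 4.0), concentrations=1.0)
    m = n_axis_functions(1)
    coeffs = np.zeros((m, m))
    coeffs[1, 0] = -3.0
    coeffs[0, 2] = 2.0
    bias = BiasModel(1, coeffs)
    g = 400
    x = (np.arange(g) + 0.5) / g * 2 * np.pi - np.pi
    pp, qq = np.meshgrid(x, x, indexing="ij")
    u = p.energy(pp, qq)
    v = bias.evaluate(pp, qq)
    prob = np.exp(-BETA * (u + v)).ravel()
    prob /= prob.sum()
    rng = np.random.default_rng(2)
    idx = rng.choice(prob.size, size=1_000_000, p=prob)
    phi = pp.ravel()[idx]
    psi = qq.ravel()[idx]
    traj = CVTrajectory(
        np.arange(idx.size, dtype=float), {"phi": phi, "psi": psi}, v.ravel()[idx]
    )
    ws = compute_weights(traj, burn_in_fraction=0.0)
    fes = estimate_fes_2d(ws, nbins=50)
    xc = fes.centers_phi
    cp, cq = np.meshgrid(xc, xc, indexing="ij")
    truth = p.energy(cp, cq)
    truth -= truth.min()
    mask = fes.finite_mask() & (fes.counts >= 200)
    assert np.sqrt(np.mean((fes.values[mask] - truth[mask]) ** 2)) < 0.5


def test_fes_file_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    values = rng.uniform(0, 20, size=(12, 12))
    values[2, 3] = np.nan
    values -= np.nanmin(values)
    fes = _grid_from_values(values)
    path = tmp_path / "fes.dat"
    write_fes(fes, path)
    back = read_fes(path)
    np.testing.assert_array_equal(back.values, values)
    assert back.beta == fes.beta
    np.testing.assert_allclose(back.edges_phi, fes.edges_phi)
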