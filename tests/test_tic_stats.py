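"""TIC computation, group statistics and z-value maps.

The standard-deviation statistic uses the population divisor n and the
z-map uses the (mean - sample)/sigma orientation; both are checked
against independent brute-force oracles.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromacube import (
    TICGrid, compute_tic, group_stats, z_map, diff_grid, tic_to_csv, tic_from_csv,
)

from conftest import make_dataset


def brute_force_group_stats(grids):
    """Two-pass elementwise mean / population-sd oracle (math.fsum based)."""
    shape = grids[0].shape
    n = len(grids)
    mu = np.empty(shape)
    sigma = np.empty(shape)
    for idx in np.ndindex(shape):
        xs = [g[idx] for g in grids]
        m = math.fsum(xs) / n
        mu[idx] = m
        sigma[idx] = math.sqrt(math.fsum((x - m) ** 2 for x in xs) / n)
    return mu, sigma


def grid(values, period=2.0):
    values = np.asarray(values, dtype=np.float64)
    r1, r2 = values.shape
    return TICGrid(period * np.arange(r1), (period / r2) * np.arange(r2), values)


class TestComputeTic:
    def test_single_cell_sum(self):
        from chromacube import MSDataset
        ds = MSDataset("s", [0.0], [0.0], [50, 51, 52],
                       np.array([[[1.0, 2.0, 3.0]]]), 1.0)
        assert compute_tic(ds).values.tolist() == [[6.0]]

    def test_full_filter_equals_unfiltered(self, small_ds):
        full = compute_tic(small_ds, masses=small_ds.mass_axis.tolist())
        assert np.array_equal(full.values, compute_tic(small_ds).values)
        assert full.mass_filter == tuple(small_ds.mass_axis.tolist())

    def test_disjoint_filters_are_additive(self, rng):
        ds = make_dataset(rng, (3, 4, 6))
        m = ds.mass_axis.tolist()
        m1, m2 = m[:2], m[2:]
        left = compute_tic(ds, m1).values + compute_tic(ds, m2).values
        assert np.allclose(left, compute_tic(ds, m).values, rtol=1e-12)

    def test_conserves_cube_total(self, rng):
        ds = make_dataset(rng, (5, 4, 8))
        assert compute_tic(ds).values.sum() == pytest.approx(
            ds.total_intensity(), rel=1e-9)

    def test_empty_and_unknown_filters_rejected(self, small_ds):
        with pytest.raises(ValueError):
            compute_tic(small_ds, masses=[])
        with pytest.raises(ValueError, match="999"):
            compute_tic(small_ds, masses=[999])


class TestGroupStats:
    def test_hand_case_two_values(self):
        st_ = group_stats([grid([[2.0]]), grid([[4.0]])], "g")
        assert st_.mu.values[0, 0] == 3.0
        assert st_.sigma.values[0, 0] == 1.0  # sqrt(((2-3)^2+(4-3)^2)/2)

    def test_identical_grids_have_zero_sigma(self, rng):
        g = grid(rng.random((3, 3)))
        st_ = group_stats([g] * 4, "g")
        assert np.array_equal(st_.mu.values, g.values)
        assert np.all(st_.sigma.values == 0)

    def test_matches_brute_force_oracle(self, rng):
        grids = [rng.random((4, 4)) * 100 for _ in range(5)]
        st_ = group_stats([grid(g) for g in grids], "g")
        mu, sigma = brute_force_group_stats(grids)
        assert np.allclose(st_.mu.values, mu, rtol=1e-10)
        assert np.allclose(st_.sigma.values, sigma, rtol=1e-10, atol=1e-12)

    def test_sample_divisor_switch(self, rng):
        grids = [rng.random((2, 2)) for _ in range(4)]
        pop = group_stats([grid(g) for g in grids], "g").sigma.values
        samp = group_stats([grid(g) for g in grids], "g", ddof=1).sigma.values
        assert np.allclose(samp, pop * math.sqrt(4 / 3), rtol=1e-12)

    def test_empty_group_and_axis_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            group_stats([], "g")
        with pytest.raises(ValueError, match="axes"):
            group_stats([grid(np.zeros((2, 2))), grid(np.zeros((3, 2)))], "g")

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(2, 6), st.integers(0, 2 ** 31 - 1))
    def test_property_matches_numpy_free_oracle(self, n, seed):
        r = np.random.default_rng(seed)
        grids = [r.normal(50, 10, (3, 3)) for _ in range(n)]
        st_ = group_stats([grid(g) for g in grids], "g")
        mu, sigma = brute_force_group_stats(grids)
        assert np.allclose(st_.mu.values, mu, rtol=1e-10)
        assert np.allclose(st_.sigma.values, sigma, rtol=1e-10, atol=1e-12)


class TestZMap:
    def test_hand_case_sign_convention(self):
        st_ = group_stats([grid([[2.0]]), grid([[4.0]])], "g")  # mu=3 sigma=1
        zm = z_map(st_, grid([[5.0]]))
        assert zm.values[0, 0] == pytest.approx(-2.0)  # (3-5)/1, sample above mean

    def test_group_mean_scores_exactly_zero(self, rng):
        grids = [grid(rng.random((4, 3)) * 10) for _ in range(5)]
        st_ = group_stats(grids, "g")
        assert np.all(z_map(st_, st_.mu).values == 0.0)

    def test_sigma_zero_uses_clip(self):
        st_ = group_stats([grid([[1.0]])], "g")  # n=1 -> sigma 0
        assert z_map(st_, grid([[0.0]]), z_clip=10).values[0, 0] == 10.0
        assert z_map(st_, grid([[1.0]])).values[0, 0] == 0.0
        assert z_map(st_, grid([[2.0]]), z_clip=7).values[0, 0] == -7.0

    def test_invalid_clip_rejected(self):
        st_ = group_stats([grid([[1.0]])], "g")
        with pytest.raises(ValueError):
            z_map(st_, grid([[1.0]]), z_clip=0.0)

    def test_tail_fraction_calibrated_on_gaussian_noise(self):
        # For per-cell normal noise the empirical |z| > 2 rate should
        # approach the two-sided nominal tail (~4.55%) within binomial error.
        r = np.random.default_rng(7)
        n, cells = 40, (50, 50)
        grids = [grid(r.normal(100, 5, cells)) for _ in range(n)]
        st_ = group_stats(grids, "g")
        sample = grid(r.normal(100, 5, cells))
        z = z_map(st_, sample).values
        frac = np.mean(np.abs(z) > 2)
        p = 0.0455
        se = math.sqrt(p * (1 - p) / z.size)
        assert abs(frac - p) < 6 * se + 0.01


class TestDiffGrid:
    def test_identity_and_hand_case(self, rng):
        g = grid(rng.random((3, 3)))
        assert np.all(diff_grid(g, g).values == 0)
        assert diff_grid(grid([[5.0]]), grid([[2.0]])).values[0, 0] == 3.0

    def test_antisymmetry(self, rng):
        a, b = grid(rng.random((4, 4))), grid(rng.random((4, 4)))
        assert np.array_equal(diff_grid(a, b).values, -diff_grid(b, a).values)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="axes"):
            diff_grid(grid(np.zeros((2, 2))), grid(np.zeros((2, 3))))


def test_csv_round_trip(rng, tmp_path):
    g = grid(rng.random((4, 3)) * 1e6)
    p = tmp_path / "t.csv"
    tic_to_csv(g, p)
    back = tic_from_csv(p)
    assert np.array_equal(back.values, g.values)  # repr round-trips doubles
    assert np.array_equal(back.rt1_axis, g.rt1_axis)
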