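import numpy as np
import pytest

from cdsfcrf import (
    CRFConfig,
    acquire,
    forward_transform,
    inverse_transform,
    radial_mask,
    SamplingMask,
    KSpaceData,
    sample_cliques,
    pairwise_feature,
    unary_energy,
    pairwise_energy,
    total_energy,
    energy_gradient,
)
from cdsfcrf.crf_model import CliqueSet


def _random_instance(seed, h=8, w=8, lambda_p=1.0):
    """A random small problem: mask, k-data, cliques, and a complex estimate
    with magnitudes bounded away from zero (the magnitude chain rule is
    non-differentiable at the origin)."""
    rng = np.random.default_rng(seed)
    mask = radial_mask(h, w, int(rng.integers(1, 6)))
    kdata = acquire(rng.normal(size=(h, w)), mask)
    cfg = CRFConfig(
        lambda_u=rng.uniform(0.2, 2.0),
        lambda_p=lambda_p if lambda_p is not None else rng.uniform(0.2, 2.0),
        sigma=rng.uniform(0.1, 0.5),
        clique_gamma=2.0,
        clique_rho=0.7,
        max_radius=3,
        seed=seed,
    )
    guide = np.abs(inverse_transform(kdata.coeffs))
    cliques = sample_cliques(h, w, guide, cfg)
    Y = rng.uniform(0.5, 1.5, size=(h, w)) * np.exp(1j * rng.uniform(0, 2 * np.pi, size=(h, w)))
    return Y, kdata, guide, cliques, cfg


def finite_difference_gradient(Y, kdata, guide, cliques, cfg, eps=1e-5):
    """Central-difference oracle over real and imaginary perturbations."""
    fd = np.zeros_like(Y, dtype=complex)
    for idx in np.ndindex(Y.shape):
        for unit in (1.0, 1j):
            Yp, Ym = Y.copy(), Y.copy()
            Yp[idx] += eps * unit
            Ym[idx] -= eps * unit
            d = (
                total_energy(Yp, kdata, guide, cliques, cfg)
                - total_energy(Ym, kdata, guide, cliques, cfg)
            ) / (2 * eps)
            fd[idx] += d if unit == 1.0 else 1j * d
    return fd


class TestCRFConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CRFConfig(lambda_u=0.0, lambda_p=0.0)
        with pytest.raises(ValueError):
            CRFConfig(sigma=0.0)
        with pytest.raises(ValueError):
            CRFConfig(clique_rho=0.0)
        with pytest.raises(ValueError):
            CRFConfig(clique_rho=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = CRFConfig(lambda_p=0.3, sigma=0.2, seed=9)
        cfg.to_yaml(tmp_path / "crf.yaml")
        assert CRFConfig.from_yaml(tmp_path / "crf.yaml") == cfg


class TestCliqueSet:
    def test_canonicalizes_and_deduplicates(self):
        cs = CliqueSet([3, 0, 0], [0, 3, 1], shape=(2, 2))
        assert cs.as_pair_set() == {(0, 3), (0, 1)}

    def test_rejects_self_pairs_and_out_of_range(self):
        with pytest.raises(ValueError):
            CliqueSet([1], [1], shape=(2, 2))
        with pytest.raises(ValueError):
            CliqueSet([0], [4], shape=(2, 2))

    def test_csv_export(self, tmp_path):
        cs = CliqueSet([0, 1], [2, 3], shape=(2, 2))
        cs.to_csv(tmp_path / "edges.csv")
        data = np.loadtxt(tmp_path / "edges.csv", delimiter=",", skiprows=1, dtype=int)
        assert data.tolist() == [[0, 2], [1, 3]]


class TestSampleCliques:
    def test_vanishing_rho_leaves_exactly_the_4_neighborhood(self):
        cfg = CRFConfig(clique_rho=1e-12, sigma=0.1, clique_gamma=1.0, max_radius=3, seed=0)
        cs = sample_cliques(4, 4, np.zeros((4, 4)), cfg)
        expected = set()
        for y in range(4):
            for x in range(4):
                if x + 1 < 4:
                    expected.add((y * 4 + x, y * 4 + x + 1))
                if y + 1 < 4:
                    expected.add((y * 4 + x, (y + 1) * 4 + x))
        assert cs.as_pair_set() == expected

    def test_all_inclusive_limit_is_fully_connected(self):
        cfg = CRFConfig(clique_rho=1.0, sigma=1e6, clique_gamma=1e6, max_radius=None, seed=0)
        cs = sample_cliques(4, 4, np.zeros((4, 4)), cfg)
        n = 16
        assert len(cs) == n * (n - 1) // 2

    def test_deterministic_for_fixed_seed(self, rng):
        guide = rng.random((8, 8))
        cfg = CRFConfig(seed=5, sigma=0.3, clique_rho=0.5, max_radius=4)
        a = sample_cliques(8, 8, guide, cfg)
        b = sample_cliques(8, 8, guide, cfg)
        assert a.as_pair_set() == b.as_pair_set()

    def test_pairs_are_valid_and_canonical(self, rng):
        guide = rng.random((8, 8))
        cs = sample_cliques(8, 8, guide, CRFConfig(seed=1, sigma=0.3, max_radius=4))
        assert np.all(cs.i < cs.j)
        assert cs.j.max() < 64

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sample_cliques(8, 8, np.zeros((4, 4)), CRFConfig())


class TestPairwiseFeature:
    def test_unit_value_when_either_difference_vanishes(self):
        assert pairwise_feature(0.5, 0.5, 0.1, 0.9, sigma=0.2) == 1.0
        assert pairwise_feature(0.1, 0.9, 0.5, 0.5, sigma=0.2) == 1.0

    def test_exp_minus_one_at_kernel_scale(self):
        # (y_i - y_j)^2 (x_i - x_j)^2 = 3 sigma^2
        sigma = 0.3
        dy = 0.7
        dx = np.sqrt(3 * sigma**2) / dy
        assert pairwise_feature(dy, 0.0, dx, 0.0, sigma) == pytest.approx(np.exp(-1))

    def test_symmetry_range_and_monotonicity(self, rng):
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        f = pairwise_feature(y, -y, x, -x, sigma=0.4)
        assert np.all((0 < f) & (f <= 1))
        np.testing.assert_allclose(
            pairwise_feature(y, -y, x, -x, 0.4), pairwise_feature(-y, y, -x, x, 0.4)
        )
        dys = np.linspace(0, 3, 20)
        vals = pairwise_feature(dys, 0.0, 1.0, 0.0, sigma=0.4)
        assert np.all(np.diff(vals) <= 0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            pairwise_feature(0.0, 1.0, 0.0, 1.0, sigma=0.0)


class TestEnergies:
    def test_unary_zero_for_consistent_estimate(self, rng):
        img = rng.normal(size=(8, 8))
        kdata = acquire(img, SamplingMask.full(8, 8))
        Y = inverse_transform(kdata.coeffs)
        assert unary_energy(Y, kdata, CRFConfig()) < 1e-20

    def test_unary_zero_for_empty_mask(self, rng):
        kdata = KSpaceData(np.zeros((8, 8), dtype=complex), SamplingMask(np.zeros((8, 8), bool)))
        assert unary_energy(rng.normal(size=(8, 8)), kdata, CRFConfig()) == 0.0

    def test_unary_matches_per_frequency_loop(self, rng):
        Y, kdata, _, _, cfg = _random_instance(3)
        expected = 0.0
        F = forward_transform(Y)
        for a in range(8):
            for b in range(8):
                if kdata.mask.grid[a, b]:
                    expected += cfg.lambda_u * abs(F[a, b] - kdata.coeffs[a, b]) ** 2
        assert unary_energy(Y, kdata, cfg) == pytest.approx(expected)

    def test_pairwise_zero_for_constant_estimate(self, rng):
        guide = rng.random((6, 6))
        cfg = CRFConfig(sigma=0.2, seed=0, max_radius=2)
        cliques = sample_cliques(6, 6, guide, cfg)
        assert pairwise_energy(np.full((6, 6), 0.4), guide, cliques, cfg) == 0.0

    def test_pairwise_zero_for_empty_clique_set(self, rng):
        cfg = CRFConfig(sigma=0.2)
        empty = CliqueSet(np.empty(0, int), np.empty(0, int), (6, 6))
        assert pairwise_energy(rng.random((6, 6)), rng.random((6, 6)), empty, cfg) == 0.0

    def test_pairwise_matches_brute_force_loop(self, rng):
        Y = rng.random((6, 6))
        guide = rng.random((6, 6))
        i = rng.integers(0, 36, size=20)
        j = rng.integers(0, 36, size=20)
        j[j == i] = (i[j == i] + 1) % 36
        cliques = CliqueSet(i, j, (6, 6))
        cfg = CRFConfig(lambda_p=1.7, sigma=0.25)
        expected = 0.0
        for a, b in cliques.as_pair_set():
            f = np.exp(
                -((Y.ravel()[a] - Y.ravel()[b]) ** 2)
                * ((guide.ravel()[a] - guide.ravel()[b]) ** 2)
                / (3 * cfg.sigma**2)
            )
            expected += cfg.lambda_p * (1 - f)
        assert pairwise_energy(Y, guide, cliques, cfg) == pytest.approx(expected)

    def test_total_is_sum_of_components(self):
        Y, kdata, guide, cliques, cfg = _random_instance(4)
        assert total_energy(Y, kdata, guide, cliques, cfg) == pytest.approx(
            unary_energy(Y, kdata, cfg) + pairwise_energy(Y, guide, cliques, cfg)
        )

    def test_invalid_clique_index_rejected(self, rng):
        with pytest.raises(ValueError):
            CliqueSet([0], [100], (6, 6))


class TestEnergyGradient:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_finite_differences(self, seed):
        Y, kdata, guide, cliques, cfg = _random_instance(seed, lambda_p=None)
        g = energy_gradient(Y, kdata, guide, cliques, cfg)
        fd = finite_difference_gradient(Y, kdata, guide, cliques, cfg)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-4

    def test_zero_at_quadratic_minimum(self, rng):
        img = rng.normal(size=(8, 8))
        kdata = acquire(img, SamplingMask.full(8, 8))
        cfg = CRFConfig(lambda_u=1.0, lambda_p=0.0)
        Y = inverse_transform(kdata.coeffs)
        empty = CliqueSet(np.empty(0, int), np.empty(0, int), (8, 8))
        g = energy_gradient(Y, kdata, np.abs(Y), empty, cfg)
        assert np.abs(g).max() < 1e-12

    def test_additive_in_weights(self):
        Y, kdata, guide, cliques, cfg = _random_instance(8)
        both = energy_gradient(Y, kdata, guide, cliques, cfg)
        unary_only = energy_gradient(
            Y, kdata, guide, cliques,
            CRFConfig(lambda_u=cfg.lambda_u, lambda_p=0.0, sigma=cfg.sigma, seed=cfg.seed),
        )
        pairwise_only = energy_gradient(
            Y, kdata, guide, cliques,
            CRFConfig(lambda_u=0.0, lambda_p=cfg.lambda_p, sigma=cfg.sigma, seed=cfg.seed),
        )
        np.testing.assert_allclose(both, unary_only + pairwise_only, rtol=1e-12)
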