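"""Orientation field, circular statistics, PCA, and box counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from histoquant.fibers import (
    alignment_statistic,
    box_count_dimension,
    fiber_feature_pca,
    fiber_metrics,
    orientation_field,
    rayleigh_test,
)
from histoquant.phantoms import PhantomSpec, make_fiber_phantom, make_fractal_phantom


def bessel_ratio(kappa: float) -> float:
    """Population mean resultant length of a von Mises sample."""
    return float(i1(kappa) / i0(kappa)) if kappa > 0 else 0.0


class TestOrientationField:
    def test_grating_orientation_recovered(self):
        """Sinusoidal grating at 30 degrees: retained angles concentrate there."""
        theta = np.deg2rad(30)
        y, x = np.mgrid[:128, :128].astype(float)
        # stripes along theta vary along the normal direction
        phase = (x * np.sin(theta) + y * np.cos(theta)) * (2 * np.pi / 8)
        img = np.sin(phase)
        f = orientation_field(img, sigma=2)
        ang = f.retained_angles(0.65)
        assert ang.size > 1000
        _, mean_ax = alignment_statistic(ang)
        assert np.rad2deg(mean_ax) == pytest.approx(30.0, abs=2.0)

    def test_constant_image_retains_nothing(self):
        f = orientation_field(np.full((64, 64), 0.5), sigma=2)
        assert f.retained_angles(0.65).size == 0
        assert np.all(f.coherence == 0)

    def test_phantom_modal_angle_matches_mu(self):
        mu = np.deg2rad(75)
        spec = PhantomSpec(
            kind="fiber_texture", width=256, height=256, seed=4,
            params={"n_fibers": 120, "kappa": 1e7, "mu": mu},
        )
        img, _ = make_fiber_phantom(spec)
        ang = orientation_field(img, 2).retained_angles(0.65)
        _, mean_ax = alignment_statistic(ang)
        assert np.rad2deg(mean_ax) == pytest.approx(75.0, abs=2.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            orientation_field(np.zeros((4, 4, 3)), 2)
        with pytest.raises(ValueError):
            orientation_field(np.zeros((8, 8)), 0.5)


class TestAlignmentStatistic:
    def test_identical_angles_give_unity(self):
        rbar, mean_ax = alignment_statistic(np.full(10, 0.7))
        assert rbar == pytest.approx(1.0)
        assert mean_ax == pytest.approx(0.7)

    def test_perpendicular_pair_cancels(self):
        """Axial 0 and 90 degrees double to antipodal points: R-bar = 0."""
        rbar, _ = alignment_statistic(np.array([0.0, np.pi / 2]))
        assert rbar == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_bessel_ratio(self):
        rng = np.random.default_rng(8)
        theta = np.mod(rng.vonmises(0.6, 2.0, 2000) / 2, np.pi)
        rbar, _ = alignment_statistic(theta)
        assert rbar == pytest.approx(bessel_ratio(2.0), abs=0.03)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        theta = np.mod(rng.vonmises(0.0, 1.0, 500) / 2, np.pi)
        r0, _ = alignment_statistic(theta)
        for shift in (0.3, 1.0, 2.5):
            r1, _ = alignment_statistic(np.mod(theta + shift, np.pi))
            assert r1 == pytest.approx(r0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            alignment_statistic(np.array([]))


class TestRayleigh:
    def test_identical_angles_z_equals_n(self):
        z, p = rayleigh_test(np.full(10, 1.0))
        assert z == pytest.approx(10.0)
        assert p < 1e-3

    def test_zero_resultant_gives_p_one(self):
        angles = np.array([0.0, np.pi / 2, 0.0, np.pi / 2])
        z, p = rayleigh_test(angles)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        theta = np.mod(rng.vonmises(0.0, 0.5, 100) / 2, np.pi)
        _, p0 = rayleigh_test(theta)
        _, p1 = rayleigh_test(np.mod(theta + 0.9, np.pi))
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_null_p_values_are_uniform(self):
        """Under uniform axial angles the Rayleigh p is ~ U(0,1) (KS check)."""
        rng = np.random.default_rng(11)
        pvals = [
            rayleigh_test(rng.uniform(0, np.pi, 1000))[1] for _ in range(200)
        ]
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            rayleigh_test(np.array([0.1, 0.2, 0.3]))


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = fiber_feature_pca(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_eigen_oracle_and_reconstruction(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = fiber_feature_pca(df)
        x = df.to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = np.corrcoef(z, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(
            res.explained_variance_ratio, ev / ev.sum(), atol=1e-10
        )
        # full-rank reconstruction of the standardized data
        assert np.abs(res.scores @ res.loadings.T - z).max() < 1e-8
        # eigenvalue sum equals feature count (trace of the correlation matrix)
        assert ev.sum() == pytest.approx(3.0)
        # scores are centered
        assert np.abs(res.scores.mean(0)).max() < 1e-12

    def test_zero_variance_feature_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "flat": [1.0, 1, 1]})
        with pytest.raises(ValueError, match="flat"):
            fiber_feature_pca(df)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fiber_feature_pca(pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]}))


class TestBoxCounting:
    def test_filled_square_dimension_two(self):
        mask, truth = make_fractal_phantom(
            PhantomSpec(kind="fractal", width=128, height=128, params={"pattern": "filled_square"})
        )
        d, r2, counts = box_count_dimension(mask, (2, 4, 8, 16, 32))
        assert d == pytest.approx(2.0, abs=0.05)
        assert r2 > 0.999

    def test_line_dimension_one(self):
        mask, _ = make_fractal_phantom(
            PhantomSpec(kind="fractal", width=128, height=128, params={"pattern": "line"})
        )
        d, _, _ = box_count_dimension(mask, (2, 4, 8, 16, 32))
        assert d == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_closed_form(self):
        mask, truth = make_fractal_phantom(
            PhantomSpec(kind="fractal", width=128, height=128, params={"pattern": "sierpinski_triangle", "depth": 7})
        )
        d, _, counts = box_count_dimension(mask, (2, 4, 8, 16, 32))
        assert truth.data["dimension"] == pytest.approx(np.log(3) / np.log(2))
        assert d == pytest.approx(np.log(3) / np.log(2), abs=0.03)
        # self-similar set: N(s) = 3^(depth - log2 s) exactly
        assert counts[2] == 3**6 and counts[4] == 3**5

    def test_counts_monotone_and_dimension_bounded(self):
        rng = np.random.default_rng(13)
        mask = rng.random((100, 100)) > 0.6
        d, _, counts = box_count_dimension(mask, (2, 4, 8, 16, 32))
        sizes = sorted(counts)
        assert all(counts[a] >= counts[b] for a, b in zip(sizes, sizes[1:]))
        assert 0.0 <= d <= 2.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            box_count_dimension(np.zeros((8, 8), bool), (1, 2, 4, 8))
        with pytest.raises(ValueError, match="box sizes"):
            box_count_dimension(np.ones((8, 8), bool), (2, 4, 8))


class TestEndToEnd:
    def test_alignment_monotone_in_kappa(self):
        """Higher concentration always reads out as higher alignment."""
        rbars = {}
        for kappa in (0.25, 1.0, 4.0):
            vals = []
            for seed in range(3):
                spec = PhantomSpec(
                    kind="fiber_texture", width=512, height=512, seed=20 + seed,
                    params={"n_fibers": 300, "length": 70, "kappa": kappa, "mu": 0.9},
                )
                img, _ = make_fiber_phantom(spec)
                vals.append(fiber_metrics(img).alignment)
            rbars[kappa] = np.mean(vals)
        assert rbars[4.0] > rbars[1.0] > rbars[0.25]

    def test_fiber_metrics_fields_consistent(self):
        spec = PhantomSpec(
            kind="fiber_texture", width=256, height=256, seed=30,
            params={"n_fibers": 150, "kappa": 2.0, "mu": 0.4},
        )
        img, _ = make_fiber_phantom(spec)
        m = fiber_metrics(img)
        assert 0.0 <= m.alignment <= 1.0
        assert 0.0 < m.rayleigh_p <= 1.0
        assert m.rayleigh_z == pytest.approx(m.n_angles * m.alignment**2, rel=1e-9)
        assert 0.0 <= m.fractal_dimension <= 2.0
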