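"""Phantom generators: determinism, ground-truth bookkeeping, placement."""

import numpy as np
import pytest
from skimage import measure

from histoquant.deconvolution import TRICHROME_STAIN_MATRIX, deconvolve, rgb_to_od
from histoquant.phantoms import (
    GroundTruth,
    PhantomSpec,
    PlacementError,
    make_clone_phantom,
    make_fiber_phantom,
    make_fractal_phantom,
    make_if_phantom,
    make_phantom,
    make_trichrome_phantom,
)


@pytest.mark.parametrize(
    "kind,params",
    [
        ("trichrome", {"uniform": (0.2, 0.4, 0.1)}),
        ("if_field", {"n_nuclei": 10}),
        ("clone_field", {"areas": [500, 2500]}),
        ("fiber_texture", {"n_fibers": 50, "kappa": 2.0}),
        ("fractal", {"pattern": "sierpinski_triangle", "depth": 6}),
    ],
)
def test_identical_spec_gives_bit_identical_output(kind, params):
    spec = PhantomSpec(kind=kind, width=128, height=128, seed=42, params=params)
    img1, t1 = make_phantom(spec)
    img2, t2 = make_phantom(spec)
    assert np.array_equal(img1, img2)
    assert t1.summary() == t2.summary()


def test_spec_validation():
    with pytest.raises(ValueError, match="kind"):
        PhantomSpec(kind="nope")
    with pytest.raises(ValueError, match=">= 32"):
        PhantomSpec(kind="fractal", width=16)


class TestTrichromePhantom:
    def test_zero_density_is_uniform_white(self):
        img, _ = make_trichrome_phantom(
            PhantomSpec(kind="trichrome", width=32, height=32)
        )
        assert np.allclose(img, 255.0)

    def test_unit_red_density_gives_matrix_row_od(self):
        img, _ = make_trichrome_phantom(
            PhantomSpec(kind="trichrome", width=32, height=32, params={"uniform": (1.0, 0.0, 0.0)})
        )
        od = rgb_to_od(img).od[0, 0]
        assert np.allclose(od, [0.7995107, 0.5914, 0.1053], atol=1e-9)

    def test_coverage_layout_truth_fraction_exact(self):
        spec = PhantomSpec(
            kind="trichrome", width=128, height=128, seed=3,
            params={"coverage": {"trichrome_blue": {"fraction": 0.3, "density": 1.0}}},
        )
        _, truth = make_trichrome_phantom(spec)
        assert truth.data["collagen_px"] == round(0.3 * 128 * 128)

    def test_round_trip_recovers_density_planes(self):
        spec = PhantomSpec(
            kind="trichrome", width=64, height=64, seed=5,
            params={"uniform": (0.3, 0.0, 0.2),
                    "coverage": {"trichrome_blue": {"fraction": 0.25, "density": 0.8}}},
        )
        img, truth = make_trichrome_phantom(spec)
        dm = deconvolve(rgb_to_od(img), TRICHROME_STAIN_MATRIX)
        assert np.abs(dm.densities - truth.data["density_planes"]).max() <= 1e-6

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            make_trichrome_phantom(
                PhantomSpec(kind="trichrome", params={"uniform": (-0.1, 0, 0)})
            )


class TestIfPhantom:
    def test_zero_nuclei_background_only(self):
        img, truth = make_if_phantom(
            PhantomSpec(kind="if_field", width=64, height=64,
                        params={"n_nuclei": 0, "noise_sigma": 0.0})
        )
        assert truth.data["nucleus_count"] == 0
        assert np.allclose(img[..., 2], 0.05)

    def test_disks_exceed_size_filter(self):
        _, truth = make_if_phantom(
            PhantomSpec(kind="if_field", seed=1,
                        params={"n_nuclei": 5, "nucleus_radius": (4, 4)})
        )
        # radius-4 disk has 49 px, comfortably above the 15-px filter
        assert truth.data["nucleus_area_px"] == 5 * 49

    def test_truth_counts_match_component_recount(self):
        img, truth = make_if_phantom(
            PhantomSpec(kind="if_field", seed=2, params={"n_nuclei": 20, "noise_sigma": 0.0})
        )
        labels = measure.label(img[..., 2] > 0.4, connectivity=2)
        assert labels.max() == truth.data["nucleus_count"]

    def test_unplaceable_request_errors_with_achieved_count(self):
        with pytest.raises(PlacementError) as ei:
            make_if_phantom(
                PhantomSpec(kind="if_field", width=32, height=32,
                            params={"n_nuclei": 200, "nucleus_radius": (5, 5)})
            )
        assert ei.value.achieved < ei.value.requested


class TestClonePhantom:
    def test_empty_area_list_blank(self):
        img, truth = make_clone_phantom(
            PhantomSpec(kind="clone_field", params={"areas": [], "noise_sigma": 0.0})
        )
        assert truth.data["areas"] == []
        assert np.allclose(img, 0.02)

    def test_realized_areas_exact_and_components_disjoint(self):
        areas = [2500, 1500, 100]
        img, truth = make_clone_phantom(
            PhantomSpec(kind="clone_field", width=256, height=256, seed=7,
                        params={"areas": areas, "noise_sigma": 0.0})
        )
        assert sorted(truth.data["areas"]) == sorted(areas)
        labels = measure.label(img[..., 1] > 0.3, connectivity=2)
        assert labels.max() == len(areas)
        got = sorted(np.bincount(labels.ravel())[1:].tolist())
        assert got == sorted(areas)

    def test_truth_split_at_2000(self):
        _, truth = make_clone_phantom(
            PhantomSpec(kind="clone_field", width=512, height=512, seed=8,
                        params={"areas": [100] * 20})
        )
        assert truth.data["n_clones"] == 0
        assert truth.data["n_singletons"] == 20

    def test_multichannel_areas(self):
        img, truth = make_clone_phantom(
            PhantomSpec(kind="clone_field", width=256, height=256, seed=9,
                        params={"areas": {"red": [2100], "green": [300, 400]},
                                "noise_sigma": 0.0})
        )
        assert truth.data["areas_by_channel"] == {"red": [2100], "green": [300, 400]}
        assert int((img[..., 0] > 0.3).sum()) == 2100


class TestFiberPhantom:
    def test_degenerate_kappa_pins_all_angles(self):
        _, truth = make_fiber_phantom(
            PhantomSpec(kind="fiber_texture", seed=1,
                        params={"n_fibers": 50, "kappa": 1e7, "mu": 0.9})
        )
        assert np.allclose(truth.data["angles"], 0.9)

    def test_uniform_limit_spans_half_circle(self):
        _, truth = make_fiber_phantom(
            PhantomSpec(kind="fiber_texture", seed=2,
                        params={"n_fibers": 2000, "kappa": 0.0})
        )
        ang = truth.data["angles"]
        assert ang.min() >= 0 and ang.max() < np.pi
        # resultant of doubled angles vanishes under uniformity
        assert np.abs(np.exp(2j * ang).mean()) < 0.06

    def test_sample_resultant_matches_bessel_ratio(self):
        from scipy.special import i0, i1

        _, truth = make_fiber_phantom(
            PhantomSpec(kind="fiber_texture", seed=3,
                        params={"n_fibers": 500, "kappa": 2.0})
        )
        rbar = np.abs(np.exp(2j * truth.data["angles"]).mean())
        assert rbar == pytest.approx(i1(2) / i0(2), abs=0.05)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            make_fiber_phantom(
                PhantomSpec(kind="fiber_texture", params={"kappa": -1.0})
            )


class TestFractalPhantom:
    def test_analytic_dimensions(self):
        for pattern, dim in (
            ("filled_square", 2.0),
            ("line", 1.0),
            ("sierpinski_triangle", np.log(3) / np.log(2)),
        ):
            _, truth = make_fractal_phantom(
                PhantomSpec(kind="fractal", width=128, height=128,
                            params={"pattern": pattern, "depth": 7})
            )
            assert truth.data["dimension"] == pytest.approx(dim)

    def test_depth_exceeding_canvas_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            make_fractal_phantom(
                PhantomSpec(kind="fractal", width=64, height=64,
                            params={"pattern": "sierpinski_triangle", "depth": 8})
            )


def test_ground_truth_json_roundtrip(tmp_path):
    _, truth = make_clone_phantom(
        PhantomSpec(kind="clone_field", seed=1, params={"areas": [2500, 100]})
    )
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded["kind"] == "clone_field"
    assert loaded["units"] == "pixels"
    assert loaded["n_clones"] == 1
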