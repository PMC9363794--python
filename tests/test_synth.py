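"""Synthetic fundus generator: geometry, rasterization, and determinism."""

import math

import numpy as np
import pytest

from dfa_meter.dfa import compute_dfa
from dfa_meter.geometry import extract_centers
from dfa_meter.synth import (
    GeneratorConfig,
    PlacementError,
    SceneParams,
    default_macula_radius,
    make_dataset,
    make_scene,
    render_image,
    render_labels,
    sample_scenes,
)


class TestMakeScene:
    def test_zero_angle_is_horizontal(self):
        scene = make_scene(2584, 1985, dfa=0.0, disc_fovea_distance=800, seed=1)
        assert scene.fovea_center[1] == scene.disc_center[1]
        assert scene.fovea_center[0] == scene.disc_center[0] + 800

    @pytest.mark.parametrize("dfa,dist,seed", [(3.0, 700, 2), (-12.5, 820, 3), (0.4, 760, 4)])
    def test_distance_constraint(self, dfa, dist, seed):
        scene = make_scene(2584, 1985, dfa=dfa, disc_fovea_distance=dist, seed=seed)
        d = math.hypot(
            scene.fovea_center[0] - scene.disc_center[0],
            scene.fovea_center[1] - scene.disc_center[1],
        )
        assert abs(d - dist) <= 1.0

    def test_requested_angle_realized_within_rounding(self):
        scene = make_scene(512, 512, dfa=-7.13, disc_fovea_distance=200, seed=7)
        realized = compute_dfa(scene.disc_center, scene.fovea_center).angle
        assert realized == scene.true_dfa
        assert abs(realized - (-7.13)) <= 0.3

    def test_macula_radius_scales_with_width(self):
        assert default_macula_radius(2584) == 400.0
        scene = make_scene(512, 512, dfa=0, disc_fovea_distance=160, seed=0)
        assert scene.macula_label_radius == pytest.approx(400 * 512 / 2584)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            make_scene(128, 128, dfa=0.0, disc_fovea_distance=1000, seed=0)

    def test_mirror_places_fovea_nasally(self):
        scene = make_scene(512, 512, dfa=5.0, disc_fovea_distance=160, seed=2, mirror=True)
        assert scene.fovea_center[0] < scene.disc_center[0]


@pytest.fixture(scope="module")
def clean_scene():
    return make_scene(
        256, 256, dfa=4.0, disc_fovea_distance=80, seed=11,
        n_vessels=0, noise_sigma=0.0,
    )


class TestRenderImage:

    def test_disc_brighter_than_surrounding_ring(self, clean_scene):
        img = render_image(clean_scene).astype(float).mean(axis=2)
        yy, xx = np.mgrid[0:256, 0:256]
        ox, oy = clean_scene.disc_center
        rx, ry = clean_scene.disc_radii
        e = ((xx - ox) / rx) ** 2 + ((yy - oy) / ry) ** 2
        assert img[e <= 1].mean() > img[(e > 2) & (e < 6)].mean()

    def test_fovea_darker_than_background(self, clean_scene):
        img = render_image(clean_scene).astype(float).mean(axis=2)
        yy, xx = np.mgrid[0:256, 0:256]
        mx, my = clean_scene.fovea_center
        fov = (xx - mx) ** 2 + (yy - my) ** 2 <= 50**2
        ox, oy = clean_scene.disc_center
        rx, ry = clean_scene.disc_radii
        disc = ((xx - ox) / rx) ** 2 + ((yy - oy) / ry) ** 2 <= 4
        background = ~fov & ~disc
        assert img[fov].mean() < img[background].mean()

    def test_bit_identical_re_render(self, desk_scenes):
        scene = desk_scenes[0]
        assert np.array_equal(render_image(scene), render_image(scene))


class TestRenderLabels:
    def test_native_macula_radius_is_exactly_400(self):
        scene = make_scene(2584, 1985, dfa=5.0, disc_fovea_distance=800, seed=3)
        mask = render_labels(scene)
        ys, xs = np.nonzero(mask == 2)
        d = np.hypot(xs - scene.fovea_center[0], ys - scene.fovea_center[1])
        assert d.max() == 400.0

    def test_macula_area_close_to_analytic(self):
        scene = make_scene(2584, 1985, dfa=-2.0, disc_fovea_distance=780, seed=5)
        count = np.count_nonzero(render_labels(scene) == 2)
        assert abs(count - math.pi * 400**2) / (math.pi * 400**2) < 0.005

    def test_degenerate_half_pixel_disc(self):
        scene = SceneParams(
            width=128, height=128,
            disc_center=(30, 60), disc_radii=(0.5, 0.5),
            fovea_center=(100, 60), true_dfa=0.0,
            macula_label_radius=default_macula_radius(128),
        )
        mask = render_labels(scene)
        assert np.count_nonzero(mask == 1) in (0, 1)

    def test_mask_values_and_determinism(self, desk_scenes):
        mask = render_labels(desk_scenes[1])
        assert set(np.unique(mask)) <= {0, 1, 2}
        assert np.array_equal(mask, render_labels(desk_scenes[1]))


class TestDatasetManifest:
    def test_round_trip_and_determinism(self, tmp_path):
        config = GeneratorConfig(width=96, height=96)
        m1 = make_dataset(3, config, seed=5, out_dir=tmp_path / "a")
        m2 = make_dataset(3, config, seed=5, out_dir=tmp_path / "b")
        assert len(m1) == 3
        for col in ("disc_x", "disc_y", "fovea_x", "fovea_y", "true_dfa_deg"):
            assert (m1[col] == m2[col]).all()
        for rel in m1["image_path"]:
            assert (tmp_path / "a" / rel).exists()
        from dfa_meter.synth import load_dataset

        manifest, images, masks = load_dataset(tmp_path / "a" / "manifest.csv")
        assert images.shape == (3, 96, 96, 3)
        assert set(np.unique(masks)) <= {0, 1, 2}

    def test_manifest_ground_truth_consistent(self, tmp_path):
        config = GeneratorConfig(width=96, height=96)
        manifest = make_dataset(2, config, seed=9, out_dir=tmp_path)
        for _, row in manifest.iterrows():
            angle = compute_dfa(
                (row["disc_x"], row["disc_y"]), (row["fovea_x"], row["fovea_y"])
            ).angle
            assert abs(angle - row["true_dfa_deg"]) <= 0.3


class TestRoundTripInvariant:
    def test_extract_centers_recovers_ground_truth(self):
        config = GeneratorConfig(width=256, height=256)
        for scene in sample_scenes(10, config, seed=21):
            centers = extract_centers(render_labels(scene))
            assert math.hypot(
                centers.ox - scene.disc_center[0], centers.oy - scene.disc_center[1]
            ) <= 1.5
            assert math.hypot(
                centers.mx - scene.fovea_center[0], centers.my - scene.fovea_center[1]
            ) <= 1.5
            dfa_from_mask = compute_dfa(
                (centers.ox, centers.oy), (centers.mx, centers.my)
            ).angle
            assert abs(dfa_from_mask - scene.true_dfa) <= 0.3
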