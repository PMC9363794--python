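"""Synthetic fundus image generator with exact disc/fovea ground truth.

Real fundus photographs of this kind (non-mydriatic color images, no retinal
disease) are not redistributable, so training and evaluation run on synthetic
scenes that reproduce the geometry the measurement depends on: a bright,
roughly elliptical optic disc; a darker foveal region temporal to the disc at
a small angle to the horizontal; dark vessel arcs emanating from the disc as
nuisance texture; and sensor noise.  Each scene carries its exact integer
disc/fovea centers and the signed disc-fovea angle they imply, plus the
"virtual macular area" label: a disc of radius 400 px at the native 2,584-px
width, scaled linearly for smaller renders.

Everything is deterministic given the scene seed: rendering the same scene
twice yields bit-identical images, masks and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .dfa import compute_dfa

__all__ = [
    "SceneParams",
    "GeneratorConfig",
    "PlacementError",
    "RegionOverlapError",
    "make_scene",
    "render_image",
    "render_labels",
    "sample_scenes",
    "make_dataset",
    "load_dataset",
    "NATIVE_WIDTH",
    "NATIVE_MACULA_RADIUS",
]

NATIVE_WIDTH = 2584  # native camera frame width, px
NATIVE_HEIGHT = 1985
NATIVE_MACULA_RADIUS = 400.0  # virtual macular label radius at native width, px


class PlacementError(ValueError):
    """Requested geometry cannot be placed inside the image bounds."""


class RegionOverlapError(ValueError):
    """Disc ellipse and virtual macula circle intersect."""


def default_macula_radius(width: int) -> float:
    """Virtual-macula label radius scaled linearly from the native ratio."""
    return NATIVE_MACULA_RADIUS * width / NATIVE_WIDTH


@dataclass(frozen=True)
class SceneParams:
    """Generative description of one synthetic fundus scene.

    ``true_dfa`` is the exact signed disc-fovea angle implied by the stored
    integer centers (the angle requested from :func:`make_scene` is honored
    to within the <=0.5 px rounding of each center coordinate).
    """

    width: int
    height: int
    disc_center: tuple  # (x, y), integer pixels
    disc_radii: tuple  # (rx, ry) ellipse semi-axes, px
    fovea_center: tuple  # (x, y), integer pixels
    true_dfa: float  # degrees
    macula_label_radius: float
    n_vessels: int = 6
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        rx, ry = self.disc_radii
        if rx <= 0 or ry <= 0 or self.macula_label_radius <= 0:
            raise ValueError("disc radii and macula label radius must be positive")
        ox, oy = self.disc_center
        mx, my = self.fovea_center
        r = self.macula_label_radius
        if not (rx <= ox <= self.width - 1 - rx and ry <= oy <= self.height - 1 - ry):
            raise PlacementError("optic disc ellipse exits the image bounds")
        if not (r <= mx <= self.width - 1 - r and r <= my <= self.height - 1 - r):
            raise PlacementError("virtual macula circle exits the image bounds")
        if abs(compute_dfa(self.disc_center, self.fovea_center).angle - self.true_dfa) > 1e-9:
            raise ValueError("true_dfa is inconsistent with the stored centers")
        if abs(self.true_dfa) > 90:
            raise ValueError("true_dfa must lie in [-90, +90]")


def make_scene(
    width: int,
    height: int,
    dfa: float,
    disc_fovea_distance: float,
    seed: int,
    *,
    n_vessels: int = 6,
    noise_sigma: float = 6.0,
    macula_label_radius: float | None = None,
    mirror: bool = False,
) -> SceneParams:
    """Place a disc/fovea pair realizing a requested disc-fovea angle.

    The fovea is placed temporal (positive x) to the disc at the requested
    Euclidean distance, at the height offset that realizes ``dfa`` under the
    image-coordinate sign convention (y down; fovea below disc => negative).
    Centers are rounded to the integer pixel grid, and ``true_dfa`` is
    recomputed exactly from the rounded centers.  ``mirror=True`` flips the
    layout left/right (fovea at negative x), emulating the other eye's
    laterality.

    Raises
    ------
    PlacementError
        When no disc position keeps both regions inside the image.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be at least 64 px")
    if abs(dfa) > 90:
        raise ValueError("requested DFA must lie in [-90, +90] degrees")
    if disc_fovea_distance <= 0:
        raise ValueError("disc-fovea distance must be positive")
    rng = np.random.default_rng(seed)
    if macula_label_radius is None:
        macula_label_radius = default_macula_radius(width)
    r_mac = float(macula_label_radius)

    rx = 0.055 * width * rng.uniform(0.9, 1.1)
    ry = rx * rng.uniform(1.0, 1.15)  # disc is slightly vertically oval

    a = math.radians(dfa)
    dx = disc_fovea_distance * math.cos(a)
    dy = -disc_fovea_distance * math.sin(a)  # y grows downward
    if mirror:
        dx = -dx

    margin = 2.0
    # feasible interval for the disc center given both regions' margins
    x_lo = max(rx + margin, (r_mac + margin) - dx)
    x_hi = min(width - 1 - rx - margin, (width - 1 - r_mac - margin) - dx)
    y_lo = max(ry + margin, (r_mac + margin) - dy)
    y_hi = min(height - 1 - ry - margin, (height - 1 - r_mac - margin) - dy)
    if x_lo > x_hi or y_lo > y_hi:
        raise PlacementError(
            f"cannot place disc-fovea pair (distance {disc_fovea_distance}, "
            f"dfa {dfa} deg) inside a {width}x{height} image"
        )
    ox = int(round(rng.uniform(x_lo, x_hi)))
    oy = int(round(rng.uniform(y_lo, y_hi)))
    mx = int(round(ox + dx))
    my = int(round(oy + dy))

    center_sep = math.hypot(mx - ox, my - oy)
    if center_sep <= r_mac + max(rx, ry) + 1.0:
        raise PlacementError(
            "disc ellipse and virtual macula circle would overlap at "
            f"distance {disc_fovea_distance}"
        )
    true_dfa = compute_dfa((ox, oy), (mx, my)).angle
    return SceneParams(
        width=width,
        height=height,
        disc_center=(ox, oy),
        disc_radii=(rx, ry),
        fovea_center=(mx, my),
        true_dfa=true_dfa,
        macula_label_radius=r_mac,
        n_vessels=n_vessels,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _pixel_grids(scene: SceneParams):
    yy, xx = np.mgrid[0 : scene.height, 0 : scene.width]
    return xx, yy


def _disc_field(scene: SceneParams, xx, yy):
    """Normalized squared elliptical distance to the disc boundary (1 = edge)."""
    ox, oy = scene.disc_center
    rx, ry = scene.disc_radii
    return ((xx - ox) / rx) ** 2 + ((yy - oy) / ry) ** 2


def render_image(scene: SceneParams) -> np.ndarray:
    """Render the scene to an 8-bit RGB array (height x width x 3).

    The rendering is deliberately schematic: a reddish background with mild
    vignetting, a bright yellowish disc ellipse with a soft edge, a smooth
    darkening around the fovea, dark quadratic-Bezier vessel arcs rooted at
    the disc, and i.i.d. Gaussian sensor noise of scale ``noise_sigma``.
    Bit-identical across calls for the same scene.
    """
    h, w = scene.height, scene.width
    rng = np.random.default_rng([scene.seed, 1])
    xx, yy = _pixel_grids(scene)

    img = np.empty((h, w, 3), dtype=np.float32)
    img[..., 0] = 172.0
    img[..., 1] = 84.0
    img[..., 2] = 56.0
    # vignette toward the frame corners
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    vign = ((xx - cx) / (0.7 * w)) ** 2 + ((yy - cy) / (0.7 * h)) ** 2
    img -= (40.0 * vign)[..., None].astype(np.float32)

    # bright disc with a soft (sigmoid) edge
    e = _disc_field(scene, xx, yy)
    edge = 1.0 / (1.0 + np.exp(np.clip((e - 1.0) * 8.0, -60.0, 60.0)))
    img += (edge[..., None] * np.array([70.0, 120.0, 110.0], np.float32)).astype(
        np.float32
    )

    # foveal darkening: radial Gaussian falloff around the fovea center
    mx, my = scene.fovea_center
    sigma_f = 0.6 * scene.macula_label_radius
    fov = np.exp(-((xx - mx) ** 2 + (yy - my) ** 2) / (2.0 * sigma_f**2))
    img -= (fov[..., None] * np.array([55.0, 38.0, 26.0], np.float32)).astype(
        np.float32
    )

    if scene.n_vessels > 0:
        vmask = _vessel_mask(scene, rng)
        img -= (vmask[..., None] * np.array([70.0, 36.0, 28.0], np.float32)).astype(
            np.float32
        )

    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape).astype(np.float32)

    return np.clip(img, 0, 255).astype(np.uint8)


def _vessel_mask(scene: SceneParams, rng) -> np.ndarray:
    """Soft [0,1] mask of quadratic-Bezier vessel arcs rooted at the disc."""
    h, w = scene.height, scene.width
    ox, oy = scene.disc_center
    canvas = np.zeros((h, w), dtype=bool)
    n_steps = 4 * max(h, w)
    t = np.linspace(0.0, 1.0, n_steps)
    for _ in range(scene.n_vessels):
        # arcs leave the disc toward the temporal side, bowing up or down
        ang = rng.uniform(-math.pi / 2.5, math.pi / 2.5)
        sgn = rng.choice([-1.0, 1.0])
        length = rng.uniform(0.45, 0.8) * w
        p0 = np.array([ox, oy], dtype=float)
        p2 = p0 + length * np.array([math.cos(ang), math.sin(ang)])
        mid = (p0 + p2) / 2.0
        normal = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
        norm = np.linalg.norm(normal)
        if norm > 0:
            normal /= norm
        p1 = mid + sgn * rng.uniform(0.1, 0.25) * length * normal
        pts = (
            np.outer((1 - t) ** 2, p0)
            + np.outer(2 * (1 - t) * t, p1)
            + np.outer(t**2, p2)
        )
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        canvas[rows, cols] = True
    thickness = max(1, int(round(w / 300)))
    canvas = ndimage.binary_dilation(canvas, iterations=thickness)
    soft = ndimage.gaussian_filter(canvas.astype(np.float32), sigma=0.8)
    return np.clip(soft, 0.0, 1.0)


def render_labels(scene: SceneParams) -> np.ndarray:
    """Three-class label mask: 0 background, 1 disc ellipse, 2 virtual macula.

    Rasterization uses the pixel-center rule: pixel (x, y) belongs to a
    region iff its integer-coordinate center satisfies the region inequality
    (<= for both the ellipse and the circle), so a 400-px-radius label truly
    extends 400 px from its center.

    Raises
    ------
    RegionOverlapError
        If any pixel falls in both the disc ellipse and the macula circle.
    """
    xx, yy = _pixel_grids(scene)
    disc = _disc_field(scene, xx, yy) <= 1.0
    mx, my = scene.fovea_center
    macula = (xx - mx) ** 2 + (yy - my) ** 2 <= scene.macula_label_radius**2
    if np.any(disc & macula):
        raise RegionOverlapError("disc ellipse and virtual macula circle intersect")
    mask = np.zeros((scene.height, scene.width), dtype=np.uint8)
    mask[macula] = 2
    mask[disc] = 1
    return mask


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges for random scene sampling.

    Defaults emulate the study population at a configurable render size:
    normal eyes, disc-fovea angles within roughly +/-10 degrees of the
    horizontal, disc-fovea distance around 0.31 of the frame width (800 px at
    the native 2,584-px width), moderate vessel count and sensor noise.
    """

    width: int = 512
    height: int = 512
    dfa_range: tuple = (-10.0, 10.0)
    dist_range: tuple | None = None  # px; default (0.29, 0.33) * width
    n_vessels: int = 6
    noise_sigma: float = 6.0
    mirror_fraction: float = 0.0

    def resolved_dist_range(self) -> tuple:
        if self.dist_range is not None:
            return self.dist_range
        return (0.29 * self.width, 0.33 * self.width)


def sample_scenes(n: int, config: GeneratorConfig, seed: int) -> list:
    """Draw ``n`` scenes with parameters sampled from the config ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo_d, hi_d = config.resolved_dist_range()
    scenes = []
    for _ in range(n):
        for _attempt in range(20):
            params = dict(
                dfa=rng.uniform(*config.dfa_range),
                disc_fovea_distance=rng.uniform(lo_d, hi_d),
                seed=int(rng.integers(0, 2**31 - 1)),
                mirror=bool(rng.random() < config.mirror_fraction),
            )
            try:
                scene = make_scene(
                    config.width,
                    config.height,
                    params["dfa"],
                    params["disc_fovea_distance"],
                    params["seed"],
                    n_vessels=config.n_vessels,
                    noise_sigma=config.noise_sigma,
                    mirror=params["mirror"],
                )
                break
            except PlacementError:
                continue
        else:
            raise PlacementError(
                "could not place a valid scene after 20 attempts; "
                "check dist_range against the image size"
            )
        scenes.append(scene)
    return scenes


def make_dataset(n: int, config: GeneratorConfig, seed: int, out_dir) -> pd.DataFrame:
    """Write ``n`` image/mask pairs and a ground-truth manifest to ``out_dir``.

    Returns the manifest with columns id, image_path, mask_path, disc_x,
    disc_y, fovea_x, fovea_y, true_dfa_deg (paths relative to ``out_dir``).
    Fully reproducible from ``seed``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    scenes = sample_scenes(n, config, seed)
    rows = []
    for i, scene in enumerate(scenes):
        image_rel = f"images/{i:05d}.png"
        mask_rel = f"masks/{i:05d}.png"
        try:
            Image.fromarray(render_image(scene), mode="RGB").save(out_dir / image_rel)
            Image.fromarray(render_labels(scene), mode="L").save(out_dir / mask_rel)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / image_rel}: {exc}") from exc
        rows.append(
            dict(
                id=i,
                image_path=image_rel,
                mask_path=mask_rel,
                disc_x=scene.disc_center[0],
                disc_y=scene.disc_center[1],
                fovea_x=scene.fovea_center[0],
                fovea_y=scene.fovea_center[1],
                true_dfa_deg=round(scene.true_dfa, 4),
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path):
    """Load a generated dataset: (manifest, images (n,H,W,3) u8, masks (n,H,W) u8)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    images, masks = [], []
    for _, row in manifest.iterrows():
        images.append(np.asarray(Image.open(root / row["image_path"]).convert("RGB")))
        masks.append(np.asarray(Image.open(root / row["mask_path"]).convert("L")))
    return manifest, np.stack(images), np.stack(masks)
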