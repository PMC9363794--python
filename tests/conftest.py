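import math

import numpy as np
import pytest

from dfa_meter.geometry import CircleFit
from dfa_meter.synth import GeneratorConfig, render_image, render_labels, sample_scenes


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_mec(points) -> CircleFit:
    """O(n^4) minimum enclosing circle: try all pairs and triples."""

    def circle_two(p, q):
        cx, cy = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
        return CircleFit(cx, cy, math.hypot(p[0] - q[0], p[1] - q[1]) / 2)

    def circumcircle(a, b, c):
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if d == 0:
            return None
        a2, b2, c2 = (p[0] ** 2 + p[1] ** 2 for p in (a, b, c))
        ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
        uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
        return CircleFit(ux, uy, math.hypot(a[0] - ux, a[1] - uy))

    pts = [tuple(map(float, p)) for p in points]
    if len(pts) == 1:
        return CircleFit(pts[0][0], pts[0][1], 0.0)

    def contains_all(c):
        return all(
            math.hypot(p[0] - c.cx, p[1] - c.cy) <= c.radius + 1e-9 for p in pts
        )

    candidates = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            c = circle_two(pts[i], pts[j])
            if contains_all(c):
                candidates.append(c)
            for k in range(j + 1, len(pts)):
                c = circumcircle(pts[i], pts[j], pts[k])
                if c is not None and contains_all(c):
                    candidates.append(c)
    return min(candidates, key=lambda c: c.radius)


def flood_fill_components(binary) -> list:
    """8-connected components by explicit stack-based flood fill."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((c, r))  # (x, y)
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and binary[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def desk_config() -> GeneratorConfig:
    return GeneratorConfig(width=128, height=128)


@pytest.fixture(scope="session")
def desk_scenes(desk_config):
    return sample_scenes(12, desk_config, seed=7)


@pytest.fixture(scope="session")
def desk_images(desk_scenes):
    return np.stack([render_image(s) for s in desk_scenes])


@pytest.fixture(scope="session")
def desk_masks(desk_scenes):
    return np.stack([render_labels(s) for s in desk_scenes])
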