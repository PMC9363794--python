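"""Signed disc-fovea angle (DFA) from disc and macula center coordinates.

The DFA is the angle between the line joining the optic-disc center to the
foveal (macular) center and the horizontal line through the disc center.
Coordinates follow the image convention: x grows rightward (columns), y grows
downward (rows).  The magnitude is ``arctan(|dy| / |dx|)`` in degrees (90 deg
when the centers are vertically aligned) and the sign is flipped whenever the
macular center lies below the disc center (MY > OY).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DFAResult", "compute_dfa", "dfa_error", "CoincidentCentersError"]


class CoincidentCentersError(ValueError):
    """Raised when disc and macula centers are the same point."""


@dataclass(frozen=True)
class DFAResult:
    """Disc-fovea angle together with the centers it was computed from.

    Attributes
    ----------
    ox, oy : float
        Optic-disc center, pixels.
    mx, my : float
        Macular center, pixels.
    angle : float
        Signed disc-fovea angle in degrees, in [-90, +90].
    """

    ox: float
    oy: float
    mx: float
    my: float
    angle: float


def compute_dfa(disc_center, macula_center) -> DFAResult:
    """Compute the signed disc-fovea angle between two centers.

    Parameters
    ----------
    disc_center : (float, float)
        Optic-disc center ``(OX, OY)`` in pixel coordinates.
    macula_center : (float, float)
        Macular center ``(MX, MY)`` in pixel coordinates.

    Returns
    -------
    DFAResult
        ``angle`` is ``arctan(|OY - MY| / |OX - MX|) * 180 / pi``, taken as
        90 when ``OX == MX``, and negated when ``MY > OY`` (the fovea sits
        below the disc in image coordinates, y pointing down).

    Raises
    ------
    CoincidentCentersError
        If the two centers coincide (the angle is undefined).
    """
    ox, oy = float(disc_center[0]), float(disc_center[1])
    mx, my = float(macula_center[0]), float(macula_center[1])
    if not all(math.isfinite(v) for v in (ox, oy, mx, my)):
        raise ValueError("center coordinates must be finite")
    dx = abs(ox - mx)
    dy = abs(oy - my)
    if dx == 0.0 and dy == 0.0:
        raise CoincidentCentersError(
            "disc and macula centers coincide; DFA is undefined"
        )
    if dx == 0.0:
        magnitude = 90.0
    else:
        magnitude = math.degrees(math.atan(dy / dx))
    angle = -magnitude if my > oy else magnitude
    return DFAResult(ox=ox, oy=oy, mx=mx, my=my, angle=angle)


def dfa_error(predicted: float, truth: float) -> float:
    """Absolute difference between a predicted and a reference DFA, degrees."""
    predicted = float(predicted)
    truth = float(truth)
    if not (math.isfinite(predicted) and math.isfinite(truth)):
        raise ValueError("DFA values must be finite")
    return abs(predicted - truth)
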