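"""rASA moment of a transmembrane helix.

Successive residues of an ideal α-helix are spaced 100° apart on the helical
wheel, so residue *i* (1-based) sits at ``theta_i = (i - 1) * 100`` degrees.
Placing each residue's exposure score at its wheel position and summing the
resulting vectors gives the exposure moment::

    x = sum_i s_i * cos(theta_i)
    y = sum_i s_i * sin(theta_i)

The moment length ``|M| = sqrt(x^2 + y^2)`` measures how anisotropic the
exposure pattern is, and its direction

    gamma = arccos(x / |M|);  theta = gamma if y >= 0 else 360 - gamma

is the predicted lipid-facing direction, i.e. the predicted rotational angle
of the helix, measured from the wheel position of the first residue.
All angles are degrees in [0, 360).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

#: Helical-wheel spacing between consecutive residues, degrees.
TWIST_PER_RESIDUE = 100.0

#: Moment lengths below this are treated as directionless.
DIRECTION_EPSILON = 1e-9


class UndefinedDirectionError(ValueError):
    """Raised when the moment is too short to define a direction."""

    def __init__(self, length: float):
        self.length = length
        super().__init__(
            f"moment length {length:.3g} is below {DIRECTION_EPSILON:g}; "
            "direction undefined"
        )


@dataclass(frozen=True)
class MomentResult:
    """Exposure-moment vector of one helix."""

    x: float
    y: float
    length: float
    theta: float  # degrees in [0, 360)
    n: int


def residue_wheel_angles(n: int) -> np.ndarray:
    """Wheel angles ``(i - 1) * 100`` degrees for residues 1..n."""
    return TWIST_PER_RESIDUE * np.arange(n, dtype=float)


def moment_vector(scores: Sequence[float]) -> tuple[float, float]:
    """Vector sum of per-residue scores placed at their wheel angles."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("scores must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    theta = np.deg2rad(residue_wheel_angles(s.size))
    return float(np.sum(s * np.cos(theta))), float(np.sum(s * np.sin(theta)))


def moment_length(x: float, y: float) -> float:
    return float(np.hypot(x, y))


def moment_direction(x: float, y: float) -> float:
    """Direction of the moment vector in degrees [0, 360).

    Uses the arccos form with the sign of *y* selecting the branch; this is
    identical to the two-argument arctangent mapped to [0, 360).
    """
    m = moment_length(x, y)
    if m <= DIRECTION_EPSILON:
        raise UndefinedDirectionError(m)
    gamma = float(np.degrees(np.arccos(np.clip(x / m, -1.0, 1.0))))
    theta = gamma if y >= 0 else 360.0 - gamma
    return theta % 360.0


def predict_rotation(scores: Sequence[float], postprocess=None) -> MomentResult:
    """Predicted rotational angle of a helix from its exposure profile.

    ``postprocess`` is an optional hook applied to the raw scores before the
    moment is taken (identity by default); it exists so outlier/ramp
    smoothing schemes can be plugged in without changing the pipeline.
    """
    s = np.asarray(scores, dtype=float)
    if postprocess is not None:
        s = np.asarray(postprocess(s), dtype=float)
    x, y = moment_vector(s)
    m = moment_length(x, y)
    theta = moment_direction(x, y)
    return MomentResult(x=x, y=y, length=m, theta=theta, n=s.size)


def load_scales() -> dict[str, dict[str, float]]:
    """Bundled per-residue score scales (e.g. the Eisenberg consensus scale)."""
    with resources.files("tmexpo.data").joinpath("scales.json").open() as fh:
        return json.load(fh)


def scale_scores(sequence: str, scale: dict[str, float] | str) -> np.ndarray:
    """Per-residue values for ``sequence`` under a named or explicit scale."""
    if isinstance(scale, str):
        scales = load_scales()
        if scale not in scales:
            raise KeyError(f"unknown scale {scale!r}; bundled: {sorted(scales)}")
        table = scales[scale]
    else:
        table = scale
    missing = sorted({aa for aa in sequence if aa not in table})
    if missing:
        raise KeyError(f"scale lacks values for residues {missing}")
    return np.array([table[aa] for aa in sequence], dtype=float)
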