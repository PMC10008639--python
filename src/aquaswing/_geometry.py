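"""Small geometry helpers shared across modules.

Conventions: coordinates in Å, times in fs, frequencies in THz
(1 fs⁻¹ = 1000 THz). Boxes are orthorhombic, described by three edge
lengths.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "rotation_matrix",
    "minimum_image",
    "angle_between_deg",
]


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Return ``v`` scaled to unit norm along ``axis``.

    Raises ``ValueError`` on (near-)zero vectors: every body-fixed vector
    in this package lives on the unit sphere, so a vanishing norm always
    signals degenerate molecular geometry upstream.
    """
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a (near-)zero vector")
    return v / n


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = normalize(np.asarray(axis, dtype=float))
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = a
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(a, a)


def minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s).

    ``vec`` has shape (..., 3); ``box`` is the (3,) orthorhombic box.
    """
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between vectors in degrees, broadcast over leading axes."""
    un = u / np.linalg.norm(u, axis=-1, keepdims=True)
    vn = v / np.linalg.norm(v, axis=-1, keepdims=True)
    cosang = np.clip(np.sum(un * vn, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))
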