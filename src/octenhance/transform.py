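"""Rigid (Euclidean) transforms between repeated B-scan frames.

A transform is a rotation about the image centre followed by a translation,
which is the motion model appropriate for the short inter-frame interval of
repeated B-scan acquisition: the eye moves approximately uniformly over one
frame period, so frames of the same location differ by a small rigid motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import warp as _skimage_warp


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: rotate by ``theta`` degrees about the image centre,
    then translate by ``(dx, dy)`` pixels (x = columns, y = rows)."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.dx, self.dy, self.theta)):
            raise ValueError("rigid transform parameters must be finite")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.dx) <= tol and abs(self.dy) <= tol and abs(self.theta) <= tol
        )

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """Forward 3x3 homogeneous matrix mapping input (x, y, 1) to output
        coordinates, for an image of the given (height, width)."""
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        t = math.radians(self.theta)
        c, s = math.cos(t), math.sin(t)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        to_centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        back = np.array(
            [[1, 0, cx + self.dx], [0, 1, cy + self.dy], [0, 0, 1]], dtype=float
        )
        return back @ rot @ to_centre

    def compose(self, other: "RigidTransform", shape: tuple[int, int]) -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        m = self.matrix(shape) @ other.matrix(shape)
        return _from_matrix(m, shape)

    def inverse(self, shape: tuple[int, int]) -> "RigidTransform":
        return _from_matrix(np.linalg.inv(self.matrix(shape)), shape)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.theta)


def _from_matrix(m: np.ndarray, shape: tuple[int, int]) -> RigidTransform:
    """Recover (dx, dy, theta) from a forward matrix.

    Any rigid map equals a centre rotation R followed by a translation d with
    d = b + (A - I) c, where A, b are the linear/offset parts and c the centre.
    """
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    a, b = m[:2, :2], m[:2, 2]
    theta = math.degrees(math.atan2(a[1, 0], a[0, 0]))
    d = b + (a - np.eye(2)) @ c
    return RigidTransform(float(d[0]), float(d[1]), float(theta))


def warp_image(
    image: np.ndarray,
    transform: RigidTransform,
    cval: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Apply a rigid transform to a 2-D image (bilinear by default).

    The identity transform is short-circuited so that zero-motion acquisition
    reproduces its input bit-exactly.
    """
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if transform.is_identity():
        return image.copy()
    inv = np.linalg.inv(transform.matrix(image.shape))
    return _skimage_warp(
        image.astype(float), inv, order=order, cval=cval, mode="constant",
        preserve_range=True,
    )
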