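"""Exact 2-D affine geometry linking IF image space and tissue coordinate space.

An :class:`AffineTransform2D` stores a 3x3 homogeneous matrix that acts on
tissue coordinates in micrometres.  Coordinate spaces are tagged
(``image_px`` or ``tissue_um``); when the source or target space is the image,
the pixel pitch ``pixel_size_um`` converts between pixel indices and
micrometres on the way in or out.  Inclusion centroids are transformed from
image space into tissue space as points, rather than resampling the whole
image: for point-in-polygon containment the two are mathematically
equivalent, and transforming points avoids interpolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularTransformError, SpaceMismatchError

SPACES = ("image_px", "tissue_um")

_LAST_ROW_TOL = 1e-12


@dataclass(frozen=True)
class AffineTransform2D:
    """A homogeneous 2-D affine map between tagged coordinate spaces.

    Parameters
    ----------
    matrix
        3x3 real matrix, last row (0, 0, 1).  The linear/translation part is
        expressed in micrometres regardless of the tagged spaces.
    source_space, target_space
        ``"image_px"`` or ``"tissue_um"``.
    pixel_size_um
        Micrometres per pixel of the IF image; applied when either endpoint
        of the map is ``image_px``.
    """

    matrix: np.ndarray
    source_space: str = "image_px"
    target_space: str = "tissue_um"
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=_LAST_ROW_TOL):
            raise ValueError(f"last row of affine matrix must be (0, 0, 1), got {m[2]}")
        if abs(np.linalg.det(m[:2, :2])) < 1e-15:
            raise SingularTransformError("2x2 linear block is singular")
        for space in (self.source_space, self.target_space):
            if space not in SPACES:
                raise ValueError(f"unknown coordinate space {space!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "matrix", m)

    # convenience constructors -------------------------------------------------

    @classmethod
    def identity(cls, source_space: str = "tissue_um", target_space: str = "tissue_um",
                 pixel_size_um: float = 1.0) -> "AffineTransform2D":
        return cls(np.eye(3), source_space, target_space, pixel_size_um)

    @classmethod
    def from_parts(cls, *, scale: float = 1.0, rotation_rad: float = 0.0,
                   translation: tuple[float, float] = (0.0, 0.0),
                   source_space: str = "image_px", target_space: str = "tissue_um",
                   pixel_size_um: float = 1.0) -> "AffineTransform2D":
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        m = np.array([
            [scale * c, -scale * s, translation[0]],
            [scale * s, scale * c, translation[1]],
            [0.0, 0.0, 1.0],
        ])
        return cls(m, source_space, target_space, pixel_size_um)


def apply_affine(points, t: AffineTransform2D, space: str | None = None) -> np.ndarray:
    """Map ``points`` (n x 2) through ``t``; returns an (n, 2) float array.

    ``space``, when given, is checked against ``t.source_space`` and a
    :class:`SpaceMismatchError` is raised on disagreement.
    """
    if space is not None and space != t.source_space:
        raise SpaceMismatchError(
            f"points tagged {space!r} but transform expects {t.source_space!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if t.source_space == "image_px":
        pts = pts * t.pixel_size_um
    homog = np.column_stack([pts, np.ones(len(pts))])
    out = homog @ t.matrix.T
    out = out[:, :2]
    if t.target_space == "image_px":
        out = out / t.pixel_size_um
    return out


def invert_affine(t: AffineTransform2D) -> AffineTransform2D:
    """Inverse map; swaps the source/target space tags."""
    try:
        inv = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught at init
        raise SingularTransformError(str(exc)) from exc
    inv[2] = [0.0, 0.0, 1.0]
    return AffineTransform2D(inv, t.target_space, t.source_space, t.pixel_size_um)


def compose_affine(a: AffineTransform2D, b: AffineTransform2D) -> AffineTransform2D:
    """Composite map applying ``b`` first, then ``a`` (like matrix product a.b)."""
    if b.target_space != a.source_space:
        raise SpaceMismatchError(
            f"cannot compose: inner target {b.target_space!r} != outer source {a.source_space!r}")
    if ("image_px" in (a.source_space, a.target_space, b.source_space, b.target_space)
            and not np.isclose(a.pixel_size_um, b.pixel_size_um)):
        raise SpaceMismatchError("composing transforms with different pixel sizes")
    m = a.matrix @ b.matrix
    m[2] = [0.0, 0.0, 1.0]
    return AffineTransform2D(m, b.source_space, a.target_space, a.pixel_size_um)
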