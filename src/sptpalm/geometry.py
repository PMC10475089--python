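"""Spherocylinder cell-surface geometry.

A rod-shaped bacterium is idealised as a spherocylinder: a cylinder of
radius ``r`` capped with two hemispheres.  The cell lies on the coverslip
with its long axis horizontal, so the lowest surface point is at height 0
and the axis at height ``r``.

Local coordinates: the long axis is the x axis, centred on the cell
midpoint; y is the lateral in-plane direction and z the optical axis
(height above the cell axis, so the coverslip-proximal surface is at
``z = -r``).  The image plane sees (x, y) after rotating by the cell's
orientation and translating to its centre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellGeometry", "build_cell", "pole_surface_fraction"]


@dataclass(frozen=True)
class CellGeometry:
    """Idealised spherocylindrical cell.

    Parameters
    ----------
    total_length : float
        Pole-to-pole length in µm (including the hemispherical caps).
    width : float
        Cell diameter in µm (``2 * radius``).
    center : tuple of float
        Image-plane position of the cell midpoint, µm.
    orientation : float
        Angle of the long axis in the image plane, radians.
    """

    total_length: float
    width: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if self.total_length < self.width:
            raise ValueError(
                "no spherocylinder exists with total_length "
                f"{self.total_length} < width {self.width}"
            )

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical segment (total length minus both caps)."""
        return self.total_length - self.width

    @property
    def surface_area(self) -> float:
        """Surface area 2πr·Lcyl + 4πr² in µm²."""
        r = self.radius
        return 2.0 * math.pi * r * self.cylinder_length + 4.0 * math.pi * r * r

    # ------------------------------------------------------------------
    # surface operations (all in the local frame, µm)
    # ------------------------------------------------------------------
    def project_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Orthogonally project 3D points onto the surface.

        The nearest axis point is found by clamping x to the cylindrical
        segment; the point is then pushed radially to distance ``r``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.cylinder_length / 2.0
        axis = np.zeros_like(points)
        axis[:, 0] = np.clip(points[:, 0], -half, half)
        radial = points - axis
        norm = np.linalg.norm(radial, axis=1, keepdims=True)
        # a point exactly on the axis has no well-defined normal; push it up
        degenerate = norm[:, 0] == 0.0
        if np.any(degenerate):
            radial[degenerate] = (0.0, 0.0, 1.0)
            norm[degenerate] = 1.0
        return axis + self.radius * radial / norm

    def surface_normal(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normal at (assumed on-surface) points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.cylinder_length / 2.0
        axis = np.zeros_like(points)
        axis[:, 0] = np.clip(points[:, 0], -half, half)
        radial = points - axis
        return radial / np.linalg.norm(radial, axis=1, keepdims=True)

    def on_surface(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """True where points lie on the surface within ``tol`` µm."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        proj = self.project_to_surface(points)
        return np.linalg.norm(points - proj, axis=1) <= tol

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly on the surface (local frame, µm)."""
        r = self.radius
        area_cyl = 2.0 * math.pi * r * self.cylinder_length
        p_cyl = area_cyl / self.surface_area
        on_cyl = rng.random(n) < p_cyl
        pts = np.empty((n, 3))
        n_cyl = int(on_cyl.sum())
        half = self.cylinder_length / 2.0
        if n_cyl:
            x = rng.uniform(-half, half, n_cyl)
            phi = rng.uniform(0.0, 2.0 * math.pi, n_cyl)
            pts[on_cyl] = np.column_stack([x, r * np.sin(phi), -r * np.cos(phi)])
        n_cap = n - n_cyl
        if n_cap:
            v = rng.normal(size=(n_cap, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            # assign to the cap whose side the x-component points to
            v[:, 0] = np.abs(v[:, 0]) * np.where(rng.random(n_cap) < 0.5, 1.0, -1.0)
            pts[~on_cyl] = r * v
            pts[~on_cyl, 0] += np.sign(v[:, 0]) * half
        return pts

    def arc_depth_from_tip(self, points: np.ndarray) -> np.ndarray:
        """Arc-length distance, along the extended centreline, from each
        point's axial projection to the nearer cell tip (µm).

        For a straight cell this is ``L/2 - |x|``: on the caps it equals the
        axial depth below the tip, on the cylinder it is the cap radius plus
        the distance to the cylinder end.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self.total_length / 2.0 - np.abs(points[:, 0])

    def height_above_coverslip(self, points: np.ndarray) -> np.ndarray:
        """Height of surface points above the lowest cell point (µm)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points[:, 2] + self.radius

    def to_image_plane(self, points: np.ndarray) -> np.ndarray:
        """Project local 3D surface points to lab-frame (x, y) in µm."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        x = c * points[:, 0] - s * points[:, 1] + self.center[0]
        y = s * points[:, 0] + c * points[:, 1] + self.center[1]
        return np.column_stack([x, y])


def build_cell(
    total_length: float,
    width: float,
    center: tuple[float, float] = (0.0, 0.0),
    orientation: float = 0.0,
) -> CellGeometry:
    """Construct a :class:`CellGeometry`; rejects ``total_length < width``."""
    return CellGeometry(total_length, width, center, orientation)


def pole_surface_fraction(cell: CellGeometry, pole_depth_nm: float) -> float:
    """Fraction of the cell surface lying within ``pole_depth_nm`` (arc
    depth along the centreline) of either cell tip.

    By Archimedes' hat-box theorem the spherical zone of axial depth ``d``
    has area 2πr·d, and a cylinder band likewise, so each pole zone has
    area 2πr·d and the fraction reduces to ``2d / L`` (capped at 1 when the
    two zones meet at mid-cell).
    """
    if pole_depth_nm <= 0:
        raise ValueError("pole_depth must be positive")
    d = pole_depth_nm / 1000.0  # nm -> µm
    if d >= cell.total_length / 2.0:
        warnings.warn(
            "pole zones meet at mid-cell; the whole surface is polar",
            stacklevel=2,
        )
        return 1.0
    r = cell.radius
    zone = 2.0 * math.pi * r * d  # per pole; valid for d <= r and d > r alike
    return 2.0 * zone / cell.surface_area


def pole_surface_fraction_mc(
    cell: CellGeometry,
    pole_depth_nm: float,
    n: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo cross-check of :func:`pole_surface_fraction` by uniform
    surface sampling."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = cell.sample_surface(n, rng)
    return float(np.mean(cell.arc_depth_from_tip(pts) <= pole_depth_nm / 1000.0))
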