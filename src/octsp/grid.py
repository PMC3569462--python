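"""Scan-grid geometry shared by every stage of the pipeline.

All 2D maps live on a square ``n x n`` grid of A-scan positions covering a
fixed 6 x 6 mm field centred on the optic nerve head (ONH).  The angular
convention is: 0 deg at the temporal horizontal (+x), increasing
counter-clockwise, so the superior hemifield is (0, 180) deg and the
inferior hemifield (180, 360) deg.  Left eyes are assumed mirrored to this
convention before processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FIELD_MM = 6.0  # lateral extent of the ONH cube scan


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the sampling grid.

    Parameters
    ----------
    n : int
        Grid side length in pixels (A-scans per B-scan and B-scans).
    spacing_um : float
        Lateral pitch in micrometres per pixel.  The default 30 um/px
        corresponds to the 200 x 200 protocol over 6 x 6 mm.
    disc_center : (float, float)
        ONH centre as (row, col); defaults to the grid centre.
    disc_radius_mm : float
        Radius of the disc region where RNFL thickness is undefined.
    axial_um : float
        Axial voxel size for 3D cubes.
    """

    n: int = 200
    spacing_um: float = 30.0
    disc_center: tuple[float, float] | None = None
    disc_radius_mm: float = 0.9
    axial_um: float = 2.0

    @classmethod
    def for_size(cls, n: int, **kw) -> "GridSpec":
        """Grid of side ``n`` covering the same 6 x 6 mm field of view."""
        return cls(n=n, spacing_um=FIELD_MM * 1000.0 / n, **kw)

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        c = (self.n - 1) / 2.0
        return (c, c)

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    def mm_to_px(self, mm: float) -> float:
        return mm / self.spacing_mm

    def px_to_mm(self, px: float) -> float:
        return px * self.spacing_mm

    @property
    def disc_radius_px(self) -> float:
        return self.mm_to_px(self.disc_radius_mm)

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel radius (px) and angle (deg, [0, 360)) about the disc."""
        cy, cx = self.center
        yy, xx = np.mgrid[0 : self.n, 0 : self.n]
        r = np.hypot(yy - cy, xx - cx)
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        return r, theta

    def disc_mask(self) -> np.ndarray:
        r, _ = self.polar()
        return r < self.disc_radius_px

    def circle_points(
        self, radius_px: float, angles_deg: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of points on a circle about the disc centre."""
        cy, cx = self.center
        a = np.radians(np.asarray(angles_deg, float))
        return cy + radius_px * np.sin(a), cx + radius_px * np.cos(a)


def sample_map(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling of ``img`` at fractional (row, col) positions."""
    return ndimage.map_coordinates(
        np.asarray(img, float), [rows, cols], order=1, mode="nearest"
    )


def angular_profile(
    img: np.ndarray, grid: GridSpec, radius_px: float, n_angles: int = 360
) -> tuple[np.ndarray, np.ndarray]:
    """Thickness profile on one circle; returns (angles_deg, values)."""
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rows, cols = grid.circle_points(radius_px, angles)
    return angles, sample_map(img, rows, cols)
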