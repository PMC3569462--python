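"""2D feature-map generation: RNFL reflectivity, vessel-shadow inpainting
and composition of the scalar channel that drives segmentation.

The cube is reduced to three registered 2D channels — vessel-inpainted
normalized thickness (um), RNFL internal reflectivity ([0, 1], each voxel
first normalized to its own A-scan's saturation) and the normative
deviation map — plus a combined scalar intensity used by the graph
partitioner.  The combination is multiplicative,
``(T / Tmax) * (w_r + (1 - w_r) * R)``: it preserves thickness ordering and
damps intensity where reflectivity is low, as in glaucomatous RNFL, while
the deviation stays a separate channel consumed by the partition rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridSpec

DEFAULT_W_R = 0.7  # weight of the constant term in the reflectivity factor


@dataclass
class FeatureMap:
    thickness: np.ndarray  # um, vessel-inpainted (and normally warp-normalized)
    reflectivity: np.ndarray  # [0, 1]
    deviation: np.ndarray  # nonnegative z-units
    disc_mask: np.ndarray  # bool
    scalar_intensity: np.ndarray  # [0, 1]
    grid: GridSpec
    #: (mean, SD, max) thickness of a fixed population reference (normative
    #: atlas); used by the partition rule so its branch thresholds do not
    #: drift with the severity of the eye under test.  None -> own map.
    reference_stats: tuple[float, float, float] | None = None


def rnfl_reflectivity(
    cube: np.ndarray, top: np.ndarray, bottom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean saturation-normalized intensity strictly between the surfaces.

    Per A-scan, every voxel is divided by that A-scan's maximum intensity
    before averaging over voxels with ``top < z < bottom``.  Zero-thickness
    slabs get reflectivity 0 and are flagged.

    Returns ``(reflectivity, flagged)``.
    """
    cube = np.asarray(cube, float)
    top = np.asarray(top)
    bottom = np.asarray(bottom)
    if np.any(bottom < top):
        raise ValueError("surfaces must satisfy bottom >= top")
    amax = cube.max(axis=2)
    amax = np.where(amax > 0, amax, 1.0)
    norm = cube / amax[..., None]
    cum = np.concatenate(
        [np.zeros(cube.shape[:2] + (1,)), np.cumsum(norm, axis=2)], axis=2
    )
    lo = np.ceil(top).astype(int) + 1  # first voxel strictly above top
    hi = np.ceil(bottom).astype(int)  # one past the last voxel strictly below
    lo = np.clip(lo, 0, cube.shape[2])
    hi = np.clip(hi, 0, cube.shape[2])
    count = hi - lo
    flagged = count <= 0
    ii, jj = np.indices(cube.shape[:2])
    total = cum[ii, jj, hi] - cum[ii, jj, np.minimum(lo, hi)]
    refl = np.where(flagged, 0.0, total / np.where(flagged, 1, count))
    return refl, flagged


def inpaint_vessels(thickness_map: np.ndarray, vessel_mask: np.ndarray,
                    exclude_mask: np.ndarray | None = None) -> np.ndarray:
    """Replace vessel pixels by separable bilinear interpolation.

    Each vessel pixel takes the average of a row-wise and a column-wise
    linear interpolation between its nearest non-vessel neighbours
    (inverse-distance weighting, which is exact on affine surfaces — the
    defining property of bilinear interpolation).  Non-vessel pixels are
    untouched, so the operation is idempotent.  ``exclude_mask`` (e.g. the
    disc) marks pixels that are neither sources nor targets.
    """
    t = np.asarray(thickness_map, float)
    vessel = np.asarray(vessel_mask, bool)
    if exclude_mask is None:
        exclude_mask = np.zeros_like(vessel)
    exclude_mask = np.asarray(exclude_mask, bool)
    vessel = vessel & ~exclude_mask
    evaluable = ~exclude_mask
    if evaluable.sum() and vessel.sum() > 0.5 * evaluable.sum():
        raise ValueError("mask implausible: covers > 50% of evaluable pixels")
    good = evaluable & ~vessel

    def _axis_interp(arr, good_mask):
        # linear interpolation along axis 1 between flanking good pixels;
        # one-sided positions are left invalid (no extrapolation) so the
        # other axis or the nearest-neighbour fallback decides there
        out = np.full_like(arr, np.nan)
        idx = np.arange(arr.shape[1])
        for i in range(arr.shape[0]):
            g = good_mask[i]
            if g.sum() >= 2:
                vals = np.interp(idx, idx[g], arr[i, g])
                vals[(idx < idx[g][0]) | (idx > idx[g][-1])] = np.nan
                out[i] = vals
        return out

    row_est = _axis_interp(t, good)
    col_est = _axis_interp(t.T, good.T).T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan positions
        est = np.nanmean(np.stack([row_est, col_est]), axis=0)
    out = t.copy()
    fill = vessel & np.isfinite(est)
    out[fill] = est[fill]
    rest = vessel & ~np.isfinite(est)
    if rest.any() and good.any():
        # border pixels with no flanking pair on either axis
        _, (iy, ix) = ndimage.distance_transform_edt(~good, return_indices=True)
        out[rest] = t[iy[rest], ix[rest]]
    return out


def compose_feature_map(
    thickness_inpainted: np.ndarray,
    reflectivity: np.ndarray,
    deviation: np.ndarray,
    disc_mask: np.ndarray,
    grid: GridSpec,
    w_r: float = DEFAULT_W_R,
    reference_stats: tuple[float, float, float] | None = None,
) -> FeatureMap:
    """Combine the channels into the scalar intensity fed to segmentation."""
    t_max = float(np.max(thickness_inpainted))
    if t_max <= 0:
        raise ValueError("Tmax = 0: empty thickness map")
    scalar = (thickness_inpainted / t_max) * (w_r + (1.0 - w_r) * reflectivity)
    scalar = np.clip(scalar, 0.0, 1.0)
    scalar = np.where(disc_mask, 0.0, scalar)
    return FeatureMap(
        thickness=thickness_inpainted,
        reflectivity=reflectivity,
        deviation=deviation,
        disc_mask=np.asarray(disc_mask, bool),
        scalar_intensity=scalar,
        grid=grid,
        reference_stats=reference_stats,
    )
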