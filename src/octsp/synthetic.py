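"""Synthetic SD-OCT eyes for end-to-end testing of the analysis pipeline.

No public dataset exists for ONH-cube RNFL analysis, so every downstream
stage is exercised on generated eyes.  The generator reproduces the gross
statistical structure of real RNFL thickness maps:

* a "double hump" angular profile — thick superior and inferior arcuate
  nerve fiber bundles over a thinner temporal/nasal baseline;
* radial decay of thickness away from the disc;
* an optic disc where thickness is undefined (zero);
* curvilinear vessel shadows radiating from the disc;
* per-eye jitter of the bundle positions (the spatial variability that
  normative-atlas normalization removes);
* glaucomatous damage as focal wedge defects (multiplicative sector
  attenuation in polar coordinates) and/or diffuse thinning.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import GridSpec

# Population anatomy (angles in the package convention: 0 deg temporal,
# counter-clockwise; superior hemifield (0, 180)).
POP_BUNDLE_ANGLES = (65.0, 295.0)
BUNDLE_JITTER_SD = 7.0  # deg, eye-to-eye variation of bundle position
BUNDLE_SIGMA = 30.0  # deg, angular half-width of each bundle hump
PROFILE_FLOOR = 60.0  # um, temporal/nasal baseline at the 1.7 mm circle
BUNDLE_AMP = 100.0  # um, hump amplitude at the 1.7 mm circle
R_REF_MM = 1.7  # radius where the profile above is calibrated
RADIAL_EXP = 0.7  # thickness ~ (R_REF/r)^RADIAL_EXP
NOISE_REL_SD = 0.04  # smooth multiplicative noise field
VESSEL_SHADOW = 0.65  # thickness attenuation under a vessel shadow


@dataclass(frozen=True)
class Defect:
    """Focal wedge defect: sector attenuation about the disc centre."""

    center_angle: float  # deg
    angular_width: float  # deg, full width of the attenuated sector
    depth_fraction: float  # in [0, 1]; 1 = complete RNFL loss
    radial_extent_mm: float  # outer radius of the wedge
    radial_inner_mm: float | None = None  # defaults to the disc edge

    def __post_init__(self):
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must be in [0, 1]")
        if self.angular_width <= 0:
            raise ValueError("angular_width must be positive")


@dataclass(frozen=True)
class EyePhenotype:
    group: str = "healthy"  # healthy | suspect | glaucoma
    bundle_angles: tuple[float, float] = POP_BUNDLE_ANGLES
    defects: tuple[Defect, ...] = ()
    vessel_seed: int = 0
    global_thinning: float = 0.0

    def __post_init__(self):
        if self.group not in ("healthy", "suspect", "glaucoma"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.global_thinning <= 1.0:
            raise ValueError("global_thinning must be in [0, 1]")
        if self.group == "glaucoma" and not self.defects and self.global_thinning == 0:
            raise ValueError("glaucoma phenotype needs a defect or global thinning")


@dataclass
class RnflMapSet:
    """Registered per-eye 2D maps on the scan grid."""

    thickness: np.ndarray  # um
    reflectivity: np.ndarray  # [0, 1]
    vessel_mask: np.ndarray  # bool
    disc_mask: np.ndarray  # bool
    grid: GridSpec
    qc_flags: np.ndarray | None = None  # per-B-scan segmentation-error flags


@dataclass
class SyntheticEye:
    maps: RnflMapSet
    truth: EyePhenotype
    cube: np.ndarray | None = None  # (n, n, nz) intensities
    surfaces: tuple[np.ndarray, np.ndarray] | None = None  # (top, bottom) voxel idx


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _wedge_weight(theta: np.ndarray, center: float, width: float, taper: float = 3.0):
    """1 inside the sector, cosine-free smooth taper to 0 over ``taper`` deg."""
    d = np.abs((theta - center + 180.0) % 360.0 - 180.0)
    half = width / 2.0
    return _smoothstep((half + taper - d) / taper) * (d <= half + taper)


def _radial_band(r_mm: np.ndarray, inner: float, outer: float, taper: float = 0.15):
    lo = _smoothstep((r_mm - inner) / taper + 1.0)
    hi = _smoothstep((outer - r_mm) / taper + 1.0)
    return lo * hi


def _vessel_mask(grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    """Dilated random-walk curves radiating from the disc margin."""
    n = grid.n
    mask = np.zeros((n, n), bool)
    cy, cx = grid.center
    r0 = grid.disc_radius_px
    step = max(1.0, grid.mm_to_px(0.05))
    n_vessels = 8
    # vessels emerge near the bundles (arcuate course), a couple elsewhere
    starts = np.concatenate(
        [
            rng.normal(POP_BUNDLE_ANGLES[0], 25.0, n_vessels // 2),
            rng.normal(POP_BUNDLE_ANGLES[1], 25.0, n_vessels - n_vessels // 2),
        ]
    )
    half_w = max(1, int(round(grid.mm_to_px(0.035))))
    for ang0 in starts:
        ang = np.radians(ang0)
        y, x = cy + r0 * np.sin(ang), cx + r0 * np.cos(ang)
        heading = ang
        for _ in range(int(3.0 * n)):
            yi, xi = int(round(y)), int(round(x))
            if not (0 <= yi < n and 0 <= xi < n):
                break
            mask[
                max(0, yi - half_w) : yi + half_w + 1,
                max(0, xi - half_w) : xi + half_w + 1,
            ] = True
            heading += rng.normal(0.0, 0.18)
            # pull the heading back towards radially-outward
            out = np.arctan2(y - cy, x - cx)
            heading += 0.25 * np.angle(np.exp(1j * (out - heading)))
            y += step * np.sin(heading)
            x += step * np.cos(heading)
    return mask


def generate_eye(
    phenotype: EyePhenotype,
    grid: GridSpec | None = None,
    rng_seed: int = 0,
    make_cube: bool = False,
    cube_nz: int = 160,
) -> SyntheticEye:
    """Render one synthetic eye from its phenotype.

    The thickness model is separable in polar coordinates about the disc
    centre: ``T(r, theta) = radial(r) * profile(theta) * noise * defects``.
    Deterministic given ``rng_seed`` (the vessel pattern additionally uses
    ``phenotype.vessel_seed`` so paired eyes can share vasculature).
    """
    if grid is None:
        grid = GridSpec()
    rng = np.random.default_rng(rng_seed)
    r_px, theta = grid.polar()
    r_mm = r_px * grid.spacing_mm

    sup, inf = phenotype.bundle_angles
    prof = PROFILE_FLOOR + BUNDLE_AMP * (
        _wrapped_gauss(theta, sup, BUNDLE_SIGMA) + _wrapped_gauss(theta, inf, BUNDLE_SIGMA)
    )
    with np.errstate(divide="ignore"):
        radial = np.clip((R_REF_MM / np.maximum(r_mm, 1e-6)) ** RADIAL_EXP, 0.35, 2.2)

    noise = rng.standard_normal((grid.n, grid.n))
    noise = ndimage.gaussian_filter(noise, sigma=grid.n / 50.0)
    noise *= NOISE_REL_SD / max(noise.std(), 1e-12)
    field_ = np.clip(1.0 + noise, 0.05, None)

    thickness = prof * radial * field_

    att = np.ones_like(thickness)
    scan_r = grid.px_to_mm(grid.n / 2.0) * np.sqrt(2.0)
    for d in phenotype.defects:
        outer = d.radial_extent_mm
        if outer > scan_r:
            warnings.warn("defect radial extent exceeds the scan; clipped")
            outer = scan_r
        inner = d.radial_inner_mm if d.radial_inner_mm is not None else grid.disc_radius_mm
        w = _wedge_weight(theta, d.center_angle, d.angular_width) * _radial_band(
            r_mm, inner, outer
        )
        att *= 1.0 - d.depth_fraction * w
    att *= 1.0 - phenotype.global_thinning
    thickness *= att

    vrng = np.random.default_rng(phenotype.vessel_seed)
    vessels = _vessel_mask(grid, vrng)
    thickness = np.where(vessels, thickness * VESSEL_SHADOW, thickness)

    disc = grid.disc_mask()
    thickness = np.where(disc, 0.0, np.maximum(thickness, 0.0))
    vessels &= ~disc

    refl_noise = ndimage.gaussian_filter(
        rng.standard_normal((grid.n, grid.n)), sigma=grid.n / 60.0
    )
    refl_noise *= 0.03 / max(refl_noise.std(), 1e-12)
    reflectivity = 0.35 + 0.35 * att + refl_noise
    reflectivity = np.where(vessels, reflectivity * 0.75, reflectivity)
    reflectivity = np.where(disc, 0.0, np.clip(reflectivity, 0.0, 1.0))

    maps = RnflMapSet(
        thickness=thickness,
        reflectivity=reflectivity,
        vessel_mask=vessels,
        disc_mask=disc,
        grid=grid,
        qc_flags=np.zeros(grid.n, bool),
    )
    eye = SyntheticEye(maps=maps, truth=phenotype)
    if make_cube:
        eye.cube, eye.surfaces = _render_cube(maps, grid, cube_nz)
    return eye


def _wrapped_gauss(theta: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = (theta - center + 180.0) % 360.0 - 180.0
    return np.exp(-0.5 * (d / sigma) ** 2)


# ---------------------------------------------------------------------------
# thin 3D cubes and the two-surface segmenter used for them


def _render_cube(maps: RnflMapSet, grid: GridSpec, nz: int):
    """Cube with two intensity interfaces bounding a bright RNFL slab."""
    n = grid.n
    top = np.full((n, n), 20.0)
    thick_vox = maps.thickness / grid.axial_um
    bottom = np.clip(top + thick_vox, None, nz - 2)
    z = np.arange(nz)[None, None, :]
    slab = (z >= np.round(top)[..., None]) & (z < np.round(bottom)[..., None])
    below = z >= np.round(bottom)[..., None]
    cube = np.full((n, n, nz), 0.15)
    cube[slab] = 0.85
    cube[below] = 0.40
    # reflectivity modulates the slab brightness
    cube = np.where(slab, 0.15 + (0.85 - 0.15) * np.clip(
        maps.reflectivity[..., None] / 0.7, 0.3, 1.0), cube)
    return cube, (np.round(top).astype(int), np.round(bottom).astype(int))


def segment_synthetic_cube(
    cube: np.ndarray, grid: GridSpec | None = None, smooth_sigma: float = 1.5
):
    """Recover the two RNFL interfaces of a synthetic cube per A-scan.

    A deliberately small threshold-crossing segmenter for generated cubes
    only: the bright slab is found as the longest run of axially smoothed
    intensity above the midpoint between slab and background levels.

    Returns ``(thickness_um, reflectivity, top, bottom, qc_bad)`` where
    ``qc_bad`` flags A-scans with no detectable slab.
    """
    if grid is None:
        grid = GridSpec.for_size(cube.shape[0])
    sm = ndimage.gaussian_filter1d(cube.astype(float), smooth_sigma, axis=2)
    lo = np.percentile(sm, 5)
    hi = np.percentile(sm, 99)
    thr = 0.5 * (lo + hi)
    bright = sm > thr

    n, m, nz = cube.shape
    top = np.zeros((n, m), int)
    bottom = np.zeros((n, m), int)
    qc_bad = np.zeros((n, m), bool)
    # longest True-run per A-scan, vectorized over the lateral grid
    padded = np.zeros((n, m, nz + 2), bool)
    padded[..., 1:-1] = bright
    d = np.diff(padded.astype(np.int8), axis=2)
    for i in range(n):
        for j in range(m):
            starts = np.flatnonzero(d[i, j] == 1)
            ends = np.flatnonzero(d[i, j] == -1)
            if starts.size == 0:
                qc_bad[i, j] = True
                continue
            k = np.argmax(ends - starts)
            top[i, j], bottom[i, j] = starts[k], ends[k]
    thickness = (bottom - top) * grid.axial_um
    thickness[qc_bad] = 0.0

    from .featuremap import rnfl_reflectivity

    refl, refl_bad = rnfl_reflectivity(cube, top, bottom)
    return thickness, refl, top, bottom, qc_bad | refl_bad


# ---------------------------------------------------------------------------
# cohorts


#: severity distributions per clinical group (chosen once; see docs/methods.md)
DEFAULT_COHORT_CONFIG = {
    "suspect_defect_prob": 0.7,
    "suspect_depth": (0.25, 0.45),
    "suspect_width": (12.0, 25.0),
    "suspect_thinning": (0.05, 0.12),
    "glaucoma_depth": (0.55, 0.95),
    "glaucoma_width": (30.0, 60.0),
    "glaucoma_thinning": (0.05, 0.25),
    "defect_extent_mm": (1.8, 3.0),
    "defect_inner_mm": None,  # None -> disc edge
    "two_defect_prob": 0.4,  # glaucoma only
}


def _sample_defect(rng, depth_rng, width_rng, cfg) -> Defect:
    # defects are arcuate: centred near one of the two bundles
    bundle = rng.choice(POP_BUNDLE_ANGLES)
    center = bundle + rng.choice([-1.0, 1.0]) * rng.uniform(5.0, 35.0)
    return Defect(
        center_angle=center % 360.0,
        angular_width=rng.uniform(*width_rng),
        depth_fraction=rng.uniform(*depth_rng),
        radial_extent_mm=rng.uniform(*cfg["defect_extent_mm"]),
        radial_inner_mm=cfg["defect_inner_mm"],
    )


def sample_phenotype(group: str, rng: np.random.Generator, config=None) -> EyePhenotype:
    cfg = dict(DEFAULT_COHORT_CONFIG)
    if config:
        cfg.update(config)
    angles = (
        rng.normal(POP_BUNDLE_ANGLES[0], BUNDLE_JITTER_SD),
        rng.normal(POP_BUNDLE_ANGLES[1], BUNDLE_JITTER_SD),
    )
    vessel_seed = int(rng.integers(0, 2**31 - 1))
    defects: tuple[Defect, ...] = ()
    thinning = 0.0
    if group == "suspect":
        if rng.random() < cfg["suspect_defect_prob"]:
            defects = (
                _sample_defect(rng, cfg["suspect_depth"], cfg["suspect_width"], cfg),
            )
        else:
            thinning = rng.uniform(*cfg["suspect_thinning"])
    elif group == "glaucoma":
        k = 2 if rng.random() < cfg["two_defect_prob"] else 1
        defects = tuple(
            _sample_defect(rng, cfg["glaucoma_depth"], cfg["glaucoma_width"], cfg)
            for _ in range(k)
        )
        thinning = rng.uniform(*cfg["glaucoma_thinning"])
    return EyePhenotype(
        group=group,
        bundle_angles=angles,
        defects=defects,
        vessel_seed=vessel_seed,
        global_thinning=thinning,
    )


def generate_cohort(
    n_per_group: tuple[int, int, int],
    grid: GridSpec | None = None,
    config=None,
    rng_seed: int = 0,
) -> list[SyntheticEye]:
    """Synthetic study cohort: (healthy, suspect, glaucoma) eyes in order."""
    if any(n < 1 for n in n_per_group):
        raise ValueError("need at least one eye per group")
    rng = np.random.default_rng(rng_seed)
    eyes = []
    for group, n_g in zip(("healthy", "suspect", "glaucoma"), n_per_group):
        for _ in range(n_g):
            ph = sample_phenotype(group, rng, config)
            eyes.append(generate_eye(ph, grid, rng_seed=int(rng.integers(0, 2**31 - 1))))
    return eyes
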