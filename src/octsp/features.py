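"""The 68 superpixel features summarizing a segmented RNFL map.

Decomposition: 9 counts + 16 moment features + 40 histogram-bin values +
3 global thickness averages.

* Counts: total number of superpixels; small superpixels
  (``Tmin < size < T1``); large superpixels (``size > T2``); segments with
  mean thickness in [0, 30), [75, 120), [120, 165) um; segments with size
  in [30, 120), [360, 420), [420, 540) px.
* Moments (mean, (n-1) SD, standardized skewness m3/s^3, standardized
  kurtosis m4/s^4, non-excess) for four groups: segment thickness (all),
  segment size (all), segment thickness of the small group, segment
  thickness of the large group.
* Histograms: 20 equal-width bins of segment mean thickness over
  [0, 165] um and 20 bins of segment size over [0, 600] px, normalized to
  segment-count fractions.
* Global averages: mean thickness on the 3.4 mm circle, over the whole
  scan, and over the scan excluding the disc.

Size thresholds are defined on the 200 x 200 grid and scale with pixel
area for other grid sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grid import GridSpec, sample_map
from .superpixel import SuperPixelMap

CP_CIRCLE_DIAMETER_MM = 3.4
CP_CIRCLE_POINTS = 256

THICKNESS_RANGES_UM = ((0.0, 30.0), (75.0, 120.0), (120.0, 165.0))
SIZE_RANGES_PX = ((30.0, 120.0), (360.0, 420.0), (420.0, 540.0))
THICKNESS_HIST_MAX_UM = 165.0
SIZE_HIST_MAX_PX = 600.0
N_BINS = 20


@dataclass(frozen=True)
class SizeThresholds:
    t_min: float = 50.0
    t1: float = 133.0
    t2: float = 400.0
    area_scale: float = 1.0  # (grid_n / 200)^2

    def __post_init__(self):
        if not self.t_min < self.t1 < self.t2:
            raise ValueError("need t_min < t1 < t2")

    @classmethod
    def for_grid(cls, n: int) -> "SizeThresholds":
        a = (n / 200.0) ** 2
        return cls(t_min=50.0 * a, t1=133.0 * a, t2=400.0 * a, area_scale=a)


def _moment4(values: np.ndarray) -> tuple[float, float, float, float, bool]:
    """(mean, sample SD, skewness, kurtosis, flagged) of a value list.

    Skewness/kurtosis use population central moments (m3/s^3, m4/s^4,
    non-excess).  Empty groups give all zeros; single-member groups give
    zero spread/shape; both are flagged.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        return 0.0, 0.0, 0.0, 0.0, True
    if v.size == 1:
        return float(v[0]), 0.0, 0.0, 0.0, True
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if np.isclose(v.std(), 0.0):
        return m, sd, 0.0, 0.0, True
    skew = float(sps.skew(v, bias=True))
    kurt = float(sps.kurtosis(v, fisher=False, bias=True))
    return m, sd, skew, kurt, False


def count_features(spm: SuperPixelMap, th: SizeThresholds) -> np.ndarray:
    """The 9 count features (interval convention [lo, hi) for ranges)."""
    sizes = np.array([s.size for s in spm.segments], float)
    means = np.array([s.mean_t for s in spm.segments], float)
    a = th.area_scale
    counts = [
        len(spm.segments),
        int(np.sum((sizes > th.t_min) & (sizes < th.t1))),
        int(np.sum(sizes > th.t2)),
    ]
    for lo, hi in THICKNESS_RANGES_UM:
        counts.append(int(np.sum((means >= lo) & (means < hi))))
    for lo, hi in SIZE_RANGES_PX:
        counts.append(int(np.sum((sizes >= lo * a) & (sizes < hi * a))))
    return np.array(counts, float)


def moment_features(spm: SuperPixelMap, th: SizeThresholds) -> np.ndarray:
    """The 16 moment features (4 moments x 4 groups)."""
    sizes = np.array([s.size for s in spm.segments], float)
    means = np.array([s.mean_t for s in spm.segments], float)
    small = (sizes > th.t_min) & (sizes < th.t1)
    large = sizes > th.t2
    out = []
    for vals in (means, sizes, means[small], means[large]):
        out.extend(_moment4(vals)[:4])
    return np.array(out, float)


def histogram_features(spm: SuperPixelMap, th: SizeThresholds | None = None) -> np.ndarray:
    """The 40 normalized histogram bins (20 thickness + 20 size)."""
    a = th.area_scale if th is not None else 1.0
    sizes = np.array([s.size for s in spm.segments], float)
    means = np.array([s.mean_t for s in spm.segments], float)
    out = []
    for vals, vmax in ((means, THICKNESS_HIST_MAX_UM), (sizes, SIZE_HIST_MAX_PX * a)):
        if len(vals) and (vals.min() < 0 or vals.max() >= vmax):
            warnings.warn("histogram value beyond range; clipped into end bin")
        clipped = np.clip(vals, 0.0, np.nextafter(vmax, 0.0))
        h, _ = np.histogram(clipped, bins=N_BINS, range=(0.0, vmax))
        out.append(h / max(1, len(vals)))
    return np.concatenate(out)


def global_thickness_features(
    thickness_map: np.ndarray, disc_mask: np.ndarray, grid: GridSpec
) -> np.ndarray:
    """Mean thickness on the 3.4 mm circle, whole scan, and scan minus disc."""
    r_px = grid.mm_to_px(CP_CIRCLE_DIAMETER_MM / 2.0)
    cy, cx = grid.center
    if (
        cy - r_px < 0 or cx - r_px < 0
        or cy + r_px > grid.n - 1 or cx + r_px > grid.n - 1
    ):
        raise ValueError("3.4 mm circle exits the scan grid")
    angles = np.arange(CP_CIRCLE_POINTS) * (360.0 / CP_CIRCLE_POINTS)
    rows, cols = grid.circle_points(r_px, angles)
    circle_mean = float(sample_map(thickness_map, rows, cols).mean())
    whole = float(np.mean(thickness_map))
    outside = float(np.mean(thickness_map[~disc_mask]))
    return np.array([circle_mean, whole, outside])


def feature_names(n_bins: int = N_BINS) -> list[str]:
    names = [
        "n_sp_total",
        "n_sp_small",
        "n_sp_large",
        "n_sp_thickness_0_30",
        "n_sp_thickness_75_120",
        "n_sp_thickness_120_165",
        "n_sp_size_30_120",
        "n_sp_size_360_420",
        "n_sp_size_420_540",
    ]
    for group in ("thickness_all", "size_all", "thickness_small", "thickness_large"):
        names += [f"{group}_{m}" for m in ("mean", "sd", "skew", "kurt")]
    names += [f"hist_thickness_bin{i:02d}" for i in range(n_bins)]
    names += [f"hist_size_bin{i:02d}" for i in range(n_bins)]
    names += ["mean_cp_circle", "mean_scan", "mean_scan_no_disc"]
    return names


FEATURE_NAMES = feature_names()


def extract_all(
    spm: SuperPixelMap,
    thickness_map: np.ndarray,
    disc_mask: np.ndarray,
    th: SizeThresholds | None = None,
) -> np.ndarray:
    """Full 68-value feature vector, in ``FEATURE_NAMES`` order."""
    if th is None:
        th = SizeThresholds.for_grid(spm.grid.n)
    vec = np.concatenate(
        [
            count_features(spm, th),
            moment_features(spm, th),
            histogram_features(spm, th),
            global_thickness_features(thickness_map, disc_mask, spm.grid),
        ]
    )
    assert vec.size == len(FEATURE_NAMES) == 68
    return vec
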