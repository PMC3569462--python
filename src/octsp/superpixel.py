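"""Variable-size superpixel segmentation by recursive normalized cuts.

The feature map is first partitioned into ``k_init`` (default 100)
superpixels by k-way spectral normalized cuts.  Each superpixel is then
recursively re-partitioned: a segment that is thick and homogeneous is left
alone, while thin, heterogeneous or normative-deviant segments are split
into many small pieces, so damaged regions end up covered by small
superpixels and normal regions by large ones.

The number of extra parts for a segment with size ``S``, mean thickness
``mT``, thickness SD ``sT`` and mean deviation ``D`` (against the map-wide
mean ``mu``, SD ``sigma`` and maximum ``Tmax``) is::

    S < 2 * S_min                -> N = 0
    mT >= mu  (thick branch)     -> N = round(C_thick * S/S_min * sT/sigma)
                                    if sT > sigma else 0
    mT <  mu  (thin branch)      -> N = round(C_thin * S/S_min * ((1 - mT/Tmax) + D))

capped at ``floor(S / (2 * S_min))``; the segment is re-cut into ``N + 1``
connected parts.  ``C_thick = 0.2`` keeps thick regions coarse,
``C_thin = 1.2`` forces thin regions into many small segments.

The ncut "stability" parameter is mapped onto the spatial-coherence weight
of the k-means discretization (``lambda_c = 0.01 / |stability|``): the
initial value -0.1 gives flexible boundaries, the recursive value -0.006
compact, smooth segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .featuremap import FeatureMap
from .grid import GridSpec


@dataclass(frozen=True)
class SegmentationParams:
    k_init: int = 100
    stability_init: float = -0.1
    stability_recursive: float = -0.006
    s_min: int = 50  # px, minimal superpixel size (200 x 200 grid)
    c_thick: float = 0.2
    c_thin: float = 1.2
    affinity_radius: float = 3.0  # px
    sigma_intensity: float = 0.1
    sigma_spatial: float = 4.0
    max_iter: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k_init < 1 or self.s_min < 1:
            raise ValueError("k_init and s_min must be >= 1")
        if self.stability_init >= 0 or self.stability_recursive >= 0:
            raise ValueError("stabilities must be negative")

    @classmethod
    def for_grid(cls, n: int, **kw) -> "SegmentationParams":
        """Scale pixel-count parameters to an ``n x n`` grid (reference 200)."""
        area = (n / 200.0) ** 2
        kw.setdefault("s_min", max(2, int(round(50 * area))))
        kw.setdefault("affinity_radius", 3.0 if n >= 150 else 2.0)
        return cls(**kw)


@dataclass
class SuperPixel:
    label: int
    size: int
    mean_t: float
    sd_t: float
    mean_dev: float


@dataclass
class SuperPixelMap:
    """Integer label image (0 = outside region, labels 1..K) + statistics."""

    labels: np.ndarray
    segments: list[SuperPixel]
    mu_map: float  # mean thickness over the evaluable region
    sigma_map: float  # SD of thickness over the evaluable region
    t_max: float
    grid: GridSpec

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def segment_stats(
    labels: np.ndarray, thickness: np.ndarray, deviation: np.ndarray
) -> list[SuperPixel]:
    """Per-segment size / mean / SD / mean-deviation from the label image."""
    lab = labels.ravel()
    inside = lab > 0
    lab = lab[inside]
    t = thickness.ravel()[inside]
    d = deviation.ravel()[inside]
    k = lab.max() if lab.size else 0
    size = np.bincount(lab, minlength=k + 1)[1:]
    sum_t = np.bincount(lab, weights=t, minlength=k + 1)[1:]
    sum_d = np.bincount(lab, weights=d, minlength=k + 1)[1:]
    with np.errstate(invalid="ignore"):
        mean_t = np.where(size > 0, sum_t / np.maximum(size, 1), 0.0)
    # two-pass variance: stable when a segment is near-constant
    centered2 = (t - mean_t[lab - 1]) ** 2
    sum_c2 = np.bincount(lab, weights=centered2, minlength=k + 1)[1:]
    out = []
    for i in range(k):
        n = int(size[i])
        if n == 0:
            continue
        out.append(
            SuperPixel(
                label=i + 1,
                size=n,
                mean_t=float(mean_t[i]),
                sd_t=float(np.sqrt(sum_c2[i] / n)),
                mean_dev=float(sum_d[i] / n),
            )
        )
    return out


# ---------------------------------------------------------------------------
# affinity graph


def build_affinity(
    intensity: np.ndarray,
    region_mask: np.ndarray,
    params: SegmentationParams,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse pixel-affinity graph on the masked region.

    ``W(p, q) = exp(-(I_p - I_q)^2 / sigma_I^2) * exp(-|p - q|^2 / sigma_X^2)``
    for ``|p - q| <= r``, zero otherwise and on the diagonal.  Disconnected
    regions are bridged by nearest-pixel edges (with a warning) so the
    spectral solver sees one component.

    Returns ``(W, coords)`` where ``coords`` is the (n_nodes, 2) array of
    (row, col) positions defining node order.
    """
    mask = np.asarray(region_mask, bool)
    h, w = mask.shape
    idx = -np.ones((h, w), np.int64)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(len(coords))
    inten = np.asarray(intensity, float)

    r = params.affinity_radius
    ri = int(np.floor(r))
    rows, cols, vals = [], [], []
    for dy in range(0, ri + 1):
        for dx in range(-ri, ri + 1):
            if dy == 0 and dx <= 0:
                continue  # each unordered pair once
            if dy * dy + dx * dx > r * r:
                continue
            a = idx[: h - dy, :]
            b = idx[dy:, :]
            ia = inten[: h - dy, :]
            ib = inten[dy:, :]
            if dx > 0:
                a, ia = a[:, : w - dx], ia[:, : w - dx]
                b, ib = b[:, dx:], ib[:, dx:]
            elif dx < 0:
                a, ia = a[:, -dx:], ia[:, -dx:]
                b, ib = b[:, : w + dx], ib[:, : w + dx]
            m = (a >= 0) & (b >= 0)
            if not m.any():
                continue
            wgt = np.exp(
                -((ia[m] - ib[m]) ** 2) / params.sigma_intensity**2
            ) * np.exp(-(dy * dy + dx * dx) / params.sigma_spatial**2)
            rows.append(a[m])
            cols.append(b[m])
            vals.append(wgt)
    n = len(coords)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:
        rows = cols = np.zeros(0, np.int64)
        vals = np.zeros(0)
    W = sp.coo_matrix(
        (np.r_[vals, vals], (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n)
    ).tocsr()

    n_comp, comp = csgraph.connected_components(W, directed=False)
    if n_comp > 1:
        warnings.warn(f"region has {n_comp} components; bridging")
        bridges_r, bridges_c = [], []
        main = comp == np.bincount(comp).argmax()
        tree = cKDTree(coords[main])
        main_idx = np.flatnonzero(main)
        for c in range(n_comp):
            sel = comp == c
            if sel[main].all() or not sel.any() or (sel & main).any():
                continue
            d, j = tree.query(coords[sel])
            k = np.argmin(d)
            bridges_r.append(np.flatnonzero(sel)[k])
            bridges_c.append(main_idx[j[k]])
        if bridges_r:
            B = sp.coo_matrix(
                (
                    np.full(2 * len(bridges_r), 1e-3),
                    (np.r_[bridges_r, bridges_c], np.r_[bridges_c, bridges_r]),
                ),
                shape=(n, n),
            )
            W = (W + B).tocsr()
    return W, coords


# ---------------------------------------------------------------------------
# spectral k-way partition with weighted k-means discretization


def _weighted_kmeans(X, weights, k, rng, n_iter=60, tol=1e-7):
    """Seeded k-means++ with sample weights; returns labels."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    p = weights / weights.sum()
    centers[0] = X[rng.choice(n, p=p)]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for j in range(1, k):
        pj = weights * d2
        s = pj.sum()
        centers[j] = X[rng.choice(n, p=pj / s) if s > 0 else rng.integers(n)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(1))
    prev = np.inf
    for _ in range(n_iter):
        d = ((X[:, None, :] - centers[None]) ** 2).sum(-1) if n * k * X.shape[1] < 2e7 \
            else (X * X).sum(1)[:, None] - 2 * X @ centers.T + (centers * centers).sum(1)[None]
        lab = np.argmin(d, axis=1)
        obj = float((weights * d[np.arange(n), lab]).sum())
        for j in range(k):
            sel = lab == j
            wj = weights[sel]
            if wj.sum() > 0:
                centers[j] = np.average(X[sel], axis=0, weights=wj)
            else:  # re-seed empty cluster at the worst-fit point
                centers[j] = X[np.argmax(weights * d[np.arange(n), lab])]
        if prev - obj <= tol * max(1.0, abs(prev)):
            break
        prev = obj
    return lab


def _spectral_embedding(W: sp.csr_matrix, k: int) -> np.ndarray:
    """First k generalized eigenvectors of (D - W) x = lam D x."""
    n = W.shape[0]
    d = np.asarray(W.sum(axis=1)).ravel()
    d = np.maximum(d, 1e-12)
    dmh = 1.0 / np.sqrt(d)
    A = sp.diags(dmh) @ W @ sp.diags(dmh)
    if n <= 800 or k >= n - 1:
        evals, evecs = np.linalg.eigh(A.toarray())
        U = evecs[:, -k:]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector: deterministic
        try:
            _, U = spl.eigsh(A, k=k, which="LA", v0=v0)
        except spl.ArpackError:
            A = A + sp.eye(n) * 1e-8
            _, U = spl.eigsh(A, k=k, which="LA", v0=v0)
    V = U * dmh[:, None]
    norms = np.linalg.norm(V, axis=0)
    return V / np.maximum(norms, 1e-12)


def _components_of(lab, Wb, keep=None):
    """Connected components of the graph restricted to same-label edges."""
    same = lab[Wb.row] == lab[Wb.col]
    if keep is not None:
        same = same & keep
    sub = sp.coo_matrix((Wb.data[same], (Wb.row[same], Wb.col[same])), shape=(len(lab),) * 2)
    _, comp = csgraph.connected_components(sub, directed=False)
    _, comp = np.unique(comp, return_inverse=True)
    return comp


def _connected_relabel(lab, W, coords, k, weights):
    """Split k-means labels into connected components, then merge/split to k."""
    n = len(lab)
    Wb = W.tocoo()
    # enforce connectivity in the 8-neighbour sense, not just within the
    # (longer-range) affinity radius; fall back to the full edge set when
    # the region itself is only connected through bridge edges
    adj = np.abs(coords[Wb.row] - coords[Wb.col]).max(axis=1) <= 1
    if _components_of(np.zeros(n, int), Wb, adj).max() > _components_of(
        np.zeros(n, int), Wb
    ).max():
        adj = None
    comp = _components_of(lab, Wb, adj)
    for _ in range(4 * n):  # safety bound; each step moves |n_comp - k| by 1
        n_comp = comp.max() + 1
        if n_comp == k:
            break
        if n_comp > k:
            # merge the smallest component into its strongest neighbour,
            # considering only 8-adjacent components so merged segments
            # stay connected in the pixel sense
            S = sp.coo_matrix(
                (np.ones(n), (np.arange(n), comp)), shape=(n, n_comp)
            ).tocsr()
            if adj is not None:
                Wa = sp.coo_matrix(
                    (Wb.data[adj], (Wb.row[adj], Wb.col[adj])), shape=W.shape
                )
                A = (S.T @ Wa @ S).toarray()
            else:
                A = (S.T @ W @ S).toarray()
            np.fill_diagonal(A, 0.0)
            sizes = np.bincount(comp, minlength=n_comp)
            small = int(np.argmin(sizes))
            row = A[small]
            if row.max() > 0:
                target = int(np.argmax(row))
            else:  # no boundary affinity: nearest centroid
                cy = coords[comp == small].mean(0)
                cents = np.array(
                    [coords[comp == c].mean(0) for c in range(n_comp)]
                )
                d = np.linalg.norm(cents - cy, axis=1)
                d[small] = np.inf
                target = int(np.argmin(d))
            comp[comp == small] = target
            _, comp = np.unique(comp, return_inverse=True)
        else:
            # split the largest component across its widest coordinate
            sizes = np.bincount(comp, minlength=n_comp)
            big = int(np.argmax(sizes))
            if sizes[big] < 2:
                break
            sel = comp == big
            pts = coords[sel].astype(float)
            axis = int(np.argmax(np.ptp(pts, axis=0)))
            med = np.median(pts[:, axis])
            half = pts[:, axis] > med
            if not half.any() or half.all():
                order = np.argsort(pts[:, axis], kind="stable")
                half = np.zeros(len(pts), bool)
                half[order[len(order) // 2 :]] = True
            tmp = comp.copy()
            tmp[np.flatnonzero(sel)[half]] = n_comp
            comp = _components_of(tmp, Wb, adj)
    return comp


def ncut_segment(
    W: sp.csr_matrix,
    coords: np.ndarray,
    k: int,
    stability: float,
    seed: int = 0,
) -> np.ndarray:
    """k-way normalized-cut partition of the affinity graph.

    Spectral relaxation (k smallest generalized eigenvectors of the
    normalized Laplacian) discretized by weighted k-means whose feature
    space appends spatial coordinates with weight
    ``lambda_c = 0.01 / |stability|``; connectivity is then enforced and
    the partition adjusted to exactly ``k`` connected segments.
    Deterministic given ``seed``.  Returns labels in ``0..k-1`` per node.
    """
    n = W.shape[0]
    if k > n:
        raise ValueError("k exceeds number of nodes")
    if k == 1:
        return np.zeros(n, int)
    if k == n:
        return np.arange(n)
    V = _spectral_embedding(W, k)
    lam_c = 0.01 / abs(stability)
    xy = coords.astype(float)
    xy = xy - xy.mean(0)
    nrm = np.linalg.norm(xy, axis=0)
    xy = xy / np.maximum(nrm, 1e-12)
    X = np.hstack([V, lam_c * xy])
    d = np.asarray(W.sum(axis=1)).ravel()
    rng = np.random.default_rng(seed)
    lab = _weighted_kmeans(X, np.maximum(d, 1e-12), k, rng)
    return _connected_relabel(lab, W, coords, k, d)


def ncut_value(W: np.ndarray | sp.spmatrix, labels: np.ndarray) -> float:
    """Normalized-cut objective of a partition (any number of segments)."""
    W = sp.csr_matrix(W)
    labels = np.asarray(labels)
    d = np.asarray(W.sum(axis=1)).ravel()
    total = 0.0
    for s in np.unique(labels):
        sel = labels == s
        assoc = d[sel].sum()
        within = W[sel][:, sel].sum()
        if assoc <= 0:
            return np.inf
        total += (assoc - within) / assoc
    return float(total)


# ---------------------------------------------------------------------------
# the variable-size partition rule


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def partition_count_raw(
    sp_stats: SuperPixel, mu_map: float, sigma_map: float, t_max: float,
    params: SegmentationParams,
) -> int:
    """The branch formula before the size cap (see module docstring)."""
    s_ratio = sp_stats.size / params.s_min
    if sp_stats.mean_t >= mu_map:
        if sigma_map <= 0 or sp_stats.sd_t <= sigma_map:
            return 0
        return _round_half_away(params.c_thick * s_ratio * sp_stats.sd_t / sigma_map)
    if t_max <= 0:
        return 0
    thin = (1.0 - sp_stats.mean_t / t_max) + sp_stats.mean_dev
    return _round_half_away(params.c_thin * s_ratio * thin)


def partition_count(
    sp_stats: SuperPixel, mu_map: float, sigma_map: float, t_max: float,
    params: SegmentationParams,
) -> int:
    """Number of *additional* superpixels a segment is split into."""
    if sp_stats.size < 2 * params.s_min:
        return 0
    cap = sp_stats.size // (2 * params.s_min)
    return int(np.clip(partition_count_raw(sp_stats, mu_map, sigma_map, t_max, params), 0, cap))


# ---------------------------------------------------------------------------
# initial segmentation + recursive refinement


def initial_segmentation(
    fm: FeatureMap, params: SegmentationParams | None = None
) -> tuple[SuperPixelMap, sp.csr_matrix, np.ndarray]:
    """ncut into ``k_init`` superpixels on the evaluable (non-disc) region.

    Returns the map plus the affinity graph and node coordinates so
    refinement can reuse them.
    """
    if params is None:
        params = SegmentationParams.for_grid(fm.grid.n)
    region = ~fm.disc_mask
    if region.sum() < params.k_init:
        raise ValueError("region smaller than k_init")
    W, coords = build_affinity(fm.scalar_intensity, region, params)
    lab = ncut_segment(W, coords, params.k_init, params.stability_init, params.seed)
    labels = np.zeros(fm.scalar_intensity.shape, int)
    labels[coords[:, 0], coords[:, 1]] = lab + 1
    if fm.reference_stats is not None:
        mu, sigma, t_max = fm.reference_stats
    else:
        t = fm.thickness[region]
        mu, sigma, t_max = float(t.mean()), float(t.std()), float(t.max())
    spm = SuperPixelMap(
        labels=labels,
        segments=segment_stats(labels, fm.thickness, fm.deviation),
        mu_map=mu,
        sigma_map=sigma,
        t_max=t_max,
        grid=fm.grid,
    )
    return spm, W, coords


def recursive_refine(
    spm: SuperPixelMap,
    fm: FeatureMap,
    params: SegmentationParams | None = None,
    W: sp.csr_matrix | None = None,
    coords: np.ndarray | None = None,
) -> SuperPixelMap:
    """Recursively split segments until the partition rule is satisfied.

    Each pass re-cuts every segment with ``partition_count >= 1`` into
    ``N + 1`` parts with the compact (recursive) stability, until no
    segment wants to split or ``max_iter`` passes elapse.
    """
    if params is None:
        params = SegmentationParams.for_grid(fm.grid.n)
    if W is None or coords is None:
        W, coords = build_affinity(fm.scalar_intensity, spm.labels > 0, params)
    node_label = spm.labels[coords[:, 0], coords[:, 1]].copy()
    rng = np.random.default_rng(params.seed + 1)

    for it in range(params.max_iter):
        segs = segment_stats(
            _labels_image(node_label, coords, fm.grid.n), fm.thickness, fm.deviation
        )
        split_any = False
        next_label = node_label.max() + 1
        for s in segs:
            n_split = partition_count(s, spm.mu_map, spm.sigma_map, spm.t_max, params)
            if n_split < 1:
                continue
            sel = np.flatnonzero(node_label == s.label)
            k_parts = min(n_split + 1, len(sel))
            if k_parts < 2:
                continue
            Wsub = W[sel][:, sel]
            sub_lab = ncut_segment(
                Wsub,
                coords[sel],
                k_parts,
                params.stability_recursive,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            node_label[sel[sub_lab > 0]] = next_label + sub_lab[sub_lab > 0] - 1
            next_label += k_parts - 1
            split_any = True
        if not split_any:
            break
    else:
        warnings.warn("recursive refinement hit max_iter without converging")

    # contiguous labels 1..K
    _, node_label = np.unique(node_label, return_inverse=True)
    node_label += 1
    labels = _labels_image(node_label, coords, fm.grid.n)
    return SuperPixelMap(
        labels=labels,
        segments=segment_stats(labels, fm.thickness, fm.deviation),
        mu_map=spm.mu_map,
        sigma_map=spm.sigma_map,
        t_max=spm.t_max,
        grid=fm.grid,
    )


def _labels_image(node_label: np.ndarray, coords: np.ndarray, n: int) -> np.ndarray:
    img = np.zeros((n, n), int)
    img[coords[:, 0], coords[:, 1]] = node_label
    return img


def segment_feature_map(
    fm: FeatureMap, params: SegmentationParams | None = None
) -> SuperPixelMap:
    """Initial 100-superpixel ncut followed by recursive refinement."""
    if params is None:
        params = SegmentationParams.for_grid(fm.grid.n)
    spm, W, coords = initial_segmentation(fm, params)
    return recursive_refine(spm, fm, params, W, coords)
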