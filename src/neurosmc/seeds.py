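"""Seed extraction: multiscale tubularity, maxima selection, suppression.

Tracing is initialized at points with a high probability of lying on the
centerline of a neuron branch.  Tubularity is scored per voxel from the
eigenvalues of the Gaussian-scale Hessian (the classic vesselness
construction): for a bright tube on a dark background the two eigenvalues
across the tube are large and negative while the one along it is near
zero.  The best scale and the axial eigenvector are kept per voxel.
Candidate seeds are noise-tolerant local maxima of the tubularity map,
thinned by non-maximum suppression in oriented cylindrical neighborhoods
and finally vetted by the same cylindrical-template correlation the
tracer uses for termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .template import zncc

__all__ = [
    "Seed",
    "SeedParams",
    "TubularityMap",
    "hessian_eigen",
    "frangi_tubularity",
    "multiscale_tubularity",
    "find_maxima_3d",
    "cylindrical_nms",
    "filter_seeds",
    "extract_seeds",
]


@dataclass
class Seed:
    """Tracer initialization: position, axial unit direction, scale."""

    p: np.ndarray  # (x, y, z)
    v: np.ndarray  # unit direction
    sigma: float
    tubularity: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        n = np.linalg.norm(self.v)
        if n == 0:
            raise ValueError("seed direction must be nonzero")
        self.v = self.v / n


@dataclass
class SeedParams:
    """scales: Gaussian sigmas (voxels) probed by the multiscale filter.
    tau: noise tolerance on the 8-bit-scaled tubularity map.
    alpha, beta: vesselness plate/blob sensitivity constants.
    c_frac: the structureness constant c is this fraction of the maximum
    Hessian norm at each scale.
    c_min: template-correlation threshold shared with tracer termination.
    """

    scales: tuple[float, ...] = (2.0, 4.0, 6.0)
    tau: float = 10.0
    alpha: float = 0.5
    beta: float = 0.5
    c_frac: float = 0.5
    c_min: float = 0.5
    use_frobenius: bool = False

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("scales must be nonempty")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class TubularityMap:
    value: np.ndarray  # (nz, ny, nx) in [0, 1]
    scale: np.ndarray  # (nz, ny, nx) best sigma
    direction: np.ndarray  # (nz, ny, nx, 3) axial unit vectors (x, y, z)


def hessian_eigen(
    volume: np.ndarray,
    sigma: float,
    voxel_aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the scale-normalized Gaussian Hessian.

    Second derivatives of the image smoothed at scale ``sigma`` are
    computed by separable Gaussian-derivative filtering (multiplied by
    sigma^2 for cross-scale comparability, the standard gamma
    normalization); the derivative scale along z is divided by the
    z-aspect.  Returns eigenvalues sorted by absolute value,
    |l1| <= |l2| <= |l3|, shape (..., 3), and the matching eigenvectors in
    (x, y, z) components, shape (..., 3, 3), with ``vecs[..., i, :]`` the
    eigenvector of ``lams[..., i]``.
    """
    if sigma < 0.5:
        raise ValueError("sigma below 0.5 voxel degenerates derivative kernels")
    vol = np.asarray(volume, dtype=float)
    z_aspect = float(voxel_aspect[2]) / float(voxel_aspect[0])
    sig = (sigma / z_aspect, sigma, sigma)  # (z, y, x)
    # orders are (z, y, x); axis x=2, y=1, z=0
    d = {}
    for name, orders in {
        "xx": (0, 0, 2),
        "yy": (0, 2, 0),
        "zz": (2, 0, 0),
        "xy": (0, 1, 1),
        "xz": (1, 0, 1),
        "yz": (1, 1, 0),
    }.items():
        d[name] = ndimage.gaussian_filter(vol, sigma=sig, order=orders) * sigma**2
    H = np.empty(vol.shape + (3, 3))
    H[..., 0, 0] = d["xx"]
    H[..., 1, 1] = d["yy"]
    H[..., 2, 2] = d["zz"]
    H[..., 0, 1] = H[..., 1, 0] = d["xy"]
    H[..., 0, 2] = H[..., 2, 0] = d["xz"]
    H[..., 1, 2] = H[..., 2, 1] = d["yz"]
    lams, vecs = np.linalg.eigh(H)  # ascending eigenvalues; vecs columns
    order = np.argsort(np.abs(lams), axis=-1)
    lams = np.take_along_axis(lams, order, axis=-1)
    # reorder columns, then transpose so vecs[..., i, :] matches lams[..., i]
    vecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
    vecs = np.swapaxes(vecs, -1, -2)
    return lams, vecs


def frangi_tubularity(
    l1: np.ndarray,
    l2: np.ndarray,
    l3: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    c: float = 1.0,
    use_frobenius: bool = False,
) -> np.ndarray:
    """Three-factor vesselness from abs-sorted Hessian eigenvalues.

    Zero wherever l2 > 0 or l3 > 0 (bright-on-dark tubes only), otherwise
    (1 - exp(-Ra^2/2a^2)) * exp(-Rb^2/2b^2) * (1 - exp(-S^2/2c^2)) with
    Ra = |l2|/|l3|, Rb = |l1|/sqrt(|l2 l3|) and S = sqrt(l1^2 + l2^2)
    (optionally the full Frobenius norm including l3).  Division guards
    return 0 instead of NaN.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    eps = np.finfo(float).tiny
    ra = np.abs(l2) / np.maximum(np.abs(l3), eps)
    rb = np.abs(l1) / np.maximum(np.sqrt(np.abs(l2 * l3)), eps)
    if use_frobenius:
        s2 = l1**2 + l2**2 + l3**2
    else:
        s2 = l1**2 + l2**2
    c = max(float(c), eps)
    ups = (
        (1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
        * np.exp(-(rb**2) / (2 * beta**2))
        * (1.0 - np.exp(-s2 / (2 * c**2)))
    )
    ups = np.where((l2 > 0) | (l3 > 0) | (l3 == 0), 0.0, ups)
    return ups


def multiscale_tubularity(
    volume: np.ndarray,
    params: SeedParams,
    voxel_aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> TubularityMap:
    """Per-voxel maximum tubularity over scales with argmax scale/direction.

    The structureness constant c is ``c_frac`` times the maximum Hessian
    norm (the S statistic) over the whole scale set.  Sharing one c across
    scales keeps the third vesselness factor commensurable between scales,
    which makes the per-voxel scale argmax well-behaved; a per-scale c
    renders the factor scale-relative and lets noise flip near-ties toward
    too-large scales.
    """
    vol = np.asarray(volume, dtype=float)
    best = np.zeros(vol.shape)
    best_scale = np.full(vol.shape, params.scales[0], dtype=float)
    best_dir = np.zeros(vol.shape + (3,))
    best_dir[..., 2] = 1.0
    per_scale = []
    s_max = 0.0
    for sigma in params.scales:
        lams, vecs = hessian_eigen(vol, sigma, voxel_aspect)
        l1, l2, l3 = lams[..., 0], lams[..., 1], lams[..., 2]
        if params.use_frobenius:
            s = np.sqrt(l1**2 + l2**2 + l3**2)
        else:
            s = np.sqrt(l1**2 + l2**2)
        s_max = max(s_max, float(s.max()))
        per_scale.append((sigma, l1, l2, l3, vecs))
    c = params.c_frac * s_max
    if c <= 0:
        return TubularityMap(best, best_scale, best_dir)
    for sigma, l1, l2, l3, vecs in per_scale:
        ups = frangi_tubularity(
            l1, l2, l3, params.alpha, params.beta, c, params.use_frobenius
        )
        improved = ups > best
        best = np.where(improved, ups, best)
        best_scale = np.where(improved, sigma, best_scale)
        axial = vecs[..., 0, :]  # eigenvector of the abs-smallest eigenvalue
        # direction is axial; fix the sign deterministically: first
        # non-negative z, then y, then x
        flip = (axial[..., 2] < 0) | (
            (axial[..., 2] == 0) & ((axial[..., 1] < 0) | ((axial[..., 1] == 0) & (axial[..., 0] < 0)))
        )
        axial = np.where(flip[..., None], -axial, axial)
        best_dir = np.where(improved[..., None], axial, best_dir)
    return TubularityMap(best, best_scale, best_dir)


_NEIGHBORS_26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def find_maxima_3d(value: np.ndarray, tau: float) -> list[tuple[int, int, int]]:
    """Noise-tolerant local maxima (ImageJ find-maxima semantics in 3D).

    The map is affinely scaled to [0, 255]; candidates (26-connected local
    maxima) are processed in decreasing value and a candidate survives
    unless the flood region reachable without descending more than ``tau``
    below its value touches a voxel already claimed by a higher maximum.
    Returns (x, y, z) voxel positions.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    v = np.asarray(value, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return []
    scaled = (v - lo) / (hi - lo) * 255.0
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = (scaled == ndimage.maximum_filter(scaled, footprint=footprint)) & (
        scaled > 0
    )
    cz, cy, cx = np.nonzero(is_max)
    vals = scaled[cz, cy, cx]
    # decreasing value, lexicographic (z, y, x) tie-break
    order = np.lexsort((cx, cy, cz, -vals))
    claimed = np.full(v.shape, -1, dtype=np.int32)
    shape = np.array(v.shape)
    kept: list[tuple[int, int, int]] = []
    for rank, idx in enumerate(order):
        z0, y0, x0 = int(cz[idx]), int(cy[idx]), int(cx[idx])
        if claimed[z0, y0, x0] != -1:
            continue
        peak = scaled[z0, y0, x0]
        floor_val = peak - tau
        stack = [(z0, y0, x0)]
        claimed[z0, y0, x0] = rank
        region = [(z0, y0, x0)]
        survives = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in _NEIGHBORS_26:
                nz_, ny_, nx_ = z + dz, y + dy, x + dx
                if not (
                    0 <= nz_ < shape[0] and 0 <= ny_ < shape[1] and 0 <= nx_ < shape[2]
                ):
                    continue
                if scaled[nz_, ny_, nx_] < floor_val:
                    continue
                prev = claimed[nz_, ny_, nx_]
                if prev == rank:
                    continue
                if prev != -1:
                    survives = False  # touched a higher maximum's basin
                    continue
                claimed[nz_, ny_, nx_] = rank
                region.append((nz_, ny_, nx_))
                stack.append((nz_, ny_, nx_))
        if survives:
            kept.append((x0, y0, z0))
    return kept


def cylindrical_nms(
    candidates: Sequence[tuple[int, int, int]],
    tub_map: TubularityMap,
) -> list[Seed]:
    """Keep candidates that dominate their own oriented cylinder.

    A candidate at p with scale sigma and axis v is kept iff its tubularity
    is the maximum of the map over voxels inside the cylinder of radius
    3 sigma and total length sigma (half-length sigma/2 along v) centered
    at p; ties are broken toward the lexicographically smallest position.
    """
    value = tub_map.value
    shape = np.array(value.shape)  # (nz, ny, nx)
    seeds: list[Seed] = []
    for x0, y0, z0 in candidates:
        ups = value[z0, y0, x0]
        sigma = float(tub_map.scale[z0, y0, x0])
        v = tub_map.direction[z0, y0, x0]
        r = 3.0 * sigma
        half_len = sigma / 2.0
        ext = int(np.ceil(np.sqrt(r * r + half_len * half_len)))
        zlo, zhi = max(0, z0 - ext), min(shape[0], z0 + ext + 1)
        ylo, yhi = max(0, y0 - ext), min(shape[1], y0 + ext + 1)
        xlo, xhi = max(0, x0 - ext), min(shape[2], x0 + ext + 1)
        Z, Y, X = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        dx = X - x0
        dy = Y - y0
        dz = Z - z0
        axial = dx * v[0] + dy * v[1] + dz * v[2]
        rad2 = dx * dx + dy * dy + dz * dz - axial * axial
        inside = (np.abs(axial) <= half_len) & (rad2 <= r * r)
        patch = value[zlo:zhi, ylo:yhi, xlo:xhi]
        vals = patch[inside]
        if vals.size == 0 or ups < vals.max():
            continue
        if ups == vals.max():
            # tie-break: keep only the lexicographically smallest position
            tz, ty, tx = np.nonzero(inside & (patch == ups))
            tied = sorted(zip(tx + xlo, ty + ylo, tz + zlo))
            if tied[0] != (x0, y0, z0):
                continue
        seeds.append(Seed(np.array([x0, y0, z0], float), v.copy(), sigma, float(ups)))
    return seeds


def filter_seeds(
    seeds: Sequence[Seed],
    volume: np.ndarray,
    c_min: float,
) -> list[Seed]:
    """Drop seeds whose cylindrical-template correlation is below c_min."""
    return [s for s in seeds if zncc(volume, s.p, s.v, s.sigma) >= c_min]


def extract_seeds(
    volume: np.ndarray,
    params: SeedParams,
    voxel_aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[Seed]:
    """Full seed pipeline, ordered by decreasing tubularity."""
    tub = multiscale_tubularity(volume, params, voxel_aspect)
    candidates = find_maxima_3d(tub.value, params.tau)
    seeds = cylindrical_nms(candidates, tub)
    seeds = filter_seeds(seeds, volume, params.c_min)
    seeds.sort(key=lambda s: (-s.tubularity, s.p[0], s.p[1], s.p[2]))
    return seeds
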