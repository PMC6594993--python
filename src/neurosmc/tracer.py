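"""Sequential Monte Carlo branch tracing.

Each (seed, direction) pair spawns one particle filter that follows the
local image structure.  The hidden state x = [p, v, sigma] holds the
branch centerline position, axial direction and cross-sectional scale; the
posterior over states is approximated by N weighted particles.  Per
iteration: new states are drawn from the transition prior (a von
Mises-Fisher direction about the previous direction, a truncated-Gaussian
step length around the tracing step size, and a truncated-Gaussian scale
perturbation), weights are updated with the exponential
template-correlation likelihood exp(K c) and renormalized, systematic
resampling fires when the effective sample size drops below 80% of N, and
the posterior centroid is emitted as a trace node.  Tracing stops when
the average correlation falls below c_min, the iteration limit is hit,
the local node density exceeds its cap, or the estimate leaves the
volume.

Because every seed is traced in both directions, a branch is typically
covered by several probabilistically independent traces; the merging
stage exploits that redundancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .seeds import Seed
from .template import zncc

__all__ = [
    "TraceState",
    "TracerParams",
    "Trace",
    "TraceNodeRecord",
    "NodeDensityGrid",
    "sample_transition",
    "transition_logpdf",
    "update_weights",
    "effective_sample_size",
    "systematic_resample",
    "estimate_state",
    "trace_branch",
    "trace_all",
]


@dataclass
class TraceState:
    p: np.ndarray  # (x, y, z) voxels
    v: np.ndarray  # unit direction
    sigma: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        n = np.linalg.norm(self.v)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.v = self.v / n
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class TracerParams:
    """Particle-filter parameters (defaults: the method's standard values).

    n_particles: samples per filter (N).
    kappa: von Mises-Fisher concentration of the direction prior.
    step: tracing step size d (voxels); step lengths are Gaussian around d
    with std d/3 truncated to (0, 2d].
    zeta: std of the scale random walk; scale changes truncated to 3 zeta.
    sensitivity: K in the likelihood exp(K c).
    c_min: mean-correlation termination threshold.
    max_iters: iteration limit L per trace.
    density_limit / density_neighborhood: stop when the count of already
    emitted nodes within the n-voxel neighborhood (n in {1, 5, 9}, in-plane)
    exceeds the limit.
    """

    n_particles: int = 20
    kappa: float = 3.0
    step: float = 3.0
    zeta: float = 1.0
    sensitivity: float = 20.0
    c_min: float = 0.5
    max_iters: int = 200
    density_limit: int = 4
    density_neighborhood: int = 9
    resample_frac: float = 0.8
    sigma_min: float = 0.25
    sigma_max: float = 9.0

    def __post_init__(self) -> None:
        if not (0 < self.resample_frac <= 1):
            raise ValueError("resample_frac must be in (0, 1]")
        for name in ("n_particles", "kappa", "step", "zeta", "max_iters"):
            if getattr(self, name) <= 0 and name != "max_iters":
                raise ValueError(f"{name} must be positive")
        if self.density_neighborhood not in (1, 5, 9):
            raise ValueError("density_neighborhood must be 1, 5 or 9")


@dataclass
class TraceNodeRecord:
    """One emitted trace node: centerline point, radius, mean correlation."""

    p: np.ndarray
    r: float
    c: float


@dataclass
class Trace:
    nodes: list[TraceNodeRecord] = field(default_factory=list)
    seed_index: int = -1
    direction_sign: int = +1

    def __len__(self) -> int:
        return len(self.nodes)


class NodeDensityGrid:
    """Counts of emitted trace nodes per voxel, shared across traces.

    The density at a position is the total count within an in-plane
    neighborhood of n voxels (n = 1: the voxel itself; n = 5: plus the
    4-connected x/y neighbors; n = 9: the full in-plane 3x3).  In-plane
    neighborhoods suit stacks with large voxel anisotropy in z.
    """

    _OFFSETS = {
        1: [(0, 0)],
        5: [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)],
        9: [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)],
    }

    def __init__(self, shape: Sequence[int], neighborhood: int = 9) -> None:
        self.counts = np.zeros(tuple(shape), dtype=np.int32)  # (nz, ny, nx)
        if neighborhood not in self._OFFSETS:
            raise ValueError("neighborhood must be 1, 5 or 9")
        self.neighborhood = neighborhood

    def _voxel(self, p: np.ndarray) -> tuple[int, int, int] | None:
        x, y, z = (int(round(c)) for c in p)
        nz, ny, nx = self.counts.shape
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            return None
        return z, y, x

    def density(self, p: np.ndarray) -> int:
        vox = self._voxel(p)
        if vox is None:
            return 0
        z, y, x = vox
        nz, ny, nx = self.counts.shape
        total = 0
        for dy, dx in self._OFFSETS[self.neighborhood]:
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx:
                total += int(self.counts[z, yy, xx])
        return total

    def add(self, p: np.ndarray) -> None:
        vox = self._voxel(p)
        if vox is not None:
            self.counts[vox] += 1


def _truncated_normal(
    mean: float, std: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Inverse-CDF draw from N(mean, std) truncated to [lo, hi]."""
    a = (lo - mean) / std
    b = (hi - mean) / std
    fa, fb = ndtr(a), ndtr(b)
    u = rng.uniform(fa, fb)
    return mean + std * float(ndtri(u))


def _vmf_direction(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a unit vector from the 3D von Mises-Fisher distribution.

    In three dimensions the cosine w of the angle to the mean direction
    has the closed-form inverse CDF w = 1 + log(u + (1 - u) e^{-2 kappa}) / kappa.
    """
    u = rng.uniform()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal basis about mu
    a = np.array([0.0, 0.0, 1.0]) if abs(mu[2]) <= 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def sample_transition(
    prev: TraceState, params: TracerParams, rng: np.random.Generator
) -> TraceState:
    """Draw a new state from the transition prior.

    Direction ~ vMF(prev.v, kappa); step length ~ N(d, (d/3)^2) truncated
    to (0, 2d]; sigma ~ N(prev.sigma, zeta^2) with |delta| <= 3 zeta,
    clamped to the well-posed template range.  The new direction is set by
    the displacement, v = (p - p_prev) / ||p - p_prev||.
    """
    d = params.step
    direction = _vmf_direction(prev.v, params.kappa, rng)
    step_len = _truncated_normal(d, d / 3.0, 1e-9, 2.0 * d, rng)
    sigma = _truncated_normal(
        prev.sigma,
        params.zeta,
        prev.sigma - 3.0 * params.zeta,
        prev.sigma + 3.0 * params.zeta,
        rng,
    )
    sigma = float(np.clip(sigma, params.sigma_min, params.sigma_max))
    p = prev.p + step_len * direction
    v = (p - prev.p) / np.linalg.norm(p - prev.p)
    return TraceState(p, v, sigma)


def transition_logpdf(new: TraceState, prev: TraceState, params: TracerParams) -> float:
    """Log transition prior up to an additive constant.

    kappa * (v_i . v_{i-1}) - (d_i - d)^2 / (2 (d/3)^2)
    - (sigma_i - sigma_{i-1})^2 / (2 zeta^2), with support d_i in (0, 2d]
    and |delta sigma| <= 3 zeta.  Normalization constants cancel in the
    weight renormalization.
    """
    d = params.step
    di = float(np.linalg.norm(new.p - prev.p))
    dsig = new.sigma - prev.sigma
    if di <= 0 or di > 2.0 * d or abs(dsig) > 3.0 * params.zeta + 1e-9:
        return -np.inf
    return (
        params.kappa * float(np.dot(new.v, prev.v))
        - (di - d) ** 2 / (2.0 * (d / 3.0) ** 2)
        - dsig**2 / (2.0 * params.zeta**2)
    )


def update_weights(
    prev_weights: np.ndarray,
    transition_logpdfs: np.ndarray,
    correlations: np.ndarray,
    sensitivity: float,
) -> np.ndarray:
    """Weight update: w propto w_prev * p(x_i | x_{i-1}) * exp(K c), normalized.

    Computed in log space; if every weight underflows the set is reset to
    uniform with a warning.
    """
    prev_weights = np.asarray(prev_weights, dtype=float)
    with np.errstate(divide="ignore"):
        logw = (
            np.log(prev_weights)
            + np.asarray(transition_logpdfs, dtype=float)
            + sensitivity * np.asarray(correlations, dtype=float)
        )
    m = np.max(logw)
    if not np.isfinite(m):
        warnings.warn("degenerate likelihood: resetting weights to uniform")
        return np.full(len(prev_weights), 1.0 / len(prev_weights))
    w = np.exp(logw - m)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish/Kong effective sample size 1 / sum(w^2) of normalized weights."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w * w))


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic (low-variance) resampling; returns offspring indices.

    A single uniform offset u in [0, 1/N) is compared against the
    cumulative weights at positions u + k/N, guaranteeing each particle
    between floor(N w) and ceil(N w) offspring.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    positions = (rng.uniform() + np.arange(n)) / n
    cumulative = np.cumsum(w)
    cumulative[-1] = 1.0  # guard rounding
    return np.searchsorted(cumulative, positions, side="right").clip(0, n - 1)


def estimate_state(
    states: Sequence[TraceState],
    weights: np.ndarray,
    correlations: np.ndarray,
    prev_direction: np.ndarray | None = None,
) -> tuple[TraceState, float]:
    """Posterior centroid of the particle set plus the mean correlation.

    Position and scale are weighted means; the direction is the normalized
    weighted mean of particle directions (falling back to the previous
    direction if the spread is degenerate).  The returned correlation is
    the unweighted average over particles, the tracer's termination
    statistic.
    """
    w = np.asarray(weights, dtype=float)
    P = np.stack([s.p for s in states])
    V = np.stack([s.v for s in states])
    sig = np.array([s.sigma for s in states])
    p_hat = w @ P
    sigma_hat = float(w @ sig)
    v_hat = w @ V
    norm = np.linalg.norm(v_hat)
    if norm < 1e-12:
        if prev_direction is None:
            raise ValueError("degenerate direction spread with no fallback")
        v_hat = np.asarray(prev_direction, dtype=float)
    else:
        v_hat = v_hat / norm
    mean_corr = float(np.mean(correlations))
    return TraceState(p_hat, v_hat, sigma_hat), mean_corr


def _in_volume(p: np.ndarray, shape: Sequence[int]) -> bool:
    nz, ny, nx = shape
    x, y, z = p
    return -0.5 <= x < nx - 0.5 and -0.5 <= y < ny - 0.5 and -0.5 <= z < nz - 0.5


def trace_branch(
    seed: Seed,
    sign: int,
    volume: np.ndarray,
    density: NodeDensityGrid,
    params: TracerParams,
    rng: np.random.Generator,
) -> Trace:
    """Trace one branch from a seed in direction ``sign * seed.v``.

    Returns a (possibly empty) trace.  The seed state itself is emitted as
    the first node when at least one filter iteration succeeds, so the two
    opposite-direction traces of a seed share their starting point.
    """
    trace = Trace(direction_sign=sign)
    n = params.n_particles
    states = [TraceState(seed.p.copy(), sign * seed.v, seed.sigma) for _ in range(n)]
    weights = np.full(n, 1.0 / n)
    prev_dir = sign * seed.v
    vol = np.asarray(volume, dtype=float)

    for _ in range(params.max_iters):
        # predict -> update -> (conditional resample) -> estimate
        new_states = [sample_transition(s, params, rng) for s in states]
        logpdfs = np.array(
            [transition_logpdf(ns, s, params) for ns, s in zip(new_states, states)]
        )
        corrs = np.array([zncc(vol, ns.p, ns.v, ns.sigma) for ns in new_states])
        weights = update_weights(weights, logpdfs, corrs, params.sensitivity)
        states = new_states
        if effective_sample_size(weights) < params.resample_frac * n:
            idx = systematic_resample(weights, rng)
            states = [
                TraceState(states[i].p.copy(), states[i].v.copy(), states[i].sigma)
                for i in idx
            ]
            corrs = corrs[idx]
            weights = np.full(n, 1.0 / n)
        # termination statistic: unweighted mean correlation of the
        # current particle set
        mean_corr = float(np.mean(corrs))
        if mean_corr < params.c_min:
            break
        est, _ = estimate_state(states, weights, corrs, prev_dir)
        if not _in_volume(est.p, vol.shape):
            break
        if density.density(est.p) > params.density_limit:
            break
        if not trace.nodes:
            seed_corr = zncc(vol, seed.p, seed.v, seed.sigma)
            trace.nodes.append(TraceNodeRecord(seed.p.copy(), seed.sigma, seed_corr))
            density.add(seed.p)
        trace.nodes.append(TraceNodeRecord(est.p, est.sigma, mean_corr))
        density.add(est.p)
        prev_dir = est.v
    return trace


def trace_all(
    seeds: Sequence[Seed],
    volume: np.ndarray,
    params: TracerParams,
    rng: np.random.Generator,
) -> list[Trace]:
    """Trace every seed in both directions against a shared density grid.

    Seeds are processed in decreasing tubularity order (the caller's
    ordering is preserved); the density grid caps redundant coverage.
    Returns the nonempty traces.
    """
    density = NodeDensityGrid(volume.shape, params.density_neighborhood)
    traces: list[Trace] = []
    for i, seed in enumerate(seeds):
        for sign in (+1, -1):
            t = trace_branch(seed, sign, volume, density, params, rng)
            t.seed_index = i
            if len(t) > 0:
                traces.append(t)
    return traces
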