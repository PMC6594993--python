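"""Cylindrical-template correlation.

Branch presence is measured by the zero-normalized cross-correlation
(ZNCC) between the local image and a cylindrical intensity model with a
Gaussian cross-section: G_sigma(k, l) = exp(-(k^2 + l^2) / 2 sigma^2),
constant along the cylinder axis m.  ZNCC is invariant to intensity
scalings and offsets and ranges from -1 (inverse correlation) through 0
(no correlation) to +1 (full correlation).  The same score drives seed
filtering and the tracer's likelihood and termination criterion.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["template_frame", "template_grid", "zncc"]


def template_frame(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame (u, w) perpendicular to axis v.

    u = normalize(v x a) with a = z-hat unless v is nearly axial
    (|v.z| > 0.9), in which case a = x-hat; w = v x u.
    """
    v = np.asarray(v, dtype=float)
    a = np.array([0.0, 0.0, 1.0]) if abs(v[2]) <= 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(v, a)
    u = u / np.linalg.norm(u)
    w = np.cross(v, u)
    return u, w


def template_grid(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Integer template coordinates (k, l, m) and model values G.

    k, l span [floor(-3 sigma), ceil(3 sigma)] across the axis; m spans the
    symmetric band [floor(-sigma), ceil(sigma)] along it, so the template
    is centered on the node.
    """
    kl = np.arange(int(np.floor(-3 * sigma)), int(np.ceil(3 * sigma)) + 1)
    m = np.arange(int(np.floor(-sigma)), int(np.ceil(sigma)) + 1)
    K, L, M = np.meshgrid(kl, kl, m, indexing="ij")
    G = np.exp(-(K**2 + L**2) / (2.0 * sigma**2))
    return K.ravel().astype(float), L.ravel().astype(float), M.ravel().astype(float), G.ravel()


def zncc(
    volume: np.ndarray,
    p: np.ndarray,
    v: np.ndarray,
    sigma: float,
) -> float:
    """ZNCC of the image against the cylindrical template at pose (p, v, sigma).

    The image is sampled by trilinear interpolation at
    p' = p + k u + l w + m v; samples outside the volume take the border
    value.  A constant image patch (zero variance) yields 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    u, w = template_frame(v)
    K, L, M, G = template_grid(sigma)
    pts = p[None, :] + K[:, None] * u + L[:, None] * w + M[:, None] * v
    # volume is indexed [z, y, x]
    coords = np.stack([pts[:, 2], pts[:, 1], pts[:, 0]])
    samples = map_coordinates(
        volume.astype(float), coords, order=1, mode="nearest"
    )
    si = samples - samples.mean()
    sg = G - G.mean()
    denom = np.sqrt(np.sum(si * si) * np.sum(sg * sg))
    if denom == 0:
        return 0.0
    return float(np.clip(np.sum(si * sg) / denom, -1.0, 1.0))
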