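"""SWC morphology I/O and shared geometry utilities.

SWC is the de-facto plain-text format for digital neuron reconstructions:
one node per line with seven whitespace-separated columns
``id type x y z radius parent`` and ``#`` comment lines.  Coordinates and
radii are kept in voxel units of the associated image; physical distances
multiply per-axis differences by the ``voxel_aspect`` metadata before
taking the Euclidean norm, so anisotropy enters the pipeline in exactly
one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SwcNode",
    "SwcTree",
    "SwcParseError",
    "SwcStructureError",
    "DEFAULT_UNKNOWN_ASPECT",
    "read_swc",
    "write_swc",
    "resample_polyline",
    "scaled_distance",
]

#: Convention for stacks whose physical voxel size is unknown: the axial
#: (z) sampling of fluorescence stacks is typically about twice as coarse
#: as the lateral sampling.
DEFAULT_UNKNOWN_ASPECT = (1.0, 1.0, 2.0)

SOMA_TYPE = 1
NEURITE_TYPE = 3


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """The node records do not form a valid rooted forest."""


@dataclass
class SwcNode:
    """One SWC record: a sphere at ``p`` linked to its parent."""

    id: int
    type_code: int
    p: np.ndarray  # (3,) float, (x, y, z) in voxels
    radius: float
    parent: int  # -1 for a root

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        if self.id <= 0:
            raise SwcStructureError(f"node id must be positive, got {self.id}")
        if not self.radius > 0:
            raise SwcStructureError(f"node {self.id}: radius must be > 0")


@dataclass
class SwcTree:
    """An ordered sequence of SWC nodes forming a rooted tree (or forest)."""

    nodes: list[SwcNode] = field(default_factory=list)
    voxel_aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxel_aspect = tuple(float(a) for a in self.voxel_aspect)
        if len(self.voxel_aspect) != 3 or any(a <= 0 for a in self.voxel_aspect):
            raise ValueError("voxel_aspect must be 3 positive scalars")

    def __len__(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Check id uniqueness, parent resolvability and acyclicity."""
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SwcStructureError("duplicate node ids")
        by_id = {n.id: n for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1 and n.parent not in by_id:
                raise SwcStructureError(
                    f"node {n.id} references missing parent id {n.parent}"
                )
        # Cycle check by walking each node towards a root.
        state: dict[int, int] = {}  # 0 = in progress, 1 = done
        for n in self.nodes:
            path = []
            cur = n.id
            while cur != -1 and state.get(cur) != 1:
                if state.get(cur) == 0:
                    raise SwcStructureError(f"cycle detected at node id {cur}")
                state[cur] = 0
                path.append(cur)
                cur = by_id[cur].parent
            for nid in path:
                state[nid] = 1

    def roots(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.parent == -1]

    def edges(self) -> list[tuple[SwcNode, SwcNode]]:
        """(parent, child) pairs."""
        by_id = {n.id: n for n in self.nodes}
        return [(by_id[n.parent], n) for n in self.nodes if n.parent != -1]

    def positions(self) -> np.ndarray:
        if not self.nodes:
            return np.zeros((0, 3))
        return np.stack([n.p for n in self.nodes])

    def translated(self, offset: Sequence[float]) -> "SwcTree":
        off = np.asarray(offset, dtype=float)
        return SwcTree(
            [replace(n, p=n.p + off) for n in self.nodes],
            voxel_aspect=self.voxel_aspect,
        )


def scaled_distance(
    a: np.ndarray, b: np.ndarray, aspect: Sequence[float] = (1.0, 1.0, 1.0)
) -> float | np.ndarray:
    """Anisotropy-aware Euclidean distance between voxel-unit positions.

    ``a`` and ``b`` broadcast; the last axis is (x, y, z).
    """
    d = (np.asarray(a, float) - np.asarray(b, float)) * np.asarray(aspect, float)
    return np.sqrt(np.sum(d * d, axis=-1))


def read_swc(path: str | Path, voxel_aspect: Sequence[float] | None = None) -> SwcTree:
    """Read and validate an SWC file.

    Parameters
    ----------
    path:
        File with ``#`` comments and 7-column data lines.
    voxel_aspect:
        Physical x:y:z voxel scaling. When ``None`` the 1:1:2 convention
        for stacks of unknown voxel size is used.
    """
    aspect = DEFAULT_UNKNOWN_ASPECT if voxel_aspect is None else tuple(voxel_aspect)
    nodes: list[SwcNode] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                tcode = int(fields[1])
                xyz = [float(v) for v in fields[2:5]]
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            nodes.append(SwcNode(nid, tcode, np.array(xyz), radius, parent))
    tree = SwcTree(nodes, voxel_aspect=aspect)
    tree.validate()
    return tree


def write_swc(tree: SwcTree, path: str | Path) -> None:
    """Write a validated tree; positions and radii printed to 3 decimals."""
    tree.validate()
    lines = ["# id type x y z radius parent"]
    for n in tree.nodes:
        lines.append(
            f"{n.id} {n.type_code} {n.p[0]:.3f} {n.p[1]:.3f} {n.p[2]:.3f} "
            f"{n.radius:.3f} {n.parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _resample_attrs(
    points: np.ndarray,
    attrs: np.ndarray,
    step: float,
    aspect: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Densify a polyline so consecutive points are <= step apart.

    ``attrs`` is an (n, k) matrix of per-vertex values (radius, correlation,
    ...) interpolated linearly along with the positions.  Original vertices
    are preserved.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    attrs = np.asarray(attrs, dtype=float).reshape(len(points), -1)
    if step <= 0:
        raise ValueError("step must be > 0")
    if len(points) == 1:
        return points.copy(), attrs.copy()
    out_p = [points[0]]
    out_a = [attrs[0]]
    for i in range(len(points) - 1):
        p0, p1 = points[i], points[i + 1]
        seg = float(scaled_distance(p0, p1, aspect))
        nsub = max(1, int(np.ceil(seg / step - 1e-12)))
        for j in range(1, nsub + 1):
            t = j / nsub
            out_p.append(p0 + t * (p1 - p0))
            out_a.append(attrs[i] + t * (attrs[i + 1] - attrs[i]))
    return np.stack(out_p), np.stack(out_a)


def resample_polyline(
    points: Iterable[Sequence[float]],
    radii: Iterable[float],
    step: float,
    aspect: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an ordered polyline to spacing <= ``step``.

    Returns the densified positions and linearly interpolated radii; the
    first and last input points are preserved exactly.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 3)
    rad = np.asarray(list(radii), dtype=float).reshape(-1)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(pts) != len(rad):
        raise ValueError("points and radii length mismatch")
    out_p, out_a = _resample_attrs(pts, rad[:, None], step, aspect)
    return out_p, out_a[:, 0]
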