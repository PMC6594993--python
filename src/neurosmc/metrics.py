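"""Reconstruction quality measures: SD, SSD, %SSD, precision/recall/F.

Both the reconstruction and the gold standard are densely resampled so
adjacent nodes are at most one voxel apart, then reciprocal
nearest-neighbor distances are computed: for every reconstruction node
the distance to the nearest gold-standard node and vice versa.  SD is the
mean of all these distances; SSD the mean over only the distances larger
than a threshold S ("substantially distant" nodes) and %SSD their
percentage.  Overlap is summarized by precision, recall and the F score
of nodes matched within S.  S = 2 voxels is the field's customary
default, although rankings can depend on the choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .swc_io import SwcTree, resample_polyline

__all__ = ["ScoreReport", "score", "score_sweep", "resampled_points"]

DEFAULT_S = 2.0


@dataclass
class ScoreReport:
    sd: float
    ssd: float
    pct_ssd: float
    precision: float
    recall: float
    f: float
    tp: int
    fp: int
    fn: int
    s: float
    ssd_defined: bool = True  # False when no node exceeds S (SSD reported as 0)


def resampled_points(tree: SwcTree, step: float = 1.0) -> np.ndarray:
    """All node positions after resampling each edge to ``step`` spacing."""
    if len(tree) == 0:
        return np.zeros((0, 3))
    by_id = {n.id: n for n in tree.nodes}
    pts = [n.p for n in tree.nodes]
    for n in tree.nodes:
        if n.parent == -1:
            continue
        parent = by_id[n.parent]
        dense, _ = resample_polyline(
            [parent.p, n.p], [parent.radius, n.radius], step, tree.voxel_aspect
        )
        pts.extend(dense[1:-1])  # endpoints already present as nodes
    return np.stack(pts)


def score(recon: SwcTree, truth: SwcTree, s: float = DEFAULT_S) -> ScoreReport:
    """Score a reconstruction against ground truth at threshold ``s``.

    Distances are anisotropy-aware via the trees' voxel aspect metadata
    (the two trees must agree on it).
    """
    if s <= 0:
        raise ValueError("S must be > 0")
    if len(recon) == 0 or len(truth) == 0:
        raise ValueError("cannot score an empty tree")
    if tuple(recon.voxel_aspect) != tuple(truth.voxel_aspect):
        raise ValueError("voxel aspects of the two trees differ")
    aspect = np.asarray(truth.voxel_aspect, dtype=float)
    pr = resampled_points(recon) * aspect
    pt = resampled_points(truth) * aspect
    tree_r = cKDTree(pr)
    tree_t = cKDTree(pt)
    d_recon, _ = tree_t.query(pr)  # recon node -> nearest truth
    d_truth, _ = tree_r.query(pt)  # truth node -> nearest recon
    d_all = np.concatenate([d_recon, d_truth])
    sd = float(d_all.mean())
    far = d_all > s
    if far.any():
        ssd = float(d_all[far].mean())
        ssd_defined = True
    else:
        ssd = 0.0
        ssd_defined = False
    pct_ssd = float(100.0 * far.mean())
    tp = int(np.sum(d_recon <= s))
    fp = int(np.sum(d_recon > s))
    fn = int(np.sum(d_truth > s))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return ScoreReport(sd, ssd, pct_ssd, precision, recall, f, tp, fp, fn, s, ssd_defined)


def score_sweep(
    recon: SwcTree, truth: SwcTree, s_values: Sequence[float]
) -> list[ScoreReport]:
    """One report per threshold S."""
    return [score(recon, truth, s) for s in s_values]
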