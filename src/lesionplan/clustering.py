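"""Grouping suprathreshold vertex predictions into candidate lesion clusters."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .surface_io import HemisphereSurface, Overlay, ShapeError
from .features import vertex_areas

#: Clusters smaller than this surface area are discarded as noise (mm^2).
DEFAULT_MIN_AREA_MM2 = 50.0


@dataclass
class Cluster:
    """An edge-connected set of suprathreshold vertices on one hemisphere."""

    vertex_ids: np.ndarray          # sorted vertex indices
    hemisphere: str
    area_mm2: float
    mean_prediction: float
    centroid_mm: np.ndarray         # (3,)
    rank: Optional[int] = None
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        self.vertex_ids = np.unique(np.asarray(self.vertex_ids, dtype=np.int64))
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=np.float64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)


def extract_clusters(surface: HemisphereSurface, scores: Overlay,
                     threshold: float,
                     min_area_mm2: float = DEFAULT_MIN_AREA_MM2
                     ) -> list[Cluster]:
    """Connected components of {score > threshold}, area-filtered.

    Connectivity is shared-triangle-edge adjacency; the threshold comparison
    is strict. Components whose summed vertex area falls below
    ``min_area_mm2`` are dropped.
    """
    if len(scores) != surface.n_vertices:
        raise ShapeError("scores do not match surface vertex count")
    supra = scores.values > threshold
    if not supra.any():
        return []
    areas = vertex_areas(surface).values
    sub = surface.adjacency()[supra][:, supra]
    n_comp, comp_labels = connected_components(sub, directed=False)
    supra_ids = np.flatnonzero(supra)
    clusters = []
    for comp in range(n_comp):
        members = supra_ids[comp_labels == comp]
        area = float(areas[members].sum())
        if area < min_area_mm2:
            continue
        clusters.append(Cluster(
            vertex_ids=members,
            hemisphere=surface.hemisphere,
            area_mm2=area,
            mean_prediction=float(scores.values[members].mean()),
            centroid_mm=surface.vertex_coords[members].mean(axis=0)))
    return clusters


def rank_clusters(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Rank by descending mean prediction; ties broken by larger area, then
    hemisphere name, then lowest member vertex id. Rank 1 is best."""
    def sort_key(c: Cluster):
        first_vertex = int(c.vertex_ids[0]) if c.n_vertices else -1
        return (-c.mean_prediction, -c.area_mm2, c.hemisphere, first_vertex)

    ordered = sorted(clusters, key=sort_key)
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def overlap_with_mask(cluster: Cluster, mask: Overlay) -> bool:
    """True iff the cluster shares at least one vertex with a binary mask."""
    mask_ids = np.flatnonzero(mask.values > 0)
    return bool(np.intersect1d(cluster.vertex_ids, mask_ids, assume_unique=False).size)


def clusters_to_label_overlay(clusters: Sequence[Cluster], n_vertices: int) -> Overlay:
    """Integer label overlay: 0 background, cluster rank (or position) otherwise."""
    labels = np.zeros(n_vertices)
    for i, c in enumerate(clusters, start=1):
        labels[c.vertex_ids] = c.rank if c.rank is not None else i
    return Overlay(labels, name="cluster_labels")


def write_cluster_manifest(path: str, clusters: Sequence[Cluster]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "hemisphere", "area_mm2", "mean_prediction",
                         "rank", "n_vertices", "cx", "cy", "cz", "artifact"])
        for i, c in enumerate(clusters, start=1):
            writer.writerow([i, c.hemisphere, f"{c.area_mm2:.4f}",
                             f"{c.mean_prediction:.6f}", c.rank, c.n_vertices,
                             *(f"{v:.4f}" for v in c.centroid_mm),
                             int(c.artifact_flag)])
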