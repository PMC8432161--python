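"""Colocalization of predicted lesion clusters with depth-electrode contacts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .clustering import Cluster
from .surface_io import (AffineTransform, Contact, HemisphereSurface,
                         ValidationError)

#: A cluster closer than this to an SOZ contact counts as colocalized (strict).
DEFAULT_DISTANCE_THRESHOLD_MM = 10.0

LATERALITIES = ("left", "right", "bilateral")


@dataclass
class ElectrodeSet:
    contacts: list[Contact]
    implant_laterality: str = "bilateral"

    def __post_init__(self) -> None:
        if not self.contacts:
            raise ValidationError("electrode set must contain at least 1 contact")
        if self.implant_laterality not in LATERALITIES:
            raise ValidationError(f"implant_laterality must be one of {LATERALITIES}")

    def by_label(self, label: str) -> list[Contact]:
        return [c for c in self.contacts if c.label == label]


@dataclass
class ConcordanceResult:
    """Distances from clusters to each contact class plus the colocalization call."""

    min_distance_by_label: Dict[str, float]      # label -> min over all pairs (mm)
    colocalized: Optional[bool]                  # None when not applicable
    nearest_pair: Optional[tuple]                # (cluster index, Contact)
    per_cluster: list[Dict[str, float]] = field(default_factory=list)


def transform_contacts(contacts: Sequence[Contact], affine: AffineTransform
                       ) -> list[Contact]:
    """Map contact coordinates through an affine, preserving labels."""
    coords = affine.apply(np.array([c.coord for c in contacts]))
    return [replace(c, coord=coords[i]) for i, c in enumerate(contacts)]


def cluster_contact_distance(cluster: Cluster, surface: HemisphereSurface,
                             contact_coord: np.ndarray) -> float:
    """Minimum Euclidean distance from any cluster vertex to the contact (mm)."""
    if cluster.n_vertices == 0:
        raise ValidationError("empty cluster has no distance")
    pts = surface.vertex_coords[cluster.vertex_ids]
    return float(np.min(np.linalg.norm(pts - np.asarray(contact_coord), axis=1)))


def assess_colocalization(clusters: Sequence[Cluster],
                          surfaces: Dict[str, HemisphereSurface],
                          electrodes: ElectrodeSet,
                          threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM
                          ) -> ConcordanceResult:
    """Colocalized iff some cluster lies strictly within ``threshold_mm`` of
    some SOZ contact. Distances to the other contact classes are reported for
    audit. With no SOZ contacts the call is not applicable (None)."""
    soz_contacts = electrodes.by_label("SOZ")
    per_cluster = []
    min_by_label: Dict[str, float] = {}
    nearest = None
    nearest_d = np.inf
    for ci, cluster in enumerate(clusters):
        surface = surfaces[cluster.hemisphere]
        dists = {}
        for contact in electrodes.contacts:
            d = cluster_contact_distance(cluster, surface, contact.coord)
            if d < dists.get(contact.label, np.inf):
                dists[contact.label] = d
            if contact.label == "SOZ" and d < nearest_d:
                nearest_d = d
                nearest = (ci, contact)
        per_cluster.append(dists)
        for label, d in dists.items():
            if d < min_by_label.get(label, np.inf):
                min_by_label[label] = d
    if not soz_contacts:
        return ConcordanceResult(min_by_label, None, None, per_cluster)
    colocalized = bool(clusters) and min_by_label.get("SOZ", np.inf) < threshold_mm
    return ConcordanceResult(min_by_label, colocalized,
                             nearest if colocalized else nearest, per_cluster)


def classify_patient(concordance: ConcordanceResult, seeg_outcome: str) -> str:
    """Concordance field for a patient record: yes/no for focal outcomes,
    not-applicable otherwise (mesial/diffuse onsets are outside the method's
    cortical scope)."""
    if seeg_outcome != "focal":
        return "not-applicable"
    return "yes" if concordance.colocalized else "no"
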