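"""Fully synthetic cohorts for end-to-end testing.

Hemisphere meshes are mirror-symmetric deformed icospheres (vertex-paired
white/gray, identity template correspondence). Control features are smooth
spatial mean fields plus per-subject Gaussian noise; lesions are geodesic
patches with channel offsets expressed in control-noise standard deviations;
electrodes are straight trajectories of equally spaced contacts labelled by
distance from the designated seizure onset patch.

Folded cortical geometry is deliberately not simulated: mean curvature and
sulcal depth are synthetic smooth fields, since the classifier consumes
feature channels rather than geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import dijkstra

from . import features as feat
from .classifier import SubjectData
from .features import CHANNELS, FeatureSet, SmoothingSpec, build_feature_matrix
from .surface_io import (Contact, HemisphereSurface, Overlay, PatientRecord,
                         TemplateCorrespondence, ValidationError,
                         read_cohort_table)
from .seeg import ElectrodeSet

#: Control-population generating parameters per channel:
#: (baseline mean, noise sd, spatial-field amplitude)
CHANNEL_PARAMS = {
    "thickness": (2.5, 0.25, 0.3),
    "gw_contrast": (1.0, 0.10, 0.1),
    "mean_curvature": (0.0, 0.05, 0.05),
    "sulcal_depth": (0.0, 1.0, 1.5),
    "intrinsic_curvature": (6.25e-4, 2.0e-4, 2.0e-4),
    "intensity_25": (110.0, 5.0, 5.0),
    "intensity_50": (100.0, 5.0, 5.0),
    "intensity_75": (90.0, 5.0, 5.0),
    "intensity_gw": (80.0, 5.0, 5.0),
    "intensity_sub_0.5": (75.0, 5.0, 5.0),
    "intensity_sub_1.0": (70.0, 5.0, 5.0),
}

#: Default lesion effect sizes in control-noise sd units: thicker cortex,
#: blurred gray-white transition, brighter intracortical signal.
DEFAULT_LESION_EFFECTS = {
    "thickness": 3.0,
    "gw_contrast": -3.0,
    "intensity_50": 3.0,
    "intensity_gw": 3.0,
    "intensity_sub_0.5": 3.0,
    "intensity_sub_1.0": 3.0,
}


@dataclass
class LesionSpec:
    center_vertex: int
    geodesic_radius_mm: float
    effects: Dict[str, float]        # channel -> offset in control-noise sd
    hemisphere: str
    taper_fraction: float = 0.3      # cosine rim width relative to the radius

    def __post_init__(self) -> None:
        if self.geodesic_radius_mm <= 0:
            raise ValidationError("lesion radius must be positive")
        if not all(np.isfinite(list(self.effects.values()))):
            raise ValidationError("lesion effects must be finite")


@dataclass
class SyntheticCohortSpec:
    n_patients: int = 8
    n_controls: int = 10
    subdivision: int = 4
    radius_mm: float = 40.0
    lesion_radius_mm: Optional[float] = 11.0   # None -> lognormal draw
    lesion_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_EFFECTS))
    n_electrodes: int = 3
    n_contacts: int = 8
    contact_spacing_mm: float = 3.5
    seed: int = 0

    #: Median manually-delineated lesion area on real cortex (mm^2) and the
    #: real hemisphere area it is scaled against when drawing random sizes.
    real_lesion_median_mm2: float = 1185.0
    real_hemisphere_area_mm2: float = 90000.0


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def icosphere(subdivision: int, radius: float = 1.0):
    """Geodesic sphere: icosahedron with ``subdivision`` rounds of edge
    midpoint subdivision (10 * 4**n + 2 vertices)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivision):
        cache: dict = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return verts * radius, faces


def _deformation_fields(unit_dirs: np.ndarray, radius: float):
    """Fixed smooth radius perturbation and thickness fields, both even in x
    so the mirrored hemisphere gets identical values."""
    x, y, z = unit_dirs.T
    bump = 0.04 * np.sin(3.0 * z) + 0.03 * np.cos(2.0 * y) + 0.02 * np.cos(4.0 * x**2)
    white_radius = radius * (1.0 + bump)
    thickness = 2.5 + 0.4 * np.sin(2.0 * z) * np.cos(1.5 * y)
    return white_radius, thickness


def make_hemisphere_pair(subdivision: int, radius_mm: float = 40.0,
                         separation_mm: Optional[float] = None):
    """Vertex-paired white/gray/mid surfaces for two mirror hemispheres.

    Returns ``(surfaces, thickness, correspondence)`` where ``surfaces`` maps
    hemisphere -> {white, gray, mid} -> HemisphereSurface, ``thickness`` is
    the generating thickness field (identical for both hemispheres by
    construction), and the template correspondence is the identity.
    """
    if subdivision < 2:
        raise ValidationError("subdivision must be >= 2")
    unit, faces = icosphere(subdivision, 1.0)
    white_radius, thickness = _deformation_fields(unit, radius_mm)
    offset = separation_mm if separation_mm is not None else radius_mm + 15.0

    left_white = unit * white_radius[:, None]
    left_gray = unit * (white_radius + thickness)[:, None]
    left_white[:, 0] -= offset
    left_gray[:, 0] -= offset

    surfaces: Dict[str, Dict[str, HemisphereSurface]] = {}
    for hemi, sign in (("left", 1.0), ("right", -1.0)):
        mirror = np.array([sign, 1.0, 1.0])
        hemi_surfs = {}
        for kind, coords in (("white", left_white), ("gray", left_gray),
                             ("mid", 0.5 * (left_white + left_gray))):
            hemi_surfs[kind] = HemisphereSurface(
                coords * mirror, faces.copy(), hemisphere=hemi,
                surface_kind="pial" if kind == "gray" else kind)
        surfaces[hemi] = hemi_surfs
    corr = TemplateCorrespondence.identity(len(unit))
    return surfaces, Overlay(thickness, name="thickness", units="mm"), corr


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _spatial_field(unit_dirs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean field on the sphere from a few random low-order lobes."""
    out = np.zeros(len(unit_dirs))
    for _ in range(4):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        out += rng.normal() * (unit_dirs @ direction) ** 2
    return out - out.mean()


def cohort_mean_fields(spec: SyntheticCohortSpec) -> Dict[str, np.ndarray]:
    """Per-channel spatial mean fields shared by the whole cohort (seeded by
    the cohort seed, identical on both hemispheres)."""
    unit, _ = icosphere(spec.subdivision, 1.0)
    rng = np.random.default_rng(spec.seed)
    fields = {}
    for channel in CHANNELS:
        mean, _sd, amp = CHANNEL_PARAMS[channel]
        fields[channel] = mean + amp * _spatial_field(unit, rng)
    return fields


def noise_sds() -> Dict[str, float]:
    return {ch: CHANNEL_PARAMS[ch][1] for ch in CHANNELS}


def generate_control(spec: SyntheticCohortSpec, seed: int
                     ) -> Dict[str, FeatureSet]:
    """One control subject: shared mean fields + per-vertex Gaussian noise."""
    fields = cohort_mean_fields(spec)
    rng = np.random.default_rng(seed)
    out = {}
    for hemi in ("left", "right"):
        channels = {ch: fields[ch] + CHANNEL_PARAMS[ch][1]
                    * rng.normal(size=len(fields[ch])) for ch in CHANNELS}
        out[hemi] = FeatureSet(channels, hemi, stage="raw")
    return out


def _two_ring_graph(surface: HemisphereSurface):
    """Euclidean-length graph over 1- and 2-ring neighborhoods.

    Adding 2-ring chords cuts the metrication bias of shortest edge-path
    distances, giving geodesic discs much closer to their nominal radius.
    """
    from scipy.sparse import coo_matrix
    adj = surface.adjacency()
    two = ((adj @ adj) + adj).tocoo()
    mask = two.row < two.col
    rows, cols = two.row[mask], two.col[mask]
    v = surface.vertex_coords
    lengths = np.linalg.norm(v[rows] - v[cols], axis=1)
    n = surface.n_vertices
    return coo_matrix((np.concatenate([lengths, lengths]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))), shape=(n, n)).tocsr()


def geodesic_distances_from(surface: HemisphereSurface, vertex: int,
                            limit: float = np.inf) -> np.ndarray:
    return dijkstra(_two_ring_graph(surface), directed=False, indices=vertex,
                    limit=limit)


def inject_lesion(subject: Dict[str, FeatureSet],
                  surfaces: Dict[str, Dict[str, HemisphereSurface]],
                  lesion: LesionSpec):
    """Offset channels inside a geodesic patch; returns (features, mask).

    The effect is constant within the geodesic radius and falls off over a
    cosine rim beyond it; the binary mask covers the constant core. The
    contralateral hemisphere is untouched.
    """
    surface = surfaces[lesion.hemisphere]["white"]
    rim = lesion.geodesic_radius_mm * (1.0 + lesion.taper_fraction)
    dist = geodesic_distances_from(surface, lesion.center_vertex)
    if lesion.geodesic_radius_mm >= dist.max():
        raise ValidationError("lesion radius exceeds the hemisphere extent")
    profile = np.zeros(surface.n_vertices)
    core = dist <= lesion.geodesic_radius_mm
    rim_band = (~core) & (dist <= rim)
    profile[core] = 1.0
    t = (dist[rim_band] - lesion.geodesic_radius_mm) / (rim - lesion.geodesic_radius_mm)
    profile[rim_band] = 0.5 * (1.0 + np.cos(np.pi * t))

    sds = noise_sds()
    out = {hemi: fs.copy() for hemi, fs in subject.items()}
    target = out[lesion.hemisphere]
    for channel, effect in lesion.effects.items():
        target.channels[channel] = target.channels[channel] + effect * sds[channel] * profile
    mask = Overlay(core.astype(float), name="lesion_mask")
    return out, mask


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------

def generate_electrodes(surface: HemisphereSurface, targets: np.ndarray,
                        n_contacts: int, spacing_mm: float, seed: int,
                        soz_center: Optional[np.ndarray] = None,
                        soz_radius_mm: float = 10.0,
                        irritative_radius_mm: float = 20.0,
                        implant_laterality: str = "bilateral") -> ElectrodeSet:
    """Straight electrode trajectories toward the given target points.

    Contacts run from the target outward (away from the hemisphere centroid)
    at fixed spacing. Contacts within ``soz_radius_mm`` of ``soz_center`` are
    labelled SOZ, within ``irritative_radius_mm`` irritative, otherwise
    uninvolved.
    """
    rng = np.random.default_rng(seed)
    center = surface.vertex_coords.mean(axis=0)
    contacts = []
    for ei, target in enumerate(np.atleast_2d(targets), start=1):
        direction = target - center
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        jitter = rng.normal(scale=0.1, size=3)
        for ci in range(n_contacts):
            coord = target + direction * spacing_mm * ci + jitter
            if soz_center is not None:
                d = np.linalg.norm(coord - soz_center)
                if d <= soz_radius_mm:
                    label = "SOZ"
                elif d <= irritative_radius_mm:
                    label = "irritative"
                else:
                    label = "uninvolved"
            else:
                label = "uninvolved"
            contacts.append(Contact(f"E{ei}", ci + 1, coord, label))
    return ElectrodeSet(contacts, implant_laterality=implant_laterality)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    subject_id: str
    raw_features: Dict[str, FeatureSet]
    mask: Overlay
    lesion: LesionSpec
    electrodes: ElectrodeSet


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    surfaces: Dict[str, Dict[str, HemisphereSurface]]
    thickness: Overlay
    correspondence: TemplateCorrespondence
    patients: list[SyntheticPatient]
    controls: list[Dict[str, FeatureSet]]


def _draw_lesion_radius(spec: SyntheticCohortSpec, surface_area: float,
                        rng: np.random.Generator) -> float:
    if spec.lesion_radius_mm is not None:
        return spec.lesion_radius_mm
    scale = surface_area / spec.real_hemisphere_area_mm2
    median_area = spec.real_lesion_median_mm2 * scale
    area = median_area * np.exp(rng.normal(scale=0.5))
    return float(np.sqrt(area / np.pi))


def make_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``spec.seed``."""
    surfaces, thickness, corr = make_hemisphere_pair(spec.subdivision,
                                                     spec.radius_mm)
    rng = np.random.default_rng(spec.seed + 1)
    area = float(feat.vertex_areas(surfaces["left"]["white"]).values.sum())
    patients = []
    for i in range(spec.n_patients):
        hemi = "left" if rng.uniform() < 0.5 else "right"
        center = int(rng.integers(surfaces[hemi]["white"].n_vertices))
        lesion = LesionSpec(
            center_vertex=center,
            geodesic_radius_mm=_draw_lesion_radius(spec, area, rng),
            effects=dict(spec.lesion_effects),
            hemisphere=hemi)
        base = generate_control(spec, seed=spec.seed + 100 + i)
        raw, mask = inject_lesion(base, surfaces, lesion)
        white = surfaces[hemi]["white"]
        soz_center = white.vertex_coords[center]
        other_targets = white.vertex_coords[
            rng.integers(white.n_vertices, size=max(spec.n_electrodes - 1, 0))]
        targets = np.vstack([soz_center[None], other_targets])
        electrodes = generate_electrodes(
            white, targets, spec.n_contacts, spec.contact_spacing_mm,
            seed=spec.seed + 200 + i, soz_center=soz_center,
            implant_laterality=hemi)
        patients.append(SyntheticPatient(f"patient-{i:02d}", raw, mask,
                                         lesion, electrodes))
    controls = [generate_control(spec, seed=spec.seed + 1000 + i)
                for i in range(spec.n_controls)]
    return SyntheticCohort(spec, surfaces, thickness, corr, patients, controls)


def prepare_classifier_data(cohort: SyntheticCohort,
                            smoothing: Optional[SmoothingSpec] = None,
                            z_score_channels=None):
    """Preprocess the cohort and package per-subject design matrices.

    Returns ``(patient_data, control_data, stats)`` with
    :class:`~lesionplan.classifier.SubjectData` entries ready for training,
    LOOCV and specificity evaluation. Cluster geometry uses the mid surface.
    """
    mid = {h: cohort.surfaces[h]["mid"] for h in cohort.surfaces}
    processed_patients, processed_controls, stats = feat.preprocess_cohort(
        [p.raw_features for p in cohort.patients], cohort.controls, mid,
        smoothing, z_score_channels)

    def matrices(processed):
        return {h: build_feature_matrix(processed[h]) for h in processed}

    patient_data = [
        SubjectData(p.subject_id, matrices(proc), mid,
                    mask=p.mask.values > 0, mask_hemisphere=p.lesion.hemisphere)
        for p, proc in zip(cohort.patients, processed_patients)]
    control_data = [
        SubjectData(f"control-{i:02d}", matrices(proc), mid,
                    mask=np.zeros(cohort.correspondence.template_vertex_count,
                                  dtype=bool),
                    mask_hemisphere=None)
        for i, proc in enumerate(processed_controls)]
    return patient_data, control_data, stats


# ---------------------------------------------------------------------------
# Printed cohort table fixture
# ---------------------------------------------------------------------------

def table1_fixture() -> list[PatientRecord]:
    """The packaged 34-patient cohort outcome table."""
    path = resources.files("lesionplan") / "data" / "table1.csv"
    with resources.as_file(path) as p:
        return read_cohort_table(p)
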