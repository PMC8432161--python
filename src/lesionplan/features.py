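"""Per-vertex surface feature computation and preprocessing.

The feature channels carried through the pipeline are cortical thickness,
gray-white intensity contrast, mean curvature, sulcal depth, intrinsic
(Gaussian) curvature, and intracortical/subcortical intensity samples at six
depths. Preprocessing runs smoothing -> within-subject z-scoring ->
between-subject z-scoring against control statistics -> interhemispheric
asymmetry, after which the design matrix for the vertex classifier can be
assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import csr_matrix, coo_matrix
from scipy.sparse.csgraph import dijkstra

from .surface_io import (AffineTransform, HemisphereSurface, Overlay,
                         ShapeError, ValidationError)

#: Canonical channel order for the classifier design matrix.
CHANNELS = (
    "thickness",
    "gw_contrast",
    "mean_curvature",
    "sulcal_depth",
    "intrinsic_curvature",
    "intensity_25",
    "intensity_50",
    "intensity_75",
    "intensity_gw",
    "intensity_sub_0.5",
    "intensity_sub_1.0",
)

INTENSITY_CHANNELS = tuple(c for c in CHANNELS if c.startswith("intensity"))

STAGES = ("raw", "smoothed", "normalized", "asymmetry-augmented")

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: Relative floor applied to standard deviations before division.
SD_FLOOR_REL = 1e-6


@dataclass
class SmoothingSpec:
    """Per-channel Gaussian smoothing widths (FWHM, mm).

    Defaults: 10 mm for thickness, gray-white contrast and all intensity
    samples; 20 mm for intrinsic curvature; no smoothing for mean curvature
    and sulcal depth.
    """

    fwhm_mm: Dict[str, float] = field(default_factory=lambda: {
        "thickness": 10.0,
        "gw_contrast": 10.0,
        "mean_curvature": 0.0,
        "sulcal_depth": 0.0,
        "intrinsic_curvature": 20.0,
        **{c: 10.0 for c in INTENSITY_CHANNELS},
    })

    def __post_init__(self) -> None:
        for channel, fwhm in self.fwhm_mm.items():
            if fwhm < 0:
                raise ValidationError(f"{channel}: negative FWHM")

    def fwhm(self, channel: str) -> float:
        return self.fwhm_mm.get(channel, 0.0)


@dataclass
class FeatureSet:
    """Named per-vertex feature channels for one hemisphere."""

    channels: Dict[str, np.ndarray]
    hemisphere: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ShapeError(f"channels have inconsistent lengths: {lengths}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        self.channels = {k: np.asarray(v, dtype=np.float64)
                         for k, v in self.channels.items()}

    @property
    def n_vertices(self) -> int:
        return len(next(iter(self.channels.values())))

    def advance_stage(self, new_stage: str) -> None:
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise ValidationError(
                f"stage may only move forward ({self.stage} -> {new_stage})")
        self.stage = new_stage

    def copy(self) -> "FeatureSet":
        return FeatureSet({k: v.copy() for k, v in self.channels.items()},
                          self.hemisphere, self.stage)


@dataclass
class ControlStats:
    """Per-vertex channel mean/sd over the control population."""

    mean: Dict[str, Dict[str, np.ndarray]]  # hemisphere -> channel -> array
    sd: Dict[str, Dict[str, np.ndarray]]
    n_controls: int

    def has_channel(self, hemisphere: str, channel: str) -> bool:
        return channel in self.mean.get(hemisphere, {})


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def triangle_areas(surface: HemisphereSurface) -> np.ndarray:
    v = surface.vertex_coords
    t = surface.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(surface: HemisphereSurface) -> Overlay:
    """Per-vertex area: one third of the incident triangle areas (mm^2)."""
    tri_area = triangle_areas(surface)
    if np.any(tri_area == 0.0):
        warnings.warn("mesh contains degenerate zero-area triangles")
    areas = np.zeros(surface.n_vertices)
    np.add.at(areas, surface.triangles.ravel(), np.repeat(tri_area / 3.0, 3))
    return Overlay(areas, name="vertex_area", units="mm^2")


def _incident_angles(surface: HemisphereSurface) -> np.ndarray:
    """Sum of incident triangle corner angles per vertex (radians)."""
    v = surface.vertex_coords
    t = surface.triangles
    total = np.zeros(surface.n_vertices)
    for corner in range(3):
        a = v[t[:, corner]]
        b = v[t[:, (corner + 1) % 3]]
        c = v[t[:, (corner + 2) % 3]]
        u1 = b - a
        u2 = c - a
        cosang = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1))
        np.add.at(total, t[:, corner], np.arccos(np.clip(cosang, -1.0, 1.0)))
    return total


def _border_vertices(surface: HemisphereSurface) -> np.ndarray:
    """Vertices on edges that belong to a single triangle."""
    tri = surface.triangles
    e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    border = np.zeros(surface.n_vertices, dtype=bool)
    border[uniq[counts == 1].ravel()] = True
    return border


def angle_deficits(surface: HemisphereSurface) -> np.ndarray:
    """Angle deficit per vertex: 2*pi (interior) or pi (border) minus the
    summed incident angles. Summed over a closed mesh this equals
    2*pi times the Euler characteristic (Gauss-Bonnet)."""
    angles = _incident_angles(surface)
    full = np.where(_border_vertices(surface), np.pi, 2.0 * np.pi)
    return full - angles


def intrinsic_curvature(surface: HemisphereSurface) -> Overlay:
    """Gaussian curvature via angle deficit over vertex area (1/mm^2).

    Vertices with no incident triangles are returned as NaN.
    """
    deficit = angle_deficits(surface)
    areas = vertex_areas(surface).values
    with np.errstate(divide="ignore", invalid="ignore"):
        k = deficit / areas
    isolated = np.ones(surface.n_vertices, dtype=bool)
    isolated[surface.triangles.ravel()] = False
    k[isolated | (areas == 0.0)] = np.nan
    return Overlay(k, name="intrinsic_curvature", units="1/mm^2")


# ---------------------------------------------------------------------------
# Depth sampling
# ---------------------------------------------------------------------------

def sample_at_depth(volume: np.ndarray, vox2mm: AffineTransform,
                    white: HemisphereSurface, gray: HemisphereSurface,
                    depth_fraction: Optional[float] = None,
                    subcortical_mm: Optional[float] = None) -> Overlay:
    """Trilinearly sample a volume along the white->gray vertex axis.

    ``depth_fraction`` in [0, 1] samples at white + f*(gray - white);
    ``subcortical_mm`` samples below the white surface along the inward
    continuation of that axis. Exactly one of the two must be given.
    Samples falling outside the volume are NaN (with a warning).
    """
    if (depth_fraction is None) == (subcortical_mm is None):
        raise ValueError("give exactly one of depth_fraction or subcortical_mm")
    if white.n_vertices != gray.n_vertices:
        raise ShapeError("white and gray surfaces are not vertex-paired")
    w = white.vertex_coords
    g = gray.vertex_coords
    if depth_fraction is not None:
        if not 0.0 <= depth_fraction <= 1.0:
            raise ValueError("depth_fraction must lie in [0, 1]")
        points = w + depth_fraction * (g - w)
        name = f"intensity_{int(round(depth_fraction * 100))}"
    else:
        axis = g - w
        norm = np.linalg.norm(axis, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        points = w - subcortical_mm * axis / norm
        name = f"intensity_sub_{subcortical_mm:g}"
    voxels = vox2mm.inverse().apply(points)
    values = map_coordinates(volume, voxels.T, order=1, mode="constant",
                             cval=np.nan)
    n_outside = int(np.isnan(values).sum())
    if n_outside:
        warnings.warn(f"{n_outside} sample points fell outside the volume")
    return Overlay(values, name=name)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

_SMOOTHER_CACHE: dict = {}


def _edge_graph(surface: HemisphereSurface) -> csr_matrix:
    e = surface.edges()
    v = surface.vertex_coords
    lengths = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    n = surface.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.concatenate([lengths, lengths])
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _smoothing_operator(surface: HemisphereSurface, fwhm_mm: float) -> csr_matrix:
    """Area-weighted geodesic Gaussian smoothing operator.

    Geodesic distances are approximated by shortest edge paths (Dijkstra),
    truncated at 3 sigma. The raw Gaussian kernel is rescaled by a symmetric
    Sinkhorn iteration so the operator both preserves constants and conserves
    the area-weighted overlay sum (to iteration tolerance).
    """
    sigma = fwhm_mm / FWHM_TO_SIGMA
    dist = dijkstra(_edge_graph(surface), directed=False, limit=3.0 * sigma)
    finite = np.isfinite(dist)
    kernel = np.zeros_like(dist)
    kernel[finite] = np.exp(-0.5 * (dist[finite] / sigma) ** 2)
    np.fill_diagonal(kernel, 1.0)

    areas = vertex_areas(surface).values
    sqrt_a = np.sqrt(areas)
    kprime = kernel * sqrt_a[:, None] * sqrt_a[None, :]
    # symmetric Sinkhorn: find s with  s_i * (K' s)_i = a_i
    s = np.ones_like(areas)
    for _ in range(200):
        s_new = areas / (kprime @ s)
        s_next = np.sqrt(s * s_new)
        if np.max(np.abs(s_next / s - 1.0)) < 1e-13:
            s = s_next
            break
        s = s_next
    weights = (kprime * s[:, None] * s[None, :]) / areas[:, None]
    return csr_matrix(weights)


def smooth_overlay(surface: HemisphereSurface, overlay: Overlay,
                   fwhm_mm: float) -> Overlay:
    """Geodesic Gaussian smoothing of an overlay; ``fwhm_mm=0`` is identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0.0:
        return Overlay(overlay.values.copy(), name=overlay.name, units=overlay.units)
    key = (id(surface), float(fwhm_mm))
    op = _SMOOTHER_CACHE.get(key)
    if op is None:
        op = _smoothing_operator(surface, fwhm_mm)
        _SMOOTHER_CACHE[key] = op
    return Overlay(op @ overlay.values, name=overlay.name, units=overlay.units)


def smooth_featureset(surface: HemisphereSurface, features: FeatureSet,
                      spec: Optional[SmoothingSpec] = None) -> FeatureSet:
    spec = spec or SmoothingSpec()
    out = {ch: smooth_overlay(surface, Overlay(vals), spec.fwhm(ch)).values
           for ch, vals in features.channels.items()}
    result = FeatureSet(out, features.hemisphere, features.stage)
    result.advance_stage("smoothed")
    return result


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _sd_floor(sd_scale: float) -> float:
    return max(SD_FLOOR_REL * sd_scale, 1e-12)


def normalize_within_subject(overlay: Overlay,
                             mask: Optional[np.ndarray] = None) -> Overlay:
    """Z-score an overlay against the subject's own vertex distribution."""
    values = overlay.values
    valid = np.isfinite(values)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if valid.sum() < 2:
        raise ValidationError("need at least 2 unmasked vertices to z-score")
    mu = values[valid].mean()
    sd = values[valid].std()  # population sd
    floor = _sd_floor(abs(sd) if sd > 0 else 1.0)
    if sd < floor:
        warnings.warn(f"{overlay.name}: near-constant overlay, z-scores set to 0")
        return Overlay(np.zeros_like(values), name=overlay.name, units="z")
    return Overlay((values - mu) / sd, name=overlay.name, units="z")


def build_control_stats(controls: Sequence[Dict[str, FeatureSet]]) -> ControlStats:
    """Estimate per-vertex channel mean/sd from >=2 control subjects.

    ``controls`` is a sequence of ``{hemisphere: FeatureSet}`` mappings, all
    on the common template index space and at the same stage.
    """
    if len(controls) < 2:
        raise ValidationError("need at least 2 controls for population stats")
    mean: Dict[str, Dict[str, np.ndarray]] = {}
    sd: Dict[str, Dict[str, np.ndarray]] = {}
    for hemi in controls[0]:
        mean[hemi] = {}
        sd[hemi] = {}
        for channel in controls[0][hemi].channels:
            stack = np.stack([c[hemi].channels[channel] for c in controls])
            mean[hemi][channel] = stack.mean(axis=0)
            sd[hemi][channel] = stack.std(axis=0, ddof=1)
    return ControlStats(mean, sd, n_controls=len(controls))


def normalize_between_subjects(overlay: Overlay, stats: ControlStats,
                               channel: str, hemisphere: str) -> Overlay:
    """Z-score a template-space overlay against the control population."""
    if not stats.has_channel(hemisphere, channel):
        raise ValidationError(f"control stats missing channel {channel!r} "
                              f"for hemisphere {hemisphere!r}")
    mu = stats.mean[hemisphere][channel]
    sd = stats.sd[hemisphere][channel]
    if len(overlay) != len(mu):
        raise ShapeError("overlay length does not match control stats")
    floor = _sd_floor(float(np.nanstd(
        np.concatenate([v for h in stats.mean.values() for v in [h[channel]]]))) or 1.0)
    divisor = np.maximum(sd, floor)
    return Overlay((overlay.values - mu) / divisor, name=overlay.name, units="z")


def interhemispheric_asymmetry(left_overlay: Overlay, right_overlay: Overlay
                               ) -> tuple[Overlay, Overlay]:
    """Left-minus-right and right-minus-left maps on the symmetric template."""
    if len(left_overlay) != len(right_overlay):
        raise ShapeError("hemisphere overlays differ in length")
    diff = left_overlay.values - right_overlay.values
    name = left_overlay.name
    return (Overlay(diff, name=f"{name}_asym"),
            Overlay(-diff, name=f"{name}_asym"))


# ---------------------------------------------------------------------------
# Subject pipeline and design matrix
# ---------------------------------------------------------------------------

def normalize_subject(features: Dict[str, FeatureSet],
                      stats: Optional[ControlStats] = None,
                      z_score_channels: Optional[Iterable[str]] = None
                      ) -> Dict[str, FeatureSet]:
    """Within-subject then between-subject z-scoring of both hemispheres.

    By default every channel is z-scored; pass ``z_score_channels`` to
    restrict normalization to a subset (others pass through unchanged).
    """
    selected = set(z_score_channels) if z_score_channels is not None else None
    out: Dict[str, FeatureSet] = {}
    for hemi, fs in features.items():
        channels = {}
        for name, vals in fs.channels.items():
            if selected is not None and name not in selected:
                channels[name] = vals.copy()
                continue
            z = normalize_within_subject(Overlay(vals, name=name))
            if stats is not None:
                z = normalize_between_subjects(z, stats, name, hemi)
            channels[name] = z.values
        result = FeatureSet(channels, hemi, fs.stage)
        result.advance_stage("normalized")
        out[hemi] = result
    return out


def add_asymmetry(features: Dict[str, FeatureSet]) -> Dict[str, FeatureSet]:
    """Append ``*_asym`` channels computed across the hemisphere pair."""
    left, right = features["left"], features["right"]
    new_left = dict(left.channels)
    new_right = dict(right.channels)
    for name in list(left.channels):
        la, ra = interhemispheric_asymmetry(
            Overlay(left.channels[name], name=name),
            Overlay(right.channels[name], name=name))
        new_left[f"{name}_asym"] = la.values
        new_right[f"{name}_asym"] = ra.values
    out = {}
    for hemi, chans in (("left", new_left), ("right", new_right)):
        fs = FeatureSet(chans, hemi, features[hemi].stage)
        fs.advance_stage("asymmetry-augmented")
        out[hemi] = fs
    return out


#: Column order of the classifier design matrix.
MATRIX_COLUMNS = tuple(CHANNELS) + tuple(f"{c}_asym" for c in CHANNELS)


def build_feature_matrix(features: FeatureSet) -> np.ndarray:
    """Stack the normalized channels and their asymmetry counterparts.

    Rows are template vertices of one hemisphere; columns follow
    :data:`MATRIX_COLUMNS` (11 feature channels + 11 asymmetry channels).
    """
    if features.stage != "asymmetry-augmented":
        raise ValidationError("feature matrix requires the asymmetry-augmented stage")
    cols = []
    for name in MATRIX_COLUMNS:
        if name not in features.channels:
            raise ValidationError(f"missing channel {name!r}")
        cols.append(features.channels[name])
    return np.column_stack(cols)


def apply_between_subject_stats(features: Dict[str, FeatureSet],
                                stats: ControlStats,
                                z_score_channels: Optional[Iterable[str]] = None
                                ) -> Dict[str, FeatureSet]:
    """Between-subject z-scoring of already within-normalized hemispheres."""
    selected = set(z_score_channels) if z_score_channels is not None else None
    out = {}
    for hemi, fs in features.items():
        channels = {}
        for name, vals in fs.channels.items():
            if selected is not None and name not in selected:
                channels[name] = vals.copy()
            else:
                channels[name] = normalize_between_subjects(
                    Overlay(vals, name=name), stats, name, hemi).values
        out[hemi] = FeatureSet(channels, hemi, fs.stage)
    return out


def preprocess_subject(features: Dict[str, FeatureSet],
                       surfaces: Dict[str, HemisphereSurface],
                       stats: Optional[ControlStats] = None,
                       smoothing: Optional[SmoothingSpec] = None,
                       z_score_channels: Optional[Iterable[str]] = None
                       ) -> Dict[str, FeatureSet]:
    """Full preprocessing chain: smooth -> z_within -> z_between -> asymmetry.

    ``stats`` must have been built from controls processed through the same
    smoothing and within-subject z-scoring (see :func:`preprocess_cohort`).
    """
    smoothed = {hemi: smooth_featureset(surfaces[hemi], fs, smoothing)
                for hemi, fs in features.items()}
    within = normalize_subject(smoothed, stats=None,
                               z_score_channels=z_score_channels)
    if stats is not None:
        within = apply_between_subject_stats(within, stats, z_score_channels)
    return add_asymmetry(within)


def preprocess_cohort(patients: Sequence[Dict[str, FeatureSet]],
                      controls: Sequence[Dict[str, FeatureSet]],
                      surfaces: Dict[str, HemisphereSurface],
                      smoothing: Optional[SmoothingSpec] = None,
                      z_score_channels: Optional[Iterable[str]] = None):
    """Preprocess a whole cohort sharing one template surface pair.

    Control statistics are estimated from the controls after smoothing and
    within-subject z-scoring, then applied to everyone. Returns
    ``(processed_patients, processed_controls, stats)``.
    """
    def _within(raw: Dict[str, FeatureSet]) -> Dict[str, FeatureSet]:
        smoothed = {hemi: smooth_featureset(surfaces[hemi], fs, smoothing)
                    for hemi, fs in raw.items()}
        return normalize_subject(smoothed, stats=None,
                                 z_score_channels=z_score_channels)

    controls_within = [_within(c) for c in controls]
    stats = build_control_stats(controls_within)

    def _finish(within: Dict[str, FeatureSet]) -> Dict[str, FeatureSet]:
        between = apply_between_subject_stats(within, stats, z_score_channels)
        return add_asymmetry(between)

    processed_controls = [_finish(c) for c in controls_within]
    processed_patients = [_finish(_within(p)) for p in patients]
    return processed_patients, processed_controls, stats
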