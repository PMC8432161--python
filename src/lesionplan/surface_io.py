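"""Readers and writers for cortical surface data and cohort records.

Supported formats: FreeSurfer binary surfaces, FreeSurfer "curv" and MGH
per-vertex overlays, NIfTI/MGH volumes, Slicer FCSV fiducials or plain CSV
electrode contact files, whitespace-delimited 4x4 affines, and the cohort
record CSV.

Conventions: coordinates are millimetres in scanner RAS; vertex indices are
0-based; affines act on column vectors with a homogeneous coordinate
appended.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class FormatError(ValueError):
    """File does not conform to the declared on-disk format."""


class ShapeError(ValueError):
    """Array sizes are inconsistent (e.g. overlay vs surface)."""


class ValidationError(ValueError):
    """Semantically invalid content (unknown enum value, bad matrix...)."""


HEMISPHERES = ("left", "right")
SURFACE_KINDS = ("white", "pial", "mid")
CONTACT_LABELS = ("SOZ", "irritative", "uninvolved")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HemisphereSurface:
    """Triangulated cortical hemisphere surface in scanner RAS (mm)."""

    vertex_coords: np.ndarray  # (n_vertices, 3) float
    triangles: np.ndarray      # (n_triangles, 3) int
    hemisphere: str = "left"
    surface_kind: str = "white"

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ShapeError("vertex_coords must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ShapeError("triangles must be (m, 3)")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"hemisphere must be one of {HEMISPHERES}")
        if self.surface_kind not in SURFACE_KINDS:
            raise ValidationError(f"surface_kind must be one of {SURFACE_KINDS}")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) sorted-index array."""
        tri = self.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def adjacency(self):
        """Sparse symmetric vertex adjacency (shared-edge connectivity)."""
        e = self.edges()
        n = self.n_vertices
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def validate(self) -> None:
        """Enforce the structural invariants; raise ValidationError if broken."""
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices:
                raise ValidationError("triangle indices out of range")
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            raise ValidationError("surface has vertices not referenced by any triangle")
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        if n_comp != 1:
            raise ValidationError(f"surface is not edge-connected ({n_comp} components)")


@dataclass
class Overlay:
    """One scalar value per surface vertex."""

    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TemplateCorrespondence:
    """Per-vertex mapping from subject vertices onto a symmetric template.

    Both hemispheres map into the same template index space so that
    left/right values can be compared vertex-by-vertex.
    """

    subject_to_template: dict  # hemisphere -> int array of template indices
    template_vertex_count: int

    def __post_init__(self) -> None:
        for hemi, idx in self.subject_to_template.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.min(initial=0) < 0 or (idx.size and idx.max() >= self.template_vertex_count):
                raise ValidationError(f"{hemi}: template indices out of range")
            self.subject_to_template[hemi] = idx

    @classmethod
    def identity(cls, n_vertices: int) -> "TemplateCorrespondence":
        idx = np.arange(n_vertices)
        return cls({"left": idx.copy(), "right": idx.copy()}, n_vertices)

    def to_template(self, hemisphere: str, overlay: Overlay) -> Overlay:
        idx = self.subject_to_template[hemisphere]
        if len(overlay) != len(idx):
            raise ShapeError("overlay length does not match correspondence table")
        out = np.full(self.template_vertex_count, np.nan)
        out[idx] = overlay.values
        return Overlay(out, name=overlay.name, units=overlay.units)


@dataclass
class AffineTransform:
    """4x4 homogeneous affine between two named coordinate spaces."""

    matrix: np.ndarray
    source_space: str = "source"
    target_space: str = "target"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ShapeError("affine must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-8):
            raise ValidationError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix),
                               source_space=self.target_space,
                               target_space=self.source_space)


@dataclass
class Contact:
    """A single depth-electrode recording contact."""

    electrode: str
    index: int
    coord: np.ndarray  # (3,) mm
    label: str

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=np.float64).ravel()
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValidationError("contact coordinate must be 3 finite numbers")
        if self.label not in CONTACT_LABELS:
            raise ValidationError(
                f"unknown contact label {self.label!r}; allowed: {list(CONTACT_LABELS)}")


INDICATIONS = ("lesion-negative", "discordance", "not-definitive")
OUTCOMES = ("focal", "mTLE", "diffuse", "likely-focal")
CONCORDANCES = ("yes", "no", "not-applicable")
SURGERIES = ("yes", "no", "thermocoagulation", "thermocoagulation+laser")
HISTOLOGIES = ("FCD IIA", "FCD IIB", "FCD II", "HS", "nondiagnostic", "other",
               "not-applicable")
SEIZURE_FREE = ("yes", "no", "not-applicable")


@dataclass
class PatientRecord:
    """One row of the cohort outcome table."""

    patient_id: int
    seeg_indication: str
    seeg_outcome: str
    n_clusters: int
    concordance: str
    surgery: str
    histology: str
    seizure_free: str
    followup_months: Optional[int] = None

    def __post_init__(self) -> None:
        for value, allowed, name in (
                (self.seeg_indication, INDICATIONS, "seeg_indication"),
                (self.seeg_outcome, OUTCOMES, "seeg_outcome"),
                (self.concordance, CONCORDANCES, "concordance"),
                (self.surgery, SURGERIES, "surgery"),
                (self.histology, HISTOLOGIES, "histology"),
                (self.seizure_free, SEIZURE_FREE, "seizure_free")):
            if value not in allowed:
                raise ValidationError(
                    f"patient {self.patient_id}: {name}={value!r} not in {list(allowed)}")
        if self.n_clusters < 0:
            raise ValidationError(f"patient {self.patient_id}: negative cluster count")
        # Concordance is assessed only when sEEG found a focal cortical onset.
        if (self.concordance == "not-applicable") != (self.seeg_outcome != "focal"):
            raise ValidationError(
                f"patient {self.patient_id}: concordance must be not-applicable "
                f"exactly when sEEG outcome is non-focal")


# ---------------------------------------------------------------------------
# Surfaces and overlays
# ---------------------------------------------------------------------------

def _infer_hemisphere(path: str) -> str:
    base = os.path.basename(path)
    if base.startswith("rh.") or "right" in base:
        return "right"
    return "left"


def _infer_kind(path: str) -> str:
    base = os.path.basename(path)
    for kind in ("pial", "mid"):
        if kind in base:
            return kind
    return "white"


def read_surface(path: str, hemisphere: Optional[str] = None,
                 surface_kind: Optional[str] = None) -> HemisphereSurface:
    """Read a FreeSurfer binary surface file."""
    try:
        coords, faces = nib.freesurfer.read_geometry(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a FreeSurfer surface file ({exc})") from exc
    return HemisphereSurface(
        coords, faces,
        hemisphere=hemisphere or _infer_hemisphere(path),
        surface_kind=surface_kind or _infer_kind(path))


def write_surface(path: str, surface: HemisphereSurface) -> None:
    nib.freesurfer.write_geometry(path, surface.vertex_coords, surface.triangles)


def read_overlay(path: str, surface: Optional[HemisphereSurface] = None,
                 name: str = "") -> Overlay:
    """Read a per-vertex overlay in FreeSurfer curv or MGH format."""
    if str(path).endswith((".mgh", ".mgz")):
        img = nib.load(path)
        values = np.asarray(img.get_fdata()).ravel()
    else:
        try:
            values = nib.freesurfer.read_morph_data(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a curv overlay ({exc})") from exc
    overlay = Overlay(values, name=name or os.path.basename(str(path)))
    if surface is not None and len(overlay) != surface.n_vertices:
        raise ShapeError(
            f"{path}: overlay has {len(overlay)} values but surface has "
            f"{surface.n_vertices} vertices")
    return overlay


def write_overlay(path: str, overlay: Overlay) -> None:
    if str(path).endswith((".mgh", ".mgz")):
        data = overlay.values.astype(np.float32).reshape(-1, 1, 1)
        nib.save(nib.MGHImage(data, np.eye(4)), path)
    else:
        nib.freesurfer.write_morph_data(path, overlay.values.astype(np.float32))


def read_volume(path: str):
    """Load a NIfTI/MGH volume; returns (data array, voxel->mm AffineTransform)."""
    img = nib.load(path)
    return (np.asarray(img.get_fdata(), dtype=np.float64),
            AffineTransform(img.affine, "voxel", "mm"))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _split_contact_name(name: str) -> tuple[str, int]:
    for sep in ("-", "_"):
        if sep in name:
            stem, _, tail = name.rpartition(sep)
            if tail.isdigit():
                return stem, int(tail)
    # trailing digits without separator, e.g. "LA3"
    i = len(name)
    while i > 0 and name[i - 1].isdigit():
        i -= 1
    if i < len(name):
        return name[:i], int(name[i:])
    return name, 0


def _read_contacts_fcsv(path: str) -> list[Contact]:
    contacts = []
    lps = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line and ("LPS" in line or "= 0" in line):
                    lps = True
                continue
            parts = line.split(",")
            # columns: id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,assoc
            x, y, z = (float(parts[i]) for i in (1, 2, 3))
            if lps:
                x, y = -x, -y
            name = parts[11] if len(parts) > 11 else parts[0]
            label = parts[12].strip() if len(parts) > 12 else ""
            electrode, idx = _split_contact_name(name.strip())
            contacts.append(Contact(electrode, idx, (x, y, z), label))
    return contacts


def _read_contacts_csv(path: str) -> list[Contact]:
    contacts = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"electrode", "contact", "x", "y", "z", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: contact CSV must have columns {sorted(required)}")
        for row in reader:
            contacts.append(Contact(
                row["electrode"], int(row["contact"]),
                (float(row["x"]), float(row["y"]), float(row["z"])),
                row["label"].strip()))
    return contacts


def read_contacts(path: str) -> list[Contact]:
    """Read electrode contacts from a Slicer FCSV fiducial file or a CSV."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        return _read_contacts_fcsv(path)
    return _read_contacts_csv(path)


def write_contacts_csv(path: str, contacts: Sequence[Contact]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["electrode", "contact", "x", "y", "z", "label"])
        for c in contacts:
            writer.writerow([c.electrode, c.index, *(f"{v:.6f}" for v in c.coord), c.label])


def read_affine(path: str, source_space: str = "source",
                target_space: str = "target") -> AffineTransform:
    """Read a whitespace-delimited 4x4 affine text file."""
    try:
        mat = np.loadtxt(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse affine ({exc})") from exc
    if mat.shape != (4, 4):
        raise FormatError(f"{path}: affine must be 4x4, got {mat.shape}")
    return AffineTransform(mat, source_space, target_space)


def write_affine(path: str, affine: AffineTransform) -> None:
    np.savetxt(path, affine.matrix, fmt="%.10g")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

_INDICATION_MAP = {
    "lesion-negative": "lesion-negative", "lesion negative": "lesion-negative",
    "mri-negative": "lesion-negative",
    "discordance": "discordance",
    "not definitive": "not-definitive", "not-definitive": "not-definitive",
}
_OUTCOME_MAP = {
    "focal": "focal",
    "mtle": "mTLE",
    "diffuse": "diffuse", "diffuse (rasmussen)": "diffuse",
    "likely focal": "likely-focal", "likely-focal": "likely-focal",
}
_YN_MAP = {"y": "yes", "yes": "yes", "n": "no", "no": "no",
           "n.a.": "not-applicable", "na": "not-applicable", "": "not-applicable"}
_SURGERY_MAP = {
    "y": "yes", "yes": "yes", "n": "no", "no": "no",
    "tc": "thermocoagulation", "thermocoagulation": "thermocoagulation",
    "tc & laser": "thermocoagulation+laser", "tc&laser": "thermocoagulation+laser",
    "thermocoagulation+laser": "thermocoagulation+laser",
}
_HISTOLOGY_MAP = {
    "fcd iia": "FCD IIA", "fcd iib": "FCD IIB", "fcd ii": "FCD II",
    "hs": "HS", "non-diag": "nondiagnostic", "nondiagnostic": "nondiagnostic",
    "non diag": "nondiagnostic", "other": "other",
    "n.a.": "not-applicable", "na": "not-applicable", "": "not-applicable",
}
_SEIZURE_MAP = {
    "seizure-free": "yes", "seizure free": "yes", "yes": "yes", "y": "yes",
    "not seizure-free": "no", "not seizure free": "no", "no": "no", "n": "no",
    "n.a.": "not-applicable", "na": "not-applicable", "": "not-applicable",
}


def _map_enum(raw, mapping: dict, column: str, row_id) -> str:
    key = str(raw).strip().lower().replace("‐", "-").replace("‑", "-")
    if key in mapping:
        return mapping[key]
    raise ValidationError(f"row {row_id}: cannot map {column} value {raw!r}")


def read_cohort_table(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for _, row in df.iterrows():
        pid = int(row["patient"])
        followup = str(row.get("followup_months", "")).strip().lower()
        followup_months = None if followup in ("", "n.a.", "na", "nan") else int(float(followup))
        records.append(PatientRecord(
            patient_id=pid,
            seeg_indication=_map_enum(row["seeg_indication"], _INDICATION_MAP,
                                      "seeg_indication", pid),
            seeg_outcome=_map_enum(row["seeg_outcome"], _OUTCOME_MAP, "seeg_outcome", pid),
            n_clusters=int(row["n_clusters"]),
            concordance=_map_enum(row["concordance"], _YN_MAP, "concordance", pid),
            surgery=_map_enum(row["surgery"], _SURGERY_MAP, "surgery", pid),
            histology=_map_enum(row["histology"], _HISTOLOGY_MAP, "histology", pid),
            seizure_free=_map_enum(row["outcome"], _SEIZURE_MAP, "outcome", pid),
            followup_months=followup_months,
        ))
    return records
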