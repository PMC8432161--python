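"""Vertex-wise lesion classifier.

A single-hidden-layer network scores every cortical vertex as lesional or
non-lesional. The hidden layer width is the smallest number of principal
components explaining more than 99% of the control-cohort feature variance.
Training examples are balanced per subject: all vertices inside the lesion
mask against an equal number sampled from the contralateral hemisphere. The
decision threshold maximizes the Youden index on the training scores, and
evaluation uses leave-one-out cross-validation plus a control-cohort
specificity check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .clustering import DEFAULT_MIN_AREA_MM2, extract_clusters, overlap_with_mask
from .surface_io import HemisphereSurface, Overlay, ValidationError

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 10)
MAX_ITER = 500


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything needed to use one lesional subject in training/evaluation."""

    subject_id: str
    matrices: Dict[str, np.ndarray]          # hemisphere -> (n_vertices, n_features)
    surfaces: Dict[str, HemisphereSurface]
    mask: np.ndarray                         # boolean, on the mask hemisphere
    mask_hemisphere: Optional[str]           # None for controls

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class TrainingSet:
    X: np.ndarray
    y: np.ndarray                 # 1 lesional, 0 healthy
    subject_ids: np.ndarray       # provenance, one entry per row
    vertex_ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.y) == len(self.subject_ids) == len(self.vertex_ids) == n):
            raise ValidationError("training-set arrays have inconsistent lengths")


@dataclass
class ClassifierModel:
    """Trained one-hidden-layer network plus its decision threshold."""

    network: MLPClassifier
    input_dim: int
    hidden_size: int
    training_seed: int
    decision_threshold: Optional[float] = None
    converged: bool = True
    training_subject_ids: tuple = ()

    def to_json(self) -> str:
        net = self.network
        payload = {
            "format": "lesionplan-classifier-v1",
            "input_dim": self.input_dim,
            "hidden_size": self.hidden_size,
            "training_seed": self.training_seed,
            "decision_threshold": self.decision_threshold,
            "converged": self.converged,
            "training_subject_ids": list(self.training_subject_ids),
            "coefs": [w.tolist() for w in net.coefs_],
            "intercepts": [b.tolist() for b in net.intercepts_],
        }
        return json.dumps(payload)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        payload = json.loads(text)
        if payload.get("format") != "lesionplan-classifier-v1":
            raise ValidationError("unrecognized classifier file format")
        net = MLPClassifier(hidden_layer_sizes=(payload["hidden_size"],),
                            activation="logistic", max_iter=MAX_ITER)
        # minimal fitted-state reconstruction
        net.coefs_ = [np.asarray(w) for w in payload["coefs"]]
        net.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
        net.n_layers_ = 3
        net.n_outputs_ = 1
        net.out_activation_ = "logistic"
        net.classes_ = np.array([0, 1])
        net._label_binarizer = None
        return cls(network=net, input_dim=payload["input_dim"],
                   hidden_size=payload["hidden_size"],
                   training_seed=payload["training_seed"],
                   decision_threshold=payload["decision_threshold"],
                   converged=payload["converged"],
                   training_subject_ids=tuple(payload["training_subject_ids"]))

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_hidden_size(control_matrix: np.ndarray, variance_target: float = 0.99
                       ) -> int:
    """Smallest number of principal components explaining > ``variance_target``
    of the control feature variance (capped at matrix rank)."""
    X = np.asarray(control_matrix, dtype=np.float64)
    X = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0.0:
        return 1
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = max(int((s > tol).sum()), 1)
    cumulative = np.cumsum(var) / total
    k = int(np.searchsorted(cumulative, variance_target, side="right")) + 1
    return min(k, rank)


def assemble_training_set(subjects: Sequence[SubjectData], seed: int
                          ) -> TrainingSet:
    """Balanced lesional/contralateral-healthy vertex examples.

    For every subject, all mask vertices become lesional rows and an equal
    number of vertices sampled without replacement from the contralateral
    hemisphere become healthy rows.
    """
    rng = np.random.default_rng(seed)
    xs, ys, sids, vids = [], [], [], []
    for subj in subjects:
        if subj.mask_hemisphere is None:
            raise ValidationError(f"{subj.subject_id}: no lesion mask")
        if subj.mask_hemisphere not in ("left", "right"):
            raise ValidationError(
                f"{subj.subject_id}: bilateral or unknown mask hemisphere; "
                "contralateral sampling undefined")
        lesional_ids = np.flatnonzero(subj.mask)
        if lesional_ids.size == 0:
            raise ValidationError(f"{subj.subject_id}: empty lesion mask")
        contra = "right" if subj.mask_hemisphere == "left" else "left"
        contra_matrix = subj.matrices[contra]
        if lesional_ids.size > contra_matrix.shape[0]:
            raise ValidationError(
                f"{subj.subject_id}: mask larger than contralateral hemisphere")
        healthy_ids = rng.choice(contra_matrix.shape[0], size=lesional_ids.size,
                                 replace=False)
        xs.append(subj.matrices[subj.mask_hemisphere][lesional_ids])
        ys.append(np.ones(lesional_ids.size, dtype=np.int64))
        xs.append(contra_matrix[healthy_ids])
        ys.append(np.zeros(healthy_ids.size, dtype=np.int64))
        sids.extend([subj.subject_id] * (2 * lesional_ids.size))
        vids.append(lesional_ids)
        vids.append(healthy_ids)
    return TrainingSet(np.vstack(xs), np.concatenate(ys),
                       np.asarray(sids), np.concatenate(vids))


def train_network(training_set: TrainingSet, hidden_size: int, seed: int
                  ) -> ClassifierModel:
    """Train the one-hidden-layer sigmoidal network (cross-entropy loss)."""
    if len(np.unique(training_set.y)) < 2:
        raise ValidationError("training set must contain both classes")
    if hidden_size < 1:
        raise ValidationError("hidden_size must be >= 1")
    net = MLPClassifier(hidden_layer_sizes=(hidden_size,), activation="logistic",
                        solver="lbfgs", max_iter=MAX_ITER, random_state=seed)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        net.fit(training_set.X, training_set.y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("network did not converge within the iteration cap")
    return ClassifierModel(network=net, input_dim=training_set.X.shape[1],
                           hidden_size=hidden_size, training_seed=seed,
                           converged=converged,
                           training_subject_ids=tuple(
                               np.unique(training_set.subject_ids).tolist()))


def predict_vertices(model: ClassifierModel, matrix: np.ndarray) -> Overlay:
    """Per-vertex lesion scores in [0, 1]."""
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValidationError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.input_dim}")
    scores = model.network.predict_proba(X)[:, 1]
    return Overlay(np.clip(scores, 0.0, 1.0), name="lesion_score")


def youden_threshold(scores: np.ndarray, labels: np.ndarray,
                     grid: Optional[np.ndarray] = None) -> float:
    """Grid threshold maximizing sensitivity + specificity - 1.

    A vertex is called lesional when its score is >= the threshold. Ties are
    broken toward the highest threshold (favoring specificity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("Youden threshold needs both classes present")
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_j = None, -np.inf
    for t in grid:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and (best_t is None or t > best_t)):
            best_j, best_t = j, float(t)
    return best_t


@dataclass
class FoldResult:
    subject_id: str
    detected: bool
    threshold: float
    n_clusters: int
    training_subject_ids: tuple


@dataclass
class LoocvResult:
    folds: list[FoldResult]

    @property
    def sensitivity(self) -> float:
        return float(np.mean([f.detected for f in self.folds]))


def _subject_clusters(model: ClassifierModel, subject: SubjectData,
                      threshold: float, min_area_mm2: float):
    clusters = {}
    for hemi, matrix in subject.matrices.items():
        scores = predict_vertices(model, matrix)
        clusters[hemi] = extract_clusters(subject.surfaces[hemi], scores,
                                          threshold, min_area_mm2)
    return clusters


def loocv(subjects: Sequence[SubjectData], hidden_size: int, seed: int,
          threshold_grid: Optional[np.ndarray] = None,
          min_area_mm2: float = DEFAULT_MIN_AREA_MM2) -> LoocvResult:
    """Leave-one-out cross-validation over the lesional cohort.

    Each fold trains the network and picks the Youden threshold using only
    the remaining subjects, then scores both hemispheres of the left-out
    subject; the lesion counts as detected when any suprathreshold cluster
    on the mask hemisphere overlaps the lesion mask.
    """
    if len(subjects) < 2:
        raise ValidationError("LOOCV needs at least 2 subjects")
    folds = []
    for i, held_out in enumerate(subjects):
        training_subjects = [s for j, s in enumerate(subjects) if j != i]
        ts = assemble_training_set(training_subjects, seed=seed + i)
        model = train_network(ts, hidden_size, seed=seed + i)
        train_scores = predict_vertices(model, ts.X).values
        threshold = youden_threshold(train_scores, ts.y, threshold_grid)
        model.decision_threshold = threshold
        clusters = _subject_clusters(model, held_out, threshold, min_area_mm2)
        mask_overlay = Overlay(held_out.mask.astype(float))
        detected = any(overlap_with_mask(c, mask_overlay)
                       for c in clusters[held_out.mask_hemisphere])
        folds.append(FoldResult(
            subject_id=held_out.subject_id,
            detected=detected,
            threshold=threshold,
            n_clusters=sum(len(v) for v in clusters.values()),
            training_subject_ids=model.training_subject_ids))
        assert held_out.subject_id not in model.training_subject_ids
    return LoocvResult(folds)


def control_specificity(model: ClassifierModel, controls: Sequence[SubjectData],
                        threshold: Optional[float] = None,
                        min_area_mm2: float = DEFAULT_MIN_AREA_MM2
                        ) -> tuple[int, float]:
    """(total false-positive clusters, fraction of controls with none)."""
    threshold = model.decision_threshold if threshold is None else threshold
    if threshold is None:
        raise ValidationError("model has no decision threshold set")
    n_false = 0
    n_clean = 0
    for control in controls:
        clusters = _subject_clusters(model, control, threshold, min_area_mm2)
        n = sum(len(v) for v in clusters.values())
        n_false += n
        n_clean += int(n == 0)
    return n_false, n_clean / len(controls)
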