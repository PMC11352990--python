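"""Group templates, Procrustes alignment and cosine network/node distances.

Because the bilinear-pooled network is invariant to orthogonal rotation of
the latent coordinates, per-subject embeddings are only defined up to a
rotation and cannot be averaged or compared directly.  Subjects are
therefore aligned by orthogonal Procrustes — the rotation Q minimising
||E Q - R||_F — to an iteratively refined mean reference, after which
group templates are plain element-wise means:

    C+ = mean over aligned healthy subjects,
    C- = mean over aligned patients.

A subject is then summarised by two numbers: the cosine distance of its
flattened aligned representation to each template,

    CosDist(a, b) = 1 - a.b / (||a|| ||b||)   in [0, 2],

and per-node by the cosine distance between matching embedding rows.
Alignment is an isometry on rows, so it never changes row norms, row Gram
matrices, or cosine distances between two subjects rotated by the same Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .diffusion import NodeEmbeddings
from .exceptions import UndefinedDistanceError, ValidationError


@dataclass
class Template:
    group: str
    C: np.ndarray  # (n, d) mean aligned representation
    m_count: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.m_count < 1:
            raise ValidationError("template must average at least one subject")
        if not np.isfinite(self.C).all():
            raise ValidationError("template contains non-finite entries")


@dataclass
class DistanceFeatures:
    """The 2-vector fed to the classifier: distance to each group template."""

    subject_id: str
    d_healthy: float
    d_patient: float

    def __post_init__(self) -> None:
        for name, v in (("d_healthy", self.d_healthy), ("d_patient", self.d_patient)):
            if not (-1e-12 <= v <= 2 + 1e-12):
                raise ValidationError(f"{name}={v} outside [0, 2]")

    def as_array(self) -> np.ndarray:
        return np.array([self.d_healthy, self.d_patient])


@dataclass
class NodeDistanceVector:
    subject_id: str
    template_group: str
    d: np.ndarray  # (n,), each in [0, 2]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.size and (self.d.min() < -1e-12 or self.d.max() > 2 + 1e-12):
            raise ValidationError("node distances outside [0, 2]")


def cos_dist(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine distance 1 - cos(a, b), in [0, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedDistanceError("cosine distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def _as_matrix(E) -> np.ndarray:
    return E.E if isinstance(E, NodeEmbeddings) else np.asarray(E, dtype=float)


def align_to_reference(E, R) -> np.ndarray:
    """E Q with Q the orthogonal Procrustes solution of min ||E Q - R||_F."""
    E, R = _as_matrix(E), _as_matrix(R)
    if E.shape != R.shape:
        raise ValidationError(f"shape mismatch: {E.shape} vs {R.shape}")
    Q, _ = orthogonal_procrustes(E, R)
    return E @ Q


def build_template(
    embeddings: list, group: str = "", iterations: int = 3
) -> tuple[Template, list[np.ndarray]]:
    """Iterative aligned mean: align all to the reference, re-average, repeat.

    The first subject seeds the reference.  Returns the final mean as the
    template together with the per-subject aligned matrices.
    """
    if not embeddings:
        raise ValidationError("cannot build a template from an empty list")
    mats = [_as_matrix(e) for e in embeddings]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValidationError("all embeddings must share a shape")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    reference = mats[0]
    aligned = mats
    for _ in range(iterations):
        aligned = [align_to_reference(m, reference) for m in mats]
        reference = np.mean(aligned, axis=0)
    return Template(group, reference, len(mats)), aligned


def network_distance_features(
    aligned: np.ndarray, c_plus: Template, c_minus: Template, subject_id: str = ""
) -> DistanceFeatures:
    """Cosine distances of the row-major-flattened subject to each template."""
    A = _as_matrix(aligned)
    if A.shape != c_plus.C.shape or A.shape != c_minus.C.shape:
        raise ValidationError("subject/template shape mismatch")
    return DistanceFeatures(
        subject_id,
        cos_dist(A.ravel(), c_plus.C.ravel()),
        cos_dist(A.ravel(), c_minus.C.ravel()),
    )


def node_distances(aligned: np.ndarray, template: Template, subject_id: str = "") -> NodeDistanceVector:
    """Per-node cosine distance between matching rows of subject and template."""
    A = _as_matrix(aligned)
    if A.shape != template.C.shape:
        raise ValidationError("subject/template shape mismatch")
    out = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        if np.linalg.norm(A[i]) == 0.0 or np.linalg.norm(template.C[i]) == 0.0:
            raise UndefinedDistanceError(f"zero-norm row at node {i}")
        out[i] = cos_dist(A[i], template.C[i])
    return NodeDistanceVector(subject_id, template.group, out)
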