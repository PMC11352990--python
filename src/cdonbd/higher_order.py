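"""Higher-order brain network via homologous bilinear pooling.

Node latent features F (n x m) are fused into a network-level object by
the Gram matrix B = F F^T: entry (i, j) is the inner product of node i's
and node j's latent feature vectors, so B expresses pairwise similarity of
nodes in latent space rather than raw signal correlation.  B is symmetric
positive-semidefinite with rank at most m, and is invariant to any
orthogonal rotation of the latent coordinates — which is why downstream
embeddings need explicit alignment before they can be averaged.

No normalisation is applied to B here; the diffusion stage owns the
conversion to nonnegative walk weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cdon import LatentFeatures
from .exceptions import ValidationError


@dataclass
class HigherOrderNetwork:
    subject_id: str
    B: np.ndarray  # (n, n), symmetric PSD
    source: str  # latent feature source: "encoder" | "decoder"

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2 or self.B.shape[0] != self.B.shape[1]:
            raise ValidationError("higher-order network must be square")
        if np.abs(self.B - self.B.T).max() > 1e-10:
            raise ValidationError("higher-order network must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.B.shape[0]


def bilinear_pool(lf: LatentFeatures) -> HigherOrderNetwork:
    """B = F F^T, the matrix of node-pair inner products in latent space."""
    F = lf.F
    if not np.isfinite(F).all():
        raise ValidationError("latent features contain non-finite entries")
    B = F @ F.T
    B = (B + B.T) / 2.0  # exact symmetry despite fp round-off
    return HigherOrderNetwork(lf.subject_id, B, lf.source)
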