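"""Synthetic two-group connectome cohorts with known affected nodes.

The generator emulates a case/control resting-state study at the level
the pipeline consumes: regional time series whose population correlation
structure differs between groups on a known node subset.

Construction.  A control population correlation matrix Sigma0 is built
from a random sparse factor model: sparse loadings L (density
``base_density``) give a factor correlation structure, shrunk toward the
identity (Sigma0 = 0.6 * corr(L L^T) + 0.4 * I) so the matrix is
comfortably positive-definite and off-diagonal correlations are moderate,
as in real Fisher-z connectomes.  The patient matrix Sigma1 adds
``delta`` to the correlations of every pair of affected nodes and is
re-projected to the nearest positive-definite correlation matrix
(eigenvalue clipping at 1e-6 + diagonal renormalisation, iterated with
the affected-pair targets restored so the injected effect survives the
projection).  Each subject perturbs its group matrix with symmetric
entry-wise jitter of scale ``within_group_noise`` (re-projected) and
draws ``n_timepoints`` i.i.d. multivariate-normal samples.

Time series — not matrices — are generated so the Pearson + Fisher-z
network construction path is exercised end to end.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome_io import (
    RegionalTimeSeries,
    SubjectManifest,
    write_manifest,
    write_time_series,
)
from .exceptions import InfeasibleSpecError, ValidationError

EIG_FLOOR = 1e-6
_SHRINKAGE = 0.6  # weight of the factor structure vs the identity in Sigma0


@dataclass
class SyntheticSpec:
    n_nodes: int = 30
    n_timepoints: int = 150
    subjects_per_group: int = 20
    affected_nodes: tuple[int, ...] = ()
    delta: float = 0.0  # correlation offset on affected node pairs
    base_density: float = 0.3
    within_group_noise: float = 0.02
    seed: int = 0
    group_labels: tuple[str, str] = ("HC", "patient")  # (control, case)

    def __post_init__(self) -> None:
        self.affected_nodes = tuple(sorted(set(int(i) for i in self.affected_nodes)))
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints must be >= 3")
        if self.subjects_per_group < 1:
            raise ValidationError("subjects_per_group must be >= 1")
        if not 0.0 < self.base_density < 1.0:
            raise ValidationError("base_density must lie in (0, 1)")
        if self.within_group_noise < 0:
            raise ValidationError("within_group_noise must be nonnegative")
        if any(i < 0 or i >= self.n_nodes for i in self.affected_nodes):
            raise ValidationError("affected_nodes must lie in [0, n_nodes)")
        if self.delta > 0 and len(self.affected_nodes) < 2:
            raise ValidationError(
                "delta > 0 requires at least two affected nodes (the effect is pairwise)"
            )
        if len(self.group_labels) != 2 or self.group_labels[0] == self.group_labels[1]:
            raise ValidationError("group_labels must be two distinct labels")


@dataclass
class GroundTruth:
    affected_nodes: tuple[int, ...]
    delta: float
    sigma0: np.ndarray
    sigma1: np.ndarray
    group_labels: tuple[str, str]
    seed: int


def _eigclip_renormalise(M: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at the floor, then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    vals = np.maximum(vals, EIG_FLOOR)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def nearest_pd_correlation(
    M: np.ndarray,
    target_mask: np.ndarray | None = None,
    targets: np.ndarray | None = None,
    max_iter: int = 30,
) -> np.ndarray:
    """Nearest positive-definite correlation matrix by alternating projection.

    With a ``target_mask`` the masked entries are restored to ``targets``
    between projections so a deliberately injected effect is preserved;
    the final pass is a plain projection to guarantee validity.
    """
    A = np.asarray(M, dtype=float).copy()
    np.fill_diagonal(A, 1.0)
    for _ in range(max_iter):
        A = _eigclip_renormalise(A)
        if target_mask is not None:
            if np.abs(A[target_mask] - targets).max() < 1e-4:
                break
            A[target_mask] = targets
        else:
            break
    A = _eigclip_renormalise(A)
    if not np.isfinite(A).all():
        raise InfeasibleSpecError("projection to a PD correlation matrix failed")
    return A


def _control_correlation(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_nodes
    k = max(2, n // 6)
    loadings = rng.normal(size=(n, k)) * (rng.random((n, k)) < spec.base_density)
    S = loadings @ loadings.T + np.eye(n) * 1e-3
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    sigma0 = _SHRINKAGE * C + (1.0 - _SHRINKAGE) * np.eye(n)
    np.fill_diagonal(sigma0, 1.0)
    return nearest_pd_correlation(sigma0)


def _patient_correlation(spec: SyntheticSpec, sigma0: np.ndarray) -> np.ndarray:
    if spec.delta == 0 or len(spec.affected_nodes) < 2:
        return sigma0.copy()
    n = spec.n_nodes
    mask = np.zeros((n, n), dtype=bool)
    idx = np.asarray(spec.affected_nodes)
    mask[np.ix_(idx, idx)] = True
    np.fill_diagonal(mask, False)
    targets = np.clip(sigma0[mask] + spec.delta, -0.97, 0.97)
    raw = sigma0.copy()
    raw[mask] = targets
    return nearest_pd_correlation(raw, target_mask=mask, targets=targets)


def _sample_subject(
    sigma: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator, subject_id: str
) -> RegionalTimeSeries:
    n = spec.n_nodes
    if spec.within_group_noise > 0:
        noise = rng.normal(scale=spec.within_group_noise, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        sigma_i = nearest_pd_correlation(sigma + noise)
    else:
        sigma_i = sigma
    chol = np.linalg.cholesky(sigma_i + 1e-10 * np.eye(n))
    data = (rng.standard_normal((spec.n_timepoints, n)) @ chol.T).T
    return RegionalTimeSeries(subject_id, data)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[SubjectManifest, dict[str, RegionalTimeSeries], GroundTruth]:
    """Draw the full two-group cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sigma0 = _control_correlation(spec, rng)
    sigma1 = _patient_correlation(spec, sigma0)

    rows = []
    series: dict[str, RegionalTimeSeries] = {}
    for g, (label, sigma) in enumerate(
        zip(spec.group_labels, (sigma0, sigma1))
    ):
        for i in range(spec.subjects_per_group):
            sid = f"sub-{label}-{i:03d}"
            series[sid] = _sample_subject(sigma, spec, rng, sid)
            rows.append({"subject_id": sid, "group": label, "path": ""})
    manifest = SubjectManifest(pd.DataFrame(rows))
    truth = GroundTruth(
        spec.affected_nodes, spec.delta, sigma0, sigma1, spec.group_labels, spec.seed
    )
    return manifest, series, truth


def ground_truth_report(truth: GroundTruth) -> dict:
    """JSON-serialisable record of the affected set and pairwise effects."""
    effects = {}
    idx = list(truth.affected_nodes)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            effects[f"{i}-{j}"] = float(truth.sigma1[i, j] - truth.sigma0[i, j])
    return {
        "affected_nodes": list(truth.affected_nodes),
        "delta": float(truth.delta),
        "pairwise_effects": effects,
        "group_labels": list(truth.group_labels),
        "seed": int(truth.seed),
    }


def write_cohort(
    manifest: SubjectManifest,
    series: dict[str, RegionalTimeSeries],
    out_dir,
) -> SubjectManifest:
    """Write time-series files + manifest under ``out_dir``; returns the
    manifest with real file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = manifest.table.copy()
    paths = []
    for sid in table["subject_id"]:
        path = out_dir / f"{sid}.tsv"
        write_time_series(series[sid], path)
        paths.append(str(path))
    table["path"] = paths
    on_disk = SubjectManifest(table)
    write_manifest(on_disk, out_dir / "manifest.csv")
    return on_disk
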