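"""End-to-end pipeline: networks -> CDON -> bilinear -> diffusion -> metrics.

Stages are wired per the ablation mode:

* ``full``          — CDON latent features, bilinear pooling, diffusion
                      embedding; subjects represented by node embeddings.
* ``cdon_bilinear`` — stop after bilinear pooling; subjects represented by
                      the higher-order network B.
* ``cdon_only``     — subjects represented by the latent feature matrix F.

Whatever the representation, classification works the same way: align
subjects to an iterated mean template, compute the two cosine distances
to the healthy and patient group templates, and cross-validate an
RBF-SVM on those 2-D features.  In the default ``per_fold`` template mode
the templates are rebuilt inside every training fold so no held-out
subject influences template construction; ``whole_cohort`` mirrors the
simpler (leak-prone) protocol and is kept for comparison.

Every stage's RNG stream is derived from the single global seed by
hashing the stage name, so one integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome_io as cio
from .cdon import CdonConfig, extract_latent, split_columns, train_cdon
from .diffusion import CbowConfig, WalkConfig, generate_walks, train_cbow, transform_weights
from .evaluation import FoldScheme, Metrics, SvmParams, crossval_classify, node_group_stats
from .exceptions import CdonBdError, ValidationError
from .higher_order import bilinear_pool
from .synthetic import SyntheticSpec, generate_cohort, ground_truth_report
from .template_metrics import (
    Template,
    align_to_reference,
    build_template,
    network_distance_features,
    node_distances,
)

logger = logging.getLogger("cdonbd")

ABLATION_MODES = ("full", "cdon_bilinear", "cdon_only")
TEMPLATE_MODES = ("per_fold", "whole_cohort")
INPUT_MODES = ("timeseries", "matrices")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    input_mode: str = "timeseries"
    matrices_are_fisher_z: bool = False
    feature_source: str = "encoder"
    ablation: str = "full"
    template_mode: str = "per_fold"
    template_iterations: int = 3
    positive_group: str | None = None  # default: the non-control label
    cdon: CdonConfig = field(default_factory=CdonConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    cbow: CbowConfig = field(default_factory=CbowConfig)
    folds: FoldScheme = field(default_factory=FoldScheme)
    svm: SvmParams = field(default_factory=SvmParams)

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValidationError(f"input_mode must be one of {INPUT_MODES}")
        if self.feature_source not in ("encoder", "decoder"):
            raise ValidationError("feature_source must be 'encoder' or 'decoder'")
        if self.ablation not in ABLATION_MODES:
            raise ValidationError(f"ablation must be one of {ABLATION_MODES}")
        if self.template_mode not in TEMPLATE_MODES:
            raise ValidationError(f"template_mode must be one of {TEMPLATE_MODES}")
        if self.template_iterations < 1:
            raise ValidationError("template_iterations must be >= 1")
        # stage RNGs descend from the global seed unless set explicitly
        self.cdon = dataclasses.replace(self.cdon, seed=stage_seed(self.seed, "cdon"))
        self.walk = dataclasses.replace(self.walk, seed=stage_seed(self.seed, "walk"))
        self.cbow = dataclasses.replace(self.cbow, seed=stage_seed(self.seed, "cbow"))
        self.folds = dataclasses.replace(self.folds, seed=stage_seed(self.seed, "folds"))

    def fingerprint(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if callable(obj):
                return getattr(obj, "__name__", str(obj))
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = plain(getattr(self, f.name))
        return out


def scaled_config(n_nodes: int, seed: int = 0, **overrides) -> PipelineConfig:
    """Pipeline configuration scaled to the cohort's node count.

    The reference geometry is a 90-node parcellation with a 40-unit hidden
    layer, 60-dimensional embeddings and 10 walks per node.  For smaller
    networks the hidden width and embedding dimension shrink with the same
    compression ratios (m/n = 40/90, d/n = 60/90) so the autoencoder stays
    compressive and the embedding stays under-parameterised, and walks per
    node grow so the total walk corpus is comparable.  ``overrides`` are
    forwarded to :class:`PipelineConfig`.
    """
    m = max(2, round(n_nodes * 40 / 90))
    d = max(2, round(n_nodes * 60 / 90))
    r = max(10, round(10 * 90 / n_nodes))
    defaults = dict(
        seed=seed,
        cdon=CdonConfig(hidden_units=m),
        cbow=CbowConfig(dim=d),
        walk=WalkConfig(walks_per_node=r),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@dataclass
class PipelineResult:
    metrics: Metrics
    features: pd.DataFrame  # whole-cohort distance features (reporting)
    node_stats: dict[str, pd.DataFrame]  # keyed by template group
    subject_ids: list[str]
    labels: np.ndarray
    positive_group: str
    healthy_group: str
    representations: dict[str, np.ndarray]
    config: dict

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(
                {
                    "metrics": self.metrics.to_dict(),
                    "positive_group": self.positive_group,
                    "healthy_group": self.healthy_group,
                    "n_subjects": len(self.subject_ids),
                },
                fh,
                indent=2,
            )
        self.features.to_csv(out_dir / "distance_features.csv", index=False)
        for group, table in self.node_stats.items():
            table.to_csv(out_dir / f"node_stats_vs_{group}_template.csv", index=False)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(self.config, fh, indent=2)


def _load_networks(
    manifest: cio.SubjectManifest,
    config: PipelineConfig,
    series: dict[str, cio.RegionalTimeSeries] | None,
) -> dict[str, cio.ConnectivityMatrix]:
    networks = {}
    for sid, path in zip(manifest.subject_ids, manifest.table["path"]):
        try:
            if config.input_mode == "timeseries":
                ts = series[sid] if series is not None else cio.read_time_series(path, sid)
                cm = cio.fisher_z(cio.pearson_network(ts))
            else:
                cm = cio.read_matrix(path, sid, is_fisher_z=config.matrices_are_fisher_z)
                if not cm.is_fisher_z:
                    cm = cio.fisher_z(cm)
        except CdonBdError as exc:
            raise type(exc)(f"[network construction] subject {sid!r}: {exc}") from exc
        networks[sid] = cm
    return networks


def subject_representation(
    cm: cio.ConnectivityMatrix, config: PipelineConfig
) -> np.ndarray:
    """One subject through CDON (-> bilinear (-> diffusion)) per the ablation."""
    weights = train_cdon(split_columns(cm), config.cdon)
    latent = extract_latent(weights, config.feature_source, cm.subject_id)
    if config.ablation == "cdon_only":
        return latent.F
    hon = bilinear_pool(latent)
    if config.ablation == "cdon_bilinear":
        return hon.B
    W = transform_weights(hon, config.walk.weight_transform)
    corpus = generate_walks(W, config.walk)
    emb = train_cbow(corpus, config.cbow, cm.subject_id)
    return emb.E


def _template_features(
    reps: list[np.ndarray],
    labels: np.ndarray,
    healthy: str,
    patient: str,
    train_idx: np.ndarray,
    iterations: int,
) -> tuple[np.ndarray, list[np.ndarray], Template, Template]:
    """Align everyone to a training-subject template; 2-D distance features."""
    grand, _ = build_template([reps[i] for i in train_idx], "train", iterations)
    aligned = [align_to_reference(r, grand.C) for r in reps]
    train_set = set(train_idx.tolist())
    h_idx = [i for i in range(len(reps)) if labels[i] == healthy and i in train_set]
    p_idx = [i for i in range(len(reps)) if labels[i] == patient and i in train_set]
    if not h_idx or not p_idx:
        raise ValidationError("training subjects must cover both groups")
    c_plus = Template(healthy, np.mean([aligned[i] for i in h_idx], axis=0), len(h_idx))
    c_minus = Template(patient, np.mean([aligned[i] for i in p_idx], axis=0), len(p_idx))
    feats = np.array(
        [
            network_distance_features(aligned[i], c_plus, c_minus).as_array()
            for i in range(len(reps))
        ]
    )
    return feats, aligned, c_plus, c_minus


def _loo_node_distances(
    aligned: np.ndarray, template_idx: np.ndarray, group: str, sids: list[str]
) -> np.ndarray:
    """Per-node distances of every subject to the ``template_idx`` group mean.

    Subjects inside the template group are scored against the mean of the
    *other* members (leave-one-out) so their distances are out-of-sample,
    as they already are for everyone else.  Requires >= 2 template members.
    """
    if template_idx.size < 2:
        raise ValidationError("leave-one-out template needs >= 2 group members")
    total = aligned[template_idx].sum(axis=0)
    m = template_idx.size
    in_group = set(template_idx.tolist())
    dist = np.empty((aligned.shape[0], aligned.shape[1]))
    for i in range(aligned.shape[0]):
        C = (total - aligned[i]) / (m - 1) if i in in_group else total / m
        dist[i] = node_distances(aligned[i], Template(group, C, m), sids[i]).d
    return dist


def classify_representations(
    reps: list[np.ndarray],
    labels: np.ndarray,
    healthy: str,
    patient: str,
    config: PipelineConfig,
) -> Metrics:
    """Cross-validated classification on template-distance features."""
    all_idx = np.arange(len(reps))
    if config.template_mode == "whole_cohort":
        feats, *_ = _template_features(
            reps, labels, healthy, patient, all_idx, config.template_iterations
        )
        features: np.ndarray | callable = feats
    else:

        def features(train_idx: np.ndarray) -> np.ndarray:
            feats, *_ = _template_features(
                reps, labels, healthy, patient, train_idx, config.template_iterations
            )
            return feats

    return crossval_classify(
        features, labels, config.folds, config.svm, positive_label=patient
    )


def _resolve_groups(manifest: cio.SubjectManifest, config: PipelineConfig) -> tuple[str, str]:
    a, b = manifest.validate_two_groups()
    if config.positive_group is not None:
        if config.positive_group not in (a, b):
            raise ValidationError(f"positive_group {config.positive_group!r} not in manifest")
        patient = config.positive_group
    elif "HC" in (a, b):
        patient = b if a == "HC" else a
    else:
        patient = b
    healthy = a if patient == b else b
    return healthy, patient


def run_pipeline(
    config: PipelineConfig,
    manifest: cio.SubjectManifest,
    series: dict[str, cio.RegionalTimeSeries] | None = None,
    out_dir=None,
) -> PipelineResult:
    """Execute the configured pipeline over the cohort in the manifest."""
    healthy, patient = _resolve_groups(manifest, config)
    labels = np.asarray(manifest.groups)
    sids = manifest.subject_ids
    logger.info(
        "pipeline: %d subjects (%s vs %s), ablation=%s, template_mode=%s",
        len(sids), healthy, patient, config.ablation, config.template_mode,
    )

    networks = _load_networks(manifest, config, series)
    reps = []
    for sid in sids:
        try:
            reps.append(subject_representation(networks[sid], config))
        except CdonBdError as exc:
            raise type(exc)(f"[representation] subject {sid!r}: {exc}") from exc
        logger.debug("representation done: %s", sid)

    metrics = classify_representations(reps, labels, healthy, patient, config)

    # whole-cohort templates for the reported distance features
    feats, _, _, _ = _template_features(
        reps, labels, healthy, patient, np.arange(len(reps)), config.template_iterations
    )
    features_df = pd.DataFrame(
        {
            "subject_id": sids,
            "group": labels,
            "d_healthy": feats[:, 0],
            "d_patient": feats[:, 1],
        }
    )

    # node statistics in the healthy-norm frame: the alignment reference is
    # the iterated mean of the control group, so patient deviations are
    # measured against the healthy template rather than a pooled mean that
    # already absorbs half of the group effect.  Subjects belonging to the
    # template's own group are scored against the leave-one-out mean —
    # comparing a subject to a template containing itself biases its
    # distance low and fabricates group differences under the null.
    h_idx = np.flatnonzero(labels == healthy)
    p_idx = np.flatnonzero(labels == patient)
    hc_tmpl, _ = build_template(
        [reps[i] for i in h_idx], healthy, config.template_iterations
    )
    aligned_h = np.stack([align_to_reference(r, hc_tmpl.C) for r in reps])
    node_stats = {}
    node_labels = [f"node_{i}" for i in range(reps[0].shape[0])]
    for group, own_idx in ((healthy, h_idx), (patient, p_idx)):
        dist = _loo_node_distances(aligned_h, own_idx, group, sids)
        node_stats[group] = node_group_stats(
            dist[h_idx], dist[p_idx], node_labels
        )

    result = PipelineResult(
        metrics=metrics,
        features=features_df,
        node_stats=node_stats,
        subject_ids=sids,
        labels=labels,
        positive_group=patient,
        healthy_group=healthy,
        representations={sid: rep for sid, rep in zip(sids, reps)},
        config=config.fingerprint(),
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


def run_synthetic_benchmark(
    spec: SyntheticSpec, config: PipelineConfig, out_dir=None
) -> dict:
    """Generate a cohort, run the pipeline and score affected-node recovery.

    Recovery compares the nodes called significant (p_FDR < 0.05, node
    distances to the healthy template) against the generator's affected
    set, reporting precision and recall.
    """
    manifest, series, truth = generate_cohort(spec)
    result = run_pipeline(config, manifest, series=series)

    stats = result.node_stats[result.healthy_group]
    significant = set(np.flatnonzero(stats["significant"].to_numpy()).tolist())
    affected = set(truth.affected_nodes)
    tp = len(significant & affected)
    recall = tp / len(affected) if affected else float("nan")
    precision = tp / len(significant) if significant else float("nan")

    report = {
        "metrics": result.metrics.to_dict(),
        "ground_truth": ground_truth_report(truth),
        "significant_nodes": sorted(significant),
        "node_recall": recall,
        "node_precision": precision,
        "config": result.config,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.save(out_dir)
        with open(out_dir / "benchmark_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
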