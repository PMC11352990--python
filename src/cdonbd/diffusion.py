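"""Diffusion module: biased random walks + CBOW embedding of the nodes.

The higher-order network B is first converted into nonnegative walk
weights (negative inner products mean *dissimilar* nodes, so the default
clamps them to zero; an absolute-value mode is kept for sensitivity
analysis).  Second-order biased random walks are then run on the weighted
graph: when the walk sits at node c having arrived from s, the
unnormalised score of moving to neighbour t is

    lambda(s, t) * w_ct,   lambda = 1/p if t == s        (return)
                                    1   if t adjacent s  (stay close)
                                    1/q otherwise        (move outward)

with p the return parameter and q the in-out parameter.  The resulting
node sequences are treated as sentences and embedded with a continuous
bag-of-words (CBOW) model trained by negative sampling: each position
predicts its centre node from the *average* input embedding of the nodes
inside a symmetric window, against k noise nodes drawn from the corpus
unigram distribution raised to 3/4.  The input embedding table is the
subject's higher-order representation (n x d, default d = 60).

Everything is deterministic given the configured seeds.  Optimisation is
plain per-position stochastic gradient descent on the negative-sampling
loss, visiting positions in a seeded random order each epoch; the hot
loop is JIT-compiled with numba, with a pure-numpy loss/gradient function
(:func:`ns_loss_and_grad`) kept alongside as the checkable definition of
the update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .exceptions import DegenerateCorpusError, ValidationError
from .higher_order import HigherOrderNetwork


@dataclass
class WalkConfig:
    p: float = 1.0  # return parameter
    q: float = 1.0  # in-out parameter
    walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0
    weight_transform: str = "clamp_negative_to_zero"  # or "absolute_value"

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be positive")
        if self.walks_per_node < 1:
            raise ValidationError("walks_per_node must be >= 1")
        if self.walk_length < 2:
            raise ValidationError("walk_length must be >= 2")
        if self.weight_transform not in ("clamp_negative_to_zero", "absolute_value"):
            raise ValidationError(f"unknown weight_transform {self.weight_transform!r}")


@dataclass
class WalkCorpus:
    walks: list[list[int]]
    n_nodes: int

    def __post_init__(self) -> None:
        for w in self.walks:
            for v in w:
                if not (0 <= v < self.n_nodes):
                    raise ValidationError(f"walk node index {v} outside [0, {self.n_nodes})")

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class CbowConfig:
    dim: int = 60
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0
    noise_exponent: float = 0.75

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negatives < 1:
            raise ValidationError("dim, window and negatives must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")


@dataclass
class NodeEmbeddings:
    """Per-subject higher-order representation: row i embeds node i.

    ``E`` is the CBOW input table (the representation used downstream);
    ``output_table`` keeps the output/target table for objective
    evaluation and diagnostics.
    """

    subject_id: str
    E: np.ndarray  # (n, d)
    fingerprint: dict = field(default_factory=dict)
    output_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2:
            raise ValidationError("embeddings must be a 2-D matrix")
        if not np.isfinite(self.E).all():
            raise ValidationError("embeddings contain non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.E.shape[0]

    @property
    def dim(self) -> int:
        return self.E.shape[1]


def transform_weights(
    hon: HigherOrderNetwork | np.ndarray, mode: str = "clamp_negative_to_zero"
) -> np.ndarray:
    """Nonnegative walk weights from B; diagonal zeroed; isolated nodes warned."""
    B = hon.B if isinstance(hon, HigherOrderNetwork) else np.asarray(hon, dtype=float)
    if mode == "clamp_negative_to_zero":
        W = np.maximum(B, 0.0)
    elif mode == "absolute_value":
        W = np.abs(B)
    else:
        raise ValidationError(f"unknown weight transform {mode!r}")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    isolated = np.flatnonzero(W.sum(axis=1) == 0.0)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} node(s) have no positive-weight neighbour "
            f"(indices {isolated.tolist()}); walks from them stop at length 1",
            stacklevel=2,
        )
    return W


def transition_distribution(
    W: np.ndarray, prev: int | None, curr: int, p: float, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order transition law at ``curr`` given the previous node.

    Returns ``(candidates, probs)``; both empty when ``curr`` is isolated
    (a termination signal, not an error).  With ``prev is None`` (first
    step) the distribution is proportional to the edge weights alone.
    """
    w_row = W[curr]
    candidates = np.flatnonzero(w_row > 0.0)
    if candidates.size == 0:
        return candidates, np.empty(0)
    scores = w_row[candidates].astype(float)
    if prev is not None:
        lam = np.where(W[prev, candidates] > 0.0, 1.0, 1.0 / q)
        lam[candidates == prev] = 1.0 / p
        scores = scores * lam
    return candidates, scores / scores.sum()


def generate_walks(W: np.ndarray, cfg: WalkConfig) -> WalkCorpus:
    """r biased walks of length <= l from every node, advanced in lock-step.

    All active walks take one step per iteration with a shared seeded RNG,
    which is fast and still deterministic.  Each step samples exactly the
    law of :func:`transition_distribution`.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    rng = np.random.default_rng(cfg.seed)
    adj = W > 0.0
    inv_p, inv_q = 1.0 / cfg.p, 1.0 / cfg.q

    starts = np.repeat(np.arange(n), cfg.walks_per_node)
    n_walks = starts.size
    paths = np.full((n_walks, cfg.walk_length), -1, dtype=np.int64)
    paths[:, 0] = starts
    active = W[starts].sum(axis=1) > 0.0

    for step in range(1, cfg.walk_length):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        curr = paths[idx, step - 1]
        scores = W[curr].copy()  # (a, n)
        if step >= 2:
            prev = paths[idx, step - 2]
            lam = np.where(adj[prev], 1.0, inv_q)
            lam[np.arange(idx.size), prev] = inv_p
            scores *= lam
        totals = scores.sum(axis=1)
        alive = totals > 0.0
        if not alive.all():
            active[idx[~alive]] = False
            idx = idx[alive]
            scores = scores[alive]
            totals = totals[alive]
            if idx.size == 0:
                continue
        cdf = np.cumsum(scores, axis=1)
        u = rng.random(idx.size) * totals
        nxt = (cdf < u[:, None]).sum(axis=1)
        paths[idx, step] = nxt
        # a move into an isolated node ends the walk at the next step
        active[idx] = W[nxt].sum(axis=1) > 0.0

    walks = [row[row >= 0].tolist() for row in paths]
    return WalkCorpus(walks, n)


def write_corpus(corpus: WalkCorpus, path) -> None:
    """One walk per line, space-separated node indices."""
    with open(path, "w") as fh:
        for walk in corpus.walks:
            fh.write(" ".join(str(v) for v in walk) + "\n")


def read_corpus(path, n_nodes: int) -> WalkCorpus:
    with open(path) as fh:
        walks = [[int(v) for v in ln.split()] for ln in fh if ln.strip()]
    return WalkCorpus(walks, n_nodes)


# ---------------------------------------------------------------------------
# CBOW with negative sampling
# ---------------------------------------------------------------------------


def corpus_to_windows(
    walks: Sequence[Sequence[int]], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a corpus into (centers, padded context indices, context mask).

    Positions whose walk has length 1 (no context) are dropped.  Context
    padding uses index 0 with a False mask entry.
    """
    centers: list[int] = []
    ctx_rows: list[list[int]] = []
    width = 2 * window
    for walk in walks:
        L = len(walk)
        if L < 2:
            continue
        for t in range(L):
            lo, hi = max(0, t - window), min(L, t + window + 1)
            ctx = [walk[i] for i in range(lo, hi) if i != t]
            centers.append(walk[t])
            ctx_rows.append(ctx)
    n_pos = len(centers)
    ctx_arr = np.zeros((n_pos, width), dtype=np.int64)
    mask = np.zeros((n_pos, width), dtype=bool)
    for i, ctx in enumerate(ctx_rows):
        ctx_arr[i, : len(ctx)] = ctx
        mask[i, : len(ctx)] = True
    return np.asarray(centers, dtype=np.int64), ctx_arr, mask


def unigram_noise_distribution(
    walks: Sequence[Sequence[int]], n_nodes: int, exponent: float
) -> np.ndarray:
    """Corpus unigram counts raised to ``exponent``, normalised."""
    counts = np.zeros(n_nodes)
    for walk in walks:
        np.add.at(counts, np.asarray(walk, dtype=np.int64), 1.0)
    weights = np.where(counts > 0, counts**exponent, 0.0)
    total = weights.sum()
    if total <= 0:
        raise DegenerateCorpusError("empty corpus")
    return weights / total


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


@njit(cache=False)
def _sgd_epoch(
    Win, Wout, centers, ctx, mask, counts, order, negs, lr0, step0, total_steps
):  # pragma: no cover
    """One SGD epoch over all positions, in the order given.

    Word2vec-style in-place updates: for each position the context mean v
    is fixed, the output rows of the target and the k negatives are
    updated immediately, and the accumulated gradient w.r.t. v is pushed
    back to the context rows of the input table afterwards.  The step size
    decays linearly over the whole run from lr0 to lr0/10000 (the usual
    convention for this embedding family), which anneals the final iterate
    instead of leaving it bouncing at the initial step scale.
    """
    d = Win.shape[1]
    k = negs.shape[1]
    width = ctx.shape[1]
    v = np.empty(d)
    dv = np.empty(d)
    for ii in range(order.size):
        frac = (step0 + ii) / total_steps
        lr = lr0 * max(1.0 - frac, 0.0001)
        i = order[ii]
        c = centers[i]
        cnt = counts[i]
        for a in range(d):
            v[a] = 0.0
        for j in range(width):
            if mask[i, j]:
                row = ctx[i, j]
                for a in range(d):
                    v[a] += Win[row, a]
        for a in range(d):
            v[a] /= cnt
        s = 0.0
        for a in range(d):
            s += v[a] * Wout[c, a]
        g = 1.0 / (1.0 + np.exp(-s)) - 1.0
        for a in range(d):
            dv[a] = g * Wout[c, a]
            Wout[c, a] -= lr * g * v[a]
        for kk in range(k):
            nrow = negs[i, kk]
            s = 0.0
            for a in range(d):
                s += v[a] * Wout[nrow, a]
            g = 1.0 / (1.0 + np.exp(-s))
            for a in range(d):
                dv[a] += g * Wout[nrow, a]
                Wout[nrow, a] -= lr * g * v[a]
        for j in range(width):
            if mask[i, j]:
                row = ctx[i, j]
                for a in range(d):
                    Win[row, a] -= lr * dv[a] / cnt


def ns_loss_and_grad(
    Win: np.ndarray,
    Wout: np.ndarray,
    context: Sequence[int],
    target: int,
    negatives: Sequence[int],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Single-position negative-sampling loss and full-table gradients.

    Loss = -log sigma(v . u_t) - sum_neg log sigma(-v . u_neg) with v the
    mean input embedding of the context.  Returns dense gradients the same
    shape as the tables; intended for small instances and gradient checks.
    """
    context = np.asarray(context, dtype=np.int64)
    negatives = np.asarray(negatives, dtype=np.int64)
    if context.size == 0:
        raise ValidationError("empty context")
    v = Win[context].mean(axis=0)
    u_t = Wout[target]
    u_n = Wout[negatives]
    s_pos = float(v @ u_t)
    s_neg = u_n @ v
    loss = float(-_log_sigmoid(np.asarray(s_pos)) - _log_sigmoid(-s_neg).sum())

    g_pos = _sigmoid(np.asarray(s_pos)) - 1.0
    g_neg = _sigmoid(s_neg)
    gWout = np.zeros_like(Wout)
    gWout[target] += g_pos * v
    np.add.at(gWout, negatives, g_neg[:, None] * v[None, :])
    dv = g_pos * u_t + g_neg @ u_n
    gWin = np.zeros_like(Win)
    np.add.at(gWin, context, dv[None, :] / context.size)
    return loss, gWin, gWout


def negative_sampling_objective(
    Win: np.ndarray,
    Wout: np.ndarray,
    centers: np.ndarray,
    ctx: np.ndarray,
    mask: np.ndarray,
    negatives: np.ndarray,
) -> float:
    """Mean per-position objective log sigma(v.u_t) + sum log sigma(-v.u_neg).

    This is the quantity the trainer ascends (the negative of its loss);
    ``negatives`` is a fixed (N, k) sample so the value is comparable
    across parameter settings.
    """
    counts = mask.sum(axis=1)
    V = (Win[ctx] * mask[:, :, None]).sum(axis=1) / counts[:, None]
    s_pos = np.einsum("nd,nd->n", V, Wout[centers])
    s_neg = np.einsum("nd,nkd->nk", V, Wout[negatives])
    return float((_log_sigmoid(s_pos) + _log_sigmoid(-s_neg).sum(axis=1)).mean())


def train_cbow(corpus: WalkCorpus, cfg: CbowConfig, subject_id: str = "") -> NodeEmbeddings:
    """Train the two embedding tables and return the input table as E.

    Input table initialised uniform(-0.5, 0.5)/d from the seed (identical
    across subjects given the same seed and node count, so downstream
    alignment starts from a common frame); output table starts at zero.
    """
    walks = corpus.walks
    distinct = {v for walk in walks for v in walk}
    if len(distinct) < 2:
        raise DegenerateCorpusError(
            f"corpus has {len(distinct)} distinct node(s); need at least 2"
        )
    n, d = corpus.n_nodes, cfg.dim
    rng = np.random.default_rng(cfg.seed)
    Win = (rng.random((n, d)) - 0.5) / d
    Wout = np.zeros((n, d))

    centers, ctx, mask = corpus_to_windows(walks, cfg.window)
    N = centers.size
    if N == 0:
        raise DegenerateCorpusError("corpus has no position with a nonempty context")
    counts = mask.sum(axis=1).astype(float)
    noise = unigram_noise_distribution(walks, n, cfg.noise_exponent)
    noise_cdf = np.cumsum(noise)
    lr, k = cfg.learning_rate, cfg.negatives

    total_steps = cfg.epochs * N
    for epoch in range(cfg.epochs):
        order = rng.permutation(N)
        negs = np.searchsorted(noise_cdf, rng.random((N, k)), side="right").astype(np.int64)
        np.clip(negs, 0, n - 1, out=negs)
        _sgd_epoch(
            Win, Wout, centers, ctx, mask, counts, order, negs, lr, epoch * N, total_steps
        )

    fingerprint = {
        "dim": d,
        "window": cfg.window,
        "negatives": k,
        "epochs": cfg.epochs,
        "learning_rate": lr,
        "seed": cfg.seed,
        "noise_exponent": cfg.noise_exponent,
    }
    return NodeEmbeddings(subject_id, Win, fingerprint, output_table=Wout)
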