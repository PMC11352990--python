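# Methods

This note documents the models and procedures implemented in `cdonbd`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not establish.

## Overview

The package learns a *higher-order* representation of a functional brain
network and uses it for two-group disease analysis. For each subject:

1. **Network construction** — Pearson correlation between regional BOLD
   time series, then Fisher's r-to-z (`z = atanh(r)`). Self-connections
   are fixed at 0 throughout: self-loops are meaningless for random
   walks, and `atanh(1)` is infinite. Correlations of magnitude 1 are
   clipped to `1 − 1e−7` before the transform.
2. **CDON (Continuous Dictionary of Nodes)** — the n×n network is split
   into its n columns, and a three-layer *linear* autoencoder
   (`h = We x + be`, `x̂ = Wd h + bd`, hidden width m) is trained on those
   columns by full-batch gradient descent on the mean squared
   reconstruction error. The encoder weight matrix, transposed to n×m,
   is read out as per-node latent features (row i ↔ node i); the decoder
   weights offer an alternative, typically weaker, read-out.
3. **Bilinear pooling** — `B = F Fᵀ`, the Gram matrix of node latent
   features: symmetric, PSD, rank ≤ m, and invariant to any orthogonal
   rotation of the latent axes. `B` is used as-is (no row normalisation).
4. **Diffusion** — `B` is clamped to nonnegative walk weights (a negative
   inner product means *dissimilar* nodes, hence no edge; an
   absolute-value mode is kept for sensitivity analysis). Second-order
   biased random walks (return parameter p, in-out parameter q; score of
   moving from c to t after arriving from s is `λ(s,t)·ω_ct` with
   λ = 1/p, 1, 1/q for t = s, t adjacent to s, otherwise) generate node
   sequences, which a CBOW model with negative sampling embeds into an
   n×d table — the subject's higher-order representation.
5. **Templates and distances** — subjects are aligned by orthogonal
   Procrustes to an iteratively refined mean, group templates are
   element-wise means of aligned subjects, and each subject is summarised
   by cosine distances (`1 − cos`, range [0, 2]) to the healthy and
   patient templates — flattened matrices for the network distance,
   matching rows for node distances.
6. **Evaluation** — stratified 10-fold cross-validated RBF-SVM on the
   2-D distance features (templates rebuilt from training subjects inside
   every fold by default, so held-out subjects never influence template
   construction), and per-node Welch t-tests with Benjamini–Hochberg FDR
   across nodes, reported with `−log10(p_FDR)` and a 0.05 threshold.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| hidden width m | 40 | CDON compression; must stay **below n** (see below) |
| CDON learning rate | 1.0 | full-batch GD step on per-entry MSE |
| CDON epochs | 2000 | enough to reach final loss ~1e−3 on Fisher-z networks |
| walk p, q | 1.0, 1.0 | return / in-out bias; q > 1 biases breadth-first |
| walks per node r | 10 | corpus size |
| walk length l | 80 | sequence length |
| embedding dim d | 60 | higher-order representation width |
| CBOW window w | 5 | context half-width |
| negatives k | 5 | noise samples per position, unigram^0.75 |
| CBOW epochs / lr | 5 / 0.025 | SGD passes; lr decays linearly to lr/10⁴ |
| folds | 10 | stratified CV |
| SVM C, gamma | 1, 1/(2·Var) | sklearn "scale" gamma on 2 standardised features |

The CDON learning rate deserves a note: the loss is normalised per matrix
entry, so its gradient carries a 1/n² factor and small steps barely move
the weights — at small steps the "latent features" are dominated by their
random initialisation. A stability scan on Fisher-z networks at n = 30
and n = 90 showed monotone convergence for steps up to 5; the default of
1.0 sits well inside the stable region and reaches reconstruction losses
around 1e−3.

**Compression is essential.** With m ≥ n the linear autoencoder is
overcomplete: at convergence `Wd We → I` and the balanced solutions make
`B = Weᵀ We` approach the identity, i.e. the higher-order network forgets
the data. The defaults (m = 40, d = 60) assume the 90-node parcellation
of the reference setting. For other network sizes,
`pipeline.scaled_config(n)` preserves the reference compression ratios
(m/n = 40/90, d/n = 60/90) and total walk-corpus size; the synthetic
experiments in the test suite use it at n = 30 (m = 13, d = 20, r = 30).

## Design choices in open territory

* **σ is the identity.** The model is stated as a linear autoencoder
  while writing a generic activation; linearity wins, and the activation
  remains a configurable hook.
* **dist(x, x̂) is mean squared error** over matrix entries.
* **Encoder weights are m×n** and latent features are `Weᵀ`; bilinear
  pooling requires node-indexed rows, which fixes the orientation.
* **Optimiser** is deliberately plain: full-batch GD, fixed step, seeded
  uniform init scaled by 1/√n, zero biases. One CDON per subject, no
  test set, no weight sharing.
* **First walk step** (no previous node) samples proportionally to edge
  weight. `d_st` uses standard second-order walk semantics on the
  transformed graph (0 = return, 1 = adjacent, 2 = otherwise).
* **CBOW details**: context aggregation is the mean; the input table is
  the returned embedding; updates are per-position SGD in word2vec
  style (output rows updated in place, context rows pushed afterwards),
  with a linearly decaying step so the final iterate is annealed rather
  than bouncing at the initial step scale. The input table is
  initialised identically for every subject given the same seed and node
  count, so all subjects start in a common frame before alignment.
* **Alignment is orthogonal Procrustes** to an iteratively refined mean
  (3 iterations). Bilinear pooling makes embeddings rotation-ambiguous,
  so some alignment is mathematically required before averaging;
  Procrustes is the minimal-assumption choice. Network vectorisation is
  row-major flattening.
* **Leakage control**: by default templates are rebuilt from training
  subjects inside each CV fold (`template_mode="per_fold"`); a
  whole-cohort mode mirrors the simpler protocol for comparison.
* **Node statistics** are computed in the *healthy-norm frame*: the
  alignment reference is the iterated mean of the control group, and
  each subject's per-node distances are taken to the group templates in
  that frame. A pooled reference absorbs half of the group effect into
  the frame itself and weakens node-level contrasts. Subjects belonging
  to the template's own group are scored against the leave-one-out mean;
  comparing a subject to a template containing itself biases its
  distance low and fabricates group differences under the null (this was
  measured, and the leave-one-out correction removes it).
* **Statistics**: Welch (unequal-variance) t-test, Benjamini–Hochberg
  FDR, `−log` in base 10, patients are the "positive" class (sensitivity
  = patient detection).

## Synthetic cohorts

`synthetic.generate_cohort` emulates a two-group resting-state study at
the point the pipeline consumes it: per-subject regional time series with
a known group difference. A control correlation matrix Σ₀ comes from a
sparse random factor model shrunk toward the identity
(Σ₀ = 0.6·corr(LLᵀ) + 0.4·I, loading density 0.3 by default), giving
moderate off-diagonal correlations and a comfortably positive-definite
spectrum. The patient matrix Σ₁ adds `delta` to the correlations of all
pairs of affected nodes, then is re-projected to the nearest
positive-definite correlation matrix (eigenvalue clipping at 1e−6 plus
diagonal renormalisation, iterated with the affected-pair targets
restored so the injected effect survives; the realised offsets stay
within a few thousandths of `delta`). Subjects jitter their group matrix
entry-wise (scale 0.02 by default — modest relative to the sampling noise
of a 150-sample correlation, ≈0.08) and draw independent
multivariate-normal time points.

Deliberate limitations: the time series are i.i.d. Gaussian draws — no
hemodynamic convolution, no temporal autocorrelation, no scanner
artefacts, no site effects. Passing tests on these cohorts show that the
pipeline recovers a known second-order group difference end to end; they
do not certify performance on real BOLD data, where preprocessing,
autocorrelation (which inflates correlation variance), and cohort
heterogeneity all matter.

Default problem sizes in the test suite — 30 nodes, 20+20 subjects, 150
time points, five affected nodes, `delta` 0.4–0.5 — are the package's
desk-scale study conditions; paper-scale runs (90 nodes, ~50 subjects per
group) use the same code paths with the default geometry.

## What the method localises — and what it does not

Classification on template distances is a *global* statistic and is
robust: across generator seeds the full pipeline separates the synthetic
groups with cross-validated accuracy 0.9–1.0, and ablations behave as
expected (latent-only and bilinear representations also classify well on
this easy effect; the diffusion stage adds no accuracy at desk scale but
none is needed — its value claim concerns representation, not this
benchmark).

Node-level localisation is different. A correlation perturbation confined
to five nodes perturbs the *walk process* everywhere: transition
probabilities renormalise row-wise, and window-5 contexts mix multi-step
transitions, so every node's co-occurrence distribution — and therefore
every node's embedding — shifts between groups. Measured on the
synthetic cohorts, per-node effect sizes are |d| ≈ 0.9 at affected nodes
but ≈ 0.6 at unaffected ones: the contrast that survives diffusion is
only ~1.5×, below what 20+20 subjects can reliably separate after FDR
across 30 nodes. The same statistical protocol applied to the raw
Fisher-z networks (the information ceiling) recovers ~90% of affected
nodes, and applied to the bilinear network `B` it still localises; the
delocalisation is a property of the diffusion embedding, not of the
statistics. Richer walk corpora do not help — they *sharpen* the
estimate of a genuinely global difference. Users who need node-level
anatomy should read the node statistics of the bilinear stage
(`ablation="cdon_bilinear"`) alongside the full pipeline's.

Under null cohorts (`delta = 0`) the node statistics are clean: across 20
replicates no spurious node survives FDR, and label-permuted
cross-validation scores at chance, confirming that the per-fold template
rebuild leaks nothing.

## Numerical conventions

* Matrix files: plain delimited text (comma/tab auto-detected), no
  header, 17 significant digits on write; manifests are headered CSV.
* Symmetry tolerance 1e−10; PSD tolerance −1e−8 on eigenvalues.
* Cosine distance against a zero vector raises rather than returning a
  sentinel; undefined classification ratios (empty denominator) are
  reported as NaN, never as 0.
* All stage RNG streams derive from one global seed by hashing the stage
  name (`stage_seed`), each below 2³¹.
* Walks from isolated nodes have length 1; a walk entering a node whose
  only positive weight points back where it came from continues (the
  return move is legal); degenerate corpora (fewer than two distinct
  nodes) are rejected.
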