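# Methods

## Scope and model

`plantood` implements post-hoc open-set scoring: given per-sample
classifier logits `z ∈ R^K` over the K known classes, image embeddings
from a fine-tuned encoder `M_ft` and from its frozen pretrained
counterpart `M_pt`, and training-set feature banks in both spaces, it
assigns each test sample an uncertainty score (higher = more anomalous)
and thresholds it.  No training, feature extraction or image handling
happens inside the package; those live upstream.

### Base scores

- Max-logit family (`max_logit_score`).  The default dialect `msp`
  returns `−max softmax(z/T)`.  A second dialect `raw_maxlogit` returns
  `−max z`.  A third dialect, `literal`, divides `z/T` by the plain
  (non-exponentiated) row sum; this linear normalization is undefined
  when the row sums to zero and such rows are rejected with a named-row
  error.  `msp` is the default because it is well defined for arbitrary
  logits and preserves the intended confidence ranking; the other
  dialects are selectable for comparability.
- Energy (`energy_score`): `−log Σᵢ exp(zᵢ/T)`, computed with an
  overflow-safe log-sum-exp.  With one class it is exactly `−z/T`.
  Note the score is the negative log-sum-exp itself, without an outer
  factor of T; at the default T = 1 this coincides with the common
  `−T·logsumexp(z/T)` form.
- Concept matching (`mcm_score`): `−max softmax(cos(f, gᵢ)/T)` over
  per-class text embeddings `gᵢ`.  Image and text vectors are
  L2-normalized internally before the cosine.

### Feature-matching scores

`knn_dissimilarity` is the shared kernel: the negative maximum cosine
similarity between a test embedding and the rows of a training feature
bank, in [−1, 1], with −1 for an exact duplicate of a bank row.
Embeddings carry a `space_tag` (`finetuned` / `pretrained`); comparing
across spaces is a protocol error, never a silent cast.  Applied in the
fine-tuned space the normalized result is the domain-specific knowledge
score `S_DSK`; in the pretrained space, the general-knowledge score
`S_GK`.

### Normalization and fusion

Each component is min-max scaled to [0, 1] *transductively*: the min
and max are taken over the full set of scores being jointly evaluated
(the test set).  Each component carries its own min/max; components do
not share normalization statistics.  Min-max scaling is strictly
increasing, so ranking — and hence AUROC — is unchanged by it; only the
fused mean depends on it.  Two numerical rules:

- Degenerate component (max = min): all values map to 0.5, so the
  component contributes a constant to the mean and the ensemble ranking
  is governed by the remaining components, rather than producing NaNs.
- For single-sample deployment, `MinMaxNormalizer` freezes min/max on a
  calibration set and clips transformed scores into [0, 1].

Fusion (`ensemble_score`) is the unweighted arithmetic mean of the
normalized components: `(S_CPD + S_DSK + S_GK)/3` in the visual mode,
`(S_DSK + S_GK)/2` in the VLM mode (concept matching is retained as an
optional third component in `vlm_three_way`).  Components are aligned
by sample id; a mismatch in ids or order is an error — silent
reordering is never performed.

### Decision rule and metrics

A sample is declared unknown iff `S(x) > λ`; a score exactly equal to λ
is accepted as known.  Known samples are the positive class throughout;
the complementary orientation is deliberately not exposed.  λ defaults
to the smallest order statistic of the known scores achieving
TPR ≥ 0.95, i.e. the k-th smallest known score with
k = ceil(0.95·n_known).  At small n the exact level may be
unattainable, so the achieved TPR is reported next to the target.
FPR@TPR95 is the fraction of unknown samples with `S ≤ λ`.  AUROC is
the Mann-Whitney statistic `P(S_unknown > S_known) + ½·P(=)`
(computed via scikit-learn's ROC routine; the test suite checks it
against exhaustive pair counting).  Closed-set accuracy is the argmax
accuracy over known-labelled samples only, from logits or — in VLM
modes — from image-text cosine similarity.

## Few-shot protocol

M-shot banks are drawn per class by a seeded shuffle followed by prefix
selection, with the per-class stream keyed on (seed, class name).
Consequences: draws are deterministic, independent of other classes'
row counts, and *nested* — the 2-shot bank is a subset of the 4-shot
bank, and so on — which makes shot ablations monotone in the
conditioning data.  A class with fewer than M rows raises an error
naming the class.  Banks are validated to contain known classes only
before any scoring.

## Synthetic study conditions

The generator (`plantood.synthetic`) emulates the separability premise
of the method, not any particular dataset:

- `k = 6` known and `u = 4` unknown classes, embedding dimension
  `d = 64`, `16` training rows per known class, `50` test samples per
  class, seed `7` by default.
- Class centers are unit vectors with pairwise angle ≥ `separation`
  (0.5 rad default), drawn by rejection sampling; an unsatisfiable
  request raises a generation error.
- Both encoder spaces share the center layout and differ only in noise:
  `sigma_ft = 0.2` (the fine-tuned encoder clusters the task classes
  tightly) versus `sigma_pt = 0.4` (the frozen encoder sees the same
  layout more diffusely).  This two-space structure is a modeling
  choice of the fixture.
- Unknown centers are pushed a distance `unknown_shift` (0.5 default)
  away from the centroid of the known centers and re-normalized.
  Pushing away from the centroid, rather than away from the nearest
  known center, makes mean separability monotone in the shift: a
  nearest-center push can move an unknown class toward a *different*
  known class.
- Logits are a linear-head surrogate: cosine similarity of the
  (normalized) fine-tuned test embedding to each known center, scaled
  by `logit_gain = 10` — sharp but unsaturated softmax.  Text
  embeddings for the VLM path are the known centers themselves.
- One global seed drives independent substreams for centers, bank
  noise and test noise, so changing the test-set size never perturbs
  centers or banks, and identical configs serialize byte-identically.

`degrade(bundle, channel, severity)` corrupts exactly one information
channel — permuting a fraction of logit rows (cpd), or blending test
embeddings with equal-norm random directions in one space (dsk / gk) —
leaving the other channels bit-identical.  It exists to demonstrate
complementarity: the three-way ensemble stays above any single
degraded component.

What the fixture does *not* model: class imbalance, heavy-tailed or
structured (non-isotropic) embedding noise, correlations between the
two spaces' noise beyond the shared centers, near-duplicate classes,
and any real image statistics.  Passing tests therefore demonstrate
correctness of the scoring/evaluation machinery and the qualitative
ensemble behaviour under the stated geometry — not performance on real
plant imagery.

## Problem sizes

The default fixture used by the test suite and the acceptance script
has 500 test samples (10 classes × 50) and 96 bank rows per space; the
oracle-equivalence checks run 200 random instances with up to 50 scores
per side; statistical properties (separability monotonicity, shot
trends) average over 10 seeds on a reduced fixture (k=3, u=2, d=16).
These sizes give stable statistics while keeping the full suite in the
single-digit seconds.

## Numerical and design choices

- Temperatures default to T = 1 for energy (its standard default), msp
  and concept matching; all are configurable per call.
- Cosine computations L2-normalize internally; zero-norm embedding rows
  are rejected at construction with the offending row named, since
  cosine is undefined at the origin.
- Nearest-neighbour similarities are clipped to [−1, 1] to keep the
  documented range exact under floating-point spill.
- TSV serialization uses 17 significant digits, which round-trips
  IEEE-754 doubles exactly; fixture directories are reproducible
  byte-for-byte from (config, seed).
- The CLI maps user-correctable failures (bad flags, malformed files,
  protocol violations such as overlapping known/unknown classes) to
  exit code 2 and internal errors to 1; logging verbosity never changes
  numeric outputs.

## Known limitations

- Transductive normalization couples each sample's fused score to the
  composition of the evaluated batch; the frozen-statistics normalizer
  is provided but λ chosen on one batch is not guaranteed to transfer.
- Single-nearest-neighbour matching is sensitive to bank outliers at
  very small M; no k>1 smoothing is offered (out of scope).
- The ensemble is an unweighted mean; when one channel is much weaker
  than the others (e.g. a very noisy pretrained space) it can dilute
  an otherwise stronger single component, bounded in practice by the
  complementarity checks in the test suite.
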