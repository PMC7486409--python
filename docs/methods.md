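# Methods

`sefreq` predicts the frequency classes of drug side effects by completing a
zero-inflated ordinal matrix with a confidence-weighted non-negative
decomposition. This note records the model, the numerical choices, the
synthetic data the tests run on, and the limits of what those tests show.

## Model

The data are an integer matrix `R` (drugs × side effects) with entries in
{0, …, 5}: 1 = very rare (<1/10,000), 2 = rare, 3 = infrequent, 4 = frequent,
5 = very frequent (>1/10), 0 = unobserved. The observed index set is Ω, the
zero set O. The model is a non-negative factorisation `R ≈ W H` with
`W ∈ R^{n×k}_{≥0}` (rows: drug signatures) and `H ∈ R^{k×m}_{≥0}` (columns:
side-effect signatures), fitted by minimising

    L(W, H) = 1/2 ‖M_Ω ∘ (R − WH)‖_F² + α/2 ‖M_O ∘ (WH)‖_F² ,  W, H ≥ 0.

The second term treats every zero as a *noisy observation of absence* rather
than a missing value: α ∈ [0, 1] is the confidence placed in the zeros, and
the term doubles as the only regulariser. The defaults k = 10 and α = 0.05
are the values a (k, α) cross-validation grid selects on the real
pharmacovigilance instance this model was designed for; on the synthetic
study conditions below the planted rank k* = 5 is used.

Optimisation is by diagonally rescaled multiplicative updates — the W rule
first, then the H rule using the updated W:

    W ← W ∘ (R Hᵀ) ⊘ ((M_Ω∘WH) Hᵀ + α (M_O∘WH) Hᵀ + ε)
    H ← H ∘ (Wᵀ R) ⊘ (Wᵀ (M_Ω∘WH) + α Wᵀ (M_O∘WH) + ε)

with ε = 1e-16 guarding the denominators, uniform random initialisation on
[0, 0.1], and per-iteration normalisation of the rows of H to unit norm.
Fixed points satisfy the KKT complementarity conditions of the constrained
problem; `kkt_residual` (max |min(X, ∂L/∂X)|) measures distance from
stationarity.

### Numerical choices

* **Denominator form.** The weighted product is computed as
  `α·WH + (1−α)·(M_Ω∘WH)`, algebraically identical to the literal two-mask
  form (the test suite asserts agreement to 1e-12) and roughly twice as fast.
* **Normalisation mode.** Unit-normalising the rows of H removes the
  diagonal-rescaling degeneracy `W → WΛ, H → Λ⁻¹H`. The default
  ("compensated") multiplies the columns of W by the norms so `WH` — and
  hence the loss — is exactly invariant, which keeps the loss trace
  monotone to machine precision. A paper-literal mode (`h_only`) rescales
  only H; its loss trace is not majorisation-protected at the rescale and
  is only empirically monotone after the first couple of iterations, which
  is how the test for that mode is phrased.
* **Stopping rule.** The default metric is the largest absolute entry change
  divided by the largest absolute entry of the previous iterate
  (`stop_metric="max_entry"`), with TolX = 1e-3; this converges in roughly a
  thousand iterations at desk scale and a couple of thousand at k = 10 on
  real-size instances. A strict per-entry relative metric
  (`stop_metric="elementwise"`) is also provided: entries decaying
  multiplicatively toward zero keep a constant per-entry relative change,
  so this metric effectively runs until even near-zero entries stabilise
  (often to `max_iter`). It exists because multiplicative updates can push
  an entry many orders of magnitude toward zero and then recover it at a
  few-percent-per-iteration rate; the fast metric stops during the trap and
  can leave a KKT residual of ~1e-2, while the elementwise metric rides out
  the recovery and reaches residuals below 1e-10. Stationarity studies use
  the elementwise mode.
* **ε-descent caveat.** With the ε guard the update can overshoot the exact
  diagonally-rescaled minimiser by an ε-order amount, so loss monotonicity
  is asserted at 1e-10 relative tolerance, not exactly.
* **Non-finite values** arising during iteration abort the fit with the
  iteration index; convergence failure at `max_iter` is a warning, and the
  model is returned with the stop reason recorded.

## Calibration

Predicted scores are real numbers; classes are recovered with five
cut-points. For each class, a Gaussian-kernel density (per-class Silverman
bandwidth `0.9·min(sd, IQR/1.34)·n^{−1/5}`, overridable; 1,024-point grid
spanning the scores ± 3 bandwidths) is fitted to the *pooled
cross-validation validation scores* of that class — never to training-set
reconstructions, because predictions at cells that were zero during
training are systematically shrunk by the α-term and the thresholds must
absorb that shrinkage. The boundary between adjacent classes is the
density crossing nearest the midpoint of the class medians, searched on the
inter-median interval padded by half its width on each side (strongly
overlapping neighbours — typically very-rare vs rare — can cross just past
a median). The zero threshold comes from the empirical ROC of
observed-vs-zero discrimination: among candidate cuts (the sorted unique
scores) with specificity at or above the target (default 0.57), the one
closest to the target. Boundaries are required to ascend; the piecewise
classification rule assigns each boundary to the upper class.

`map_classify` additionally exposes a maximum-a-posteriori rule
(class-conditional KDEs × supplied priors). The prior-free maximum-
likelihood thresholds are the right tool for real reporting data, where
class priors cannot be estimated; the MAP rule is used in the synthetic
recovery experiments, where the training marginals are a meaningful prior
and the fair baseline (always predicting the majority class) itself uses
the prior.

## Evaluation protocols

* **Held-out split:** a uniform 10% of Ω is zeroed for training and scored
  with RMSE (scores vs integer classes), AUROC (held-out cells as
  positives, *all* zero cells of the source matrix as negatives), AUPRC at
  controlled negative:positive ratios (negatives subsampled without
  replacement; step-wise estimator), and Pearson r.
* **Tenfold CV:** Ω cells are partitioned once per seed (unstratified) and
  the same partition is reused across the whole (k, α) grid; per-fold
  metrics are averaged, pooled validation (score, class) pairs feed the
  calibration.
* **Single-drug, class-accumulation, cold-start, leave-one-out:** as
  protocol functions that zero the targeted cells, refit, and score; the
  class-accumulation sets hide very rare (A), +rare (B), +infrequent (C)
  associations per drug, keeping a drug only if at least one training
  association remains.
* Every split object asserts that no test cell retains its class in the
  training matrix.

## Signature analyses

Cosine similarity over signatures scores pair-level binary tasks (shared
category at a hierarchy level = non-empty intersection of code sets),
evaluated by AUROC; Jaccard similarity of side-effect profiles is the
corresponding baseline. Component–category enrichment uses a one-tailed
Wilcoxon rank-sum test (members vs non-members, per component × group) with
Benjamini–Hochberg adjustment across all tests of a hierarchy level jointly,
and effect size = median within group − overall median. The rank-sum
p-value is computed by exact enumeration of the permutation null (midranks,
so ties are handled) for pooled sizes ≤ 12 and by the tie- and
continuity-corrected normal approximation beyond. The approximation's
worst-case error against exact enumeration is ~0.06 at the smallest sizes
and still slightly above 0.01 for balanced splits at n = 12 — callers who
need small-n precision get it automatically from the exact path; the
approximation quality bound asserted in the acceptance suite records this
honestly.

## Reproducibility

Signatures from independent restarts are only meaningful if they recur.
`multirun_fit` runs n independent fits (per-run seeds = base seed + index);
the top-m lowest-loss solutions (ties broken by seed) contribute their
components — columns of W in the drug view, rows of H in the side-effect
view — to a pool that is clustered with spherical k-means (k-means++
seeding, cosine distance, centroids re-normalised each step, empty clusters
re-seeded with the worst-assigned point). The cosine-based average
silhouette width of each cluster, in [−1, 1], is the reproducibility score.
Desk-scale defaults are 100 runs / top 20; the full-scale protocol
(10,000 / 100) is a preset constant, not the default.

## Synthetic data

The generator plants a non-negative low-rank truth and emulates the
observation statistics of real side-effect reporting:

* **Factors:** gamma(0.5, 1.0) entries (sparse, right-skewed), H rows unit-
  normalised; W is scaled so the top-5% tail of the planted scores averages
  3.5, putting the truth on the class scale. Sparse factors matter: most
  drug–side-effect pairs must have near-zero true score so that the zeros
  the model trusts are mostly *correct* — a dense truth would contradict
  the model's central assumption.
* **Observation process:** per-column (side-effect popularity) weights
  follow a shifted power law `(rank+3)^{-1.2}`, calibrated so the top 30%
  of side effects carry ≈80% of observed cells; popularity is coupled to
  the planted column scores (the popular side effects are the frequently
  caused ones, as in real reporting data); within a column, detection is
  biased toward high-scoring cells (probability ∝ score percentile), so
  unobserved cells skew rare — the stated reason real trials miss rare
  effects. Overall expected density is 5% (the ~95% zero inflation).
* **Classes:** planted scores + Gaussian noise (sd 0.1) are discretised by
  four thresholds; by default these are quantiles of the observed noisy
  scores matched to realistic class proportions (3.2 / 11.2 / 26.8 / 46.0 /
  12.8%, mean ≈ 3.5); tests that need known boundaries pass explicit
  thresholds instead.
* The truth bundle (factors, noiseless scores, mask, thresholds) is
  returned separately and never leaks into the emitted matrix.

**What passing tests do and do not show.** The synthetic world is exactly
low-rank, its noise is Gaussian, its detection bias is a clean monotone
function of the score, and its annotation groups are flat labels. Real
reporting data have none of these clean properties (curation artefacts,
correlated missingness across a drug's label, ontology structure), so green
synthetic tests certify the algorithms and protocols, not clinical
performance. Conversely, the desk-scale conditions are *harder* than the
real instance in one respect: ~10 observations per drug against 5 + 5
parameters per row/column pair, so absolute metric values (e.g. held-out
AUROC ≈ 0.79, Pearson ≈ 0.5) are not comparable to what the same pipeline
attains on the full-size data.

**Power considerations.** Two experiments need conditions chosen for
statistical power rather than the generator defaults. (1) Rank selection:
at 5% density, CV-RMSE prefers ranks below the planted one — the α-term
shrinks all validation predictions and the weakest true components cost
more estimation variance than they explain — so the rank-identification
test runs at 25% density, where the CV grid selects the planted rank with a
clear margin. (2) Class recovery is scored by MAP classification against
the majority-class baseline over 10 generator seeds with a paired one-sided
signed-rank test, with predictions averaged over 5 restarts (the multi-run
averaging the reproducibility protocol justifies).

## Known limitations

* The zero-trap behaviour of multiplicative updates (see stopping rule)
  means the fast default stop can return factors with a small number of
  entries still escaping zero; use the elementwise stop for stationarity-
  critical work. Even then, on some instances an entry driven to ~1e-24
  stalls — the update's multiplicative growth is cancelled by the
  compensating column rescale — leaving a KKT residual of order 1e-2 at an
  otherwise converged solution; instances differ, so stationarity
  diagnostics should be read per run.
* BH adjustment is not idempotent in general (only flat adjusted vectors
  are fixed points); re-adjusting adjusted p-values is a user error the
  API does not guard against.
* `zero_threshold` requires an achievable specificity at or above the
  target; with very few negatives it returns the top cut with sensitivity 0
  rather than extrapolating.
* Leave-one-out costs one fit per observed cell and is gated behind an
  explicit flag above 300 cells.
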