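# Methods

## Model and objective

All five factorisation algorithms minimise the half squared Frobenius
reconstruction error f(W, H) = ½‖V − W H‖²_F for a spectra matrix V
(d×n, columns UL2-normalised) and k < d sources, under constraints that
differ by method:

- **euc** — multiplicative (Lee–Seung) updates; V, W, H ≥ 0.  After each
  W update the columns of W are rescaled to sum to one, with the inverse
  scaling applied to the rows of H; this leaves the product W H — and
  hence the objective — unchanged while fixing the scale indeterminacy of
  the factorisation.  The H update uses the freshly rescaled W.
- **als** — exact alternating least squares: W ← V Hᵀ(H Hᵀ)⁻¹ with
  negatives zeroed, then H ← (WᵀW)⁻¹WᵀV against the updated W, negatives
  zeroed.  Singular Gram matrices fall back to the Moore–Penrose
  pseudo-inverse, giving the minimum-norm least-squares solution.
- **alspg** — the same alternating scheme solved by projected gradient:
  H ← P[H − α Wᵀ(W H − V)] with P the projection onto the non-negative
  orthant and α from an Armijo backtracking line search (initial step 1,
  shrink ratio β = 0.1, sufficient-decrease constant σ = 0.01, at most 20
  backtracks; a stalled search returns the iterate unchanged and flags a
  warning).  Each sub-step is non-increasing in f by construction.
- **alsobs** — ALS where, instead of plain clipping, each negative
  coordinate is pruned with an Optimal-Brain-Surgeon second-order
  correction.  The rows of W (and columns of H) are independent
  least-squares problems sharing the Hessian H Hᵀ (respectively WᵀW);
  pruning coordinate q applies −w_q · [Hess⁻¹]_{·q} / [Hess⁻¹]_{qq} to the
  row, which zeroes w_q exactly and re-optimises the survivors.
  Coordinates are pruned most-negative first and the Hessian inverse is
  recomputed on the remaining free set, so each prune is an exact
  equality-constrained re-solve; a single prune therefore coincides with
  the constrained least-squares optimum, which the tests verify directly.
  A singular Hessian degrades gracefully to plain clipping with a warning.
- **convex** — Convex-NMF: W = V A with A ≥ 0 and H ≥ 0 while V (and
  hence W) may be mixed-sign.  The multiplicative updates act on A and H
  and depend on V only through the Gram matrix G = VᵀV, computed once per
  run and split into positive/negative parts G⁺, G⁻:

      Hᵀ ← Hᵀ ⊙ √[(G⁺A + HᵀAᵀG⁻A) ⊘ (G⁻A + HᵀAᵀG⁺A)]
      A  ← A  ⊙ √[(G⁺Hᵀ + G⁻A H Hᵀ) ⊘ (G⁻Hᵀ + G⁺A H Hᵀ)]

  Multiplicative updates cannot leave zero, so convex-family
  initialisations are constructed strictly positive.

**Convergence** is declared when the absolute change in f between
consecutive iterations drops below the tolerance (default 1e-5), with a
cap of 2000 iterations.  Absolute rather than relative change is used
because the UL2 normalisation pins the scale of V, making absolute error
changes comparable across cohorts.  All multiplicative denominators carry
a 1e-12 floor against division by zero.

**Sign handling.**  The four non-negative methods require non-negative
data; mixed-sign input is passed through an absolute-value transform
(rather than truncation, which would discard the inverted-doublet
information entirely), and the result is flagged.  Convex-NMF consumes
mixed-sign data directly — this is precisely its appeal for long-echo-time
spectra — and is never transformed.

## Initialisation strategies

Six strategies serve both method families.  For the non-negative family
they produce (W⁰, H⁰); for the convex family (H⁰, A⁰):

- **random** — uniform (0, 1) entries (with a tiny positive floor).
- **kmeans** — cases are clustered in spectral space (10 seeded restarts,
  best inertia).  Non-negative family: W⁰ = centroids (negatives clipped),
  H⁰ = Euclidean distances from each case to each centroid (the distance
  convention is taken literally; note it makes H⁰ large for far cases).
  Convex family: with C the n×k hard indicator and D = diag(cluster
  sizes), H⁰ = (C + 0.2E)ᵀ and A⁰ = (C + 0.2E)D⁻¹ (E is all ones).
- **fcm** — fuzzy C-means (Bezdek iteration, fuzzifier m = 2.0, 10 seeded
  restarts).  Non-negative family: W⁰ = cluster centres, H⁰ = fuzzy
  partition matrix.  Convex family: the same (C + 0.2E) construction with
  C the fuzzy partition; cluster sizes are the membership column sums —
  the natural fuzzy analogue of points-per-cluster, and never zero even
  when hard assignment would leave a cluster empty.
- **pca** — SVD of the row-mean-centred data V_c = U S Vᵀ; the W
  candidate is U_k S_k (principal axes scaled by singular values, so the
  candidate product reconstructs V_c) and the H candidate is the score
  matrix Vᵀ_k.  Negatives are truncated for the non-negative family.
- **fastica** — independent component spectra (d×k) as the W candidate,
  the mixing matrix transposed as the H candidate; truncated likewise.
- **nmf_als** — a short seeded ALS-NMF run (random start, ≤200 sweeps, the
  standard tolerance) on |V| supplies the candidates.

For the convex family, the pca/fastica/nmf_als candidates route through a
common construction: H⁰ = max(H_cand, 0) + 0.2E, then
A = H⁰ᵀ(H⁰H⁰ᵀ)⁻¹ (pseudo-inverse if singular) and
A⁰ = (A)⁺ + 0.2·⟨(A)⁺⟩·E, where ⟨X⟩ is the sum of |X| divided by the
number of nonzero entries.  Both H⁰ and A⁰ are strictly positive by
construction, which the property tests assert.

## Unsupervised labelling

Sources are matched to classes by Pearson correlation between each source
spectrum and each class mean spectrum (class means are computed from the
UL2-normalised data, consistent with normalisation preceding everything
else).  Pearson is used because it is the spectroscopy community's default
similarity for pattern matching and is location/scale invariant;
correlations are used signed, not in absolute value.  Each source takes
the argmax class; several sources may share a class.

A case i is labelled by the source with the largest contribution
C(i,k) = Vᵢᵀ W_k H(k,i); ties break to the lowest source index.  C is
invariant under the compensated rescaling W_k → cW_k, H(k,·) → H(k,·)/c,
so the labelling does not depend on the scale indeterminacy of the
factorisation.  Class contribution profiles average C within each class,
floor negative means at zero (the statistic is sign-unrestricted for
mixed-sign sources, but a negative mean contribution carries no mass in a
percentage plot) and normalise each class row to 100.

## Dimensionality reduction and classification

Sources are orthonormalised by **modified** Gram-Schmidt (numerically
stabler than the classical recurrence), with a rank check at relative
tolerance 1e-10 that names the first dependent column.  Features are
F = UᵀV.  The classifier is Fisher LDA with class means, pooled
within-class covariance (denominator n − m) and empirical priors; a
singular pooled covariance receives a ridge of 1e-8·trace/k.  Prediction
is the argmax of the usual linear discriminant scores, ties to the
lexicographically first class.

Evaluation is a stratified bootstrap: each replicate resamples every class
with replacement at its own size (stratification prevents empty classes),
fits LDA on the replicate, and scores the out-of-bag cases; replicates
with an out-of-bag set missing a class are redrawn up to 10 times, then
skipped with a warning.  The spread reported alongside the mean is the
standard deviation across replicates.  Out-of-bag scoring was chosen over
resubstitution or .632-style corrections as the most conservative of the
simple bootstrap estimators.  BER = 1 − mean per-class recall.

The k-scan extracts sources once per k on the full training matrix
(K-means-initialised Convex-NMF — the combination that recovers sources
best in the comparison experiments); the bootstrap randomness applies only
to the classifier stage.  An independent test set is projected onto the
*training* basis and scored with accuracy and BER.

## Synthetic cohorts

The generator emulates the structure of clinical single-voxel cohorts:

- **Templates.**  Each class is a sum of Gaussian (optionally Lorentzian)
  peaks on the 195-point [4.24, 0.50] ppm grid, UL2-normalised.  The
  built-in long-echo-time set uses landmark resonances — choline 3.21,
  creatine 3.03, NAA 2.02, Glx 2.30, mobile lipids 0.90/1.30 ppm, the
  inverted Lactate doublet at 1.35 ppm (A2) and inverted Alanine doublet
  at 1.45 ppm (MM) — with amplitude ratios chosen so that all pairwise
  template correlations stay below 0.5, a separability precondition for
  the recovery tests.  The short-echo-time set uses the same centres with
  all-positive amplitudes.
- **Mixing.**  Case i of class c is V_i = Σ_j h_ij T_j + ε with h_i drawn
  from a Dirichlet whose own-class concentration is boosted so that
  E[h_ic] equals the `dominance` parameter (default 0.8; dominance 1
  degenerates to exact one-hot mixing).  Weights are non-negative and sum
  to one — the simplest simplex mixing consistent with linear tissue
  mixing.
- **Noise and normalisation.**  ε is i.i.d. Gaussian per grid point
  (default SD 0.005) added before the final UL2 normalisation, matching
  the convention that normalisation is the last preprocessing step.

Default cohort size is 20 cases per class — the order of the smaller
clinical classes.  Passing tests on these cohorts demonstrates the
algebra, the descent properties and the recovery behaviour of the
pipeline; it does not demonstrate robustness to the features real spectra
add (baseline distortions, chemical-shift misalignment, heteroscedastic
noise, class overlap far above the synthetic level).

## Numerical conventions and edge cases

- Spectra tables are TSV with a `ppm` first column, one column per case
  and an optional `#labels` row; numbers are serialised with 17
  significant digits so round-trips are exact to well below 1e-12.
  Ascending-ppm files are reversed to the decreasing display convention.
- Factorisation results persist as W.tsv / H.tsv / A.tsv /
  error_trace.tsv plus a JSON metadata record (method, init, seed,
  iterations, tolerance, convergence flag).
- Zero-variance sources or templates get correlation 0 with a warning
  rather than NaN.
- The CLI derives per-task seeds from the single `--seed` via
  `numpy.random.SeedSequence(seed).spawn`, in a fixed order, so every
  experiment is bit-reproducible end to end.

## Problem sizes used by the verification scripts

The acceptance script and the heavier tests run at deliberately modest
sizes chosen to exercise every property at desk scale: 50 random 20×30
instances for descent, 20 instances for the constraint suite, 100 for the
ALS oracle, 20 synthetic cohorts (3 classes × 20 cases) for recovery and
labelling, 1000 bootstrap repetitions for the separable-classifier check,
and 10 seeds × k ∈ [2, 6] for the number-of-sources scan (25 bootstrap
repetitions per k there, since the scanned quantity is independent-test
accuracy).

## Known limitations

- The OBS re-adjustment is a faithful second-order pruning construction;
  published descriptions of the variant leave implementation freedom
  (pruning order, re-inversion schedule), and other orderings are
  possible.
- Convex-NMF convergence is first-order (multiplicative) and can take a
  thousand-plus iterations at tolerance 1e-5; the iteration cap of 2000 is
  a practical guard, not part of the model.
- LDA assumes shared within-class covariance; heteroscedastic cohorts
  would call for QDA or regularised variants, which are out of scope.
- The fuzzy C-means fuzzifier is fixed at the universal default m = 2.0.
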