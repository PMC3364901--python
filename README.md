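# mrsnmf

Source extraction, unsupervised tumour-type labelling and linear
classification for single-voxel ¹H magnetic-resonance-spectroscopy (MRS)
data, built around non-negative matrix factorisation (NMF).

A cohort of spectra is a matrix **V** (d×n): d frequency-intensity values
per case on a decreasing ppm grid (by default 195 points over
[4.24, 0.50] ppm, each spectrum scaled to unit Euclidean length), one
column per case.  Because a voxel contains a mixture of tissues, each
spectrum is modelled as a non-negative linear combination of a small
number of constituent *source* spectra:

```
V ≈ W H,   W ∈ R^{d×k} (sources),  H ∈ R^{k×n} (mixing / abundances), H ≥ 0
```

Long-echo-time spectra are mixed-sign (inverted Lactate and Alanine
doublets near 1.35 and 1.45 ppm), which conventional NMF cannot represent.
The package therefore implements five factorisation algorithms side by
side — multiplicative updates (`euc`), alternating least squares (`als`),
projected-gradient ALS (`alspg`), ALS with Optimal-Brain-Surgeon pruning
(`alsobs`), and Convex-NMF (`convex`), which constrains **W = V A** with
A ≥ 0 so sources are convex-like combinations of observed spectra and may
keep their negative peaks — together with six initialisation strategies
(random, K-means, fuzzy C-means, PCA, FastICA, and an ALS-NMF pre-run).

On top of factorisation the package provides:

- **Unsupervised labelling.**  Each source is matched to the class whose
  mean spectrum it correlates with best; each case is then labelled by the
  source with the largest contribution `C(i,k) = Vᵢᵀ W_k H(k,i)`.
- **Dimensionality reduction + classification.**  Sources are
  orthonormalised by modified Gram-Schmidt, the data are projected onto
  the basis, and a Fisher LDA classifier is evaluated by stratified
  bootstrap (out-of-bag), with balanced error rate
  `BER = 1 − mean per-class recall`, including a scan over the number of
  sources k.
- **A synthetic cohort generator** that emulates the structure of clinical
  MRS cohorts (metabolite peak templates per class, Dirichlet mixing,
  additive noise, UL2 normalisation) so every stage is testable without
  clinical data.

## Worked example

Simulate a three-class long-echo-time cohort (grade-II astrocytoma A2,
meningioma MM, normal tissue NO; 20 cases each), then label it without
using the class labels for modelling:

```
$ mrsnmf simulate --out cohort --classes A2,MM,NO --n-per-class 20 --seed 7
$ mrsnmf label --spectra cohort/spectra.tsv --labels cohort/labels.tsv \
      --out labelled --seed 7
Total:100.0%(60/60)
A2:100.0%(20/20)
MM:100.0%(20/20)
NO:100.0%(20/20)
```

Convex-NMF with K-means initialisation extracted three sources; the
source–class correlation grid written to `labelled/correlations.tsv` shows
each source is specific to one tissue type:

```
class   S1      S2      S3
A2      0.5396  0.9965  0.5390
MM      0.9929  0.5745  0.3597
NO      0.3744  0.5513  0.9927
```

and the contribution rule recovered all 60 labels.  The supervised
counterpart (Gram-Schmidt on the sources, Fisher LDA, 1000 bootstrap
repetitions) reports per-class out-of-bag accuracies in the
`mean % ± SD` style:

```
$ mrsnmf classify --spectra cohort/spectra.tsv --out classified --seed 7
Total:100.0% ± 0.2
A2:100.0% ± 0.0
MM:100.0% ± 0.0
NO:100.0% ± 0.4
BER:0.00
```

Other subcommands: `factorize` (one method/init pair, persists
W/H/A/error-trace as TSV), `grid` (the full 5-method × 6-init correlation
comparison), `scan-k` (classification while varying k), and `run` (any of
the above from a YAML config).  The same functionality is available as a
library; see the docstrings in `mrsnmf.nmf_core`, `mrsnmf.labelling` and
`mrsnmf.dr_classify`.

## Limitations

The generator produces idealised Gaussian/Lorentzian peaks and does not
model acquisition physics (J-coupling evolution, baseline, water
residual); no vendor MRS formats are read.  See `docs/methods.md` for the
model details, parameter choices and numerical conventions.
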