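"""Dimensionality reduction via extracted sources, plus LDA classification.

The extracted source spectra span a low-dimensional subspace of the
spectral domain.  Orthonormalising them (modified Gram-Schmidt) gives a
basis U; projecting the data onto U yields k features per case, which feed
a standard Fisher linear discriminant classifier with pooled within-class
covariance and empirical priors.  Classifier performance is estimated by
stratified bootstrap: resample within each class with replacement, fit on
the replicate, score on the out-of-bag cases, and report mean +/- standard
deviation over replicates.  The balanced error rate (BER) is one minus the
mean per-class recall, which weights small classes equally with large
ones.  ``scan_number_of_sources`` repeats the whole pipeline for a range
of k to locate the most adequate number of sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .initializations import initialize
from .labelling import (
    ContributionMatrix,
    SourceClassMap,
    class_contribution_profile,
    contribution_matrix,
    match_sources_to_classes,
)
from .nmf_core import FactorizationOptions, FactorizationResult, factorize
from .preprocess import class_mean_spectra
from .spectra_io import LabelVector, SpectrumTable


@dataclass
class OrthonormalBasis:
    """Orthonormal columns spanning the same subspace as the sources."""

    U: np.ndarray
    provenance: str = ""


@dataclass
class LdaModel:
    """Fisher LDA with pooled within-class covariance."""

    class_names: list[str]
    class_means: np.ndarray        # (m, k)
    pooled_covariance: np.ndarray  # (k, k)
    priors: np.ndarray             # (m,)
    _cov_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cov_inv = np.linalg.inv(self.pooled_covariance)

    def discriminant_scores(self, F: np.ndarray) -> np.ndarray:
        """Linear scores x^T S^-1 mu_c - 1/2 mu_c^T S^-1 mu_c + log pi_c,
        one column per class, one row per case (F is k x n')."""
        X = np.atleast_2d(F).T  # (n', k)
        M = self.class_means
        lin = X @ self._cov_inv @ M.T
        quad = 0.5 * np.einsum("ck,kl,cl->c", M, self._cov_inv, M)
        return lin - quad[None, :] + np.log(self.priors)[None, :]


@dataclass
class ClassificationReport:
    """Bootstrap summary in the mean +/- SD style."""

    class_names: list[str]
    total_mean: float
    total_sd: float
    per_class_mean: dict[str, float]
    per_class_sd: dict[str, float]
    ber: float
    n_bootstrap: int
    n_skipped: int = 0

    def summary(self) -> str:
        lines = [f"Total:{100 * self.total_mean:.1f}% ± {100 * self.total_sd:.1f}"]
        for name in self.class_names:
            lines.append(
                f"{name}:{100 * self.per_class_mean[name]:.1f}% "
                f"± {100 * self.per_class_sd[name]:.1f}"
            )
        lines.append(f"BER:{self.ber:.2f}")
        return "\n".join(lines)


@dataclass
class KScanEntry:
    """Results of the pipeline at one value of k."""

    k: int
    factorization: FactorizationResult
    basis: OrthonormalBasis
    train_report: ClassificationReport
    source_class_map: SourceClassMap
    contribution_profile: tuple[list[str], np.ndarray]
    test_accuracy: float | None = None
    test_per_class: dict[str, float] | None = None
    test_ber: float | None = None


def gram_schmidt(W: np.ndarray, provenance: str = "") -> OrthonormalBasis:
    """Modified Gram-Schmidt orthonormalisation of the columns of W.

    Raises a :class:`ValidationError` naming the first numerically
    dependent column (relative residual below 1e-10).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    d, k = W.shape
    if k > d:
        raise ValidationError(f"cannot orthonormalise {k} columns in {d} dimensions")
    U = W.copy()
    for j in range(k):
        v = U[:, j]
        for i in range(j):
            v = v - (U[:, i] @ v) * U[:, i]
        norm = np.linalg.norm(v)
        ref = np.linalg.norm(W[:, j])
        if ref == 0 or norm <= 1e-10 * ref:
            raise ValidationError(
                f"column {j} of the source set is linearly dependent on its predecessors"
            )
        U[:, j] = v / norm
    return OrthonormalBasis(U=U, provenance=provenance)


def project_spectra(table: SpectrumTable, basis: OrthonormalBasis) -> np.ndarray:
    """Project every case onto the basis: F = U^T V, shape (k, n)."""
    if basis.U.shape[0] != table.d:
        raise ValidationError(
            f"basis has {basis.U.shape[0]} rows but spectra have {table.d} points"
        )
    return basis.U.T @ table.intensities


def fit_lda(features: np.ndarray, labels: LabelVector) -> LdaModel:
    """Fisher LDA: class means, pooled covariance (denominator n - m),
    empirical priors.  A singular pooled covariance gets a small ridge."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != len(labels):
        raise ValidationError(f"{F.shape[1]} feature columns for {len(labels)} labels")
    X = F.T  # (n, k)
    lab = labels.as_array()
    names = sorted(set(labels.values))
    m, n, k = len(names), X.shape[0], X.shape[1]
    counts = np.array([(lab == name).sum() for name in names])
    if np.any(counts < 2):
        tiny = [names[i] for i in np.nonzero(counts < 2)[0]]
        raise ValidationError(f"classes with fewer than 2 cases: {tiny}")
    means = np.vstack([X[lab == name].mean(axis=0) for name in names])
    S = np.zeros((k, k))
    for i, name in enumerate(names):
        R = X[lab == name] - means[i]
        S += R.T @ R
    S /= n - m
    if np.linalg.matrix_rank(S) < k or np.linalg.cond(S) > 1e12:
        warnings.warn("singular pooled covariance; adding ridge")
        S = S + (1e-8 * np.trace(S) / k + 1e-12) * np.eye(k)
    return LdaModel(
        class_names=names,
        class_means=means,
        pooled_covariance=S,
        priors=counts / n,
    )


def predict_lda(model: LdaModel, features: np.ndarray) -> LabelVector:
    """Argmax of the linear discriminant scores; ties go to the
    lexicographically first class (class names are stored sorted)."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] != model.class_means.shape[1]:
        raise ValidationError(
            f"features have dimension {F.shape[0]}, model expects "
            f"{model.class_means.shape[1]}"
        )
    scores = model.discriminant_scores(F)
    best = np.argmax(scores, axis=1)  # first max wins; names sorted
    return LabelVector([model.class_names[j] for j in best],
                       alphabet=model.class_names)


def balanced_error_rate(pred: LabelVector, truth: LabelVector) -> float:
    """BER = 1 - mean per-class recall over the classes present in truth."""
    if len(pred) != len(truth):
        raise ValidationError("prediction and truth differ in length")
    lab_t = truth.as_array()
    lab_p = pred.as_array()
    names = sorted(set(truth.values))
    recalls = []
    for name in names:
        mask = lab_t == name
        if not mask.any():
            raise ValidationError(f"class {name!r} has no cases in truth")
        recalls.append(float((lab_p[mask] == name).mean()))
    return 1.0 - float(np.mean(recalls))


def bootstrap_evaluate(
    features: np.ndarray,
    labels: LabelVector,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified bootstrap of the LDA classifier with out-of-bag scoring.

    Each replicate resamples every class with replacement at its own size,
    fits LDA on the replicate and scores the never-drawn (out-of-bag)
    cases.  A replicate whose out-of-bag set misses a class is redrawn (at
    most 10 times) and skipped if still degenerate.
    """
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    F = np.atleast_2d(np.asarray(features, dtype=float))
    lab = labels.as_array()
    names = sorted(set(labels.values))
    class_idx = {name: np.nonzero(lab == name)[0] for name in names}
    rng = np.random.default_rng(seed)
    n = len(labels)

    totals, per_class = [], {name: [] for name in names}
    recalls_sum = np.zeros(len(names))
    skipped = 0
    for _ in range(n_bootstrap):
        for _attempt in range(10):
            boot = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in class_idx.values()]
            )
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size and all(np.isin(idx, oob).any() for idx in class_idx.values()):
                break
        else:
            skipped += 1
            continue
        model = fit_lda(F[:, boot], LabelVector(list(lab[boot])))
        pred = predict_lda(model, F[:, oob]).as_array()
        truth_oob = lab[oob]
        totals.append(float((pred == truth_oob).mean()))
        for i, name in enumerate(names):
            mask = truth_oob == name
            r = float((pred[mask] == name).mean())
            per_class[name].append(r)
            recalls_sum[i] += r
    if not totals:
        raise ValidationError("all bootstrap replicates were degenerate")
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap replicates")
    n_ok = len(totals)
    return ClassificationReport(
        class_names=names,
        total_mean=float(np.mean(totals)),
        total_sd=float(np.std(totals)),
        per_class_mean={k: float(np.mean(v)) for k, v in per_class.items()},
        per_class_sd={k: float(np.std(v)) for k, v in per_class.items()},
        ber=float(1.0 - (recalls_sum / n_ok).mean()),
        n_bootstrap=n_bootstrap,
        n_skipped=skipped,
    )


def scan_number_of_sources(
    table: SpectrumTable,
    labels: LabelVector,
    k_range: tuple[int, int] = (2, 10),
    test_table: SpectrumTable | None = None,
    test_labels: LabelVector | None = None,
    seed: int = 0,
    n_bootstrap: int = 1000,
    options: FactorizationOptions | None = None,
) -> dict[int, KScanEntry]:
    """Run the convex-NMF -> Gram-Schmidt -> LDA pipeline for each k.

    Sources are extracted once per k on the full training matrix (K-means
    initialised convex factorisation); the bootstrap applies only to the
    LDA stage.  An optional independent test set is projected onto the
    training basis and scored with accuracy and BER.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if not 1 <= lo <= hi < table.d:
        raise ValidationError(f"invalid k range {k_range} for d={table.d}")
    templates = class_mean_spectra(table, labels)
    results: dict[int, KScanEntry] = {}
    for k in range(lo, hi + 1):
        init = initialize(table, k, "kmeans", "convex", seed=seed)
        fact = factorize(table, k, "convex", init, options)
        basis = gram_schmidt(fact.W, provenance=f"convex-kmeans k={k} seed={seed}")
        F = project_spectra(table, basis)
        report = bootstrap_evaluate(F, labels, n_bootstrap=n_bootstrap, seed=seed)
        mapping = match_sources_to_classes(fact.W, templates)
        C = contribution_matrix(table, fact.W, fact.H)
        profile = class_contribution_profile(C, labels)
        entry = KScanEntry(
            k=k, factorization=fact, basis=basis, train_report=report,
            source_class_map=mapping, contribution_profile=profile,
        )
        if test_table is not None and test_labels is not None:
            F_test = project_spectra(test_table, basis)
            model = fit_lda(F, labels)
            pred = predict_lda(model, F_test)
            truth_arr = test_labels.as_array()
            pred_arr = pred.as_array()
            entry.test_accuracy = float((pred_arr == truth_arr).mean())
            entry.test_per_class = {
                name: float((pred_arr[truth_arr == name] == name).mean())
                for name in sorted(set(test_labels.values))
            }
            entry.test_ber = balanced_error_rate(pred, test_labels)
        results[k] = entry
    return results
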