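"""Unsupervised tumour-type labelling from sources and the mixing matrix.

Once sources have been extracted, each source is assigned to the class
whose mean-spectrum template it correlates with best (Pearson).  A case is
then labelled by the source that contributes most to its reconstruction,
through the contribution statistic

    C(i, k) = V_i^T W_k H(k, i)

— the inner product of case i with source k, weighted by that source's
mixing coefficient for the case.  No labelled data enters the source
extraction itself, so the procedure is fully unsupervised; labels are used
only to name the sources and to score the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .preprocess import ClassTemplates
from .spectra_io import LabelVector, SpectrumTable


@dataclass
class SourceClassMap:
    """Assignment of every source to a class, with the full correlation table.

    ``correlations`` is (m classes x k sources); ``source_to_class[j]`` is
    the class whose template correlates best with source j.  Several
    sources may map to the same class, and a class may own none.
    """

    class_names: list[str]
    correlations: np.ndarray
    source_to_class: list[str]

    @property
    def class_best_source(self) -> np.ndarray:
        """Index of the best-correlated source for each class (Tables-style view)."""
        return np.argmax(self.correlations, axis=1)

    @property
    def class_best_correlation(self) -> np.ndarray:
        return np.max(self.correlations, axis=1)


@dataclass
class ContributionMatrix:
    """Per-case, per-source contribution values C (n x k), sign unrestricted."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))


@dataclass
class LabellingReport:
    """Accuracy bookkeeping for a labelling run."""

    class_names: list[str]
    confusion: np.ndarray  # (m, m), rows = truth, cols = predicted
    total_accuracy: float
    per_class_accuracy: dict[str, float]
    n: int

    def summary(self) -> str:
        lines = [f"Total:{100 * self.total_accuracy:.1f}%"
                 f"({int(np.trace(self.confusion))}/{self.n})"]
        for i, name in enumerate(self.class_names):
            size = int(self.confusion[i].sum())
            if size == 0:
                continue
            hits = int(self.confusion[i, i])
            lines.append(f"{name}:{100 * self.per_class_accuracy[name]:.1f}%({hits}/{size})")
        return "\n".join(lines)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(xc @ yc / (nx * ny))


def match_sources_to_classes(W: np.ndarray, templates: ClassTemplates) -> SourceClassMap:
    """Correlate every source with every class template and assign by argmax.

    A zero-variance source or template yields correlation 0 (with a
    warning) rather than NaN.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    T = templates.mean_spectra
    if W.shape[0] != T.shape[0]:
        raise ValidationError(
            f"sources have {W.shape[0]} points but templates have {T.shape[0]}"
        )
    m, k = T.shape[1], W.shape[1]
    corr = np.empty((m, k))
    degenerate = False
    for c in range(m):
        for j in range(k):
            if np.ptp(W[:, j]) == 0 or np.ptp(T[:, c]) == 0:
                corr[c, j] = 0.0
                degenerate = True
            else:
                corr[c, j] = _pearson(T[:, c], W[:, j])
    if degenerate:
        import warnings

        warnings.warn("zero-variance source or template; correlation set to 0")
    assigned = [templates.class_names[int(np.argmax(corr[:, j]))] for j in range(k)]
    return SourceClassMap(list(templates.class_names), corr, assigned)


def contribution_matrix(table: SpectrumTable, W: np.ndarray, H: np.ndarray) -> ContributionMatrix:
    """C(i, k) = V_i^T W_k H(k, i), computed exactly, no normalisation."""
    V = table.intensities
    W = np.atleast_2d(np.asarray(W, dtype=float))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or H.shape[0] != W.shape[1]:
        raise ValidationError(
            f"shapes do not conform: V{V.shape}, W{W.shape}, H{H.shape}"
        )
    # (V^T W) is (n, k); multiply elementwise by H^T
    return ContributionMatrix((V.T @ W) * H.T)


def predict_labels(C: ContributionMatrix, mapping: SourceClassMap) -> LabelVector:
    """Label each case by its maximum-contribution source's class.

    Ties go to the lowest source index, which keeps the rule deterministic.
    """
    values = C.values
    if values.shape[1] != len(mapping.source_to_class):
        raise ValidationError(
            f"{values.shape[1]} contribution columns for "
            f"{len(mapping.source_to_class)} mapped sources"
        )
    best = np.argmax(values, axis=1)  # first occurrence wins ties
    return LabelVector([mapping.source_to_class[j] for j in best],
                       alphabet=sorted(set(mapping.class_names)))


def evaluate_labelling(pred: LabelVector, truth: LabelVector) -> LabellingReport:
    """Total and per-class accuracy plus the full confusion matrix."""
    if len(pred) != len(truth):
        raise ValidationError("prediction and truth differ in length")
    extra = sorted(set(pred.values) - set(truth.alphabet))
    if extra:
        raise ValidationError(f"predicted classes absent from truth alphabet: {extra}")
    names = sorted(set(truth.values) | set(pred.values))
    idx = {name: i for i, name in enumerate(names)}
    m = len(names)
    conf = np.zeros((m, m), dtype=int)
    for p, t in zip(pred.values, truth.values):
        conf[idx[t], idx[p]] += 1
    n = len(truth)
    per_class = {
        name: float(conf[i, i] / conf[i].sum())
        for i, name in enumerate(names)
        if conf[i].sum() > 0
    }
    return LabellingReport(
        class_names=names,
        confusion=conf,
        total_accuracy=float(np.trace(conf) / n),
        per_class_accuracy=per_class,
        n=n,
    )


def class_contribution_profile(C: ContributionMatrix, truth: LabelVector) -> tuple[list[str], np.ndarray]:
    """Percentage of contribution of each source to each class.

    For each class the mean contribution of its cases is taken per source,
    negatives are floored at zero, and the row is normalised to sum to 100
    (an all-zero row is left at zero).  Returns (class names, m x k matrix).
    """
    values = C.values
    if values.shape[0] != len(truth):
        raise ValidationError("contribution rows and truth labels differ in length")
    names = sorted(set(truth.values))
    lab = truth.as_array()
    rows = []
    for name in names:
        mask = lab == name
        if not mask.any():
            raise ValidationError(f"class {name!r} has no cases")
        mean = np.maximum(values[mask].mean(axis=0), 0.0)
        total = mean.sum()
        rows.append(100.0 * mean / total if total > 0 else mean)
    return names, np.vstack(rows)
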