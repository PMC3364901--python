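"""Normalisation and sign handling applied before factorisation.

Spectra are unit-length (UL2) normalised case by case, matching common
practice for clinical MRS pattern recognition.  For factorisation methods
that require non-negative data, negative intensities are replaced by their
absolute values rather than truncated to zero, which preserves the
information carried by inverted doublets (Lactate at ~1.35 ppm, Alanine at
~1.45 ppm in long-echo-time spectra).  Convex factorisation accepts
mixed-sign input directly and never goes through the absolute-value
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spectra_io import LabelVector, SpectrumTable


@dataclass
class ClassTemplates:
    """Per-class mean spectra used as matching templates.

    ``mean_spectra`` is ``(d, m)`` with one column per class, computed as
    the arithmetic mean of the same-class columns of a spectra table.
    """

    class_names: list[str]
    mean_spectra: np.ndarray
    ppm_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_spectra = np.atleast_2d(np.asarray(self.mean_spectra, dtype=float))
        if len(self.class_names) != self.mean_spectra.shape[1]:
            raise ValidationError(
                f"{len(self.class_names)} class names for "
                f"{self.mean_spectra.shape[1]} template columns"
            )
        if len(self.class_names) < 1:
            raise ValidationError("at least one class template required")

    @property
    def m(self) -> int:
        return len(self.class_names)


def normalize_ul2(table: SpectrumTable) -> SpectrumTable:
    """Scale every case (column) to unit Euclidean norm.

    Signs are untouched; a spectrum that is identically zero cannot be
    normalised and raises a :class:`ValidationError` naming the case.
    """
    V = table.intensities
    norms = np.linalg.norm(V, axis=0)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValidationError(
            f"cannot UL2-normalise all-zero spectra: cases {[table.case_ids[i] for i in zero]}"
        )
    return table.with_intensities(V / norms)


def to_nonnegative(table: SpectrumTable) -> SpectrumTable:
    """Replace intensities by their absolute values (idempotent)."""
    return table.with_intensities(np.abs(table.intensities), nonnegative_transformed=True)


def class_mean_spectra(table: SpectrumTable, labels: LabelVector | None = None) -> ClassTemplates:
    """Arithmetic mean spectrum of each class.

    Labels default to those stored on the table.  Classes appear in sorted
    name order; every class must have at least one case.
    """
    if labels is None:
        if table.labels is None:
            raise ValidationError("no labels supplied and none stored on the table")
        labels = LabelVector(table.labels)
    if len(labels) != table.n:
        raise ValidationError(f"{len(labels)} labels for {table.n} cases")
    lab = labels.as_array()
    names = sorted(set(labels.values))
    cols = []
    for name in names:
        mask = lab == name
        if not mask.any():
            raise ValidationError(f"class {name!r} has no cases")
        cols.append(table.intensities[:, mask].mean(axis=1))
    return ClassTemplates(names, np.column_stack(cols), ppm_axis=table.ppm_axis)
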