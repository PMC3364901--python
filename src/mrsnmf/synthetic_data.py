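"""Synthetic MRS-like cohorts with known sources, mixing and labels.

Real single-voxel brain spectra are linear mixtures of tissue patterns:
a voxel rarely contains a single tissue type, so each measured spectrum
blends its own class pattern with neighbouring ones.  The generator
emulates exactly that structure on the standard clinical grid (195 points
over the [4.24, 0.50] ppm interval): class template spectra built from
Gaussian or Lorentzian metabolite peaks, non-negative per-case mixing
weights on the probability simplex, additive Gaussian noise, and a final
unit-length (UL2) normalisation.

The default long-echo-time (LTE) template set carries the field's
landmark features — the inverted Lactate doublet at 1.35 ppm, the
inverted Alanine doublet at 1.45 ppm, choline at ~3.21 ppm, creatine at
3.03 ppm, NAA at 2.02 ppm and mobile lipids at 0.9/1.3 ppm — so that
mixed-sign handling is genuinely exercised.  The short-echo-time (STE)
set uses the same centres with all-positive amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .preprocess import ClassTemplates
from .spectra_io import LabelVector, SpectrumTable


@dataclass
class PeakSpec:
    """One metabolite resonance: a (possibly inverted or doubled) lineshape.

    ``amplitude`` may be negative (inverted doublets at long echo time);
    ``doublet_split`` > 0 places two identical peaks at center +/- split/2.
    """

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    doublet_split: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("peak width must be positive")
        if self.doublet_split < 0:
            raise ValidationError("doublet_split must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValidationError(f"unknown lineshape {self.shape!r}")

    def evaluate(self, ppm: np.ndarray) -> np.ndarray:
        centers = [self.center]
        if self.doublet_split > 0:
            half = self.doublet_split / 2.0
            centers = [self.center - half, self.center + half]
        out = np.zeros_like(ppm)
        for c in centers:
            x = (ppm - c) / self.width
            if self.shape == "gaussian":
                out += np.exp(-0.5 * x * x)
            else:
                out += 1.0 / (1.0 + x * x)
        return self.amplitude * out


# Landmark metabolite patterns.  Amplitudes are relative; each template is
# UL2-normalised after summation, so only ratios matter.
_LTE_CLASSES: list[tuple[str, list[PeakSpec]]] = [
    ("A2", [  # low-grade astrocytoma: high choline, inverted lactate doublet
        PeakSpec(3.21, 0.035, 1.0),
        PeakSpec(3.03, 0.035, 0.25),
        PeakSpec(2.02, 0.045, 0.2),
        PeakSpec(1.35, 0.025, -0.9, doublet_split=0.06),
    ]),
    ("MM", [  # meningioma: inverted alanine doublet, choline, glutamate region
        PeakSpec(3.21, 0.035, 0.55),
        PeakSpec(2.30, 0.050, 0.5),
        PeakSpec(1.45, 0.025, -0.9, doublet_split=0.06),
    ]),
    ("NO", [  # normal parenchyma: dominant NAA, creatine, modest choline
        PeakSpec(2.02, 0.045, 1.0),
        PeakSpec(3.03, 0.035, 0.6),
        PeakSpec(3.21, 0.035, 0.35),
    ]),
    ("AG", [  # aggressive (GL+ME): strong mobile lipids, choline, some lactate
        PeakSpec(0.90, 0.060, 1.0),
        PeakSpec(1.30, 0.060, 0.9),
        PeakSpec(3.21, 0.035, 0.5),
        PeakSpec(1.35, 0.025, -0.3, doublet_split=0.06),
    ]),
]


def default_lte_classes() -> list[tuple[str, list[PeakSpec]]]:
    """Long-echo-time template set (mixed sign: inverted doublets)."""
    return [(name, list(peaks)) for name, peaks in _LTE_CLASSES]


def default_ste_classes() -> list[tuple[str, list[PeakSpec]]]:
    """Short-echo-time template set: same centres, all-positive amplitudes."""
    return [
        (name, [
            PeakSpec(p.center, p.width, abs(p.amplitude), p.shape, p.doublet_split)
            for p in peaks
        ])
        for name, peaks in _LTE_CLASSES
    ]


@dataclass
class CohortConfig:
    """Geometry and sampling conditions of a simulated cohort.

    ``dominance`` is the expected mixing weight a case places on its own
    class template; the remaining mass spreads over the other templates.
    ``noise_sd`` is the per-grid-point standard deviation of the additive
    Gaussian noise, applied before the final UL2 normalisation.
    """

    classes: list[tuple[str, list[PeakSpec]]] = field(default_factory=default_lte_classes)
    n_per_class: int = 20
    dominance: float = 0.8
    noise_sd: float = 0.005
    n_points: int = 195
    ppm_range: tuple[float, float] = (4.24, 0.50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("need at least 2 grid points")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        m = len(self.classes)
        if m < 1:
            raise ValidationError("at least one class required")
        if m > 1 and not (1.0 / m) < self.dominance <= 1.0:
            raise ValidationError(
                f"dominance must lie in (1/m, 1] = ({1.0 / m:.3f}, 1], got {self.dominance}"
            )
        if self.ppm_range[0] <= self.ppm_range[1]:
            raise ValidationError("ppm_range must be (high, low)")

    @property
    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.classes]


@dataclass
class SimulatedCohort:
    """A simulated spectra table plus its generating ground truth."""

    table: SpectrumTable
    mixing: np.ndarray  # (m templates, n cases), rows of the true H
    templates: ClassTemplates
    config: CohortConfig


def make_class_templates(config: CohortConfig) -> ClassTemplates:
    """Sum each class's peak lineshapes on the ppm grid and UL2-normalise."""
    ppm = config.ppm_axis
    hi, lo = config.ppm_range
    cols = []
    for name, peaks in config.classes:
        spectrum = np.zeros(config.n_points)
        for p in peaks:
            if not lo <= p.center <= hi:
                raise ValidationError(
                    f"class {name!r}: peak centre {p.center} ppm outside [{lo}, {hi}]"
                )
            spectrum += p.evaluate(ppm)
        norm = np.linalg.norm(spectrum)
        if norm == 0:
            raise ValidationError(f"class {name!r} template is identically zero")
        cols.append(spectrum / norm)
    return ClassTemplates(config.class_names, np.column_stack(cols), ppm_axis=ppm)


def _dirichlet_alpha(m: int, dominance: float, base: float = 1.0) -> np.ndarray:
    """Concentration vector with E[own-class weight] = dominance.

    With alpha = (a_own, base, ..., base), E[own] = a_own / (a_own +
    (m-1) base); solving for a_own gives the boost below.
    """
    if m == 1:
        return np.array([base])
    a_own = dominance * (m - 1) * base / (1.0 - dominance)
    return np.concatenate([[a_own], np.full(m - 1, base)])


def simulate_cohort(
    templates: ClassTemplates | None = None,
    config: CohortConfig | None = None,
) -> SimulatedCohort:
    """Draw a labelled cohort of linearly mixed, noisy, UL2-normalised spectra.

    Case i of class c is ``V_i = sum_j h_ij T_j + eps`` with h_i on the
    simplex (Dirichlet, tilted so the own-class weight has expectation
    ``dominance``; dominance 1 degenerates to h = one-hot) and eps
    i.i.d. Gaussian.  Ground-truth mixing weights and labels are returned
    alongside the table.
    """
    config = config or CohortConfig()
    if templates is None:
        templates = make_class_templates(config)
    T = templates.mean_spectra
    m = T.shape[1]
    n = m * config.n_per_class
    rng = np.random.default_rng(config.seed)

    H_true = np.zeros((m, n))
    labels: list[str] = []
    col = 0
    for c in range(m):
        if config.dominance == 1.0:
            Hc = np.zeros((config.n_per_class, m))
            Hc[:, c] = 1.0
        else:
            alpha = _dirichlet_alpha(m, config.dominance)
            Hc_own_first = rng.dirichlet(alpha, size=config.n_per_class)
            # move the boosted "own" coordinate into position c
            order = [c] + [j for j in range(m) if j != c]
            Hc = np.empty_like(Hc_own_first)
            Hc[:, order] = Hc_own_first
        for i in range(config.n_per_class):
            H_true[:, col] = Hc[i]
            labels.append(templates.class_names[c])
            col += 1

    V = T @ H_true
    if config.noise_sd > 0:
        V = V + rng.normal(0.0, config.noise_sd, size=V.shape)
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        raise ValidationError("simulated spectrum collapsed to zero; raise noise or dominance")
    V = V / norms

    table = SpectrumTable(
        ppm_axis=config.ppm_axis,
        intensities=V,
        case_ids=[f"{lab}_{i:03d}" for i, lab in enumerate(labels)],
        labels=labels,
    )
    return SimulatedCohort(table=table, mixing=H_true, templates=templates, config=config)


def cohort_labels(cohort: SimulatedCohort) -> LabelVector:
    return LabelVector(list(cohort.table.labels))
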