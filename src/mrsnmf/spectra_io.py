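"""Spectra tables and their on-disk delimited-text representation.

A cohort of magnetic-resonance spectra is held as a :class:`SpectrumTable`:
a ``d x n`` real matrix of frequency intensities (rows are ppm grid points,
columns are cases) together with its ppm axis, case identifiers and optional
per-case class labels.  Intensities may be of either sign — long-echo-time
spectra carry inverted doublets — so no non-negativity is assumed here.

The interchange format is tab-separated text: first column ``ppm``, one
column per case, and an optional trailing ``#labels`` row.  Numbers are
written with 17 significant digits so that write/read round-trips are
lossless well below 1e-12.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError

_FLOAT_FMT = "%.17g"


@dataclass
class SpectrumTable:
    """A d x n matrix of spectral intensities with metadata.

    Parameters
    ----------
    ppm_axis:
        Chemical-shift axis in parts per million, strictly decreasing
        (the MRS display convention puts high ppm first).
    intensities:
        ``(d, n)`` array; rows are frequencies, columns are cases.
    case_ids:
        Unique identifiers, one per column.
    labels:
        Optional class label per case (e.g. ``A2``, ``MM``, ``NO``).
    nonnegative_transformed:
        True when the absolute-value transform has been applied.
    """

    ppm_axis: np.ndarray
    intensities: np.ndarray
    case_ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    nonnegative_transformed: bool = False

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float).ravel()
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if not self.case_ids:
            self.case_ids = [f"case{i}" for i in range(self.intensities.shape[1])]
        self.case_ids = [str(c) for c in self.case_ids]
        self.validate()

    @property
    def d(self) -> int:
        return self.intensities.shape[0]

    @property
    def n(self) -> int:
        return self.intensities.shape[1]

    def validate(self) -> None:
        if self.ppm_axis.shape[0] != self.intensities.shape[0]:
            raise ValidationError(
                f"ppm axis length {self.ppm_axis.shape[0]} does not match "
                f"{self.intensities.shape[0]} intensity rows"
            )
        if self.ppm_axis.size >= 2 and not np.all(np.diff(self.ppm_axis) < 0):
            raise ValidationError("ppm_axis must be strictly decreasing")
        if len(self.case_ids) != self.n:
            raise ValidationError(
                f"{len(self.case_ids)} case ids for {self.n} cases"
            )
        if len(set(self.case_ids)) != len(self.case_ids):
            dupes = sorted({c for c in self.case_ids if self.case_ids.count(c) > 1})
            raise ValidationError(f"duplicate case ids: {dupes}")
        if self.labels is not None and len(self.labels) != self.n:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.n} cases"
            )

    def with_intensities(self, values: np.ndarray, **changes) -> "SpectrumTable":
        """Copy of this table with new intensity values (shape preserved)."""
        return replace(self, intensities=np.asarray(values, dtype=float), **changes)


@dataclass
class LabelVector:
    """Class labels over a finite alphabet, one per case."""

    values: list[str]
    alphabet: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = [str(v) for v in self.values]
        if self.alphabet is None:
            self.alphabet = sorted(set(self.values))
        else:
            self.alphabet = [str(a) for a in self.alphabet]
            bad = sorted(set(self.values) - set(self.alphabet))
            if bad:
                raise ValidationError(f"labels outside declared alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=object)


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(
            f"{path}, line {lineno}: cannot parse {token!r} as a number"
        ) from exc


def read_spectra(path: str | Path, orientation: str = "rows_are_frequencies") -> SpectrumTable:
    """Read a TSV spectra table.

    ``orientation`` describes the file layout: ``rows_are_frequencies``
    (the native layout written by :func:`write_spectra`) or
    ``rows_are_cases`` (transposed, header row carries the ppm values).
    Rows are re-ordered to decreasing ppm if the file stores them ascending.
    """
    path = Path(path)
    if orientation not in ("rows_are_frequencies", "rows_are_cases"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")

    header = lines[0].split("\t")
    labels: list[str] | None = None
    body = lines[1:]
    if body and body[-1].split("\t")[0] == "#labels":
        labels = body[-1].split("\t")[1:]
        body = body[:-1]

    if orientation == "rows_are_frequencies":
        if header[0] != "ppm":
            raise FormatError(f"{path}, line 1: first header field must be 'ppm', got {header[0]!r}")
        case_ids = header[1:]
        n = len(case_ids)
        ppm, rows = [], []
        for off, ln in enumerate(body, start=2):
            fields = ln.split("\t")
            if len(fields) != n + 1:
                raise FormatError(
                    f"{path}, line {off}: expected {n + 1} fields, got {len(fields)}"
                )
            ppm.append(_parse_float(fields[0], path, off))
            rows.append([_parse_float(f, path, off) for f in fields[1:]])
        intens = np.asarray(rows, dtype=float).reshape(len(ppm), n)
        ppm_axis = np.asarray(ppm, dtype=float)
    else:
        ppm_axis = np.asarray(
            [_parse_float(tok, path, 1) for tok in header[1:]], dtype=float
        )
        d = ppm_axis.size
        case_ids, cols = [], []
        for off, ln in enumerate(body, start=2):
            fields = ln.split("\t")
            if len(fields) != d + 1:
                raise FormatError(
                    f"{path}, line {off}: expected {d + 1} fields, got {len(fields)}"
                )
            case_ids.append(fields[0])
            cols.append([_parse_float(f, path, off) for f in fields[1:]])
        intens = np.asarray(cols, dtype=float).reshape(len(case_ids), d).T

    if ppm_axis.size == 0:
        raise FormatError(f"{path}: missing ppm axis")
    if ppm_axis.size >= 2 and np.all(np.diff(ppm_axis) > 0):
        ppm_axis = ppm_axis[::-1].copy()
        intens = intens[::-1].copy()
    if labels is not None and len(labels) != len(case_ids):
        raise FormatError(
            f"{path}: #labels row has {len(labels)} entries for {len(case_ids)} cases"
        )
    return SpectrumTable(ppm_axis, intens, case_ids, labels)


def write_spectra(table: SpectrumTable, path: str | Path) -> None:
    """Write ``table`` as TSV; round-trips through :func:`read_spectra`."""
    table.validate()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(["ppm", *table.case_ids]) + "\n")
        for i in range(table.d):
            row = [_FLOAT_FMT % table.ppm_axis[i]]
            row += [_FLOAT_FMT % v for v in table.intensities[i]]
            fh.write("\t".join(row) + "\n")
        if table.labels is not None:
            fh.write("\t".join(["#labels", *table.labels]) + "\n")


def read_labels(path: str | Path) -> tuple[list[str], LabelVector]:
    """Read a two-column (case_id, label) TSV; returns ids and labels."""
    path = Path(path)
    ids, labels = [], []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}, line {lineno}: expected 2 fields, got {len(fields)}"
                )
            ids.append(fields[0])
            labels.append(fields[1])
    return ids, LabelVector(labels)


def write_labels(case_ids: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    if len(case_ids) != len(labels):
        raise ValidationError("case_ids and labels differ in length")
    with open(path, "w") as fh:
        for cid, lab in zip(case_ids, labels):
            fh.write(f"{cid}\t{lab}\n")


def _write_matrix(M: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.atleast_2d(M), fmt=_FLOAT_FMT, delimiter="\t")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", ndmin=2))


def save_factorization(result, outdir: str | Path) -> None:
    """Persist a FactorizationResult as TSV matrices plus JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_matrix(result.W, outdir / "W.tsv")
    _write_matrix(result.H, outdir / "H.tsv")
    if result.A is not None:
        _write_matrix(result.A, outdir / "A.tsv")
    _write_matrix(np.asarray(result.error_trace, dtype=float), outdir / "error_trace.tsv")
    meta = {
        "method": result.method,
        "init_strategy": result.init_strategy,
        "seed": result.seed,
        "k": result.k,
        "iterations": result.iterations,
        "tolerance": result.tolerance,
        "converged": result.converged,
        "nonnegative_transformed": result.nonnegative_transformed,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_factorization(indir: str | Path):
    """Load a factorisation previously written by :func:`save_factorization`."""
    from .nmf_core import FactorizationResult  # local import avoids a cycle

    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    A = _read_matrix(indir / "A.tsv") if (indir / "A.tsv").exists() else None
    return FactorizationResult(
        W=_read_matrix(indir / "W.tsv"),
        H=_read_matrix(indir / "H.tsv"),
        A=A,
        method=meta["method"],
        init_strategy=meta["init_strategy"],
        seed=meta["seed"],
        error_trace=_read_matrix(indir / "error_trace.tsv").ravel(),
        iterations=meta["iterations"],
        tolerance=meta["tolerance"],
        converged=meta["converged"],
        nonnegative_transformed=meta.get("nonnegative_transformed", False),
    )
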