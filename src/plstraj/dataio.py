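"""Reading and writing spectral calibration datasets.

The canonical on-disk format is a single comma-delimited UTF-8 text file:
first column sample id, second column the reference value (e.g. water
content, %, w/w), remaining columns the spectral channels with the axis
position (nm or cm^-1) as header.  One file is one dataset, which keeps the
command-line workflow stateless.

A read-only convenience reader for MATLAB v5 containers is provided for the
public corn and tablet benchmark datasets.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AxisError, FormatError, ShapeError, SpectraParseError

#: Relative tolerance on axis-spacing uniformity.  Derivative filters assume
#: a uniform grid; both public benchmark datasets are sampled at constant
#: 2 nm / 8 cm^-1 steps, so 1% is generous.
AXIS_UNIFORMITY_RTOL = 0.01

AXIS_UNITS = ("nm", "cm-1")


@dataclass
class SpectraDataset:
    """Spectra matrix with its wavelength/wavenumber axis and reference values.

    Attributes
    ----------
    sample_ids
        Opaque sample labels, one per row of ``X``.
    axis
        Channel positions.  Strictly monotone; increasing for nm, decreasing
        allowed for cm^-1 scans stored in acquisition order.
    X
        ``(n, p)`` absorbance matrix (dimensionless).
    y
        Length-``n`` reference content on the printed scale (percent, w/w).
    axis_unit
        ``"nm"`` or ``"cm-1"``; metadata only — algorithms work on channel
        index except derivatives, which use the median absolute spacing.
    reference_label
        Header used for the reference column when written to disk.
    """

    sample_ids: list[str]
    axis: np.ndarray
    X: np.ndarray
    y: np.ndarray
    axis_unit: str = "nm"
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.sample_ids = [str(s) for s in self.sample_ids]
        validate_dataset(self)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def spacing(self) -> float:
        """Median absolute channel spacing, used to scale derivatives."""
        if self.p < 2:
            return 1.0
        return float(np.median(np.abs(np.diff(self.axis))))

    def subset(self, indices: np.ndarray | list[int]) -> "SpectraDataset":
        """Row subset (samples), preserving the given order."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
        )


def validate_dataset(ds: SpectraDataset) -> None:
    """Raise if any SpectraDataset invariant is violated."""
    n, p = ds.X.shape
    if ds.axis.ndim != 1 or len(ds.axis) != p:
        raise ShapeError(f"axis length {len(ds.axis)} != number of channels {p}")
    if len(ds.y) != n:
        raise ShapeError(f"reference vector length {len(ds.y)} != number of samples {n}")
    if len(ds.sample_ids) != n:
        raise ShapeError(f"{len(ds.sample_ids)} sample ids for {n} samples")
    if ds.axis_unit not in AXIS_UNITS:
        raise FormatError(f"axis_unit must be one of {AXIS_UNITS}, got {ds.axis_unit!r}")
    if not (np.isfinite(ds.X).all() and np.isfinite(ds.y).all()):
        raise SpectraParseError("dataset contains missing or non-finite values")
    if p >= 2:
        d = np.diff(ds.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise AxisError("spectral axis is not strictly monotone")
        if np.all(d < 0) and ds.axis_unit == "nm":
            raise AxisError("decreasing axis only allowed for cm-1 data")
        med = np.median(np.abs(d))
        if np.max(np.abs(np.abs(d) - med)) > AXIS_UNIFORMITY_RTOL * med:
            raise AxisError(
                "axis spacing non-uniform beyond "
                f"{AXIS_UNIFORMITY_RTOL:.0%} relative tolerance"
            )


@dataclass(frozen=True)
class CsvLayout:
    """Column layout of a spectra CSV.

    ``None`` means positional defaults: first column is the id, second the
    reference value, everything else a spectral channel whose header parses
    as an axis position.  ``axis_unit=None`` infers nm for increasing and
    cm-1 for decreasing axes.
    """

    id_column: str | None = None
    reference_column: str | None = None
    axis_unit: str | None = None


def read_spectra(path, layout: CsvLayout = CsvLayout()) -> SpectraDataset:
    """Read a spectra CSV into a :class:`SpectraDataset`.

    Row order is preserved.  Raises :class:`FormatError` for missing or
    duplicate headers, :class:`SpectraParseError` (with row/column location)
    for non-numeric cells, and :class:`AxisError` for a non-monotone or
    non-uniform channel axis.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 3:
        raise FormatError(f"{path}: need at least id, reference and one channel column")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate column headers {dupes}")

    id_col = layout.id_column if layout.id_column is not None else header[0]
    ref_col = layout.reference_column if layout.reference_column is not None else header[1]
    for name in (id_col, ref_col):
        if name not in header:
            raise FormatError(f"{path}: column {name!r} not found in header")

    channel_cols = [h for h in header if h not in (id_col, ref_col)]
    try:
        axis = np.array([float(h) for h in channel_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: channel header does not parse as a position: {exc}") from exc

    df = pd.read_csv(path, dtype={id_col: str})
    numeric_cols = [ref_col, *channel_cols]
    values = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise SpectraParseError(
            f"{path}: non-numeric value at data row {r + 1}, column {numeric_cols[c]!r}"
        )

    unit = layout.axis_unit
    if unit is None:
        unit = "cm-1" if len(axis) >= 2 and axis[1] < axis[0] else "nm"
    return SpectraDataset(
        sample_ids=df[id_col].tolist(),
        axis=axis,
        X=values[channel_cols].to_numpy(dtype=float),
        y=values[ref_col].to_numpy(dtype=float),
        axis_unit=unit,
        reference_label=str(ref_col),
    )


def write_spectra(ds: SpectraDataset, path) -> str:
    """Write a dataset as a spectra CSV, full float precision.

    Round-trips through :func:`read_spectra` to within 1e-12 relative error
    (values are printed with ``repr`` precision).
    """
    validate_dataset(ds)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["id", ds.reference_label, *(f"{a:.10g}" for a in ds.axis)])
    for sid, yi, row in zip(ds.sample_ids, ds.y, ds.X):
        writer.writerow([sid, repr(float(yi)), *(repr(float(v)) for v in row)])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    return str(path)


def read_matlab_container(
    path,
    spectra_key: str,
    reference_key: str,
    axis_start: float | None = None,
    axis_step: float | None = None,
    axis_unit: str = "nm",
    reference_column: int = 0,
) -> SpectraDataset:
    """Read spectra and reference values from a MATLAB v5 container.

    Intended for the public corn and tablet benchmark files.  Sample ids are
    synthesized (``s0001`` ...).  The axis is reconstructed from
    ``axis_start``/``axis_step``; when omitted the channel index is used.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    for key in (spectra_key, reference_key):
        if key not in mat:
            raise KeyError(f"{path}: key {key!r} not found in container")
    X = np.atleast_2d(np.asarray(mat[spectra_key], dtype=float))
    ref = np.atleast_2d(np.asarray(mat[reference_key], dtype=float))
    if ref.shape[0] == 1 and ref.shape[1] == X.shape[0]:
        ref = ref.T
    if ref.shape[0] != X.shape[0]:
        raise ShapeError(
            f"reference has {ref.shape[0]} rows but spectra matrix has {X.shape[0]}"
        )
    y = ref[:, reference_column]
    p = X.shape[1]
    if axis_start is None or axis_step is None:
        axis = np.arange(p, dtype=float)
    else:
        axis = axis_start + axis_step * np.arange(p, dtype=float)
    ids = [f"s{i + 1:04d}" for i in range(X.shape[0])]
    return SpectraDataset(sample_ids=ids, axis=axis, X=X, y=y, axis_unit=axis_unit)
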