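"""Spectral pretreatment: SNV, Savitzky-Golay filtering, and ordered chains.

NIR diffuse-reflectance spectra carry three classic nuisance artifacts:
multiplicative scatter from particle-size variation, additive baseline
offset/drift, and high-frequency noise.  The standard normal variate (SNV)
transform standardizes each spectrum to zero mean and unit standard
deviation, removing per-sample offset and scale.  Savitzky-Golay (SG)
filtering fits a local polynomial in a sliding window; with derivative
order 1 or 2 it annihilates constant/linear baseline terms while smoothing
noise.

Pretreatments are named by a compact label grammar used throughout the
configuration and reports::

    raw | SNV | SG(w) | 1D+SG(w) | 2D+SG(w)

joined by ``+`` and applied left-to-right, e.g. ``"1D+SG(9)+SNV"``.  A
derivative token is always fused with the SG window that follows it into a
single filter pass; a bare ``1D`` is not representable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import factorial

import numpy as np

from .errors import DegenerateSpectrumError, ParameterError, ShapeError

#: Pretreatments enumerated by default in a processing trajectory.
DEFAULT_PRETREATMENT_MENU = (
    "raw",
    "SNV",
    "SG(9)",
    "1D+SG(9)",
    "2D+SG(9)",
    "1D+SG(9)+SNV",
)

#: Polynomial order used by every SG step.  Quadratic is the conventional
#: chemometrics default and is the lowest order admitting second derivatives.
SG_POLY_ORDER = 2


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: standardize each spectrum (row) independently.

    Each output row has mean 0 and sample standard deviation 1 (n-1
    denominator).  SNV is invariant to per-row affine maps ``a*x + b``
    (a > 0), which is exactly the scatter/offset artifact it corrects.

    Raises :class:`DegenerateSpectrumError` for any constant row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateSpectrumError(
            f"sample at row {bad} has zero spectral variance; SNV undefined"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


@dataclass(frozen=True)
class PretreatmentStep:
    """One pretreatment operation: SNV, or an SG smoothing/derivative filter."""

    kind: str  # "SNV" | "SG"
    window: int = 0
    poly_order: int = SG_POLY_ORDER
    deriv_order: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "SG"):
            raise ParameterError(f"unknown pretreatment kind {self.kind!r}")
        if self.kind == "SG":
            if self.window < 3 or self.window % 2 == 0:
                raise ParameterError(f"SG window must be odd and >= 3, got {self.window}")
            if not 0 <= self.poly_order < self.window:
                raise ParameterError(
                    f"SG polynomial order {self.poly_order} must be in [0, window)"
                )
            if not 0 <= self.deriv_order <= self.poly_order:
                raise ParameterError(
                    f"derivative order {self.deriv_order} exceeds polynomial order "
                    f"{self.poly_order}"
                )

    @property
    def label(self) -> str:
        if self.kind == "SNV":
            return "SNV"
        if self.deriv_order == 0:
            return f"SG({self.window})"
        return f"{self.deriv_order}D+SG({self.window})"


@dataclass(frozen=True)
class PretreatmentSpec:
    """Ordered, possibly empty chain of pretreatment steps."""

    steps: tuple[PretreatmentStep, ...] = ()

    @property
    def label(self) -> str:
        """Canonical display label; a pure function of the steps."""
        if not self.steps:
            return "raw"
        return "+".join(s.label for s in self.steps)


_SG_RE = re.compile(r"SG\((\d+)\)")
_DERIV_RE = re.compile(r"([12])D")


def parse_pretreatment(label: str) -> PretreatmentSpec:
    """Parse a pretreatment label into a :class:`PretreatmentSpec`.

    Grammar: ``raw`` alone, or ``+``-joined tokens from ``SNV``, ``SG(w)``,
    ``1D``, ``2D``; a derivative token must be immediately followed by an
    ``SG(w)`` token, with which it fuses into one filter pass.
    """
    text = label.strip()
    if text == "raw":
        return PretreatmentSpec()
    tokens = [t.strip() for t in text.split("+")]
    steps: list[PretreatmentStep] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "SNV":
            steps.append(PretreatmentStep("SNV"))
            i += 1
            continue
        m = _SG_RE.fullmatch(tok)
        if m:
            steps.append(PretreatmentStep("SG", window=int(m.group(1))))
            i += 1
            continue
        m = _DERIV_RE.fullmatch(tok)
        if m:
            if i + 1 >= len(tokens) or not _SG_RE.fullmatch(tokens[i + 1]):
                raise ParameterError(
                    f"pretreatment label {label!r}: derivative token {tok!r} "
                    "must be followed by SG(w)"
                )
            window = int(_SG_RE.fullmatch(tokens[i + 1]).group(1))
            steps.append(
                PretreatmentStep("SG", window=window, deriv_order=int(m.group(1)))
            )
            i += 2
            continue
        raise ParameterError(f"pretreatment label {label!r}: unknown token {tok!r}")
    return PretreatmentSpec(tuple(steps))


def savgol_coefficients(
    window: int, poly_order: int, deriv_order: int, position: int | None = None
) -> np.ndarray:
    """Savitzky-Golay convolution weights for one output position.

    Weights ``w`` satisfy ``w @ f = d^k/dx^k [P](0)`` where ``P`` is the
    least-squares polynomial of degree ``poly_order`` fitted to the window
    samples ``f`` at integer offsets ``i - position``, and ``k`` is
    ``deriv_order``.  ``position`` defaults to the window center; edge
    channels use off-center positions.  Derivatives are per index step;
    physical spacing is applied in :func:`apply_savgol`.
    """
    PretreatmentStep("SG", window=window, poly_order=poly_order, deriv_order=deriv_order)
    if position is None:
        position = window // 2
    if not 0 <= position < window:
        raise ParameterError(f"position {position} outside window of {window}")
    offsets = np.arange(window, dtype=float) - position
    design = np.vander(offsets, poly_order + 1, increasing=True)
    # row deriv_order of the pseudoinverse gives the deriv_order-th
    # polynomial coefficient as a linear functional of the data
    return factorial(deriv_order) * np.linalg.pinv(design)[deriv_order]


def apply_savgol(X: np.ndarray, step: PretreatmentStep, spacing: float = 1.0) -> np.ndarray:
    """Apply an SG filter along the channel axis, preserving shape.

    Interior channels use the central weights; the ``(window-1)//2`` edge
    channels on each side are evaluated at off-center positions of the first
    or last full window, so no channels are dropped and variable indices
    stay stable for downstream selection.  Derivative output is divided by
    ``spacing**deriv_order`` to express it per axis unit.
    """
    if step.kind != "SG":
        raise ParameterError("apply_savgol requires an SG step")
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = step.window
    if p < w:
        raise ShapeError(f"{p} channels is fewer than SG window {w}")
    half = w // 2

    center = savgol_coefficients(w, step.poly_order, step.deriv_order)
    out = np.empty_like(X)
    windows = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
    out[:, half : p - half] = windows @ center
    for pos in range(half):
        coef = savgol_coefficients(w, step.poly_order, step.deriv_order, position=pos)
        out[:, pos] = X[:, :w] @ coef
        coef = savgol_coefficients(
            w, step.poly_order, step.deriv_order, position=w - 1 - pos
        )
        out[:, p - 1 - pos] = X[:, p - w :] @ coef
    if step.deriv_order:
        out /= spacing**step.deriv_order
    return out


def apply_pipeline(X: np.ndarray, spec: PretreatmentSpec, spacing: float = 1.0) -> np.ndarray:
    """Apply a pretreatment chain left-to-right; the empty chain is identity."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    for step in spec.steps:
        X = snv(X) if step.kind == "SNV" else apply_savgol(X, step, spacing)
    return X
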