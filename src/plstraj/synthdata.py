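"""Synthetic NIR-like datasets with known ground truth.

The generator emulates the structure of diffuse-reflectance NIR data via a
Beer-Lambert mixing model with the classic nuisance artifacts layered on
top.  Per sample ``i``::

    x_i(l) = m_i * sum_k c_ik * eps_k(l) + (a + b*l + c*l^2) + o_i + noise

where ``eps_k`` is constituent ``k``'s pure spectrum (a sum of overlapping
Gaussian absorption bands), ``c_ik`` are concentrations drawn uniformly on
each constituent's range (percent, w/w), ``m_i ~ N(1, scatter_sd)`` is
multiplicative scatter from particle-size variation, ``(a, b, c)`` a fixed
baseline-drift polynomial in the axis position, ``o_i ~ N(0, offset_sd)``
a per-sample additive offset, and the noise is white with SD ``noise_sd``
per channel.  The response ``y_i`` is the target constituent's
concentration, so ground truth is exact and every artifact can be switched
off independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataio import SpectraDataset
from .errors import ParameterError


@dataclass(frozen=True)
class Constituent:
    """A chemical constituent: Gaussian bands plus a concentration range."""

    bands: tuple[tuple[float, float, float], ...]  # (center, width, amplitude)
    concentration_range: tuple[float, float]  # (lo, hi), percent w/w

    def pure_spectrum(self, axis: np.ndarray) -> np.ndarray:
        """Molar-absorptivity-like profile eps(l), per percent of content."""
        eps = np.zeros_like(axis, dtype=float)
        for center, width, amplitude in self.bands:
            eps += amplitude * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
        return eps


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic dataset."""

    axis_start: float
    axis_step: float
    axis_count: int
    constituents: tuple[Constituent, ...]
    baseline: tuple[float, float, float] = (0.0, 0.0, 0.0)  # intercept, slope, curvature
    scatter_sd: float = 0.0
    offset_sd: float = 0.0
    slope_sd: float = 0.0  # SD of per-sample drift slope around the baseline slope
    smooth_drift_sd: float = 0.0  # amplitude SD of smooth per-sample baseline wander
    smooth_drift_harmonics: int = 6
    noise_sd: float = 0.0
    target_constituent: int = 0
    seed: int = 0
    axis_unit: str = "nm"

    def __post_init__(self) -> None:
        if self.axis_count < 1 or self.axis_step == 0:
            raise ParameterError("axis must have at least one channel and nonzero step")
        if not self.constituents:
            raise ParameterError("at least one constituent is required")
        if not 0 <= self.target_constituent < len(self.constituents):
            raise ParameterError(f"target_constituent {self.target_constituent} out of range")
        for sd in (self.scatter_sd, self.offset_sd, self.slope_sd,
                   self.smooth_drift_sd, self.noise_sd):
            if sd < 0:
                raise ParameterError("artifact SDs must be non-negative")
        for c in self.constituents:
            lo, hi = c.concentration_range
            if not hi > lo:
                raise ParameterError(f"degenerate concentration range ({lo}, {hi})")
            for _, width, amplitude in c.bands:
                if width <= 0 or amplitude < 0:
                    raise ParameterError("band widths must be > 0, amplitudes >= 0")

    @property
    def axis(self) -> np.ndarray:
        return self.axis_start + self.axis_step * np.arange(self.axis_count, dtype=float)


def generate(spec: SyntheticSpec, n: int) -> SpectraDataset:
    """Draw ``n`` samples from the generative model; reproducible by seed."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(spec.seed)
    axis = spec.axis
    E = np.vstack([c.pure_spectrum(axis) for c in spec.constituents])  # (k, p)
    lo = np.array([c.concentration_range[0] for c in spec.constituents])
    hi = np.array([c.concentration_range[1] for c in spec.constituents])
    conc = rng.uniform(lo, hi, size=(n, len(spec.constituents)))
    scatter = rng.normal(1.0, spec.scatter_sd, size=n) if spec.scatter_sd else np.ones(n)
    offset = rng.normal(0.0, spec.offset_sd, size=n) if spec.offset_sd else np.zeros(n)
    slope = rng.normal(0.0, spec.slope_sd, size=n) if spec.slope_sd else np.zeros(n)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=(n, spec.axis_count))
        if spec.noise_sd
        else 0.0
    )
    a, b, c2 = spec.baseline
    # drift: a shared polynomial background plus per-sample offset and slope
    # perturbations (a sample-invariant background alone would vanish under
    # mean centering and exercise nothing)
    baseline = a + b * axis + c2 * axis**2
    drift = offset[:, None] + slope[:, None] * (axis - axis.mean())
    if spec.smooth_drift_sd:
        # slowly-varying per-sample baseline wander: low-frequency cosine
        # harmonics with 1/j amplitude decay.  Unlike an offset or a shared
        # slope this is not a low-rank nuisance, so it cannot be absorbed by
        # a couple of extra latent factors — only a derivative filter (which
        # attenuates low-frequency structure relative to sharp bands)
        # suppresses it
        u = np.pi * (axis - axis[0]) / (axis[-1] - axis[0] or 1.0)
        j = np.arange(1, spec.smooth_drift_harmonics + 1)
        basis = np.concatenate([np.cos(np.outer(j, u)), np.sin(np.outer(j, u))])
        coef = rng.normal(0.0, spec.smooth_drift_sd, size=(n, 2 * len(j))) / np.tile(j, 2)
        drift = drift + coef @ basis
    X = scatter[:, None] * (conc @ E) + baseline + drift + noise
    return SpectraDataset(
        sample_ids=[f"syn{i + 1:04d}" for i in range(n)],
        axis=axis,
        X=X,
        y=conc[:, spec.target_constituent],
        axis_unit=spec.axis_unit,
        reference_label="content_pct",
    )


def corn_like_spec(seed: int = 0) -> SyntheticSpec:
    """Default study conditions: a corn-moisture-like NIR scenario.

    Axis 1100-2498 nm at 2 nm (700 channels).  The target mimics water
    (bands near 1190/1450/1940 nm, content 9.38-10.98%); two broader-band
    interferents mimic a dominant carbohydrate matrix and a protein/oil
    fraction, giving severe band overlap.  Nuisance artifacts: a shared
    linear background plus per-sample drift (offset SD 0.1 AU, slope SD
    2e-4 AU/nm, smooth low-frequency wander SD 0.1 AU), multiplicative
    scatter SD 0.5%, and white noise SD 0.002 AU (~0.2% of the ~1 AU peak
    absorbance).  The drift amplitudes are on the order of the water signal
    span (~0.1 AU), which is what makes pretreatment choice consequential.
    """
    water = Constituent(
        bands=((1190.0, 40.0, 0.020), (1450.0, 45.0, 0.055), (1940.0, 50.0, 0.070)),
        concentration_range=(9.38, 10.98),
    )
    carbohydrate = Constituent(
        bands=(
            (1210.0, 60.0, 0.0035),
            (1580.0, 90.0, 0.0045),
            (2100.0, 90.0, 0.0060),
            (2320.0, 70.0, 0.0050),
        ),
        concentration_range=(58.0, 70.0),
    )
    protein_oil = Constituent(
        bands=(
            (1510.0, 60.0, 0.012),
            (1730.0, 50.0, 0.016),
            (2180.0, 60.0, 0.018),
            (2310.0, 55.0, 0.014),
        ),
        concentration_range=(6.5, 10.5),
    )
    return SyntheticSpec(
        axis_start=1100.0,
        axis_step=2.0,
        axis_count=700,
        constituents=(water, carbohydrate, protein_oil),
        baseline=(0.05, 2.0e-4, 0.0),
        scatter_sd=0.005,
        offset_sd=0.1,
        slope_sd=2.0e-4,
        smooth_drift_sd=0.1,
        noise_sd=0.002,
        target_constituent=0,
        seed=seed,
    )


def spec_from_yaml(path) -> SyntheticSpec:
    """Load a SyntheticSpec from a YAML file mirroring the dataclass fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        constituents = tuple(
            Constituent(
                bands=tuple(tuple(float(v) for v in band) for band in c["bands"]),
                concentration_range=tuple(float(v) for v in c["concentration_range"]),
            )
            for c in raw.pop("constituents")
        )
        return SyntheticSpec(
            constituents=constituents,
            baseline=tuple(float(v) for v in raw.pop("baseline", (0.0, 0.0, 0.0))),
            **raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"{path}: malformed synthetic spec ({exc})") from exc
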