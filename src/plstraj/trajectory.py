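"""Processing-trajectory search over PLS modeling paths.

A *path* is one combination of (spectral pretreatment, latent-factor count,
variable-selection mode).  Conventional practice optimizes these three
parameters one at a time, ignoring their interaction; the processing
trajectory instead enumerates the full Cartesian grid, fits and scores
every path with the complete metric panel (RMSEC, R²cal, RMSECV, RMSEP,
R²pre, RPD), and selects the best path by RPD.  The one-at-a-time
comparator (:func:`stepwise_optimize`) is included so the two strategies
can be compared on the same grid; by construction the exhaustive search is
never worse.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from math import inf

import numpy as np

from .dataio import SpectraDataset
from .errors import ParameterError, PlstrajError, RankError, TrajectoryError
from .metrics import ModelMetrics, evaluate_model
from .plsvip import (
    cross_validate,
    fit_pls,
    max_cv_factors,
    predict,
    vip_select,
)
from .pretreat import PretreatmentSpec, apply_pipeline

VARSEL_MODES = ("full", "VIP")


@dataclass(frozen=True)
class PathConfig:
    """One point of the trajectory grid."""

    pretreatment: PretreatmentSpec
    n_factors: int
    varsel: str  # "full" | "VIP"

    def __post_init__(self) -> None:
        if self.varsel not in VARSEL_MODES:
            raise ParameterError(f"varsel must be one of {VARSEL_MODES}, got {self.varsel!r}")
        if self.n_factors < 1:
            raise ParameterError(f"n_factors must be >= 1, got {self.n_factors}")


@dataclass
class TrajectoryRecord:
    """One evaluated path: its configuration and full metric panel.

    ``a_effective`` is the factor count actually used after feasibility
    clipping (never silently substituted for the requested ``n_factors``).
    Failed paths carry ``status != "ok"`` and ``metrics is None``.
    """

    config: PathConfig
    n_selected_variables: int
    a_effective: int
    metrics: ModelMetrics | None
    rmsecv: float | None
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class TrajectoryResult:
    """All records of a grid run plus the selected best path."""

    records: list[TrajectoryRecord]
    best: TrajectoryRecord
    criterion: str = "max RPD; ties: min RMSEP, min factors, menu order, full before VIP"


def enumerate_grid(
    pretreatments: list[PretreatmentSpec],
    A_max: int,
    varsel_modes: list[str] = list(VARSEL_MODES),
) -> list[PathConfig]:
    """Full Cartesian grid, pretreatment-major, then factors, then varsel."""
    if not pretreatments or not varsel_modes:
        raise ParameterError("pretreatment menu and varsel modes must be non-empty")
    if A_max < 1:
        raise ParameterError(f"A_max must be >= 1, got {A_max}")
    return [
        PathConfig(pre, a, mode)
        for pre in pretreatments
        for a in range(1, A_max + 1)
        for mode in varsel_modes
    ]


def _cv_curve(X: np.ndarray, y: np.ndarray, a_hi: int, k: int) -> np.ndarray | None:
    """RMSECV curve for 1..a_hi, shrinking a_hi if a fold runs out of rank."""
    while a_hi >= 1:
        try:
            return cross_validate(X, y, a_hi, k)
        except RankError as exc:
            cap = exc.max_factors if exc.max_factors is not None else a_hi - 1
            a_hi = min(a_hi - 1, cap)
    return None


def evaluate_path(
    config: PathConfig,
    cal: SpectraDataset,
    val: SpectraDataset,
    vip_threshold: float = 1.0,
    cv_folds: int = 10,
) -> TrajectoryRecord:
    """Fit and score one path; failures become flagged records, not crashes.

    Pipeline: pretreat both sets -> (VIP mode only) fit a full-variable
    model at the requested factor count, score VIP, select channels,
    restrict both sets -> fit the final model at the feasible factor count
    -> metric panel on calibration and validation plus RMSECV (at the
    effective factor count) on calibration.
    """
    if not np.allclose(cal.axis, val.axis):
        raise ParameterError("calibration and validation sets must share the axis")
    A = config.n_factors
    spacing = cal.spacing
    try:
        Xc = apply_pipeline(cal.X, config.pretreatment, spacing)
        Xv = apply_pipeline(val.X, config.pretreatment, spacing)
        n_cal, p = Xc.shape
        if A > min(n_cal - 1, p):
            raise ParameterError(
                f"{A} factors infeasible for n_cal={n_cal}, p={p}"
            )
        if config.varsel == "VIP":
            full_model = fit_pls(Xc, cal.y, A)
            selected = vip_select(full_model, vip_threshold).selected
            Xc, Xv = Xc[:, selected], Xv[:, selected]
        else:
            selected = np.arange(p)
        a_eff = min(A, n_cal - 1, len(selected))
        model = fit_pls(Xc, cal.y, a_eff, variable_subset=selected)
        metrics = evaluate_model(cal.y, predict(model, Xc), val.y, predict(model, Xv))
        k = min(cv_folds, n_cal)
        a_cv = min(a_eff, max_cv_factors(n_cal, Xc.shape[1], k))
        # a fold-training set can be lower-rank than the full set; the path
        # itself is still valid, the curve just stops earlier
        curve = _cv_curve(Xc, cal.y, a_cv, k) if a_cv >= 1 else None
        rmsecv = float(curve[-1]) if curve is not None else None
        return TrajectoryRecord(config, len(selected), a_eff, metrics, rmsecv)
    except PlstrajError as exc:
        return TrajectoryRecord(config, 0, 0, None, None, status=str(exc))


def _rank_key(rec: TrajectoryRecord, grid_order: dict[int, tuple[int, int]]):
    pre_idx, var_idx = grid_order[id(rec)]
    return (-rec.metrics.rpd, rec.metrics.rmsep, rec.config.n_factors, pre_idx, var_idx)


def run_trajectory(
    cal: SpectraDataset,
    val: SpectraDataset,
    pretreatments: list[PretreatmentSpec],
    A_max: int = 10,
    varsel_modes: list[str] = list(VARSEL_MODES),
    vip_threshold: float = 1.0,
    cv_folds: int = 10,
) -> TrajectoryResult:
    """Evaluate every path of the grid and select the best by RPD.

    Ties break toward smaller RMSEP, then fewer factors, then the earlier
    pretreatment in menu order, then full variables before VIP, so the
    result is deterministic end-to-end.
    """
    configs = enumerate_grid(pretreatments, A_max, varsel_modes)
    records: list[TrajectoryRecord] = []
    grid_order: dict[int, tuple[int, int]] = {}
    for cfg in configs:
        rec = evaluate_path(cfg, cal, val, vip_threshold, cv_folds)
        grid_order[id(rec)] = (
            pretreatments.index(cfg.pretreatment),
            varsel_modes.index(cfg.varsel),
        )
        records.append(rec)
    ok = [r for r in records if r.ok]
    if not ok:
        raise TrajectoryError("every path in the trajectory grid failed")
    best = min(ok, key=lambda r: _rank_key(r, grid_order))
    return TrajectoryResult(records, best)


def stepwise_optimize(
    cal: SpectraDataset,
    val: SpectraDataset,
    pretreatments: list[PretreatmentSpec],
    A_max: int = 10,
    vip_threshold: float = 1.0,
    cv_folds: int = 10,
) -> TrajectoryRecord:
    """The conventional one-parameter-at-a-time comparator.

    (1) choose the pretreatment whose best full-variable RMSECV over
    1..A_max is smallest; (2) at that pretreatment choose the factor count
    minimizing RMSECV; (3) apply VIP selection at that factor count and
    keep it only if it improves RMSEP.  The returned record is one member
    of the full trajectory grid.
    """
    if not pretreatments:
        raise ParameterError("pretreatment menu must be non-empty")
    spacing = cal.spacing
    n = cal.n
    k = min(cv_folds, n)
    best_pre: PretreatmentSpec | None = None
    best_cv = inf
    best_a = None
    for pre in pretreatments:
        Xp = apply_pipeline(cal.X, pre, spacing)
        a_hi = min(A_max, max_cv_factors(n, Xp.shape[1], k))
        if a_hi < 1:
            continue
        curve = _cv_curve(Xp, cal.y, a_hi, k)
        if curve is None:
            continue
        a_star = int(np.argmin(curve)) + 1  # ties -> fewer factors
        if curve[a_star - 1] < best_cv:
            best_cv = float(curve[a_star - 1])
            best_pre, best_a = pre, a_star
    if best_pre is None:
        raise TrajectoryError("no pretreatment admits a cross-validated fit")
    rec_full = evaluate_path(
        PathConfig(best_pre, best_a, "full"), cal, val, vip_threshold, cv_folds
    )
    rec_vip = evaluate_path(
        PathConfig(best_pre, best_a, "VIP"), cal, val, vip_threshold, cv_folds
    )
    if rec_vip.ok and (not rec_full.ok or rec_vip.metrics.rmsep < rec_full.metrics.rmsep):
        return rec_vip
    return rec_full


REPORT_COLUMNS = (
    "pretreatment,n_factors,varsel,n_selected,a_effective,"
    "RMSEC,R2cal,RMSECV,RMSEP,R2pre,RPD,category,status"
)


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:.6g}"


def write_report(result: TrajectoryResult, path) -> str:
    """Write the trajectory as a CSV table plus a best-path summary line.

    One data row per record; failed records carry their status message and
    empty metric cells.  The summary is a trailing ``#`` comment so the
    table re-parses cleanly with any CSV reader that honors comments.
    """
    buf = io.StringIO()
    buf.write(REPORT_COLUMNS + "\n")
    for rec in result.records:
        m = rec.metrics
        cells = [
            rec.config.pretreatment.label,
            str(rec.config.n_factors),
            rec.config.varsel,
            str(rec.n_selected_variables) if rec.ok else "",
            str(rec.a_effective) if rec.ok else "",
            _fmt(m.rmsec) if m else "",
            _fmt(m.r2_cal) if m else "",
            _fmt(rec.rmsecv),
            _fmt(m.rmsep) if m else "",
            _fmt(m.r2_pre) if m else "",
            _fmt(m.rpd) if m else "",
            m.category if m else "",
            rec.status.replace(",", ";"),
        ]
        buf.write(",".join(cells) + "\n")
    b = result.best
    buf.write(
        f"# best: pretreatment={b.config.pretreatment.label} "
        f"n_factors={b.config.n_factors} varsel={b.config.varsel} "
        f"n_selected={b.n_selected_variables} RPD={_fmt(b.metrics.rpd)} "
        f"RMSEP={_fmt(b.metrics.rmsep)} R2pre={_fmt(b.metrics.r2_pre)} "
        f"({result.criterion})\n"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    return str(path)
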