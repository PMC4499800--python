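"""Kennard-Stone sample selection and the calibration/validation split.

The Kennard-Stone (K-S) algorithm picks calibration samples by a maximin
rule on Euclidean distance in spectral space: start from the two most
distant samples, then repeatedly add the sample whose nearest already-
selected neighbor is farthest.  The result spreads calibration samples over
the experimental domain and is fully deterministic, so a dataset always
splits the same way.

Distances are computed on the raw (unpretreated, uncentered) spectra: the
split happens once per dataset, before any pretreatment is chosen, so it
cannot depend on a per-path pretreatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataio import SpectraDataset
from .errors import ParameterError


@dataclass(frozen=True)
class KSSplit:
    """A Kennard-Stone calibration/validation partition.

    ``calibration_indices`` are in selection order (the order matters for
    venetian-blind cross-validation folds); ``validation_indices`` keep the
    original dataset order.
    """

    calibration_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    n_total: int

    @property
    def n_cal(self) -> int:
        return len(self.calibration_indices)

    @property
    def n_val(self) -> int:
        return len(self.validation_indices)


def kennard_stone(X: np.ndarray, n_select: int) -> list[int]:
    """Select ``n_select`` rows of ``X`` by the Kennard-Stone maximin rule.

    Returns indices in selection order.  The first two are a maximally
    distant pair; ties anywhere are broken toward the lowest original index,
    making the selection deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ParameterError(f"Kennard-Stone needs at least 2 samples, got {n}")
    if not 2 <= n_select <= n:
        raise ParameterError(f"n_select must be in [2, {n}], got {n_select}")

    D = squareform(pdist(X, metric="euclidean"))
    # argmax scans row-major: first occurrence is the lexicographically
    # smallest (i, j) among tied maximal pairs
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    # distance from every sample to its nearest selected sample
    min_dist = np.minimum(D[:, selected[0]], D[:, selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # ties -> lowest index
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[:, nxt])
        min_dist[nxt] = -np.inf
    return selected


def split_dataset(ds: SpectraDataset, cal_fraction: float = 2 / 3) -> KSSplit:
    """Split a dataset 2:1 (by default) into calibration and validation sets.

    ``n_cal = round(cal_fraction * n)`` with half-away-from-zero rounding
    (so n=80 at 2:1 gives 53/27 and n=72 gives 48/24); the calibration set
    is the Kennard-Stone selection on the raw spectra and the remainder is
    validation.
    """
    n = ds.n
    if n < 3:
        raise ParameterError(f"need at least 3 samples to split, got {n}")
    if not 0 < cal_fraction < 1:
        raise ParameterError(f"cal_fraction must be in (0, 1), got {cal_fraction}")
    n_cal = int(np.floor(cal_fraction * n + 0.5))
    if n_cal < 2 or n - n_cal < 1:
        raise ParameterError(
            f"cal_fraction {cal_fraction} on n={n} leaves an unusable split"
        )
    cal = kennard_stone(ds.X, n_cal)
    in_cal = np.zeros(n, dtype=bool)
    in_cal[cal] = True
    val = [int(i) for i in np.flatnonzero(~in_cal)]
    return KSSplit(tuple(cal), tuple(val), n)


def write_split(split: KSSplit, path) -> str:
    """Write a split report: sizes, then both index lists (one per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"n_total {split.n_total}\n")
        fh.write(f"n_cal {split.n_cal}\n")
        fh.write(f"n_val {split.n_val}\n")
        fh.write("calibration " + " ".join(map(str, split.calibration_indices)) + "\n")
        fh.write("validation " + " ".join(map(str, split.validation_indices)) + "\n")
    return str(path)


def read_split(path) -> KSSplit:
    """Read a split report written by :func:`write_split`."""
    fields: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                fields[parts[0]] = parts[1:]
    try:
        cal = tuple(int(i) for i in fields["calibration"])
        val = tuple(int(i) for i in fields["validation"])
        n_total = int(fields["n_total"][0])
    except (KeyError, IndexError, ValueError) as exc:
        raise ParameterError(f"{path}: malformed split file ({exc})") from exc
    if sorted(cal + val) != list(range(n_total)):
        raise ParameterError(f"{path}: split indices do not partition 0..{n_total - 1}")
    return KSSplit(cal, val, n_total)
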