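"""Compositional algebra for three-part physical-behaviour time use.

A workday is partitioned into sedentary behaviour (SB), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA).  The three
durations carry only relative information, so they are analysed as a
composition: closed to unit sum and mapped to isometric log-ratio (ilr)
coordinates built from the sequential binary partition

    SB | {LPA, MVPA}   then   LPA | MVPA,

giving

    ilr1 = sqrt(2/3) * ln( SB / sqrt(LPA * MVPA) )
    ilr2 = sqrt(1/2) * ln( LPA / MVPA ).

ilr1 is the trade-off of sedentary time against the geometric average of the
two active behaviours; ilr2 contrasts light against moderate-to-vigorous
activity.  Pivot coordinate systems rotate each behaviour into the first
position so that its first coordinate contrasts that behaviour against the
geometric mean of the remaining two; the rotation is an isometry, so norms
and distances are preserved.

All functions accept array-likes of shape (3,) or (n, 3) and are pure
NumPy; nothing here knows about the hierarchy or the models.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

#: Canonical part order used throughout the package.
PARTS: tuple[str, str, str] = ("sb", "lpa", "mvpa")

#: Number of parts in the behaviour composition.
D: int = 3

# Orthonormal ilr contrast matrix (rows are clr coefficients of the basis).
# Row 1: SB against geometric mean of {LPA, MVPA}; row 2: LPA against MVPA.
PSI: np.ndarray = np.array(
    [
        [math.sqrt(2.0 / 3.0), -math.sqrt(1.0 / 6.0), -math.sqrt(1.0 / 6.0)],
        [0.0, math.sqrt(0.5), -math.sqrt(0.5)],
    ]
)


class DegenerateCompositionError(ValueError):
    """Raised when an input cannot be interpreted as a positive composition."""


def _as_rows(x: Iterable[float] | np.ndarray) -> tuple[np.ndarray, bool]:
    """Coerce input to an (n, 3) float array; report whether it was 1-D."""
    arr = np.asarray(x, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != D:
        raise ValueError(f"expected {D} parts per composition, got shape {arr.shape}")
    return arr, squeeze


def close(raw: Iterable[float] | np.ndarray) -> np.ndarray:
    """Close raw durations (e.g. hours) to a unit-sum composition.

    Parameters
    ----------
    raw
        Nonnegative durations, shape ``(3,)`` or ``(n, 3)``.

    Returns
    -------
    Composition(s) proportional to the input, summing to 1.

    Raises
    ------
    DegenerateCompositionError
        If any row is all zero (no relative information), or any entry is
        negative or non-finite.
    """
    arr, squeeze = _as_rows(raw)
    if not np.all(np.isfinite(arr)):
        raise DegenerateCompositionError("non-finite duration in input")
    if np.any(arr < 0):
        raise DegenerateCompositionError("negative duration in input")
    totals = arr.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateCompositionError("all-zero duration vector has no composition")
    out = arr / totals[:, None]
    return out[0] if squeeze else out


def _require_positive(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise DegenerateCompositionError(f"non-finite value in {what}")
    if np.any(arr <= 0):
        raise DegenerateCompositionError(
            f"{what} must be strictly positive; replace zeros before transforming"
        )


def geometric_mean_composition(samples: Sequence[Iterable[float]] | np.ndarray) -> np.ndarray:
    """Part-wise geometric mean of compositions, re-closed to unit sum.

    This is the compositional centre: the closure of
    ``(prod_i x_i1, prod_i x_i2, prod_i x_i3) ** (1/n)``.  Inputs need not be
    closed themselves (closure is scale-invariant here), but every part must
    be strictly positive.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("geometric mean of an empty sample is undefined")
    _require_positive(arr, "compositions")
    gm = np.exp(np.mean(np.log(arr), axis=0))
    return close(gm)


def ilr_transform(x: Iterable[float] | np.ndarray) -> np.ndarray:
    """Map strictly positive composition(s) to (ilr1, ilr2).

    Scale-invariant: closing the input first does not change the output.
    """
    arr, squeeze = _as_rows(x)
    _require_positive(arr, "composition")
    z = np.log(arr) @ PSI.T
    return z[0] if squeeze else z


def inverse_ilr(z: Iterable[float] | np.ndarray) -> np.ndarray:
    """Map (ilr1, ilr2) coordinates back to a closed three-part composition."""
    arr = np.asarray(z, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != D - 1:
        raise ValueError(f"expected {D - 1} ilr coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite ilr coordinate")
    comp = close(np.exp(arr @ PSI))
    return comp if not squeeze else np.atleast_2d(comp)[0]


def pivot_rotate(x: Iterable[float] | np.ndarray, pivot_part: str) -> np.ndarray:
    """Pivot ilr coordinates with ``pivot_part`` rotated into first position.

    The first coordinate is ``sqrt(2/3) * ln(pivot / sqrt(other1 * other2))``;
    the second contrasts the remaining two parts in canonical order.  The
    rotation is an isometry of the basic ilr basis: the squared norm of the
    coordinate pair does not depend on the pivot choice.
    """
    if pivot_part not in PARTS:
        raise ValueError(f"unknown pivot part {pivot_part!r}; expected one of {PARTS}")
    arr, squeeze = _as_rows(x)
    _require_positive(arr, "composition")
    order = [PARTS.index(pivot_part)] + [i for i in range(D) if PARTS[i] != pivot_part]
    z = np.log(arr[:, order]) @ PSI.T
    return z[0] if squeeze else z


def percent_change(beta: float, n_parts: int = D) -> float:
    """Translate a first-pivot-coordinate regression slope into a % change.

    A one-unit determinant increase shifts the first pivot coordinate by
    ``beta``, i.e. multiplies the ratio of the pivot part to the geometric
    mean of the remaining parts by ``exp(beta * sqrt(D/(D-1)))``.  Returned
    as a percentage: ``100 * (exp(beta * sqrt(D/(D-1))) - 1)``.
    """
    if n_parts < 2:
        raise ValueError("a composition needs at least 2 parts")
    if not math.isfinite(beta):
        raise ValueError("coefficient must be finite")
    return 100.0 * math.expm1(beta * math.sqrt(n_parts / (n_parts - 1.0)))


def aitchison_distance(x: Iterable[float], y: Iterable[float]) -> float:
    """Aitchison distance between two compositions.

    Equals the Euclidean distance between their ilr coordinates (isometry).
    Computed here from the clr representation so it can serve as an
    independent check of that identity.
    """
    cx = np.log(close(x))
    cy = np.log(close(y))
    cx = cx - cx.mean()
    cy = cy - cy.mean()
    return float(np.linalg.norm(cx - cy))
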