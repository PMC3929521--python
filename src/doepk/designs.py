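"""Experimental designs for chromatographic method screening and optimization.

Two design families are provided: Taguchi orthogonal arrays (L4/L8/L9) for
factor screening via main effects, and the face-centred central composite
design (FCCD) used to fit second-order response-surface models.  Designs are
held as pandas DataFrames with ``exp_no``, ``run_order``, one coded-level
column per factor symbol, and a ``point_type`` label
(``factorial``/``axial``/``centre``).

Factor levels are coded to -1/0/+1 over the studied range.  Because real
method-development ranges are not always symmetric around the centre point
(e.g. a pH factor studied at 2.5/3.5/4.0), the coded<->actual mapping is
piecewise linear on [low, centre] and [centre, high] rather than a single
affine map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "FactorDefinition",
    "InvalidDesignError",
    "generate_fccd",
    "generate_taguchi_oa",
    "coded_to_actual",
    "actual_to_coded",
    "main_effects",
]


class InvalidDesignError(ValueError):
    """Raised when a requested design cannot be constructed or analysed."""


@dataclass(frozen=True)
class FactorDefinition:
    """A controllable factor with its low/centre/high actual levels.

    Parameters
    ----------
    name : str
        Human-readable factor name, e.g. ``"Methanol concentration"``.
    symbol : str
        Single-letter column label used in design tables (``"A"``, ``"B"``).
    low, centre, high : float
        Actual levels mapped to coded -1, 0 and +1.  Must be strictly
        increasing; they need not be equidistant.
    units : str
        Unit text, e.g. ``"% v/v"`` or ``"pH units"``.
    """

    name: str
    symbol: str
    low: float
    centre: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.centre < self.high):
            raise InvalidDesignError(
                f"factor {self.name!r}: require low < centre < high, "
                f"got {self.low}, {self.centre}, {self.high}"
            )


def coded_to_actual(factor: FactorDefinition, coded: float) -> float:
    """Map a coded level in [-1, +1] to the factor's actual units.

    Piecewise linear: [-1, 0] interpolates low..centre and [0, +1]
    interpolates centre..high, so asymmetric level triples (pH 2.5/3.5/4.0)
    round-trip exactly at the grid points.
    """
    coded = float(coded)
    if not -1.0 - 1e-12 <= coded <= 1.0 + 1e-12:
        raise ValueError(f"coded level {coded} outside [-1, +1]")
    coded = min(max(coded, -1.0), 1.0)
    if coded <= 0:
        return factor.centre + coded * (factor.centre - factor.low)
    return factor.centre + coded * (factor.high - factor.centre)


def actual_to_coded(factor: FactorDefinition, actual: float) -> float:
    """Inverse of :func:`coded_to_actual` on [low, high]."""
    actual = float(actual)
    if not factor.low - 1e-9 <= actual <= factor.high + 1e-9:
        raise ValueError(
            f"actual level {actual} outside [{factor.low}, {factor.high}] "
            f"for factor {factor.name!r}"
        )
    if actual <= factor.centre:
        return (actual - factor.centre) / (factor.centre - factor.low)
    return (actual - factor.centre) / (factor.high - factor.centre)


def generate_fccd(
    factors: list[FactorDefinition],
    n_centre: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a face-centred central composite design.

    The design has ``2**k`` factorial points (all coded levels +-1), ``2*k``
    axial points on the face centres (one factor at +-1, the rest at 0) and
    ``n_centre`` centre replicates, i.e. ``2**k + 2k + n_centre`` runs in
    total (13 for two factors with five centre replicates).  Centre
    replicates supply the pure-error estimate for the lack-of-fit test.

    Parameters
    ----------
    factors : list of FactorDefinition
        At least two factors.
    n_centre : int
        Number of centre-point replicates (>= 1).
    seed : int, optional
        Seed for the run-order randomization.  ``exp_no`` preserves standard
        order; ``run_order`` is the randomized execution order.

    Returns
    -------
    pandas.DataFrame
        Columns ``exp_no``, ``run_order``, one column per factor symbol
        (coded levels), ``point_type``.
    """
    k = len(factors)
    if k < 2:
        raise InvalidDesignError("a central composite design needs >= 2 factors")
    if n_centre < 1:
        raise InvalidDesignError("n_centre must be >= 1")
    symbols = [f.symbol for f in factors]
    if len(set(symbols)) != k:
        raise InvalidDesignError("factor symbols must be unique")

    rows: list[list[float]] = []
    types: list[str] = []
    for combo in product((-1.0, 1.0), repeat=k):
        rows.append(list(combo))
        types.append("factorial")
    for i in range(k):
        for level in (-1.0, 1.0):
            pt = [0.0] * k
            pt[i] = level
            rows.append(pt)
            types.append("axial")
    for _ in range(n_centre):
        rows.append([0.0] * k)
        types.append("centre")

    n = len(rows)
    rng = np.random.default_rng(seed)
    run_order = rng.permutation(n) + 1

    table = pd.DataFrame(rows, columns=symbols)
    table.insert(0, "exp_no", np.arange(1, n + 1))
    table.insert(1, "run_order", run_order)
    table["point_type"] = types
    return table


# Standard published Taguchi arrays, levels coded 1..n_levels.
_L4 = np.array(
    [[1, 1, 1],
     [1, 2, 2],
     [2, 1, 2],
     [2, 2, 1]]
)
_L8 = np.array(
    [[1, 1, 1, 1, 1, 1, 1],
     [1, 1, 1, 2, 2, 2, 2],
     [1, 2, 2, 1, 1, 2, 2],
     [1, 2, 2, 2, 2, 1, 1],
     [2, 1, 2, 1, 2, 1, 2],
     [2, 1, 2, 2, 1, 2, 1],
     [2, 2, 1, 1, 2, 2, 1],
     [2, 2, 1, 2, 1, 1, 2]]
)
_L9 = np.array(
    [[1, 1, 1, 1],
     [1, 2, 2, 2],
     [1, 3, 3, 3],
     [2, 1, 2, 3],
     [2, 2, 3, 1],
     [2, 3, 1, 2],
     [3, 1, 3, 2],
     [3, 2, 1, 3],
     [3, 3, 2, 1]]
)


def generate_taguchi_oa(n_factors: int, n_levels: int) -> pd.DataFrame:
    """Return the smallest standard Taguchi orthogonal array covering the request.

    Supported: L4 (up to 3 two-level factors), L8 (up to 7 two-level),
    L9 (up to 4 three-level).  Every pair of columns of the returned array
    contains each level combination equally often.

    Levels are coded 1..n_levels; columns are named F1..Fn.
    """
    if n_levels == 2 and 1 <= n_factors <= 3:
        arr = _L4
    elif n_levels == 2 and n_factors <= 7:
        arr = _L8
    elif n_levels == 3 and 1 <= n_factors <= 4:
        arr = _L9
    else:
        raise InvalidDesignError(
            f"no supported orthogonal array for {n_factors} factors "
            f"at {n_levels} levels (supported: L4, L8, L9)"
        )
    arr = arr[:, :n_factors]
    table = pd.DataFrame(arr, columns=[f"F{i + 1}" for i in range(n_factors)])
    table.insert(0, "exp_no", np.arange(1, len(arr) + 1))
    table.insert(1, "run_order", np.arange(1, len(arr) + 1))
    table["point_type"] = "screening"
    return table


def main_effects(design: pd.DataFrame, response: pd.Series | np.ndarray) -> pd.Series:
    """Per-factor main effects from a screening design.

    The effect of a factor is the mean response at its highest level minus
    the mean at its lowest level; the sign gives the direction of influence.
    Effects are invariant to run order because only group means enter.

    Parameters
    ----------
    design : DataFrame
        Design table whose factor columns are every column other than
        ``exp_no``, ``run_order`` and ``point_type``.
    response : array-like
        One measured response per design row.

    Returns
    -------
    pandas.Series
        Effect estimate per factor column.
    """
    y = np.asarray(response, dtype=float)
    factor_cols = [
        c for c in design.columns if c not in ("exp_no", "run_order", "point_type")
    ]
    if len(y) != len(design):
        raise ValueError("response length must match design rows")
    effects = {}
    for col in factor_cols:
        levels = design[col].to_numpy(dtype=float)
        lo, hi = levels.min(), levels.max()
        at_lo, at_hi = y[levels == lo], y[levels == hi]
        if lo == hi or at_lo.size == 0 or at_hi.size == 0:
            raise InvalidDesignError(
                f"factor {col!r} lacks runs at two distinct levels"
            )
        effects[col] = at_hi.mean() - at_lo.mean()
    return pd.Series(effects, name="main_effect")
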