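"""Interpolation of nanodosimetric quantities across energy and ion species.

Quantities (M1, Fk, R2) are tabulated on a log-spaced energy grid per ion
and target geometry.  Queries at experimental energies use a *local*
three-point Lagrange quadratic in log10(E): the nearest bracketing triple
of grid nodes is selected, so grid values are reproduced exactly and the
wide 0.2-1000 MeV/u range cannot drive global-polynomial oscillation.

Species not simulated directly (e.g. neon) are filled in by a least-squares
quadratic in atomic number Z across donor ions evaluated at fixed energy
per nucleon.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["lagrange_quadratic", "interpolate_quantity", "interpolate_missing_ion"]


def _pick_triple(x: np.ndarray, xq: float) -> slice:
    """Indices of the three consecutive nodes closest to the query point."""
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 grid points for quadratic interpolation")
    # triple (j-1, j, j+1) with xq in [x[j-1], x[j]], clipped to the grid
    j = int(np.searchsorted(x, xq))
    lo = min(max(j - 1, 0), n - 3)
    return slice(lo, lo + 3)


def lagrange_quadratic(
    x: np.ndarray, y: np.ndarray, xq: float
) -> float | np.ndarray:
    """Quadratic through three points, evaluated at xq; exact at the nodes."""
    x0, x1, x2 = x
    l0 = (xq - x1) * (xq - x2) / ((x0 - x1) * (x0 - x2))
    l1 = (xq - x0) * (xq - x2) / ((x1 - x0) * (x1 - x2))
    l2 = (xq - x0) * (xq - x1) / ((x2 - x0) * (x2 - x1))
    return l0 * y[0] + l1 * y[1] + l2 * y[2]


def interpolate_quantity(
    energies_MeV_per_u: Sequence[float],
    values: Sequence[float] | np.ndarray,
    energy: float,
) -> float | np.ndarray:
    """Interpolate a tabulated quantity to ``energy`` (MeV/u).

    ``values`` may be one value per grid energy, or a 2-D array with one
    row per grid energy (all columns are interpolated with the same
    Lagrange weights).  Queries outside the grid span are refused: the
    grids are wide by construction and extrapolating nanodosimetric
    quantities is never safe.
    """
    e = np.asarray(energies_MeV_per_u, dtype=float)
    v = np.asarray(values, dtype=float)
    if e.ndim != 1 or np.any(np.diff(e) <= 0):
        raise ValueError("energies must be strictly increasing")
    if v.shape[0] != e.size:
        raise ValueError("values and energies have mismatched lengths")
    if not e[0] <= energy <= e[-1]:
        raise ValueError(
            f"extrapolation refused: energy {energy} outside grid span "
            f"[{e[0]}, {e[-1]}] MeV/u"
        )
    x = np.log10(e)
    sl = _pick_triple(x, math.log10(energy))
    out = lagrange_quadratic(x[sl], v[sl], math.log10(energy))
    return out


def interpolate_missing_ion(
    donor_Z: Sequence[int],
    donor_values: Sequence[float],
    target_Z: int,
) -> float:
    """Least-squares quadratic in Z through donor-ion values at fixed E/u.

    Used for species the track-structure grids do not cover directly: the
    quantity is fitted as a second-order polynomial of atomic number over
    at least three donor ions and evaluated at the target Z, which must lie
    within the donor range.
    """
    z = np.asarray(donor_Z, dtype=float)
    v = np.asarray(donor_values, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 donor ions for the quadratic in Z")
    if not z.min() <= target_Z <= z.max():
        raise ValueError(
            f"target Z={target_Z} outside donor range [{z.min():g}, {z.max():g}]"
        )
    coeffs = np.polynomial.polynomial.polyfit(z, v, deg=2)
    return float(np.polynomial.polynomial.polyval(float(target_Z), coeffs))
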