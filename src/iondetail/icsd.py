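"""Ionization cluster size distributions and nanodosimetric statistics.

The central object is the ICSD: the discrete probability distribution
``P_nu`` of the number of ionizations ``nu`` (the *cluster size*) produced
in a nanometric target by a single primary-particle traversal.  All
nanodosimetric radiation-quality descriptors used in this package are
functionals of the ICSD:

* ``M1``     -- mean cluster size, the first moment of the distribution
  (nu = 0 events, traversals without any ionization, are included);
* ``Fk``     -- cumulative probability of a cluster of size >= k;
* ``R2(p)``  -- probability that at least two sub-lethal lesions are
  produced when each ionization independently converts into a lesion with
  probability ``p``.  This weights ``P_nu`` by the binomial survival
  function and reduces exactly to ``F2`` at p = 1;
* binomial thinning -- the ICSD seen by a detector with ion-counting
  efficiency ``eta``, which makes ``F2`` of the thinned spectrum equal to
  ``R2(eta)`` of the true one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ICSD",
    "TargetGeometry",
    "RadiationQuality",
    "normalize_icsd",
    "m1",
    "fk",
    "r2_weight",
    "r2",
    "thin",
    "weighting_profile",
]

#: construction tolerance: probabilities must close to 1 within this
SUM_TOL = 1e-9
#: inputs off by less than this are silently renormalized; beyond it -> error
RENORM_TOL = 1e-6


@dataclass(frozen=True)
class TargetGeometry:
    """Cylindrical sensitive volume, dimensions in nanometers."""

    diameter_nm: float
    height_nm: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.height_nm <= 0:
            raise ValueError("target diameter and height must be positive")

    @property
    def label(self) -> str:
        """Conventional 'd x h nm^2 (diameter x height)' label."""
        return f"{self.diameter_nm:g} x {self.height_nm:g} nm^2 (diameter x height)"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class RadiationQuality:
    """Particle identity and radiation quality (energy per nucleon, LET)."""

    symbol: str
    Z: int
    A: int
    energy_MeV_per_u: float
    let_keV_per_um: float

    def __post_init__(self) -> None:
        if self.Z <= 0 or self.A <= 0 or self.Z > self.A:
            raise ValueError(f"invalid (Z, A) = ({self.Z}, {self.A})")
        if self.energy_MeV_per_u <= 0:
            raise ValueError("energy must be strictly positive")
        if self.let_keV_per_um <= 0:
            raise ValueError("LET must be strictly positive")


@dataclass(frozen=True)
class ICSD:
    """A discrete cluster-size distribution P_nu, nu = 0 .. nu_max.

    Stored dense from nu = 0; the tail beyond ``nu_max`` is identically
    zero by construction (no extrapolation is ever performed).  Entries
    must be non-negative and close to 1 within ``SUM_TOL``; sums off by up
    to ``RENORM_TOL`` are renormalized, anything worse is rejected.
    """

    probs: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probs must be a non-empty 1-D sequence")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and non-negative")
        total = p.sum()
        if abs(total - 1.0) > RENORM_TOL:
            raise ValueError(
                f"probabilities sum to {total!r}, beyond renormalization tolerance"
            )
        if abs(total - 1.0) > SUM_TOL:
            p = p / total
        object.__setattr__(self, "probs", p)
        self.probs.flags.writeable = False

    @property
    def nu_max(self) -> int:
        return self.probs.size - 1

    @property
    def nu(self) -> np.ndarray:
        """Cluster-size support 0 .. nu_max."""
        return np.arange(self.probs.size)

    def __len__(self) -> int:
        return self.probs.size

    def with_meta(self, **meta: object) -> "ICSD":
        merged = {**dict(self.meta), **meta}
        return ICSD(self.probs, meta=merged)


def normalize_icsd(
    raw_counts: Sequence[float], meta: Mapping[str, object] | None = None
) -> ICSD:
    """Build an ICSD from raw (measured or simulated) per-cluster-size counts."""
    c = np.asarray(raw_counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(c < 0):
        raise ValueError("negative count in spectrum")
    total = c.sum()
    if total == 0:
        raise ValueError("empty spectrum: all counts are zero")
    return ICSD(c / total, meta=dict(meta or {}))


def m1(icsd: ICSD) -> float:
    """Mean cluster size: the first moment of the ICSD, nu = 0 included."""
    return float(np.dot(icsd.nu, icsd.probs))


def fk(icsd: ICSD, k: int) -> float:
    """Cumulative probability of producing a cluster of size >= k."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return 1.0
    if k > icsd.nu_max:
        return 0.0
    return float(icsd.probs[k:].sum())


def r2_weight(nu: int | np.ndarray, p: float) -> float | np.ndarray:
    """Probability that >= 2 of ``nu`` ionizations each convert to a lesion.

    Closed form of the binomial tail: ``1 - (1-p)^nu - nu p (1-p)^(nu-1)``.
    Evaluated through log1p/expm1 so that both the small-p regime (where
    the weight is ~ C(nu,2) p^2) and the p -> 1 regime are free of
    catastrophic cancellation.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    nu_arr = np.asarray(nu)
    if np.any(nu_arr < 0):
        raise ValueError("cluster size must be >= 0")
    scalar = nu_arr.ndim == 0
    n = np.atleast_1d(nu_arr).astype(float)

    if p == 1.0:
        w = (n >= 2).astype(float)
    else:
        # log(1-p) once; (1-p)^nu = exp(nu*log1p(-p)) stays accurate near p=1
        lq = math.log1p(-p)
        one_hit = n * p * np.exp((n - 1.0) * lq)       # nu p (1-p)^(nu-1)
        w = -np.expm1(n * lq) - one_hit                # 1 - (1-p)^nu - ...
        w[n < 2] = 0.0
        np.clip(w, 0.0, 1.0, out=w)
    return float(w[0]) if scalar else w


def r2(icsd: ICSD, p: float) -> float:
    """Binomially weighted damage probability R2(p) = sum_nu P_nu w(nu, p)."""
    w = r2_weight(icsd.nu, p)
    return float(np.dot(icsd.probs, w))


def thin(icsd: ICSD, eta: float) -> ICSD:
    """Binomial thinning: the ICSD registered at ion-counting efficiency eta.

    ``Q_m = sum_{nu>=m} P_nu C(nu, m) eta^m (1-eta)^(nu-m)``.  The mean
    scales as ``eta * M1`` and ``F2`` of the thinned spectrum equals
    ``R2(eta)`` of the original one — the measurement equivalence that lets
    a nanodosimeter with efficiency eta report R2 directly.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    if eta == 1.0:
        return icsd
    n = icsd.probs.size
    m_grid = np.arange(n)[:, None]   # registered count m
    nu_grid = np.arange(n)[None, :]  # true count nu
    kernel = _stats.binom.pmf(m_grid, nu_grid, eta)  # zero where m > nu
    q = kernel @ icsd.probs
    q = np.clip(q, 0.0, None)
    q /= q.sum()
    meta = {**dict(icsd.meta), "thinned_eta": eta}
    return ICSD(q, meta=meta)


def weighting_profile(kind: str, param: float, nu_max: int = 100) -> np.ndarray:
    """Cluster-size weighting function, as an array over nu = 0 .. nu_max.

    ``step_k``: the all-or-nothing weighting behind Fk — weight 0 below k,
    1 at and above k.  ``binomial_p``: the graded weighting behind R2(p).
    Both vanish at nu in {0, 1}: fewer than two ionizations cannot produce
    the two close-range lesions that constitute severe (DSB-like) damage.
    """
    nu = np.arange(nu_max + 1)
    if kind == "step_k":
        k = int(param)
        if k != param or k < 2:
            raise ValueError("step weighting requires an integer k >= 2")
        return (nu >= k).astype(float)
    if kind == "binomial_p":
        return np.asarray(r2_weight(nu, float(param)), dtype=float)
    raise ValueError(f"unknown weighting kind {kind!r}")
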