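"""Synthetic nanodosimetric and radiobiological data with known ground truth.

Full-physics track-structure transport and curated survival databases are
both outside this package; this module provides their statistical
stand-ins so that the whole pipeline is testable end to end:

* a toy **track-segment Monte Carlo**: primaries deposit ionization
  clusters along the cylinder axis as a 1-D Poisson process; each primary
  interaction spawns ``1 + Geometric`` ionizations (overdispersion), each
  displaced laterally by a 2-D Gaussian and counted only if it stays
  inside the cylinder.  The resulting per-traversal count distribution is
  an overdispersed compound Poisson, qualitatively like measured ICSDs;
* the exact **analytic counterpart** of that model (Panjer recursion over
  the compound-Poisson pgf), used to build deterministic quantity grids
  and to validate the Monte Carlo;
* a **survival-record generator**: records are constructed so that the
  inactivation cross section equals ``K_true * R2(p_true; d_true)`` at
  each record's energy (times optional multiplicative lognormal noise)
  and then inverted through the LQ cross-section formula into (alpha,
  beta) at a fixed alpha/beta ratio — a closed loop with known truth for
  parameter-recovery studies.

No claim of physical fidelity to liquid-water cross sections is made; the
conversion from LET to interaction rate uses a nominal mean energy per
ionization (default 30 eV) as a bookkeeping convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _st

from .grids import DEFAULT_K_LIST, QuantityGrid
from .icsd import ICSD, RadiationQuality, TargetGeometry, normalize_icsd, r2_weight
from .io import parse_ion_symbol
from .lq import LQConstants, SurvivalRecord, ion_category

__all__ = [
    "W_EV_PER_IONIZATION",
    "TrackModelParams",
    "SyntheticStudySpec",
    "toy_let",
    "track_params_for",
    "simulate_icsd",
    "track_icsd_analytic",
    "parametric_icsd",
    "compound_poisson_pmf",
    "make_quantity_grid",
    "default_grid_set",
    "generate_survival_dataset",
]

#: nominal mean energy spent per ionization (eV); converts LET to a linear
#: ionization density (1 keV/um = 1 eV/nm, so LET/W is directly per nm)
W_EV_PER_IONIZATION = 30.0

#: ions available to the synthetic study
DEFAULT_IONS = ("1H", "4He", "12C", "20Ne")


def toy_let(Z: int, energy_MeV_per_u: float) -> float:
    """Schematic stopping power, keV/um: LET = 26 Z^2 E^-0.78 (E in MeV/u).

    Anchored to proton values in water (≈26, 4.3 and 0.72 keV/um at 1, 10
    and 100 MeV) with a Z^2 charge scaling at equal velocity; good enough
    to span the sparse-to-dense ionization regimes the study needs, not a
    stopping-power table.
    """
    if energy_MeV_per_u <= 0:
        raise ValueError("energy must be positive")
    return 26.0 * Z * Z * energy_MeV_per_u ** -0.78


@dataclass(frozen=True)
class TrackModelParams:
    """Parameters of the toy track-segment model.

    ``mean_ionizations_per_nm`` is the linear density of *primary*
    interaction sites along the trajectory; with each site spawning
    ``1 + Geometric(cluster_multiplicity_mean)`` ionizations the total
    ionization density is ``lambda * (1 + multiplicity)``.
    """

    mean_ionizations_per_nm: float
    cluster_multiplicity_mean: float = 1.5
    radial_sigma_nm: float = 1.0
    n_histories: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_ionizations_per_nm <= 0:
            raise ValueError("primary interaction density must be > 0")
        if self.cluster_multiplicity_mean < 0 or self.radial_sigma_nm < 0:
            raise ValueError("multiplicity mean and radial sigma must be >= 0")
        if self.n_histories < 1:
            raise ValueError("need at least one history")


def track_params_for(
    quality: RadiationQuality,
    cluster_multiplicity_mean: float = 1.5,
    radial_sigma_nm: float = 1.0,
    n_histories: int = 100_000,
    seed: int = 0,
    w_ev: float = W_EV_PER_IONIZATION,
) -> TrackModelParams:
    """Track parameters for a radiation quality: lambda from LET.

    The total ionization density is LET/W (1 keV/um = 1 eV/nm); dividing
    by the mean cluster multiplicity 1 + m gives the primary-site rate.
    """
    lam_total = quality.let_keV_per_um / w_ev
    lam = lam_total / (1.0 + cluster_multiplicity_mean)
    return TrackModelParams(
        mean_ionizations_per_nm=lam,
        cluster_multiplicity_mean=cluster_multiplicity_mean,
        radial_sigma_nm=radial_sigma_nm,
        n_histories=n_histories,
        seed=seed,
    )


def _keep_probability(geometry: TargetGeometry, radial_sigma_nm: float) -> float:
    """Chance a laterally displaced ionization stays inside the cylinder.

    Displacements are isotropic 2-D Gaussian, so the radial distance is
    Rayleigh and P(r <= R) = 1 - exp(-R^2 / (2 sigma^2)).
    """
    if radial_sigma_nm == 0.0:
        return 1.0
    radius = geometry.diameter_nm / 2.0
    return -math.expm1(-(radius * radius) / (2.0 * radial_sigma_nm ** 2))


def simulate_icsd(params: TrackModelParams, geometry: TargetGeometry) -> ICSD:
    """Monte-Carlo ICSD: one history = one axial traversal of the cylinder."""
    rng = np.random.default_rng(params.seed)
    mu_prim = params.mean_ionizations_per_nm * geometry.height_nm
    n_hist = params.n_histories
    n_prim = rng.poisson(mu_prim, size=n_hist)
    total_prim = int(n_prim.sum())
    if total_prim == 0:
        counts = np.array([n_hist], dtype=float)
        return normalize_icsd(
            counts, meta={"seed": params.seed, "n_histories": n_hist}
        )
    # ionizations per primary: 1 + Geometric(mean m) extras
    m = params.cluster_multiplicity_mean
    if m > 0:
        # geometric on {0,1,...} with mean m: success prob 1/(1+m)
        extras = rng.geometric(1.0 / (1.0 + m), size=total_prim) - 1
    else:
        extras = np.zeros(total_prim, dtype=int)
    n_ion = 1 + extras
    total_ion = int(n_ion.sum())
    # lateral escape: displace each ionization by an isotropic 2-D Gaussian
    if params.radial_sigma_nm > 0:
        dx = rng.normal(0.0, params.radial_sigma_nm, size=total_ion)
        dy = rng.normal(0.0, params.radial_sigma_nm, size=total_ion)
        inside = dx * dx + dy * dy <= (geometry.diameter_nm / 2.0) ** 2
    else:
        inside = np.ones(total_ion, dtype=bool)
    # map kept ionizations back to their history
    hist_of_prim = np.repeat(np.arange(n_hist), n_prim)
    hist_of_ion = np.repeat(hist_of_prim, n_ion)
    kept_per_hist = np.bincount(hist_of_ion[inside], minlength=n_hist)
    counts = np.bincount(kept_per_hist)
    return normalize_icsd(
        counts.astype(float),
        meta={
            "seed": params.seed,
            "n_histories": n_hist,
            "geometry": geometry.label,
            "mean_ionizations_per_nm": params.mean_ionizations_per_nm,
        },
    )


# ----------------------------------------------------------------------
# analytic distributions
# ----------------------------------------------------------------------
def compound_poisson_pmf(
    mu: float, severity: np.ndarray, nu_max: int
) -> np.ndarray:
    """pmf of a Poisson(mu) sum of iid severities, by Panjer recursion.

    ``severity`` is the pmf of one cluster's contribution on {0, 1, ...};
    the recursion g_n = (mu / n) * sum_j j f_j g_{n-j} is exact and stable
    (all terms non-negative).
    """
    f = np.asarray(severity, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("severity pmf must sum to 1")
    jmax = f.size - 1
    g = np.zeros(nu_max + 1)
    g[0] = math.exp(mu * (f[0] - 1.0))
    jf = np.arange(jmax + 1) * f  # j * f_j
    for n in range(1, nu_max + 1):
        j_hi = min(n, jmax)
        stop = n - j_hi - 1
        seg = g[n - 1 : (stop if stop >= 0 else None) : -1]
        g[n] = (mu / n) * float(jf[1 : j_hi + 1] @ seg)
    return g


def _severity_pmf(multiplicity_mean: float, keep_prob: float) -> np.ndarray:
    """pmf of kept ionizations from one primary: Binomial(1 + G, q) mixture."""
    m, q = multiplicity_mean, keep_prob
    if m == 0:
        c_max = 1
        c_pmf = np.array([0.0, 1.0])
    else:
        r = m / (1.0 + m)
        # truncate the geometric where its tail is negligible
        c_max = 1 + max(1, int(math.ceil(math.log(1e-15) / math.log(r))))
        j = np.arange(c_max)  # extras
        c_pmf = np.zeros(c_max + 1)
        c_pmf[1:] = (1.0 - r) * r ** j  # cluster size c = 1 + extras
        c_pmf[-1] += 1.0 - c_pmf.sum()  # fold residual tail mass
    sizes = np.arange(c_max + 1)
    kept = np.arange(c_max + 1)[:, None]
    mix = _st.binom.pmf(kept, sizes[None, :], q) @ c_pmf
    return np.clip(mix, 0.0, None) / mix.sum()


def _auto_nu_max(mean: float, var: float) -> int:
    return int(math.ceil(mean + 12.0 * math.sqrt(max(var, 1.0)) + 20.0))


def track_icsd_analytic(
    params: TrackModelParams, geometry: TargetGeometry, nu_max: int | None = None
) -> ICSD:
    """Exact ICSD of the toy track model (no Monte-Carlo noise).

    The per-traversal count is compound Poisson: Poisson(lambda h) primary
    sites, each contributing Binomial(1 + Geometric, q_keep) retained
    ionizations.
    """
    mu = params.mean_ionizations_per_nm * geometry.height_nm
    q = _keep_probability(geometry, params.radial_sigma_nm)
    sev = _severity_pmf(params.cluster_multiplicity_mean, q)
    j = np.arange(sev.size)
    sev_mean = float(j @ sev)
    sev_m2 = float((j * j) @ sev)
    mean = mu * sev_mean
    var = mu * sev_m2  # compound-Poisson variance = mu E[X^2]
    if nu_max is None:
        nu_max = _auto_nu_max(mean, var)
    pmf = compound_poisson_pmf(mu, sev, nu_max)
    tail = 1.0 - pmf.sum()
    if tail > 1e-9:
        raise ValueError(
            f"truncation at nu_max={nu_max} leaves {tail:.3g} probability mass"
        )
    pmf = np.clip(pmf, 0.0, None)
    return ICSD(
        pmf / pmf.sum(),
        meta={"family": "track_analytic", "mu_primaries": mu, "keep_prob": q},
    )


def parametric_icsd(family: str, params: dict, nu_max: int | None = None) -> ICSD:
    """Analytic ICSD families used as exact fixtures.

    ``poisson``: {"mu"}; ``compound_poisson``: {"mu", "multiplicity_mean",
    optional "keep_prob"}; ``point_mass``: {"nu"}.  Distributions are
    truncated at ``nu_max`` and renormalized; a truncation that removes
    more than 1e-9 of mass is rejected.
    """
    if family == "point_mass":
        nu = int(params["nu"])
        if nu < 0:
            raise ValueError("point mass requires nu >= 0")
        probs = np.zeros(nu + 1)
        probs[nu] = 1.0
        return ICSD(probs, meta={"family": "point_mass", "nu": nu})
    if family == "poisson":
        mu = float(params["mu"])
        if mu < 0:
            raise ValueError("poisson mu must be >= 0")
        if nu_max is None:
            nu_max = _auto_nu_max(mu, mu)
        pmf = _st.poisson.pmf(np.arange(nu_max + 1), mu)
    elif family == "compound_poisson":
        mu = float(params["mu"])
        mult = float(params["multiplicity_mean"])
        q = float(params.get("keep_prob", 1.0))
        sev = _severity_pmf(mult, q)
        j = np.arange(sev.size)
        mean = mu * float(j @ sev)
        var = mu * float((j * j) @ sev)
        if nu_max is None:
            nu_max = _auto_nu_max(mean, var)
        pmf = compound_poisson_pmf(mu, sev, nu_max)
    else:
        raise ValueError(f"unknown ICSD family {family!r}")
    tail = 1.0 - pmf.sum()
    if tail > 1e-9:
        raise ValueError(
            f"truncation at nu_max={nu_max} leaves {tail:.3g} probability mass"
        )
    pmf = np.clip(pmf, 0.0, None)
    return ICSD(pmf / pmf.sum(), meta={"family": family, **params})


# ----------------------------------------------------------------------
# quantity grids and the synthetic survival study
# ----------------------------------------------------------------------
def make_quantity_grid(
    ion_symbol: str,
    geometry: TargetGeometry,
    energies_MeV_per_u: Sequence[float] | None = None,
    p_grid: np.ndarray | None = None,
    cluster_multiplicity_mean: float = 1.5,
    radial_sigma_nm: float = 1.0,
) -> QuantityGrid:
    """Deterministic quantity grid from the analytic track model.

    Energies default to 40 points log-spaced over 0.2-1000 MeV/u, the
    conventional span for covering both the sparse and the overkill
    ionization regimes.
    """
    z, _a = parse_ion_symbol(ion_symbol)
    if energies_MeV_per_u is None:
        energies_MeV_per_u = np.geomspace(0.2, 1000.0, 40)
    energies = np.asarray(energies_MeV_per_u, dtype=float)
    lets = np.array([toy_let(z, e) for e in energies])
    icsds = []
    for e, let in zip(energies, lets):
        quality = RadiationQuality(ion_symbol, z, max(z, 1), e, let)
        params = track_params_for(
            quality,
            cluster_multiplicity_mean=cluster_multiplicity_mean,
            radial_sigma_nm=radial_sigma_nm,
        )
        icsds.append(track_icsd_analytic(params, geometry))
    return QuantityGrid.from_icsds(
        particle=ion_symbol,
        geometry=geometry,
        energies=energies,
        lets=lets,
        icsds=icsds,
        p_grid=p_grid,
        k_list=DEFAULT_K_LIST,
    )


def default_grid_set(
    diameters_nm: Sequence[float] = (1.0, 1.6, 2.3),
    height_over_diameter: float = 3.4 / 2.3,
    ions: Sequence[str] = DEFAULT_IONS,
    energies_MeV_per_u: Sequence[float] | None = None,
    p_grid: np.ndarray | None = None,
) -> dict[TargetGeometry, dict[str, QuantityGrid]]:
    """Grids for a scan over target sizes (height/diameter fixed at ~1.48)."""
    grids: dict[TargetGeometry, dict[str, QuantityGrid]] = {}
    for d in diameters_nm:
        geometry = TargetGeometry(d, round(d * height_over_diameter, 6))
        grids[geometry] = {
            ion: make_quantity_grid(
                ion, geometry, energies_MeV_per_u=energies_MeV_per_u, p_grid=p_grid
            )
            for ion in ions
        }
    return grids


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a synthetic survival study with known ground truth.

    Defaults mirror the study conditions this package targets: ~150
    survival curves, proportionality constant 57 um^2, lesion probability
    0.35, a 2.3 x 3.4 nm cylinder, V79-like alpha/beta = 5 Gy, and a
    photon reference with the same ratio.
    """

    true_p: float = 0.35
    true_K: float = 57.0
    geometry: TargetGeometry = field(
        default_factory=lambda: TargetGeometry(2.3, 3.4)
    )
    ions: tuple[str, ...] = DEFAULT_IONS
    energy_range_MeV_per_u: tuple[float, float] = (0.25, 800.0)
    max_let_keV_per_um: float = 528.0
    sigma_log: float = 0.0
    alpha_over_beta_Gy: float = 5.0
    alpha_ref_Gy: float = 0.18
    beta_ref_Gy2: float = 0.036
    n_records: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_p <= 1.0:
            raise ValueError("true_p must lie in [0, 1]")
        if self.n_records < 1:
            raise ValueError("need at least one record")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def _lq_from_sigma(
    sigma_um2: float,
    let: float,
    alpha_over_beta: float,
    constants: LQConstants,
) -> tuple[float, float]:
    """Invert the cross-section formula into (alpha, beta) at fixed alpha/beta.

    With slope s = sigma rho / (k LET) and alpha = R beta, beta solves
    R^2 beta^2 + 4 |ln S| beta - s^2 = 0 (positive root), which always
    exists for s > 0, so the feasibility condition s^2 >= -4 beta ln S
    holds by construction.
    """
    s = sigma_um2 * constants.rho_g_per_cm3 / (
        constants.dose_fluence_constant * let
    )
    abs_ln_s = -math.log(constants.survival_level)
    R = alpha_over_beta
    beta = (-4.0 * abs_ln_s + math.sqrt(16.0 * abs_ln_s ** 2 + 4.0 * R * R * s * s)) / (
        2.0 * R * R
    )
    alpha = R * beta
    return alpha, beta


def generate_survival_dataset(
    spec: SyntheticStudySpec,
    grids: dict[str, QuantityGrid] | None = None,
    constants: LQConstants = LQConstants(),
) -> list[SurvivalRecord]:
    """Survival records whose cross sections follow K_true * R2(p_true; d_true).

    For each record an ion and a log-uniform energy are drawn, the true
    R2(p_true) is computed from the analytic track model at that exact
    energy, the target cross section ``true_K * R2`` is perturbed by
    multiplicative lognormal noise (sigma_log in natural-log units), and
    the result is inverted into LQ parameters at the configured
    alpha/beta ratio.  ``grids``, if given, maps ion symbol to the
    d_true QuantityGrid and is used only to refuse unresolvable ions.
    """
    rng = np.random.default_rng(spec.seed)
    if grids is not None:
        for ion in spec.ions:
            if ion not in grids:
                raise ValueError(f"ion {ion!r} not resolvable in the supplied grids")
    records: list[SurvivalRecord] = []
    e_lo, e_hi = spec.energy_range_MeV_per_u
    for i in range(spec.n_records):
        # draw (ion, energy) until the LET cap of the study design is met
        while True:
            ion = spec.ions[int(rng.integers(len(spec.ions)))]
            z, a = parse_ion_symbol(ion)
            energy = float(np.exp(rng.uniform(math.log(e_lo), math.log(e_hi))))
            let = toy_let(z, energy)
            if let <= spec.max_let_keV_per_um:
                break
        quality = RadiationQuality(ion, z, a, energy, let)
        params = track_params_for(quality)
        dist = track_icsd_analytic(params, spec.geometry)
        r2_true = float(dist.probs @ r2_weight(dist.nu, spec.true_p))
        noise = math.exp(rng.normal(0.0, spec.sigma_log)) if spec.sigma_log else 1.0
        sigma = spec.true_K * r2_true * noise
        alpha, beta = _lq_from_sigma(
            sigma, let, spec.alpha_over_beta_Gy, constants
        )
        records.append(
            SurvivalRecord(
                cell_line="V79-synthetic",
                quality=quality,
                alpha=alpha,
                beta=beta,
                alpha_ref=spec.alpha_ref_Gy,
                beta_ref=spec.beta_ref_Gy2,
                source_label=f"synthetic/seed{spec.seed}/{i:03d}",
                category=ion_category(z),
            )
        )
    return records
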