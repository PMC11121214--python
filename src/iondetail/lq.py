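"""Linear-quadratic survival mathematics and survival-record handling.

The LQ model writes the surviving fraction after dose D (Gy) as
``S(D) = exp(-(alpha D + beta D^2))``.  From the fitted (alpha, beta) of a
particle-irradiation experiment and of its reference photon radiation this
module computes:

* the iso-survival dose ``D_S`` solving ``alpha D + beta D^2 = -ln S``;
* the relative biological effectiveness ``RBE = D_ref / D_ion`` at the
  working survival level (default 5%);
* the inactivation cross section at survival level S,
  ``sigma_S = (k / rho) * LET * sqrt(alpha^2 - 4 beta ln S)``  [um^2],
  with k = 0.1602 converting keV/um fluence-weighted LET into Gy at unit
  density.  The square root is exactly the local slope of -ln S(D) at
  D_S, i.e. alpha + 2 beta D_S, so the beta = 0 limit is the familiar
  (k/rho) * LET * alpha.

Records fitted with a (non-physical) negative beta are repaired by the
endpoint-preserving rule alpha' = alpha + beta * D_S, beta' = 0, which
leaves the dose at the working survival level unchanged and lowers alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .icsd import RadiationQuality

__all__ = [
    "LQConstants",
    "SurvivalRecord",
    "correct_negative_beta",
    "dose_at_survival",
    "rbe_at_survival",
    "inactivation_cross_section",
    "ion_category",
    "load_survival_table",
    "SURVIVAL_COLUMNS",
]

log = logging.getLogger(__name__)

#: mandatory columns of the survival-parameter CSV dialect
SURVIVAL_COLUMNS = [
    "cell_line",
    "ion_symbol",
    "Z",
    "A",
    "energy_MeV_per_u",
    "let_keV_per_um",
    "alpha_Gy-1",
    "beta_Gy-2",
    "alpha_ref_Gy-1",
    "beta_ref_Gy-2",
    "source_label",
]


@dataclass(frozen=True)
class LQConstants:
    """Physical constants of the cross-section formula.

    ``dose_fluence_constant`` is 0.1602 for LET in keV/um, dose in Gy and
    density in g/cm^3 (it is 1.602e-19 J/eV times the unit bookkeeping).
    """

    dose_fluence_constant: float = 0.1602
    rho_g_per_cm3: float = 1.0
    survival_level: float = 0.05

    def __post_init__(self) -> None:
        if self.dose_fluence_constant <= 0 or self.rho_g_per_cm3 <= 0:
            raise ValueError("constants must be strictly positive")
        if not 0.0 < self.survival_level < 1.0:
            raise ValueError("survival level must lie in (0, 1)")


@dataclass(frozen=True)
class SurvivalRecord:
    """One cell-survival experiment: LQ parameters for ion and reference."""

    cell_line: str
    quality: RadiationQuality
    alpha: float            # Gy^-1, ion
    beta: float             # Gy^-2, ion
    alpha_ref: float | None  # Gy^-1, reference photons (None if unreported)
    beta_ref: float | None   # Gy^-2
    source_label: str = ""
    category: str = ""       # Hydrogen / Helium / heavy-ion
    beta_corrected: bool = field(default=False, compare=False)

    @property
    def has_reference(self) -> bool:
        return self.alpha_ref is not None and self.beta_ref is not None


def dose_at_survival(alpha: float, beta: float, survival: float) -> float:
    """Dose D (Gy) at which the LQ curve reaches the given survival fraction.

    Solves ``alpha D + beta D^2 = -ln(survival)`` for the positive root.
    Requires alpha > 0 and beta >= 0 (apply the negative-beta correction
    first).
    """
    if not 0.0 < survival < 1.0:
        raise ValueError("survival fraction must lie in (0, 1)")
    if beta < 0:
        raise ValueError("beta must be >= 0; apply correct_negative_beta first")
    ln_s = math.log(survival)  # < 0
    if beta == 0.0:
        if alpha <= 0:
            raise ValueError("no positive root: alpha <= 0 with beta = 0")
        return -ln_s / alpha
    # beta > 0: positive root of beta D^2 + alpha D + ln_s = 0
    disc = alpha * alpha - 4.0 * beta * ln_s
    return (-alpha + math.sqrt(disc)) / (2.0 * beta)


def correct_negative_beta(
    alpha: float, beta: float, survival_level: float = 0.05
) -> tuple[float, float]:
    """Repair a negative fitted beta into the best purely linear curve.

    Returns (alpha, beta) unchanged when beta >= 0.  When beta < 0, the
    pure-linear replacement alpha' = alpha + beta * D_S (beta' = 0) is
    chosen so the dose at the working survival level is preserved exactly;
    alpha is thereby adjusted downward.
    """
    if beta >= 0:
        return alpha, beta
    ln_s = math.log(survival_level)
    disc = alpha * alpha - 4.0 * beta * ln_s  # beta < 0 can make this negative
    if disc <= 0:
        raise ValueError(
            "LQ curve never reaches the survival level: cannot correct beta"
        )
    # smallest positive root of beta D^2 + alpha D + ln_s = 0 (beta < 0)
    d_s = (-alpha + math.sqrt(disc)) / (2.0 * beta)
    if d_s <= 0:
        d_s = (-alpha - math.sqrt(disc)) / (2.0 * beta)
    alpha_prime = -ln_s / d_s  # == alpha + beta * d_s
    if alpha_prime <= 0:
        raise ValueError("corrected alpha is non-positive; record invalid")
    return alpha_prime, 0.0


def rbe_at_survival(record: SurvivalRecord, survival: float = 0.05) -> float:
    """RBE = D_ref / D_ion at the given survival fraction."""
    if not record.has_reference:
        raise ValueError(
            f"record {record.source_label!r} lacks reference-radiation parameters"
        )
    a_ref, b_ref = correct_negative_beta(record.alpha_ref, record.beta_ref, survival)
    a_ion, b_ion = correct_negative_beta(record.alpha, record.beta, survival)
    d_ref = dose_at_survival(a_ref, b_ref, survival)
    d_ion = dose_at_survival(a_ion, b_ion, survival)
    return d_ref / d_ion


def inactivation_cross_section(
    alpha: float,
    beta: float,
    let_keV_per_um: float,
    constants: LQConstants = LQConstants(),
) -> float:
    """Inactivation cross section sigma_S in um^2 at the configured level.

    ``sigma_S = (k / rho) * LET * sqrt(alpha^2 - 4 beta ln S)``; the root
    equals the local log-survival slope alpha + 2 beta D_S, so sigma is
    the pure-linear (k/rho) * LET * alpha when beta = 0.
    """
    if let_keV_per_um <= 0:
        raise ValueError("LET must be strictly positive")
    if beta < 0:
        raise ValueError("beta must be >= 0; apply correct_negative_beta first")
    ln_s = math.log(constants.survival_level)
    disc = alpha * alpha - 4.0 * beta * ln_s
    k = constants.dose_fluence_constant / constants.rho_g_per_cm3
    return k * let_keV_per_um * math.sqrt(disc)


_HYDROGEN_Z = 1
_HELIUM_Z = 2


def ion_category(Z: int) -> str:
    """PIDE-style grouping: Hydrogen (p, d), Helium (3He, 4He, alpha), heavy-ion."""
    if Z == _HYDROGEN_Z:
        return "Hydrogen"
    if Z == _HELIUM_Z:
        return "Helium"
    return "heavy-ion"


def load_survival_table(
    path: str | Path,
    survival_level: float = 0.05,
    exclusions: list[dict] | None = None,
) -> list[SurvivalRecord]:
    """Read a survival-parameter CSV into corrected, categorized records.

    Negative ion or reference betas are corrected in place (flagged on the
    record); rows whose correction fails, or with non-positive alpha/LET,
    are excluded with a logged, machine-readable reason.  Reference fields
    may be empty: the record is kept (usable for sigma) but flagged as
    lacking a reference.  ``exclusions``, if given, collects one dict per
    dropped row.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing mandatory column(s): {missing}")
    if df.empty:
        log.warning("survival table %s is empty", path)
        return []

    records: list[SurvivalRecord] = []
    sink = exclusions if exclusions is not None else []
    for idx, row in df.iterrows():
        label = str(row["source_label"])

        def drop(reason_code: str, detail: str) -> None:
            sink.append({"row": int(idx), "reason": reason_code, "detail": detail})
            log.info("excluded row %d (%s): %s", idx, reason_code, detail)

        try:
            quality = RadiationQuality(
                symbol=str(row["ion_symbol"]),
                Z=int(row["Z"]),
                A=int(row["A"]),
                energy_MeV_per_u=float(row["energy_MeV_per_u"]),
                let_keV_per_um=float(row["let_keV_per_um"]),
            )
        except (ValueError, TypeError) as exc:
            drop("invalid_quality", str(exc))
            continue

        alpha, beta = float(row["alpha_Gy-1"]), float(row["beta_Gy-2"])
        corrected = beta < 0
        try:
            alpha, beta = correct_negative_beta(alpha, beta, survival_level)
        except ValueError as exc:
            drop("beta_correction_failed", str(exc))
            continue
        if alpha <= 0:
            drop("nonpositive_alpha", f"alpha={alpha}")
            continue

        a_ref = row["alpha_ref_Gy-1"]
        b_ref = row["beta_ref_Gy-2"]
        has_ref = pd.notna(a_ref) and pd.notna(b_ref)
        if has_ref:
            try:
                a_ref, b_ref = correct_negative_beta(
                    float(a_ref), float(b_ref), survival_level
                )
            except ValueError as exc:
                drop("reference_correction_failed", str(exc))
                continue
        else:
            a_ref = b_ref = None

        records.append(
            SurvivalRecord(
                cell_line=str(row["cell_line"]),
                quality=quality,
                alpha=alpha,
                beta=beta,
                alpha_ref=a_ref,
                beta_ref=b_ref,
                source_label=label,
                category=ion_category(quality.Z),
                beta_corrected=corrected,
            )
        )
    log.info(
        "loaded %d survival records (%d excluded) from %s",
        len(records),
        len(sink),
        path,
    )
    return records


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Flatten records back to the CSV dialect (round-trip helper)."""
    rows = []
    for r in records:
        rows.append(
            {
                "cell_line": r.cell_line,
                "ion_symbol": r.quality.symbol,
                "Z": r.quality.Z,
                "A": r.quality.A,
                "energy_MeV_per_u": r.quality.energy_MeV_per_u,
                "let_keV_per_um": r.quality.let_keV_per_um,
                "alpha_Gy-1": r.alpha,
                "beta_Gy-2": r.beta,
                "alpha_ref_Gy-1": r.alpha_ref,
                "beta_ref_Gy-2": r.beta_ref,
                "source_label": r.source_label,
            }
        )
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
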