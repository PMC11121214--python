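"""Linking nanodosimetry to radiobiology: the proportional R2 model.

The working hypothesis is that the inactivation cross section at 5%
survival is proportional to the binomially weighted cluster statistic,

    sigma_S  ~=  K * R2(p; d),

with three free quantities: the lesion probability per ionization ``p``,
the target size ``d`` (which selects a pre-computed quantity grid), and
the proportionality constant ``K`` (um^2, interpretable as a saturation
cross section of the cell line).  The fit minimizes the unweighted sum of
squared differences

    chi2(p, d, K) = sum_i ( sigma_i - K * R2(p; d, E_i) )^2

over a (p, d) grid, with K optimized per grid point (closed form, or an
explicit K scan).  Exposed statsmodels-style: build an
:class:`R2CrossSectionModel` from survival records and quantity grids,
call :meth:`~R2CrossSectionModel.fit`, and read estimates, the normalized
chi2 surface, residuals and goodness of fit off the returned
:class:`R2CrossSectionResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import QuantityGrid
from .icsd import TargetGeometry
from .lq import LQConstants, SurvivalRecord, inactivation_cross_section

__all__ = [
    "modified_chi2",
    "optimal_K",
    "coefficient_of_determination",
    "R2CrossSectionModel",
    "R2CrossSectionResults",
    "grid_fit",
]

log = logging.getLogger(__name__)


def modified_chi2(records: Sequence[tuple[float, float]], K: float) -> float:
    """Unweighted sum of squares sum_i (sigma_i - K * r_i)^2.

    ``records`` pairs each measured cross section (um^2) with the model
    statistic r_i = R2(p; d, E_i) evaluated at the experiment's energy.
    No per-point weights are applied: the survival compilations this
    mirrors do not report uncertainties.
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    arr = np.asarray(records, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigma and r2 values must be finite")
    sigma, r = arr[:, 0], arr[:, 1]
    resid = sigma - K * r
    return float(resid @ resid)


def optimal_K(
    records: Sequence[tuple[float, float]],
    mode: str = "closed_form",
    k_grid: tuple[float, float, float] = (1.0, 200.0, 1.0),
) -> float:
    """K minimizing the modified chi2 for fixed pairings (sigma_i, r_i).

    ``closed_form`` uses the least-squares solution K = sum(sigma r) /
    sum(r^2); ``grid`` scans K over (start, stop, step) as a direct
    analogue of an exhaustive parameter scan and agrees with the closed
    form to within one step.
    """
    arr = np.asarray(records, dtype=float)
    sigma, r = arr[:, 0], arr[:, 1]
    rr = float(r @ r)
    if rr == 0.0:
        raise ValueError("all r2 values are zero: K is unidentifiable")
    if mode == "closed_form":
        return float(sigma @ r) / rr
    if mode == "grid":
        start, stop, step = k_grid
        ks = np.arange(start, stop + 0.5 * step, step)
        chi = ((sigma[None, :] - ks[:, None] * r[None, :]) ** 2).sum(axis=1)
        return float(ks[int(np.argmin(chi))])
    raise ValueError(f"unknown K mode {mode!r}")


def coefficient_of_determination(
    observed: Sequence[float], model: Sequence[float]
) -> float:
    """1 - SS_res / SS_tot about the observed mean (model-agnostic)."""
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(model, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observations have zero variance")
    ss_res = float(((obs - mod) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class _PreparedData:
    """Per-geometry design data: records kept, sigma, R2 matrix, Fk columns."""

    geometry: TargetGeometry
    records: list[SurvivalRecord]
    sigma: np.ndarray                 # (n_rec,)
    r2_matrix: np.ndarray             # (n_rec, n_p)
    fk_matrix: dict[int, np.ndarray]  # k -> (n_rec,)
    m1: np.ndarray                    # (n_rec,) interpolated mean cluster size


class R2CrossSectionModel:
    """Proportional model sigma_S = K * R2(p; d) fitted over a (p, d) grid.

    Parameters
    ----------
    records
        Survival records (post negative-beta correction); each supplies
        (alpha, beta, LET, energy) from which sigma_S is computed.
    grids
        Mapping from geometry to ``{particle_symbol: QuantityGrid}``; each
        geometry in the mapping is one candidate target size ``d``.
    constants
        LQ constants (survival level, dose-fluence constant, density).
    p_grid
        Candidate lesion probabilities; defaults to the grids' own p-grid.
    """

    def __init__(
        self,
        records: Sequence[SurvivalRecord],
        grids: dict[TargetGeometry, dict[str, QuantityGrid]],
        constants: LQConstants = LQConstants(),
        p_grid: np.ndarray | None = None,
    ) -> None:
        if not records:
            raise ValueError("no survival records supplied")
        if not grids:
            raise ValueError("no quantity grids supplied")
        self.records = list(records)
        self.grids = grids
        self.constants = constants
        first = next(iter(next(iter(grids.values())).values()))
        self.p_grid = first.p_grid.copy() if p_grid is None else np.asarray(p_grid)
        self.exclusions: list[dict] = []
        self._prepared = [self._prepare(g) for g in grids]
        if all(p.sigma.size == 0 for p in self._prepared):
            raise ValueError("every record failed interpolation for every geometry")

    # ------------------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        survival_csv: str | Path,
        grid_csvs: Sequence[str | Path],
        constants: LQConstants = LQConstants(),
    ) -> "R2CrossSectionModel":
        """Convenience constructor from the CSV dialects on disk."""
        from .lq import load_survival_table

        records = load_survival_table(survival_csv, constants.survival_level)
        grids: dict[TargetGeometry, dict[str, QuantityGrid]] = {}
        for path in grid_csvs:
            df = pd.read_csv(path)
            for (particle, d, h), sub in df.groupby(
                ["particle", "target_d_nm", "target_h_nm"]
            ):
                grid = QuantityGrid.from_frame(sub)
                grids.setdefault(grid.geometry, {})[str(particle)] = grid
        return cls(records, grids, constants)

    # ------------------------------------------------------------------
    def _prepare(self, geometry: TargetGeometry) -> _PreparedData:
        by_particle = self.grids[geometry]
        kept: list[SurvivalRecord] = []
        sig, rows, m1s = [], [], []
        fk_rows: dict[int, list[float]] = {}
        for rec in self.records:
            grid = by_particle.get(rec.quality.symbol)
            if grid is None:
                self.exclusions.append(
                    {
                        "source_label": rec.source_label,
                        "geometry": geometry.label,
                        "reason": "no_grid_for_particle",
                        "detail": rec.quality.symbol,
                    }
                )
                continue
            # align this grid's p-columns with the model's p-grid
            p_idx = [grid.p_index(p) for p in self.p_grid]
            try:
                r2_row = grid.r2_row_at(rec.quality.energy_MeV_per_u)[p_idx]
                m1_val = grid.m1_at(rec.quality.energy_MeV_per_u)
                fk_vals = {
                    k: grid.fk_at(rec.quality.energy_MeV_per_u, k)
                    for k in sorted(grid.fk)
                }
            except ValueError as exc:
                self.exclusions.append(
                    {
                        "source_label": rec.source_label,
                        "geometry": geometry.label,
                        "reason": "interpolation_failed",
                        "detail": str(exc),
                    }
                )
                continue
            kept.append(rec)
            sig.append(
                inactivation_cross_section(
                    rec.alpha, rec.beta, rec.quality.let_keV_per_um, self.constants
                )
            )
            rows.append(r2_row)
            m1s.append(m1_val)
            for k, v in fk_vals.items():
                fk_rows.setdefault(k, []).append(v)
        return _PreparedData(
            geometry=geometry,
            records=kept,
            sigma=np.asarray(sig),
            r2_matrix=np.asarray(rows) if rows else np.empty((0, self.p_grid.size)),
            fk_matrix={k: np.asarray(v) for k, v in fk_rows.items()},
            m1=np.asarray(m1s),
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        k_mode: str = "closed_form",
        k_grid: tuple[float, float, float] = (1.0, 200.0, 1.0),
    ) -> "R2CrossSectionResults":
        """Optimize K at every (p, d) grid point and locate the minimum.

        Ties on the chi2 surface (within a 1e-12 relative band) are broken
        toward larger d, then smaller p, and reported on the results
        object: a shallow valley across (p, d) is an expected feature of
        this model family, not an error.
        """
        n_p = self.p_grid.size
        geoms = [prep.geometry for prep in self._prepared]
        chi2 = np.full((n_p, len(geoms)), np.nan)
        k_opt = np.full((n_p, len(geoms)), np.nan)
        for j, prep in enumerate(self._prepared):
            if prep.sigma.size == 0:
                continue
            sigma, R = prep.sigma, prep.r2_matrix
            for i in range(n_p):
                r = R[:, i]
                pairs = np.column_stack([sigma, r])
                K = optimal_K(pairs, mode=k_mode, k_grid=k_grid)
                k_opt[i, j] = K
                chi2[i, j] = modified_chi2(pairs, K)
        if np.all(np.isnan(chi2)):
            raise ValueError("chi2 surface is empty")
        max_chi = np.nanmax(chi2)
        normalized = chi2 / max_chi if max_chi > 0 else np.ones_like(chi2)

        min_chi = np.nanmin(chi2)
        tie_band = min_chi * (1.0 + 1e-12) + 1e-300
        ties = np.argwhere(chi2 <= tie_band)
        # tie-break: largest d first, then smallest p
        d_sizes = np.array([g.diameter_nm for g in geoms])
        order = sorted(
            (tuple(t) for t in ties),
            key=lambda t: (-d_sizes[t[1]], self.p_grid[t[0]]),
        )
        i_best, j_best = order[0]
        best_prep = self._prepared[j_best]
        fitted = k_opt[i_best, j_best] * best_prep.r2_matrix[:, i_best]
        resid = best_prep.sigma - fitted
        rsq = coefficient_of_determination(best_prep.sigma, fitted)
        return R2CrossSectionResults(
            model=self,
            best_p=float(self.p_grid[i_best]),
            best_geometry=best_prep.geometry,
            best_K=float(k_opt[i_best, j_best]),
            chi2_surface=pd.DataFrame(
                normalized, index=self.p_grid, columns=[g.label for g in geoms]
            ),
            chi2_raw_min=float(min_chi),
            k_surface=pd.DataFrame(
                k_opt, index=self.p_grid, columns=[g.label for g in geoms]
            ),
            rsquared=float(rsq),
            residuals=resid,
            fitted_sigma=fitted,
            observed_sigma=best_prep.sigma.copy(),
            n_ties=len(order),
            _best_prep=best_prep,
        )


@dataclass
class R2CrossSectionResults:
    """Fit results: best (p, d, K), the normalized chi2 surface, diagnostics."""

    model: R2CrossSectionModel
    best_p: float
    best_geometry: TargetGeometry
    best_K: float
    chi2_surface: pd.DataFrame   # normalized to max = 1; rows p, columns d
    chi2_raw_min: float
    k_surface: pd.DataFrame
    rsquared: float
    residuals: np.ndarray
    fitted_sigma: np.ndarray
    observed_sigma: np.ndarray
    n_ties: int
    _best_prep: _PreparedData

    @property
    def params(self) -> dict[str, float | str]:
        return {
            "p": self.best_p,
            "d_nm": self.best_geometry.diameter_nm,
            "h_nm": self.best_geometry.height_nm,
            "K_um2": self.best_K,
        }

    @property
    def nobs(self) -> int:
        return int(self.observed_sigma.size)

    # ------------------------------------------------------------------
    def compare_fk_models(self) -> pd.DataFrame:
        """Goodness of the rival step-weighted models sigma = K * Fk.

        For each tabulated k, K is optimized by least squares on the best
        geometry's pairings and the coefficient of determination computed,
        comparable with :attr:`rsquared` of the graded R2(p) model.
        """
        prep = self._best_prep
        rows = []
        for k in sorted(prep.fk_matrix):
            fkv = prep.fk_matrix[k]
            if float(fkv @ fkv) == 0.0:
                rows.append({"model": f"F{k}", "K_um2": np.nan, "r_squared": np.nan})
                continue
            K = optimal_K(np.column_stack([prep.sigma, fkv]))
            rows.append(
                {
                    "model": f"F{k}",
                    "K_um2": K,
                    "r_squared": coefficient_of_determination(prep.sigma, K * fkv),
                }
            )
        rows.append(
            {
                "model": f"R2(p={self.best_p:g})",
                "K_um2": self.best_K,
                "r_squared": self.rsquared,
            }
        )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Proportional cross-section model  sigma_S = K * R2(p; d)",
            "=" * 58,
            f"records used                {self.nobs}",
            f"survival level              {self.model.constants.survival_level:g}",
            f"best lesion probability p   {self.best_p:.2f}",
            f"best target geometry        {self.best_geometry.label}",
            f"best K                      {self.best_K:.4g} um^2",
            f"min chi2 (raw)              {self.chi2_raw_min:.6g} um^4",
            f"coefficient of determination {self.rsquared:.4f}",
            f"chi2-surface ties           {self.n_ties}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "params": self.params,
            "rsquared": self.rsquared,
            "chi2_raw_min": self.chi2_raw_min,
            "n_records": self.nobs,
            "n_ties": self.n_ties,
            "chi2_surface": {
                "p": [float(p) for p in self.chi2_surface.index],
                "geometries": list(self.chi2_surface.columns),
                "normalized_chi2": self.chi2_surface.to_numpy().tolist(),
            },
            "residuals": self.residuals.tolist(),
            "observed_sigma": self.observed_sigma.tolist(),
            "fitted_sigma": self.fitted_sigma.tolist(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    def plot_heatmap(self, path: str | Path) -> None:
        """Normalized chi2 over (p, d) as a heatmap image (smaller = better)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        surface = self.chi2_surface.to_numpy()
        fig, ax = plt.subplots(figsize=(6, 4.5))
        im = ax.imshow(
            surface.T,
            aspect="auto",
            origin="lower",
            extent=(
                float(self.chi2_surface.index[0]),
                float(self.chi2_surface.index[-1]),
                -0.5,
                surface.shape[1] - 0.5,
            ),
            cmap="viridis_r",
        )
        ax.set_yticks(range(surface.shape[1]))
        ax.set_yticklabels(self.chi2_surface.columns, fontsize=7)
        ax.set_xlabel("lesion probability p")
        ax.set_ylabel("target geometry")
        fig.colorbar(im, ax=ax, label="chi2 / max chi2")
        ax.set_title("Normalized chi2 of sigma = K R2(p; d)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def grid_fit(
    records: Sequence[SurvivalRecord],
    grids: dict[TargetGeometry, dict[str, QuantityGrid]],
    p_grid: np.ndarray | None = None,
    constants: LQConstants = LQConstants(),
    k_mode: str = "closed_form",
    k_grid: tuple[float, float, float] = (1.0, 200.0, 1.0),
) -> R2CrossSectionResults:
    """Functional wrapper: build the model and fit in one call."""
    model = R2CrossSectionModel(records, grids, constants=constants, p_grid=p_grid)
    return model.fit(k_mode=k_mode, k_grid=k_grid)
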