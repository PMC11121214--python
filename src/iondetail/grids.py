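"""Per-ion, per-geometry tables of derived nanodosimetric quantities.

A :class:`QuantityGrid` holds, for one particle species and one cylindrical
target, the energy-indexed values of mean cluster size M1, the cumulative
probabilities F2..F7, and R2(p) on a probability grid (default p = 0.2 to
1.0 in steps of 0.01, whose upper end is exactly F2).  Grids are what the
fitting layer interpolates to the energies of survival experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import icsd as _icsd
from .icsd import ICSD, TargetGeometry
from .interpolate import interpolate_quantity
from .io import ICSDEntry

__all__ = ["DEFAULT_P_GRID", "DEFAULT_K_LIST", "QuantityGrid", "quality_curves"]

#: default lesion-probability grid: 0.2 .. 1.0, step 0.01
DEFAULT_P_GRID = np.round(np.arange(20, 101) / 100.0, 10)
#: cumulative-probability orders tabulated alongside F2
DEFAULT_K_LIST = (2, 3, 4, 5, 6, 7)


def _p_col(p: float) -> str:
    return f"r2_p{int(round(p * 100)):03d}"


@dataclass
class QuantityGrid:
    """Energy-indexed derived quantities for one (particle, geometry)."""

    particle: str
    geometry: TargetGeometry
    energies: np.ndarray            # MeV/u, strictly increasing
    lets: np.ndarray                # keV/um
    m1: np.ndarray
    fk: dict[int, np.ndarray]       # k -> F_k(E)
    r2: np.ndarray                  # shape (n_energies, n_p)
    p_grid: np.ndarray = field(default_factory=lambda: DEFAULT_P_GRID.copy())

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("grid energies must be strictly increasing")
        n_e = self.energies.size
        self.lets = np.asarray(self.lets, dtype=float)
        self.m1 = np.asarray(self.m1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.r2.shape != (n_e, self.p_grid.size):
            raise ValueError("r2 matrix shape must be (n_energies, n_p)")
        for name, arr in (("lets", self.lets), ("m1", self.m1)):
            if arr.shape != (n_e,):
                raise ValueError(f"{name} must have one value per energy")
        bad = ~np.isfinite(self.m1) | (self.m1 < 0)
        if bad.any() or not np.all(np.isfinite(self.r2)):
            raise ValueError("grid quantities must be finite and non-negative")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("R2 values must lie in [0, 1]")

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_icsds(
        cls,
        particle: str,
        geometry: TargetGeometry,
        energies: Sequence[float],
        lets: Sequence[float],
        icsds: Sequence[ICSD],
        p_grid: np.ndarray | None = None,
        k_list: Iterable[int] = DEFAULT_K_LIST,
    ) -> "QuantityGrid":
        """Compute every derived quantity from per-energy distributions."""
        p_grid = DEFAULT_P_GRID.copy() if p_grid is None else np.asarray(p_grid, float)
        order = np.argsort(np.asarray(energies, dtype=float))
        energies = np.asarray(energies, dtype=float)[order]
        lets = np.asarray(lets, dtype=float)[order]
        icsds = [icsds[i] for i in order]
        m1 = np.array([_icsd.m1(d) for d in icsds])
        fk = {k: np.array([_icsd.fk(d, k) for d in icsds]) for k in k_list}
        r2 = np.array([[_icsd.r2(d, p) for p in p_grid] for d in icsds])
        return cls(particle, geometry, energies, lets, m1, fk, r2, p_grid)

    @classmethod
    def from_icsd_entries(
        cls,
        entries: Sequence[ICSDEntry],
        p_grid: np.ndarray | None = None,
        k_list: Iterable[int] = DEFAULT_K_LIST,
    ) -> dict[tuple[str, float, float], "QuantityGrid"]:
        """Group a flat ICSD table into grids keyed by (particle, d, h)."""
        buckets: dict[tuple, list[ICSDEntry]] = {}
        for e in entries:
            k = (e.particle, e.geometry.diameter_nm, e.geometry.height_nm)
            buckets.setdefault(k, []).append(e)
        grids = {}
        for key, group in buckets.items():
            grids[key] = cls.from_icsds(
                particle=key[0],
                geometry=group[0].geometry,
                energies=[e.energy_MeV_per_u for e in group],
                lets=[e.let_keV_per_um for e in group],
                icsds=[e.icsd for e in group],
                p_grid=p_grid,
                k_list=k_list,
            )
        return grids

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def energy_span(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def p_index(self, p: float) -> int:
        """Index of p on the grid; the grid step is 0.01 so exact match is expected."""
        i = int(np.argmin(np.abs(self.p_grid - p)))
        if abs(self.p_grid[i] - p) > 1e-9:
            raise ValueError(f"p={p} is not a grid point of this QuantityGrid")
        return i

    def m1_at(self, energy: float) -> float:
        return float(interpolate_quantity(self.energies, self.m1, energy))

    def let_at(self, energy: float) -> float:
        return float(interpolate_quantity(self.energies, self.lets, energy))

    def fk_at(self, energy: float, k: int) -> float:
        return float(interpolate_quantity(self.energies, self.fk[k], energy))

    def r2_row_at(self, energy: float) -> np.ndarray:
        """R2 over the whole p-grid, interpolated to one energy."""
        return np.asarray(interpolate_quantity(self.energies, self.r2, energy))

    def r2_at(self, energy: float, p: float) -> float:
        return float(
            interpolate_quantity(self.energies, self.r2[:, self.p_index(p)], energy)
        )

    # ------------------------------------------------------------------
    # serialization (derived-quantities CSV)
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            "particle": self.particle,
            "target_d_nm": self.geometry.diameter_nm,
            "target_h_nm": self.geometry.height_nm,
            "energy_MeV_per_u": self.energies,
            "let_keV_per_um": self.lets,
            "m1": self.m1,
        }
        for k in sorted(self.fk):
            data[f"f{k}"] = self.fk[k]
        for j, p in enumerate(self.p_grid):
            data[_p_col(p)] = self.r2[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "QuantityGrid":
        particle = df["particle"].iloc[0]
        geometry = TargetGeometry(
            float(df["target_d_nm"].iloc[0]), float(df["target_h_nm"].iloc[0])
        )
        df = df.sort_values("energy_MeV_per_u")
        k_cols = sorted(
            int(c[1:]) for c in df.columns if c.startswith("f") and c[1:].isdigit()
        )
        p_cols = sorted(c for c in df.columns if c.startswith("r2_p"))
        p_grid = np.array([int(c[4:]) / 100.0 for c in p_cols])
        return cls(
            particle=str(particle),
            geometry=geometry,
            energies=df["energy_MeV_per_u"].to_numpy(float),
            lets=df["let_keV_per_um"].to_numpy(float),
            m1=df["m1"].to_numpy(float),
            fk={k: df[f"f{k}"].to_numpy(float) for k in k_cols},
            r2=df[p_cols].to_numpy(float),
            p_grid=p_grid,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def quality_curves(grid: QuantityGrid, p: float) -> pd.DataFrame:
    """Per-energy radiation-quality curves at a fixed lesion probability.

    Emits energy, LET, M1, R2(p), the damage density R2/M1 (defined as 0
    where M1 = 0, i.e. where traversals essentially never ionize), and the
    tabulated Fk columns.  R2/M1 against LET or M1 traces the
    characteristic rise-and-fall of biological effectiveness with
    ionization density: sparse tracks rarely make double lesions, very
    dense tracks waste ionizations on already-doomed targets (overkill).
    """
    j = grid.p_index(p)
    r2_col = grid.r2[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(grid.m1 > 0, r2_col / np.where(grid.m1 > 0, grid.m1, 1.0), 0.0)
    data = {
        "energy_MeV_per_u": grid.energies,
        "let_keV_per_um": grid.lets,
        "m1": grid.m1,
        "r2": r2_col,
        "r2_over_m1": ratio,
    }
    for k in sorted(grid.fk):
        data[f"f{k}"] = grid.fk[k]
    return pd.DataFrame(data)
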