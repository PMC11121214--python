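"""Readers and writers for the package's tabular dialects.

Two on-disk shapes are used throughout:

* the **ICSD table** (CSV, long form): one row per (distribution, cluster
  size) with columns ``particle, energy_MeV_per_u, let_keV_per_um,
  target_d_nm, target_h_nm, nu, probability``; one distribution is the set
  of rows sharing the first five columns, and its probabilities must close
  to 1.  A JSON mirror stores each distribution with its probabilities as
  an array.
* the **survival table** (CSV): see :mod:`iondetail.lq`.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .icsd import ICSD, RENORM_TOL, TargetGeometry

__all__ = [
    "ICSDEntry",
    "ICSD_COLUMNS",
    "read_icsd_table",
    "write_icsd_table",
    "write_icsd_json",
    "read_icsd_json",
    "parse_ion_symbol",
]

ICSD_COLUMNS = [
    "particle",
    "energy_MeV_per_u",
    "let_keV_per_um",
    "target_d_nm",
    "target_h_nm",
    "nu",
    "probability",
]

_ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


def parse_ion_symbol(symbol: str) -> tuple[int, int]:
    """(Z, A) from a mass-number-prefixed ion symbol such as '4He' or '12C'."""
    m = re.fullmatch(r"(\d+)([A-Z][a-z]?)", symbol.strip())
    if not m:
        raise ValueError(f"cannot parse ion symbol {symbol!r} (expected e.g. '4He')")
    a = int(m.group(1))
    element = m.group(2)
    if element not in _ELEMENT_Z:
        raise ValueError(f"unknown element {element!r} in ion symbol {symbol!r}")
    z = _ELEMENT_Z[element]
    if z > a:
        raise ValueError(f"ion symbol {symbol!r} has Z={z} > A={a}")
    return z, a


class ICSDEntry(NamedTuple):
    """One stored distribution with its radiation quality and geometry."""

    particle: str
    energy_MeV_per_u: float
    let_keV_per_um: float
    geometry: TargetGeometry
    icsd: ICSD

    @property
    def key(self) -> tuple:
        return (
            self.particle,
            self.energy_MeV_per_u,
            self.let_keV_per_um,
            self.geometry.diameter_nm,
            self.geometry.height_nm,
        )


def write_icsd_table(entries: list[ICSDEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        for nu, prob in enumerate(e.icsd.probs):
            rows.append(
                {
                    "particle": e.particle,
                    "energy_MeV_per_u": e.energy_MeV_per_u,
                    "let_keV_per_um": e.let_keV_per_um,
                    "target_d_nm": e.geometry.diameter_nm,
                    "target_h_nm": e.geometry.height_nm,
                    "nu": nu,
                    "probability": prob,
                }
            )
    pd.DataFrame(rows, columns=ICSD_COLUMNS).to_csv(path, index=False)


def read_icsd_table(path: str | Path) -> list[ICSDEntry]:
    df = pd.read_csv(path)
    missing = [c for c in ICSD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ICSD table missing mandatory column(s): {missing}")
    group_cols = ICSD_COLUMNS[:5]
    entries: list[ICSDEntry] = []
    seen: set[tuple] = set()
    for key, grp in df.groupby(group_cols, sort=False):
        if key in seen:  # pragma: no cover - groupby already merges
            raise ValueError(f"duplicated ICSD group {key}")
        seen.add(key)
        grp = grp.sort_values("nu")
        nu = grp["nu"].to_numpy(dtype=int)
        if not np.array_equal(nu, np.arange(nu.max() + 1)):
            raise ValueError(
                f"ICSD group {key} must list every nu from 0 to nu_max exactly once"
            )
        probs = grp["probability"].to_numpy(dtype=float)
        if abs(probs.sum() - 1.0) > RENORM_TOL:
            raise ValueError(
                f"ICSD group {key} probabilities sum to {probs.sum()!r}, not 1"
            )
        particle, energy, let, d, h = key
        entries.append(
            ICSDEntry(
                particle=str(particle),
                energy_MeV_per_u=float(energy),
                let_keV_per_um=float(let),
                geometry=TargetGeometry(float(d), float(h)),
                icsd=ICSD(probs, meta={"particle": particle, "energy": energy}),
            )
        )
    return entries


def write_icsd_json(entries: list[ICSDEntry], path: str | Path) -> None:
    payload = [
        {
            "particle": e.particle,
            "energy_MeV_per_u": e.energy_MeV_per_u,
            "let_keV_per_um": e.let_keV_per_um,
            "target_d_nm": e.geometry.diameter_nm,
            "target_h_nm": e.geometry.height_nm,
            "probs": [float(x) for x in e.icsd.probs],
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_icsd_json(path: str | Path) -> list[ICSDEntry]:
    payload = json.loads(Path(path).read_text())
    return [
        ICSDEntry(
            particle=str(obj["particle"]),
            energy_MeV_per_u=float(obj["energy_MeV_per_u"]),
            let_keV_per_um=float(obj["let_keV_per_um"]),
            geometry=TargetGeometry(float(obj["target_d_nm"]), float(obj["target_h_nm"])),
            icsd=ICSD(np.asarray(obj["probs"], dtype=float)),
        )
        for obj in payload
    ]
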