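"""Pure-compound properties and thermophysical estimators.

Ships a table of 111 compounds (molar mass, critical constants, normal
boiling point, acentric factor, Lennard-Jones parameters) together with the
closed-form estimators used to fill gaps in such tables:

* Tyn-Calus molar volume at the normal boiling point from the critical
  volume,
* the Klincewicz molar-mass/boiling-point correlation for the critical
  temperature,
* the Lee-Kesler vapor-pressure relation for the acentric factor,
* the corresponding-states Lennard-Jones estimators used by the Zhu et al.
  hybrid diffusivity model.

Units follow the conventions of the diffusion literature: K, bar,
cm3 mol-1, Angstrom, with LJ energies reported as eps/kB in K.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

from ._constants import ATM_IN_BAR, AVOGADRO, BAR_TO_PA, KB_J, M_TO_ANGSTROM

__all__ = [
    "CompoundProperties",
    "SoluteLJ",
    "SolventLJ",
    "CompoundLookupError",
    "CompoundTable",
    "load_compounds",
    "lookup_compound",
    "vbp_from_vc",
    "klincewicz_tc",
    "lee_kesler_omega",
    "zhu_solute_lj",
    "zhu_solvent_lj",
]


@dataclass(frozen=True)
class CompoundProperties:
    """One row of the compound table.

    M: molar mass, g/mol. Tc, Tb: critical / normal-boiling temperature, K.
    Pc: critical pressure, bar. Vc: critical molar volume, cm3/mol.
    w: acentric factor. sigma_lj: LJ diameter, Angstrom.
    eps_lj_over_kB: LJ energy constant, K.
    """

    name: str
    cas: str
    formula: str
    M: float
    Tc: float
    Tb: float
    Pc: float
    Vc: float
    w: float
    sigma_lj: float
    eps_lj_over_kB: float
    sources: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if not (self.Tc > self.Tb > 0):
            raise ValueError(f"{self.name}: require Tc > Tb > 0")
        if not (self.Pc > 0 and self.Vc > 0 and self.sigma_lj > 0):
            raise ValueError(f"{self.name}: Pc, Vc and sigma_lj must be positive")
        # eps/kB >= 0: the packaged table prints one entry (hydrogen) as 0.00.
        if self.eps_lj_over_kB < 0:
            raise ValueError(f"{self.name}: eps_lj_over_kB must be nonnegative")


@dataclass(frozen=True)
class SoluteLJ:
    """Solute Lennard-Jones parameters from critical constants."""

    eps_over_kB: float  # K
    sigma: float        # Angstrom

    def __post_init__(self) -> None:
        if not (self.eps_over_kB > 0 and self.sigma > 0):
            raise ValueError("LJ parameters must be strictly positive")


@dataclass(frozen=True)
class SolventLJ:
    """Solvent (state-dependent) Lennard-Jones parameters.

    rho_r1 and T_r1 record the reduced density/temperature the corresponding-
    states correction was evaluated at.
    """

    eps_over_kB: float  # K
    sigma: float        # Angstrom
    rho_r1: float
    T_r1: float

    def __post_init__(self) -> None:
        if not (self.eps_over_kB > 0 and self.sigma > 0):
            raise ValueError("LJ parameters must be strictly positive")


def vbp_from_vc(vc: float) -> float:
    """Molar volume at the normal boiling point from the critical volume.

    Tyn-Calus power law Vbp = 0.285 * Vc**1.048, both in cm3/mol.
    """
    if vc < 0:
        raise ValueError("critical volume must be nonnegative")
    return 0.285 * vc**1.048


def klincewicz_tc(M: float, Tb: float) -> float:
    """Critical temperature (K) from molar mass and normal boiling point.

    Klincewicz correlation Tc = 50.2 - 0.16*M + 1.41*Tb with M in g/mol and
    Tb in K. This is the two-input (non group-contribution) form.
    """
    if M < 0 or Tb <= 0:
        raise ValueError("require M >= 0 and Tb > 0")
    return 50.2 - 0.16 * M + 1.41 * Tb


def lee_kesler_omega(Tb: float, Tc: float, Pc: float) -> float:
    """Acentric factor from Tb (K), Tc (K) and Pc (bar).

    Lee-Kesler relation with theta = Tb/Tc; the critical pressure enters in
    atmospheres, so Pc is converted from bar internally.
    """
    if not (0 < Tb and Pc > 0):
        raise ValueError("require Tb > 0 and Pc > 0")
    theta = Tb / Tc
    if theta >= 1.0:
        raise ValueError("require Tb < Tc (theta < 1)")
    pc_atm = Pc / ATM_IN_BAR
    lt = math.log(theta)
    t6 = theta**6
    num = -math.log(pc_atm) - 5.92714 + 6.09648 / theta + 1.28862 * lt - 0.169347 * t6
    den = 15.2518 - 15.6875 / theta - 13.4721 * lt + 0.43577 * t6
    return num / den


def zhu_solute_lj(Tc2: float, Pc2: float) -> SoluteLJ:
    """Solute LJ parameters from critical temperature (K) and pressure (bar).

    eps/kB = Tc/1.313; sigma = (0.13 * eps / Pc)**(1/3) where eps = kB*Tc/1.313
    in J and Pc in Pa, i.e. the cube root of a molecular volume, returned in
    Angstrom.
    """
    if Tc2 <= 0 or Pc2 <= 0:
        raise ValueError("require Tc2 > 0 and Pc2 > 0")
    eps_over_kB = Tc2 / 1.313
    sigma_m = (0.13 * KB_J * eps_over_kB / (Pc2 * BAR_TO_PA)) ** (1.0 / 3.0)
    return SoluteLJ(eps_over_kB=eps_over_kB, sigma=sigma_m * M_TO_ANGSTROM)


def zhu_solvent_lj(Tc1: float, Vc1: float, rho_r1: float, T_r1: float) -> SolventLJ:
    """Solvent LJ parameters with a corresponding-states density/temperature
    correction.

    eps/kB = (Tc1/1.313) * (1 + 0.47527332*rho_r + (0.06300484
             + 0.12374707*rho_r)*T_r)
    sigma  = (0.31/rho_nc)**(1/3) * (1 - 0.0368868*rho_r + (0.00006945
             + 0.01089228*rho_r)*T_r)

    where rho_nc = NA/Vc1 is the number critical density in cm-3 and sigma is
    returned in Angstrom. rho_r and T_r are the solvent reduced density and
    temperature (state-dependent, both dimensionless and >= 0).
    """
    if Tc1 <= 0 or Vc1 <= 0:
        raise ValueError("require Tc1 > 0 and Vc1 > 0")
    if rho_r1 < 0 or T_r1 < 0:
        raise ValueError("reduced density/temperature must be nonnegative")
    b_eps = 1.0 + 0.47527332 * rho_r1 + (0.06300484 + 0.12374707 * rho_r1) * T_r1
    b_sig = 1.0 - 0.0368868 * rho_r1 + (0.00006945 + 0.01089228 * rho_r1) * T_r1
    rho_nc = AVOGADRO / Vc1  # cm^-3
    sigma_cm = (0.31 / rho_nc) ** (1.0 / 3.0) * b_sig
    return SolventLJ(
        eps_over_kB=(Tc1 / 1.313) * b_eps,
        sigma=sigma_cm * 1.0e8,
        rho_r1=rho_r1,
        T_r1=T_r1,
    )


class CompoundLookupError(KeyError):
    """Unknown compound key; carries near-match suggestions."""

    def __init__(self, key: str, suggestions: list[str]):
        self.key = key
        self.suggestions = suggestions
        hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
        super().__init__(f"unknown compound {key!r}{hint}")


# Names whose printed table row was collapsed into another entry.
_ALIASES = {"n-butanol": "1-butanol"}

_SOURCE_COLUMNS = ("src_Tc", "src_Tb", "src_Pc", "src_Vc", "src_w", "src_lj")


class CompoundTable:
    """Case-insensitive name/CAS index over CompoundProperties rows."""

    def __init__(self, compounds: list[CompoundProperties]):
        self._compounds = list(compounds)
        self._by_name = {c.name.lower(): c for c in self._compounds}
        self._by_cas: dict[str, CompoundProperties] = {}
        for c in self._compounds:
            if c.cas in self._by_cas:
                raise ValueError(f"duplicate CAS in compound table: {c.cas}")
            self._by_cas[c.cas] = c

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[CompoundProperties]:
        return iter(self._compounds)

    def __contains__(self, key: str) -> bool:
        try:
            self.lookup(key)
        except CompoundLookupError:
            return False
        return True

    def lookup(self, key: str) -> CompoundProperties:
        """Exact lookup by CAS or (case-insensitive) name."""
        k = key.strip()
        if k in self._by_cas:
            return self._by_cas[k]
        low = _ALIASES.get(k.lower(), k.lower())
        if low in self._by_name:
            return self._by_name[low]
        pool = list(self._by_name) + list(self._by_cas)
        raise CompoundLookupError(key, difflib.get_close_matches(low, pool, n=3))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name, "cas": c.cas, "formula": c.formula,
                "M": c.M, "Tc": c.Tc, "Tb": c.Tb, "Pc": c.Pc, "Vc": c.Vc,
                "w": c.w, "sigma_lj": c.sigma_lj,
                "eps_lj_over_kB": c.eps_lj_over_kB,
            }
            for c in self._compounds
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompoundTable":
        compounds = []
        for _, row in df.iterrows():
            sources = {
                col[4:]: str(row[col])
                for col in _SOURCE_COLUMNS
                if col in df.columns and pd.notna(row[col])
            }
            compounds.append(
                CompoundProperties(
                    name=str(row["name"]),
                    cas=str(row["cas"]),
                    formula=str(row.get("formula", "")),
                    M=float(row["M"]),
                    Tc=float(row["Tc"]),
                    Tb=float(row["Tb"]),
                    Pc=float(row["Pc"]),
                    Vc=float(row["Vc"]),
                    w=float(row["w"]),
                    sigma_lj=float(row["sigma_lj"]),
                    eps_lj_over_kB=float(row["eps_lj_over_kB"]),
                    sources=sources,
                )
            )
        return cls(compounds)

    def merged_with(self, other: "CompoundTable") -> "CompoundTable":
        """New table with rows of `other` appended (CAS must stay unique)."""
        return CompoundTable(self._compounds + list(other))


_PACKAGED: CompoundTable | None = None


def load_compounds(path: str | None = None) -> CompoundTable:
    """Load a compound table; with no path, the packaged table (cached)."""
    global _PACKAGED
    if path is None:
        if _PACKAGED is None:
            src = resources.files("tracerdiff.data").joinpath("compounds.csv")
            with resources.as_file(src) as p:
                _PACKAGED = CompoundTable.from_frame(pd.read_csv(p))
        return _PACKAGED
    return CompoundTable.from_frame(pd.read_csv(path))


def lookup_compound(key: str, table: CompoundTable | None = None) -> CompoundProperties:
    """Exact-match lookup by name (case-insensitive) or CAS number."""
    return (table or load_compounds()).lookup(key)
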