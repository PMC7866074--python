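"""Four benchmark models for the tracer diffusion coefficient D12.

* Wilke-Chang: hydrodynamic (Stokes-Einstein descended), predictive.
* Tyn-Calus: hydrodynamic, predictive.
* Magalhaes et al.: 2-parameter per-system correlation D12 = a*T/mu1 + b.
* Zhu et al.: hybrid Lennard-Jones model (free-volume times energy
  contributions) for nonpolar solvents, predictive.

D12 is always in cm2/s, T in K, viscosity mu1 in cP, molar volumes in
cm3/mol, density rho1 in g/cm3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._constants import ANGSTROM_TO_CM, AVOGADRO, KB_ERG
from .compounds import CompoundProperties, zhu_solute_lj, zhu_solvent_lj

__all__ = [
    "association_factor",
    "wilke_chang",
    "tyn_calus",
    "MagalhaesFit",
    "MagalhaesFitError",
    "MIN_MAGALHAES_POINTS",
    "magalhaes_fit",
    "magalhaes_predict",
    "ZhuState",
    "zhu_state",
    "zhu_d12",
    "ZHU_EQ5_CONSTANTS",
]

# Wilke-Chang solvent association factors, keyed by CAS and common name.
_ASSOCIATION = {
    "67-56-1": 1.9, "methanol": 1.9,
    "64-17-5": 1.5, "ethanol": 1.5,
}


def association_factor(solvent: str | CompoundProperties | None) -> float:
    """Wilke-Chang association factor phi for a solvent identity.

    1.9 for methanol, 1.5 for ethanol, 1.0 for unassociated solvents.
    """
    if solvent is None:
        return 1.0
    if isinstance(solvent, CompoundProperties):
        keys = (solvent.cas, solvent.name.lower())
    else:
        keys = (solvent, solvent.lower())
    for k in keys:
        if k in _ASSOCIATION:
            return _ASSOCIATION[k]
    return 1.0


def wilke_chang(T: float, mu1: float, M1: float, Vbp2: float, phi: float = 1.0) -> float:
    """Wilke-Chang estimate of D12 (cm2/s).

    D12 = 7.4e-8 * (phi*M1)**0.5 * T / (mu1 * Vbp2**0.6)
    with M1 the solvent molar mass (g/mol) and Vbp2 the solute molar volume
    at its normal boiling point (cm3/mol).
    """
    if T <= 0 or mu1 <= 0:
        raise ValueError("temperature and viscosity must be positive")
    if M1 <= 0 or Vbp2 <= 0 or phi <= 0:
        raise ValueError("M1, Vbp2 and phi must be positive")
    return 7.4e-8 * math.sqrt(phi * M1) * T / (mu1 * Vbp2**0.6)


def tyn_calus(T: float, mu1: float, Vbp1: float, Vbp2: float) -> float:
    """Tyn-Calus estimate of D12 (cm2/s).

    D12 = 8.93e-8 * Vbp1**0.267 / Vbp2**0.433 * T / mu1, with the solvent
    boiling-point volume in the numerator (standard placement of the
    exponents).
    """
    if min(T, mu1, Vbp1, Vbp2) <= 0:
        raise ValueError("all inputs must be positive")
    return 8.93e-8 * Vbp1**0.267 / Vbp2**0.433 * T / mu1


# --- Magalhaes et al. 2-parameter correlation -------------------------------

#: Minimum number of distinct T/mu1 values for a valid fit: two parameters
#: plus one residual degree of freedom.
MIN_MAGALHAES_POINTS = 3


class MagalhaesFitError(ValueError):
    """Too few points (or a degenerate regressor) to fit a system."""


@dataclass(frozen=True)
class MagalhaesFit:
    """Per-system parameters of D12 = a*T/mu1 + b.

    a in cm2 s-1 cP K-1, b in cm2/s.
    """

    a: float
    b: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < MIN_MAGALHAES_POINTS:
            raise MagalhaesFitError(
                f"need at least {MIN_MAGALHAES_POINTS} points, got {self.n_points}"
            )
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise MagalhaesFitError("fitted parameters must be finite")


def magalhaes_fit(records: Iterable[Sequence[float]]) -> MagalhaesFit:
    """Ordinary least squares of D12 on the single regressor x = T/mu1.

    `records` yields (T, mu1, D12) triples; at least three points with
    distinct T/mu1 are required.
    """
    pts = [(float(T), float(mu), float(d)) for T, mu, d in records]
    if len(pts) < MIN_MAGALHAES_POINTS:
        raise MagalhaesFitError(
            f"need at least {MIN_MAGALHAES_POINTS} points, got {len(pts)}"
        )
    x = np.array([T / mu for T, mu, _ in pts])
    y = np.array([d for _, _, d in pts])
    if np.ptp(x) == 0.0:
        raise MagalhaesFitError("zero variance in T/mu1; slope is unidentifiable")
    a, b = np.polyfit(x, y, 1)
    return MagalhaesFit(a=float(a), b=float(b), n_points=len(pts))


def magalhaes_predict(fit: MagalhaesFit, T: float, mu1: float) -> float:
    """Evaluate a fitted correlation at (T, mu1).

    Extreme extrapolation may produce a negative value; it is returned as-is
    with a RuntimeWarning.
    """
    d12 = fit.a * T / mu1 + fit.b
    if d12 < 0:
        warnings.warn(
            "Magalhaes correlation extrapolated to a negative D12",
            RuntimeWarning,
            stacklevel=2,
        )
    return d12


# --- Zhu et al. hybrid Lennard-Jones model ----------------------------------

#: Constants of the reduced-density/temperature correction factors, kept in
#: one table so a revision against the original source touches one place.
ZHU_EQ5_CONSTANTS = {
    "f1_rho_exp": 1.029079,
    "f1_T_exp": 0.165377,
    "f2_rho_exp": 0.126978,
    "f2_num": 0.596103,
    "f2_den": 0.539292,
    "f2_T_exp_a": 0.400152,
    "f2_T_exp_b": 0.41054,
    "f2_const": 0.68856,
    "k12d": 0.7926,
}


def combine_lj(
    sigma1: float, eps1_over_kB: float, sigma2: float, eps2_over_kB: float
) -> tuple[float, float, float]:
    """Binary LJ parameters (sigma12, eps12/kB, k12d) from pure-component ones.

    k12d = 0.7926 (sigma2 - sigma1)/(sigma2 + sigma1) corrects the
    arithmetic-mean diameter; the energy is the geometric mean.
    """
    if min(sigma1, sigma2, eps1_over_kB, eps2_over_kB) <= 0:
        raise ValueError("LJ parameters must be positive")
    k12d = ZHU_EQ5_CONSTANTS["k12d"] * (sigma2 - sigma1) / (sigma2 + sigma1)
    sigma12 = (1.0 - k12d) * (sigma1 + sigma2) / 2.0
    eps12 = math.sqrt(eps1_over_kB * eps2_over_kB)
    return sigma12, eps12, k12d


@dataclass(frozen=True)
class ZhuState:
    """Reduced state and binary LJ parameters feeding the Zhu model.

    sigma12 in Angstrom, eps12_over_kB in K, rho_n1 (solvent number density)
    in cm-3, m1 (mass of one solvent molecule) in g.
    """

    sigma12: float
    eps12_over_kB: float
    k12d: float
    T12_star: float
    rho12_star: float
    rho_n1: float
    m1: float

    def __post_init__(self) -> None:
        if min(self.sigma12, self.eps12_over_kB, self.rho_n1, self.m1) <= 0:
            raise ValueError("sigma12, eps12, rho_n1 and m1 must be positive")
        if self.T12_star <= 0 or self.rho12_star < 0:
            raise ValueError("invalid reduced state")
        if abs(self.k12d) >= 1:
            raise ValueError("|k12d| must be < 1")


def zhu_state(
    T: float, rho1: float, solvent: CompoundProperties, solute: CompoundProperties
) -> ZhuState:
    """Build the reduced state for the Zhu model at (T, rho1).

    Pure-component LJ parameters come from the model's own corresponding-
    states estimators (not from tabulated LJ values): the solvent set is
    evaluated at rho_r1 = rho1/(M1/Vc1) and T_r1 = T/Tc1. Combining rules:

        k12d    = 0.7926 (sigma2 - sigma1) / (sigma2 + sigma1)
        sigma12 = (1 - k12d)(sigma1 + sigma2)/2
        eps12   = sqrt(eps1 * eps2)
    """
    if T <= 0 or rho1 <= 0:
        raise ValueError("temperature and density must be positive")
    rho_c1 = solvent.M / solvent.Vc  # g/cm3
    lj1 = zhu_solvent_lj(solvent.Tc, solvent.Vc, rho1 / rho_c1, T / solvent.Tc)
    lj2 = zhu_solute_lj(solute.Tc, solute.Pc)
    sigma12, eps12, k12d = combine_lj(
        lj1.sigma, lj1.eps_over_kB, lj2.sigma, lj2.eps_over_kB
    )
    rho_n1 = rho1 * AVOGADRO / solvent.M  # cm^-3
    return ZhuState(
        sigma12=sigma12,
        eps12_over_kB=eps12,
        k12d=k12d,
        T12_star=T / eps12,
        rho12_star=rho_n1 * (sigma12 * ANGSTROM_TO_CM) ** 3,
        rho_n1=rho_n1,
        m1=solvent.M / AVOGADRO,
    )


def zhu_d12(state: ZhuState) -> float:
    """Zhu et al. hybrid-model D12 (cm2/s) for a reduced state.

    D12 = D_kin * F1 * F2 * F3 with the dilute-gas kinetic prefactor

        D_kin = (3/8) sqrt(kB*T / (pi*m1)) / (rho_n1 * sigma12**2)

    (CGS units internally) and the density corrections

        F1 = 1 - rho***1.029079 / T***0.165377
        F2 = 1 + rho***0.126978 * [0.596103 (rho*-1) /
             (0.539292 (rho*-1) + T***(0.400152 - 0.41054 rho*)) + 0.68856]
        F3 = exp(-rho***2 / (2 T*))

    At rho* = 0 the corrections reduce to 1 and D12 equals the kinetic
    prefactor. F1 <= 0 marks a state outside the model's validity; the value
    is still returned, with a RuntimeWarning.
    """
    c = ZHU_EQ5_CONSTANTS
    T = state.T12_star * state.eps12_over_kB  # K
    sigma_cm = state.sigma12 * ANGSTROM_TO_CM
    d_kin = (
        (3.0 / 8.0)
        * math.sqrt(KB_ERG * T / (math.pi * state.m1))
        / (state.rho_n1 * sigma_cm**2)
    )
    rs, ts = state.rho12_star, state.T12_star
    if rs == 0.0:
        return d_kin
    f1 = 1.0 - rs ** c["f1_rho_exp"] / ts ** c["f1_T_exp"]
    if f1 <= 0:
        warnings.warn(
            "reduced density outside Zhu model validity (free-volume factor <= 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    f2 = 1.0 + rs ** c["f2_rho_exp"] * (
        c["f2_num"] * (rs - 1.0)
        / (c["f2_den"] * (rs - 1.0) + ts ** (c["f2_T_exp_a"] - c["f2_T_exp_b"] * rs))
        + c["f2_const"]
    )
    f3 = math.exp(-(rs**2) / (2.0 * ts))
    return d_kin * f1 * f2 * f3
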