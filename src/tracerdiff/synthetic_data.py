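"""Synthetic diffusivity databases with the schema and statistical shape of
the experimental compilation.

Real D12 compilations are scattered across primary sources; this generator
emulates their structure so every pipeline stage is testable end to end:
per-system constant compound properties, narrow per-system temperature and
viscosity windows, multiplicative (lognormal) measurement noise, and a
choice of data-generating mechanism:

* ``wilke_chang`` — records exactly follow the Wilke-Chang equation
  (noiseless data make its AARD zero by construction);
* ``magalhaes_affine`` — per-system affine law D12 = a*T/mu1 + b with known
  (a, b), for parameter-recovery tests;
* ``nonlinear_gboost_target`` — a smooth nonlinear function of the five
  nonpolar model variables (T, mu1, M2, Pc2, M1), a target a boosted
  ensemble should learn and a linear model should not.

Default property ranges are the applicability domains of the published
polar/nonpolar models; densities span the compilation's 0.30-1.65 g/cm3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classic_models import wilke_chang
from .compounds import CompoundProperties, CompoundTable, vbp_from_vc
from .dataset import DiffusionRecord

__all__ = [
    "MECHANISMS",
    "POLAR_RANGES",
    "NONPOLAR_RANGES",
    "GeneratorSpec",
    "GeneratedData",
    "generate",
    "inject_collinearity",
]

MECHANISMS = ("wilke_chang", "magalhaes_affine", "nonlinear_gboost_target")

#: Applicability domain of the published polar model (plus generic spans of
#: the compound table for properties the domain statement does not cover).
POLAR_RANGES: dict[str, tuple[float, float]] = {
    "T": (268.0, 554.0),
    "mu1": (0.0241, 17.6),
    "M2": (17.0, 674.0),
    "Pc2": (4.1, 221.2),
    "M1": (20.0, 113.0),
    "eps_lj1": (208.0, 2121.0),
    "rho1": (0.30, 1.65),
    "Tc1": (300.0, 1300.0),
    "Tc2": (190.0, 1469.0),
    "Pc1": (4.1, 221.2),
    "Vc1": (56.0, 1219.0),
    "Vc2": (56.0, 1878.0),
    "sigma_lj1": (2.9, 10.0),
    "sigma_lj2": (2.9, 10.0),
    "eps_lj2": (100.0, 1137.0),
    "w1": (0.0, 1.2),
    "w2": (0.0, 1.2),
}

#: Applicability domain of the published nonpolar model, same generic spans.
NONPOLAR_RANGES: dict[str, tuple[float, float]] = {
    **POLAR_RANGES,
    "T": (213.0, 567.0),
    "mu1": (0.0229, 2.92),
    "M2": (2.0, 461.0),
    "Pc2": (12.5, 96.3),
    "M1": (30.0, 395.0),
    "eps_lj1": (150.0, 1200.0),
}

#: Noiseless D12 must fall in the physical decade span of liquid-phase
#: tracer diffusivities; systems outside are redrawn.
_D12_BAND = (2.0e-7, 5.0e-4)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic database."""

    n_systems: int = 60
    points_per_system: tuple[int, int] = (4, 15)
    mechanism: str = "nonlinear_gboost_target"
    noise_cv: float = 0.10
    polarity_mix: float = 0.5
    seed: int = 0
    property_ranges: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not 0.0 <= self.polarity_mix <= 1.0:
            raise ValueError("polarity_mix must lie in [0, 1]")
        if self.n_systems < 1 or self.points_per_system[0] < 1:
            raise ValueError("need at least one system and one point per system")
        if self.points_per_system[0] > self.points_per_system[1]:
            raise ValueError("points_per_system range is empty")
        for name, (lo, hi) in (self.property_ranges or {}).items():
            if not lo < hi:
                raise ValueError(f"empty range for {name!r}")


@dataclass(frozen=True)
class GeneratedData:
    """Records plus the synthetic compound table and the ground truth."""

    records: list[DiffusionRecord]
    compounds: CompoundTable
    truth: dict = field(default_factory=dict)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _nonlinear_d12(T, mu1, M2, Pc2, M1):
    """Smooth nonlinear ground truth over the five nonpolar variables."""
    base = (
        2.0e-5
        * (T / 400.0) ** 1.6
        * (0.05 + mu1) ** -0.7
        * (M2 / 100.0) ** -0.45
        * (Pc2 / 40.0) ** 0.2
        * (M1 / 100.0) ** -0.25
    )
    mod = (
        1.0
        + 0.35 * np.tanh((T - 390.0) / 80.0) * np.sin(0.02 * M2)
        + 0.15 * np.cos(0.01 * M1)
    )
    return base * mod


def _draw_compound(rng, name, cas, ranges, m_key, pc_key, vc_key, eps_key, sig_key, w_key):
    Tc = _log_uniform(rng, *ranges["Tc1" if m_key == "M1" else "Tc2"])
    return CompoundProperties(
        name=name,
        cas=cas,
        formula="synthetic",
        M=_log_uniform(rng, *ranges[m_key]),
        Tc=Tc,
        Tb=Tc * rng.uniform(0.55, 0.78),
        Pc=_log_uniform(rng, *ranges[pc_key]),
        Vc=_log_uniform(rng, *ranges[vc_key]),
        w=rng.uniform(*ranges[w_key]),
        sigma_lj=_log_uniform(rng, *ranges[sig_key]),
        eps_lj_over_kB=_log_uniform(rng, *ranges[eps_key]),
    )


def generate(spec: GeneratorSpec) -> GeneratedData:
    """Draw a synthetic database, deterministically under ``spec.seed``.

    Per system: one synthetic solvent and solute (properties log-uniform in
    the polarity's ranges, constant across the system's records), a narrow
    temperature window and a viscosity sub-decade; per record: T, mu1, rho1
    within those windows and D12 from the mechanism times lognormal noise
    exp(eps), eps ~ N(0, sigma) with sigma = sqrt(ln(1 + noise_cv**2)).
    Systems whose noiseless D12 would leave the physical decade span
    (2e-7 to 5e-4 cm2/s) are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_ln = math.sqrt(math.log1p(spec.noise_cv**2))
    n_polar = int(round(spec.n_systems * spec.polarity_mix))

    records: list[DiffusionRecord] = []
    compounds: list[CompoundProperties] = []
    truth: dict = {"mechanism": spec.mechanism, "seed": spec.seed, "systems": {}}

    for i in range(spec.n_systems):
        polarity = "polar" if i < n_polar else "nonpolar"
        ranges = dict(POLAR_RANGES if polarity == "polar" else NONPOLAR_RANGES)
        ranges.update(spec.property_ranges or {})
        solvent_cas = f"9{i:04d}-10-{1 + i % 9}"
        solute_cas = f"9{i:04d}-20-{1 + i % 9}"
        n_pts = int(rng.integers(spec.points_per_system[0], spec.points_per_system[1] + 1))

        for _attempt in range(300):
            solvent = _draw_compound(
                rng, f"solvent-{i:03d}", solvent_cas, ranges,
                "M1", "Pc1", "Vc1", "eps_lj1", "sigma_lj1", "w1",
            )
            solute = _draw_compound(
                rng, f"solute-{i:03d}", solute_cas, ranges,
                "M2", "Pc2", "Vc2", "eps_lj2", "sigma_lj2", "w2",
            )
            t_lo, t_hi = ranges["T"]
            half = rng.uniform(10.0, 40.0)
            center = rng.uniform(t_lo + half, t_hi - half)
            T = rng.uniform(center - half, center + half, size=n_pts)
            # each system's series spans a half-to-one decade of viscosity,
            # as temperature series in real compilations do; this keeps the
            # T/mu1 regressor informative enough for per-system fits
            mu_lo_g, mu_hi_g = ranges["mu1"]
            factor = rng.uniform(5.0, 12.0)
            mu_lo = _log_uniform(rng, mu_lo_g, mu_hi_g / factor)
            mu1 = np.exp(rng.uniform(np.log(mu_lo), np.log(mu_lo * factor), size=n_pts))
            rho1 = rng.uniform(*ranges["rho1"], size=n_pts)

            if spec.mechanism == "wilke_chang":
                vbp2 = vbp_from_vc(solute.Vc)
                d12 = np.array(
                    [wilke_chang(t, m, solvent.M, vbp2, phi=1.0) for t, m in zip(T, mu1)]
                )
                params = {"phi": 1.0, "Vbp2": vbp2}
            elif spec.mechanism == "magalhaes_affine":
                x = T / mu1
                d_mid = _log_uniform(rng, 3.0e-6, 3.0e-5)
                a = d_mid / float(np.median(x))
                b = rng.uniform(-0.05, 0.05) * d_mid
                d12 = a * x + b
                params = {"a": a, "b": b}
            else:
                d12 = _nonlinear_d12(T, mu1, solute.M, solute.Pc, solvent.M)
                params = {}

            if np.all((d12 > _D12_BAND[0]) & (d12 < _D12_BAND[1])):
                break
        else:
            raise RuntimeError("could not draw a system inside the physical D12 band")

        noisy = d12 * np.exp(rng.normal(0.0, sigma_ln, size=n_pts))
        compounds.extend([solvent, solute])
        truth["systems"][f"{solvent_cas}|{solute_cas}"] = {
            "polarity": polarity, "n_points": n_pts, **params,
        }
        for t, m, r, d in zip(T, mu1, rho1, noisy):
            records.append(
                DiffusionRecord(
                    solvent=solvent_cas, solute=solute_cas,
                    T=float(t), rho1=float(r), mu1=float(m), D12=float(d),
                    polarity=polarity, source="synthetic",
                )
            )
    return GeneratedData(records=records, compounds=CompoundTable(compounds), truth=truth)


def inject_collinearity(
    table: pd.DataFrame,
    template: Mapping[str, Mapping[str, float | str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Append derived columns that are (noisy-)affine in existing ones.

    ``template`` maps each new column name to a spec with keys ``base``
    (existing column), ``scale``, ``offset`` and ``noise_sd`` (std of
    additive Gaussian noise; 0 plants an exact collinear pair). Row count is
    preserved.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for name, cfg in template.items():
        base = cfg["base"]
        if base not in table.columns:
            raise KeyError(f"template for {name!r} references unknown column {base!r}")
        scale = float(cfg.get("scale", 1.0))
        offset = float(cfg.get("offset", 0.0))
        noise_sd = float(cfg.get("noise_sd", 0.0))
        col = scale * table[base].to_numpy() + offset
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=len(table))
        out[name] = col
    return out
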