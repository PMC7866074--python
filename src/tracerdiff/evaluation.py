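"""Performance metrics and per-system report tables.

AARD (average absolute relative deviation, in %) is the headline metric of
the diffusion literature; RMSE and the coefficients of determination R2
(train) / Q2 (test) complement it. Reports aggregate per system: the
*global* AARD pools all points (equivalently, the NDP-weighted mean of
per-system AARDs), while the *arithmetic* AARD averages systems unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

__all__ = ["aard", "rmse", "r_squared", "EvalReport", "evaluate"]


def _as_arrays(calc, exp) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(calc, dtype=float)
    e = np.asarray(exp, dtype=float)
    if c.shape != e.shape:
        raise ValueError("calc and exp must have equal length")
    if c.size < 1:
        raise ValueError("need at least one point")
    return c, e


def aard(calc, exp) -> float:
    """Average absolute relative deviation, percent.

    100/NDP * sum(|calc_i - exp_i| / exp_i); reference values must be
    nonzero.
    """
    c, e = _as_arrays(calc, exp)
    if np.any(e == 0.0):
        raise ValueError("reference values must be nonzero")
    return float(100.0 * np.mean(np.abs((c - e) / e)))


def rmse(calc, exp) -> float:
    """Root mean squared deviation (same units as the inputs)."""
    c, e = _as_arrays(calc, exp)
    return float(np.sqrt(np.mean((c - e) ** 2)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination about the mean of `obs`.

    1 for perfect prediction, 0 for a constant predictor at the observed
    mean, negative for anything worse. Called R2 on training data and Q2 on
    held-out data.
    """
    p, o = _as_arrays(pred, obs)
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(o) == 0.0:
        raise ValueError("zero variance in observations; R2 undefined")
    return float(r2_score(o, p))


@dataclass(frozen=True)
class EvalReport:
    """Per-system and pooled deviations in the layout of the report tables."""

    per_system: Mapping[Hashable, tuple[int, float]]  # key -> (NDP, AARD %)
    n_sys: int
    ndp_total: int
    global_aard: float
    aard_arith: float
    aard_min: float
    aard_max: float
    rmse: float
    r2_train: float | None = None
    q2_test: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-system table (NDP, AARD %), one row per system."""
        rows = [
            {"system": k, "NDP": ndp, "AARD_pct": a}
            for k, (ndp, a) in self.per_system.items()
        ]
        return pd.DataFrame(rows, columns=["system", "NDP", "AARD_pct"])

    def summary(self) -> pd.DataFrame:
        """One-row summary mirroring the report-table column order."""
        return pd.DataFrame(
            [
                {
                    "NSys": self.n_sys,
                    "NDP": self.ndp_total,
                    "Global_AARD_pct": self.global_aard,
                    "AARD_arith_pct": self.aard_arith,
                    "AARD_min_pct": self.aard_min,
                    "AARD_max_pct": self.aard_max,
                    "RMSE": self.rmse,
                    "Q2": self.q2_test,
                    "R2": self.r2_train,
                }
            ]
        )


def evaluate(
    systems: Sequence[Hashable],
    calc,
    exp,
    r2_train: float | None = None,
    q2_test: float | None = None,
) -> EvalReport:
    """Aggregate predictions into a per-system + pooled report.

    `systems` tags each (calc, exp) pair with its system key. Global AARD is
    the pooled deviation over all points; the arithmetic AARD averages the
    per-system values unweighted.
    """
    c, e = _as_arrays(calc, exp)
    if len(systems) != c.size:
        raise ValueError("every prediction must be tagged with a system")
    per_system: dict[Hashable, tuple[int, float]] = {}
    keys = pd.Series(list(systems))
    for key in keys.unique():
        idx = (keys == key).to_numpy()
        per_system[key] = (int(idx.sum()), aard(c[idx], e[idx]))
    per_aards = [a for _, a in per_system.values()]
    return EvalReport(
        per_system=per_system,
        n_sys=len(per_system),
        ndp_total=int(c.size),
        global_aard=aard(c, e),
        aard_arith=float(np.mean(per_aards)),
        aard_min=float(np.min(per_aards)),
        aard_max=float(np.max(per_aards)),
        rmse=rmse(c, e),
        r2_train=r2_train,
        q2_test=q2_test,
    )
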