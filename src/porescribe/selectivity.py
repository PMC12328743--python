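"""I/V regression, reversal potentials and GHK ion selectivity.

Under a KCl gradient (e.g. 150 mM cis / 730 mM trans) a perfectly
non-selective pore reverses at 0 mV, while the Nernst potentials for pure
K+ or pure Cl- selectivity bound the attainable reversal potentials.  The
Goldman-Hodgkin-Katz voltage equation for a single 1:1 salt links the
reversal potential to the permeability ratio P_K/P_Cl:

    psi_rev = (RT/F) ln[(P_K [K]_trans + P_Cl [Cl]_cis)
                        / (P_K [K]_cis + P_Cl [Cl]_trans)]

with the potential of the cis side taken relative to trans (positive when
cis is more positive).  The inversion is algebraic and exact inside the
Nernst limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "SaltCondition",
    "IVFit",
    "SelectivityResult",
    "fit_iv",
    "ghk_reversal",
    "nernst_limits",
    "permeability_ratio_from_reversal",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K), CODATA
FARADAY = 96485.33212  # C / mol, CODATA


@dataclass(frozen=True)
class SaltCondition:
    """Symmetric-salt (KCl) bath concentrations in mM and temperature in K."""

    cis_kcl_mM: float = 150.0
    trans_kcl_mM: float = 730.0
    temperature_K: float = 298.15

    def __post_init__(self):
        if self.cis_kcl_mM <= 0 or self.trans_kcl_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_over_f_mV(self) -> float:
        return 1000.0 * GAS_CONSTANT * self.temperature_K / FARADAY


@dataclass(frozen=True)
class IVFit:
    slope_nS: float
    reversal_mV: Optional[float]  # None when the slope is zero
    r_squared: float
    residual_sd_pA: float
    level_label: Optional[str] = None


@dataclass(frozen=True)
class SelectivityResult:
    p_k_over_p_cl: float
    classification: str  # cation-selective | anion-selective | non-selective
    tolerance_mV: float


def fit_iv(
    voltages_mV: Sequence[float],
    currents_pA: Sequence[float],
    level_label: Optional[str] = None,
) -> IVFit:
    """OLS of current on voltage; the slope is the conductance in nS and the
    voltage-axis intercept (where I = 0) is the reversal potential."""
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(currents_pA, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("at least two distinct voltages required")
    res = stats.linregress(v, i)
    slope, intercept = float(res.slope), float(res.intercept)
    reversal = -intercept / slope if slope != 0 else None
    resid = i - (slope * v + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(1, v.size - 2)))
    return IVFit(slope, reversal, float(res.rvalue**2), residual_sd, level_label)


def ghk_reversal(p_ratio: float, salt: SaltCondition) -> float:
    """GHK reversal potential in mV for P_K/P_Cl = p_ratio (cis vs trans)."""
    if p_ratio <= 0:
        raise ValueError("p_ratio must be positive")
    c, t = salt.cis_kcl_mM, salt.trans_kcl_mM
    return salt.rt_over_f_mV * math.log((p_ratio * t + c) / (p_ratio * c + t))


def nernst_limits(salt: SaltCondition) -> tuple[float, float]:
    """The open interval (in mV) of reversal potentials attainable by any
    finite permeability ratio; its endpoints are the pure-Cl and pure-K
    Nernst potentials for the gradient."""
    nernst_k = salt.rt_over_f_mV * math.log(salt.trans_kcl_mM / salt.cis_kcl_mM)
    return (min(-nernst_k, nernst_k), max(-nernst_k, nernst_k))


def permeability_ratio_from_reversal(
    reversal_mV: float,
    salt: SaltCondition,
    tolerance_mV: float = 2.0,
) -> SelectivityResult:
    """Exact inversion of the GHK voltage equation for a single 1:1 salt.

    With e = exp(psi F / RT):  P_K/P_Cl = (e*trans - cis) / (trans - e*cis).
    Reversals at or beyond the Nernst limits have no finite ratio and are
    rejected.  The pore is called non-selective when |psi_rev| is within
    the tolerance (default 2 mV).
    """
    lo, hi = nernst_limits(salt)
    if not lo < reversal_mV < hi:
        raise ValueError(
            f"reversal {reversal_mV:g} mV at/outside Nernst limits "
            f"({lo:.2f}, {hi:.2f}) mV: permeability ratio undefined"
        )
    e = math.exp(reversal_mV / salt.rt_over_f_mV)
    c, t = salt.cis_kcl_mM, salt.trans_kcl_mM
    ratio = (e * t - c) / (t - e * c)
    if abs(reversal_mV) <= tolerance_mV:
        label = "non-selective"
    elif ratio > 1:
        label = "cation-selective"
    else:
        label = "anion-selective"
    return SelectivityResult(ratio, label, tolerance_mV)
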