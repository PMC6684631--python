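"""Seawater CO2-system speciation from total alkalinity and DIC.

Alkalinity is modelled with carbonate, borate and water contributions:

    TA = [HCO3-] + 2[CO3 2-] + [B(OH)4-] + [OH-] - [H+]

on the total pH scale. Equilibrium constants:

* K0  — CO2 solubility, Weiss (1974)
* K1, K2 — carbonic acid, Lueker, Dickson & Keeling (2000), total scale
* KB  — boric acid, Dickson (1990)
* KW  — water, Millero (1995)
* Total boron from salinity, Uppstrom (1974)

The pH root is found by bisection over pH in [2, 12], which brackets the
solution for any physically sensible alkalinity/DIC pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SeawaterState",
    "CarbonateSpeciation",
    "equilibrium_constants",
    "solve_speciation",
    "pco2_alkalinity_response",
    "DEFAULT_STATE",
]

_PH_LO, _PH_HI = 2.0, 12.0
_PH_TOL = 1e-12


@dataclass(frozen=True)
class SeawaterState:
    """Total alkalinity / DIC definition of a carbonate-system problem.

    Concentrations are mol kg^-1 of seawater.
    """

    alkalinity: float
    dic: float
    temperature: float = 25.0  # deg C
    salinity: float = 35.0
    total_boron: float | None = None  # mol kg^-1; default from salinity

    def __post_init__(self) -> None:
        if self.alkalinity <= 0:
            raise ValueError("alkalinity must be positive")
        if self.dic < 0:
            raise ValueError("DIC must be non-negative")
        if not (0.0 <= self.salinity <= 45.0):
            raise ValueError("salinity outside [0, 45]")

    @property
    def boron(self) -> float:
        if self.total_boron is not None:
            return self.total_boron
        # Uppstrom (1974): TB = 0.000416 * S / 35 mol kg^-1
        return 0.000416 * self.salinity / 35.0


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Solved speciation; concentrations mol kg^-1, pCO2 in microatmospheres."""

    pH: float
    co2_aq: float
    hco3: float
    co3: float
    pco2: float
    constants: dict = field(default_factory=dict, repr=False)


def equilibrium_constants(temperature: float, salinity: float) -> dict[str, float]:
    """K0, K1, K2, KB, KW at in situ T (deg C) and practical salinity.

    Total pH scale; K0 in mol kg^-1 atm^-1, others in mol kg^-1.
    """
    t_k = temperature + 273.15
    s = salinity

    # Weiss (1974) CO2 solubility
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / t_k)
        + 23.3585 * math.log(t_k / 100.0)
        + s * (0.023517 - 0.023656 * (t_k / 100.0) + 0.0047036 * (t_k / 100.0) ** 2)
    )
    k0 = math.exp(ln_k0)

    # Lueker et al. (2000), total scale
    pk1 = (
        3633.86 / t_k
        - 61.2172
        + 9.6777 * math.log(t_k)
        - 0.011555 * s
        + 0.0001152 * s * s
    )
    pk2 = (
        471.78 / t_k
        + 25.929
        - 3.16967 * math.log(t_k)
        - 0.01781 * s
        + 0.0001122 * s * s
    )
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson (1990) boric acid, total scale
    sqrt_s = math.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s)
        / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        - (24.4344 + 25.085 * sqrt_s + 0.2474 * s) * math.log(t_k)
        + 0.053105 * sqrt_s * t_k
    )
    kb = math.exp(ln_kb)

    # Millero (1995) water dissociation
    ln_kw = (
        148.9802
        - 13847.26 / t_k
        - 23.6521 * math.log(t_k)
        + (-5.977 + 118.67 / t_k + 1.0495 * math.log(t_k)) * sqrt_s
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    return {
        "K0": k0,
        "K1": k1,
        "K2": k2,
        "KB": kb,
        "KW": kw,
        "pH_scale": "total",
        "parameterization": "Weiss74/Lueker00/Dickson90/Millero95/Uppstrom74",
    }


def _alkalinity_at_h(h: float, dic: float, boron: float, k: dict[str, float]) -> float:
    """Total alkalinity implied by [H+] given DIC and total boron."""
    k1, k2 = k["K1"], k["K2"]
    denom = h * h + k1 * h + k1 * k2
    carb_alk = dic * (k1 * h + 2.0 * k1 * k2) / denom
    borate = boron * k["KB"] / (k["KB"] + h)
    return carb_alk + borate + k["KW"] / h - h


def solve_speciation(state: SeawaterState) -> CarbonateSpeciation:
    """Solve the alkalinity balance for [H+] and return full speciation.

    Raises ``ValueError`` when the alkalinity cannot be matched anywhere in
    pH [2, 12] (no bracketed root).
    """
    k = equilibrium_constants(state.temperature, state.salinity)
    tb = state.boron

    def residual(ph: float) -> float:
        return _alkalinity_at_h(10.0 ** (-ph), state.dic, tb, k) - state.alkalinity

    lo, hi = _PH_LO, _PH_HI
    f_lo, f_hi = residual(lo), residual(hi)
    # TA(H) is monotone increasing in pH: acid side short of TA, basic side over.
    if f_lo > 0 or f_hi < 0:
        raise ValueError("alkalinity balance has no root in pH [2, 12]")
    while hi - lo > _PH_TOL:
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
    ph = 0.5 * (lo + hi)
    h = 10.0 ** (-ph)

    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2_aq = state.dic * h * h / denom
    hco3 = state.dic * k["K1"] * h / denom
    co3 = state.dic * k["K1"] * k["K2"] / denom
    pco2 = co2_aq / k["K0"] * 1e6  # atm -> microatm

    return CarbonateSpeciation(
        pH=ph, co2_aq=co2_aq, hco3=hco3, co3=co3, pco2=pco2, constants=k
    )


#: Documented default "present-day" surface-ocean state (not a measured value).
DEFAULT_STATE = SeawaterState(alkalinity=2300e-6, dic=2000e-6, temperature=25.0, salinity=35.0)


def pco2_alkalinity_response(
    state: SeawaterState, alk_increase_fraction: float
) -> dict:
    """pCO2 decrease factor for a fractional alkalinity increase at fixed DIC.

    Returns the ratio pCO2_before / pCO2_after together with the speciation
    at both endpoints. The ratio is >= 1 for any positive increase.
    """
    if alk_increase_fraction < 0:
        raise ValueError("alkalinity increase fraction must be non-negative")
    before = solve_speciation(state)
    after_state = SeawaterState(
        alkalinity=state.alkalinity * (1.0 + alk_increase_fraction),
        dic=state.dic,
        temperature=state.temperature,
        salinity=state.salinity,
        total_boron=state.total_boron,
    )
    after = solve_speciation(after_state)
    if after.pco2 == 0.0:
        ratio = math.inf if before.pco2 > 0 else 1.0
    else:
        ratio = before.pco2 / after.pco2
    return {"ratio": ratio, "before": before, "after": after}
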