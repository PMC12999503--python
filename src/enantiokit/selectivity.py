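"""Interconversion of enantiomeric excess, enantiomeric ratio and ΔΔG‡.

Selectivity in a reaction proceeding through two competing diastereomeric
transition states follows the Boltzmann relation

    er = (1 + ee) / (1 - ee)          ΔΔG‡ = R·T·ln(er)

with R in kcal/(mol·K).  ΔΔG‡ is the free-energy gap between the
stereocontrolling transition states; its sign follows the sign of the e.e.
"""

from __future__ import annotations

import math

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

DEFAULT_TEMPERATURE = 298.15  # K


def ee_to_ddg(ee: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ΔΔG‡ (kcal/mol) from enantiomeric excess (fraction in (-1, 1)).

    >>> round(ee_to_ddg(0.74), 2)
    1.13
    """
    if not -1 < ee < 1:
        raise ValueError(f"|ee| must be < 1 for a finite ΔΔG‡, got {ee}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return R_KCAL * temperature * math.log((1 + ee) / (1 - ee))


def ddg_to_ee(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Enantiomeric excess (fraction) from ΔΔG‡ (kcal/mol); maps ℝ into (-1, 1)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    x = ddg / (R_KCAL * temperature)
    # tanh(x/2) == (e^x - 1)/(e^x + 1), overflow-safe
    return math.tanh(x / 2.0)


def ee_to_er(ee: float) -> float:
    """Enantiomeric ratio (major/minor) from e.e."""
    if not -1 < ee < 1:
        raise ValueError(f"|ee| must be < 1, got {ee}")
    return (1 + ee) / (1 - ee)


def er_to_ee(er: float) -> float:
    if er <= 0:
        raise ValueError("enantiomeric ratio must be > 0")
    return (er - 1) / (er + 1)


def normalize_ee(value: float) -> float:
    """Accept e.e. as percent or fraction (auto-detect by |value| > 1)."""
    return value / 100.0 if abs(value) > 1 else value
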