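"""Unit conventions and molar conversions.

All internal computation is molar: concentrations in nM, amounts in nmol,
time in days.  Observed data arrive as mass concentrations (drug in ug/mL,
target in pg/mL) and doses in mg; the helpers here convert both ways so the
binding mass balance between a 150 kDa antibody and its ~10 kDa cytokine
target is done on the molar scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UnitConventions",
    "mg_to_nmol",
    "nmol_to_mg",
    "ug_per_l_to_nm",
    "nm_to_ug_per_l",
    "pg_per_ml_to_nm",
    "nm_to_pm",
    "pm_to_nm",
]


@dataclass(frozen=True)
class UnitConventions:
    """Molar masses and the internal unit system.

    Attributes
    ----------
    mw_drug : float
        Molar mass of the antibody in g/mol (default 150 kDa).
    mw_target : float
        Molar mass of the target cytokine in g/mol (default 10 kDa for IL13).
    """

    mw_drug: float = 150_000.0
    mw_target: float = 10_000.0

    def __post_init__(self) -> None:
        if self.mw_drug <= 0 or self.mw_target <= 0:
            raise ValueError("molar masses must be strictly positive")


def mg_to_nmol(dose_mg: float, units: UnitConventions = UnitConventions()) -> float:
    """Convert a drug dose in mg to nmol.

    mg -> g is 1e-3, g / (g/mol) is mol, mol -> nmol is 1e9, hence the 1e6.
    """
    if dose_mg < 0:
        raise ValueError(f"negative dose {dose_mg!r} mg is not a valid dose record")
    return dose_mg * 1e6 / units.mw_drug


def nmol_to_mg(amount_nmol: float, units: UnitConventions = UnitConventions()) -> float:
    if amount_nmol < 0:
        raise ValueError(f"negative amount {amount_nmol!r} nmol")
    return amount_nmol * units.mw_drug / 1e6


def ug_per_l_to_nm(x, mw: float):
    """ug/L to nM for a species of molar mass ``mw`` g/mol (1 ug/L = 1000/mw nM)."""
    return x * 1e3 / mw


def nm_to_ug_per_l(x, mw: float):
    return x * mw / 1e3


def pg_per_ml_to_nm(x, mw: float):
    """pg/mL to nM (1 pg/mL = 1 ng/L = 1e-9 g/L mass concentration)."""
    return x / mw


def nm_to_pm(x):
    return x * 1e3


def pm_to_nm(x):
    return x * 1e-3
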