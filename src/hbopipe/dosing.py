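"""Unit conversions between molar medium concentrations, tissue mass
concentrations, and vehicle dilution fractions.

All conversions are linear: µg/ml = µM * MW / 1000, and a tissue
concentration in ng per mg of tissue converts to molarity through the
assumed tissue density (water-like, 1 g/ml, by default):
µM = (ng/mg) * density * 1000 / MW.
"""

from __future__ import annotations

from dataclasses import dataclass

PROPOFOL_MW = 178.27  # g/mol, 2,6-diisopropylphenol


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    mw: float                  # g/mol
    tissue_density: float = 1.0  # g/ml

    def __post_init__(self):
        if not self.mw > 0:
            raise ValueError("molecular weight must be positive")
        if not self.tissue_density > 0:
            raise ValueError("tissue density must be positive")


PROPOFOL = CompoundSpec(name="propofol", mw=PROPOFOL_MW)


def molar_to_mass_conc(c_um: float, spec: CompoundSpec = PROPOFOL) -> float:
    """µM -> µg/ml."""
    if c_um < 0:
        raise ValueError("concentration must be >= 0")
    return c_um * spec.mw / 1000.0


def mass_to_molar_conc(c_ug_ml: float, spec: CompoundSpec = PROPOFOL) -> float:
    """µg/ml -> µM (inverse of :func:`molar_to_mass_conc`)."""
    if c_ug_ml < 0:
        raise ValueError("concentration must be >= 0")
    return c_ug_ml * 1000.0 / spec.mw


def tissue_mass_to_molar(c_ng_mg: float, spec: CompoundSpec = PROPOFOL) -> float:
    """ng per mg of tissue -> µM, via the assumed tissue density."""
    if c_ng_mg < 0:
        raise ValueError("concentration must be >= 0")
    return c_ng_mg * spec.tissue_density * 1000.0 / spec.mw


def molar_to_tissue_mass(c_um: float, spec: CompoundSpec = PROPOFOL) -> float:
    """µM -> ng per mg of tissue (inverse of :func:`tissue_mass_to_molar`)."""
    if c_um < 0:
        raise ValueError("concentration must be >= 0")
    return c_um * spec.mw / (1000.0 * spec.tissue_density)


def dilution_fraction(stock_mm: float, final_um: float) -> float:
    """Percent (v/v) of vehicle in the medium when a stock of
    ``stock_mm`` (mM) is diluted to ``final_um`` (µM)."""
    if stock_mm <= 0:
        raise ValueError("stock concentration must be positive")
    if final_um < 0:
        raise ValueError("final concentration must be >= 0")
    stock_um = stock_mm * 1000.0
    if final_um > stock_um:
        raise ValueError(f"final {final_um} µM exceeds stock {stock_um} µM: impossible dilution")
    return 100.0 * final_um / stock_um
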