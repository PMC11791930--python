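"""Exact monoisotopic mass and adduct m/z arithmetic.

Every targeted m/z in the workflow (the FA 18:1 cell marker at 281.2485,
the Trp-d5 internal standard at 208.1140, the 1,5-DAN matrix peak at
157.0771, the GUV lipids DOPC/DMPC, metabolite markers such as itaconate
and taurine) is an exact deprotonated/protonated/sodiated monoisotopic
mass.  This module computes them from elemental formulas, including
heavy-isotope labels such as the five deuteriums of Trp-d5.

Adduct arithmetic is electron-corrected: [M+H]+ adds the mass of a
proton (1.007276 Da), not of a neutral hydrogen atom, and [M+Na]+ adds
the sodium cation mass.  At four decimal places this is the convention
that reproduces instrument-calibrated values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._errors import PrismError
from .tolerance import Tolerance

# Monoisotopic masses of the most abundant isotope, Da.
# Values from the IUPAC/CIAAW atomic mass evaluation (AME2020), rounded
# to 7 decimals; "D" is the deuterium (2H) label used by Trp-d5.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250,
    "D": 2.0141018,  # 2H
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "P": 30.9737615,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625909,
    "Fe": 55.9349363,
    "Se": 79.9165218,
    "I": 126.9044719,
}

#: Proton mass (1H minus one electron), Da.
PROTON = 1.0072765
#: Sodium cation mass (Na minus one electron), Da.
SODIUM_CATION = 22.9892207

_FORMULA_TOKEN = re.compile(r"(\[(\d+)([A-Z][a-z]?)(\d*)\])|([A-Z][a-z]?)(\d*)")

_HEAVY = {("H", 2): "D"}  # bracket isotopes supported in v1


@dataclass(frozen=True)
class Formula:
    """Elemental composition, optionally with heavy-isotope labels.

    ``counts`` maps element symbols (including the deuterium label "D")
    to non-negative counts.  ``Formula.parse`` accepts Hill-notation
    strings with either the "D" shorthand ("C11H7D5N2O2") or bracketed
    isotopes ("C11H7[2H5]N2O2").
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise PrismError(f"unknown element symbol {el!r}")
            if n < 0:
                raise PrismError(f"negative count for element {el!r}")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise PrismError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            if m.group(1):  # bracketed isotope, e.g. [2H5]
                mass_number, el, n = int(m.group(2)), m.group(3), int(m.group(4) or 1)
                sym = _HEAVY.get((el, mass_number))
                if sym is None:
                    raise PrismError(f"unsupported isotope [{mass_number}{el}]")
            else:
                sym, n = m.group(5), int(m.group(6) or 1)
            counts[sym] = counts.get(sym, 0) + n
        if pos != len(text) or not counts:
            raise PrismError(f"cannot parse formula {text!r}")
        return cls(counts)

    def labeled(self, isotope: str = "2H", n: int = 0) -> "Formula":
        """Substitute ``n`` light atoms with the named heavy isotope.

        Only deuteration ("2H") is supported; the labeled count may not
        exceed the formula's hydrogen count.
        """
        if isotope != "2H":
            raise PrismError(f"unsupported isotope label {isotope!r}")
        if n > self.counts.get("H", 0):
            raise PrismError(
                f"cannot label {n} H atoms in a formula with {self.counts.get('H', 0)}"
            )
        counts = dict(self.counts)
        counts["H"] = counts.get("H", 0) - n
        counts["D"] = counts.get("D", 0) + n
        return Formula(counts)

    def __str__(self) -> str:
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in
                       ((el, self.counts[el]) for el in order) if n)


@dataclass(frozen=True)
class Adduct:
    """A singly charged ion species: [M+H]+, [M-H]- or [M+Na]+."""

    kind: str
    SHIFTS = {"[M+H]+": (PROTON, +1), "[M-H]-": (-PROTON, -1), "[M+Na]+": (SODIUM_CATION, +1)}

    def __post_init__(self) -> None:
        if self.kind not in self.SHIFTS:
            raise PrismError(
                f"unsupported adduct {self.kind!r}; supported: {sorted(self.SHIFTS)}"
            )

    @property
    def mass_shift(self) -> float:
        return self.SHIFTS[self.kind][0]

    @property
    def charge(self) -> int:
        return self.SHIFTS[self.kind][1]


def monoisotopic_mass(formula: Formula | str) -> float:
    """Neutral monoisotopic mass in Da (most abundant isotopes, with any
    heavy labels substituted)."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


def adduct_mz(formula: Formula | str, adduct: Adduct | str) -> float:
    """m/z of the named singly charged adduct of a neutral formula."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    if isinstance(adduct, str):
        adduct = Adduct(adduct)
    if adduct.kind == "[M-H]-" and formula.counts.get("H", 0) < 1:
        raise PrismError(f"cannot deprotonate {formula}: no hydrogen")
    return monoisotopic_mass(formula) + adduct.mass_shift


def match_mz(observed: float, candidates, tol: Tolerance):
    """Nearest annotation within tolerance of an observed m/z.

    ``candidates`` is an :class:`prism_ms.msio.AnnotationTable`.  Ties on
    absolute mass error are broken by the lower FDR.  Returns the matching
    row (a pandas Series) or None.
    """
    frame = candidates.frame
    if frame.empty:
        return None
    delta = (frame["mz"] - observed).abs()
    within = delta <= tol.half_width(observed)
    if not within.any():
        return None
    # quantize the mass error (1e-9 Da) so numerically equal distances
    # tie and fall through to the FDR tie-break
    sub = frame[within].assign(_delta=np.round(delta[within], 9))
    sub = sub.sort_values(["_delta", "fdr"], kind="stable")
    return sub.iloc[0].drop("_delta")
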