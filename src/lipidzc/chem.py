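"""Chemical-formula arithmetic and the average oxidation state of carbon (Z_C).

For a molecule or moiety :math:`\\mathrm{C}_c\\mathrm{H}_h\\mathrm{N}_n
\\mathrm{O}_o\\mathrm{P}_p\\mathrm{S}_s` with net charge :math:`Z`,

.. math::

    Z_C = \\frac{2o + 3n - 5p - 4s - h + Z}{c}

which follows from assigning fixed oxidation states to the non-carbon
elements: H +1, O -2, N -3, P +5 (the phosphate convention) and, for the
sulfonic-acid sulfur of sulfoquinovosyl headgroups, S +4.  Z_C is -4 for
methane and +4 for carbon dioxide, the two endpoints of the carbon redox
scale.  Charge acquired by pH-dependent (de)protonation cancels against the
hydrogen it adds or removes, so Z_C is insensitive to protonation state;
a permanent quaternary-ammonium charge is not, and must be carried in ``z``.

Formulae support exact rational arithmetic: when element counts are
integers (or :class:`fractions.Fraction`), ``zc`` returns a ``Fraction`` so
repeating decimals like -1/6 are represented exactly and rounded only on
output.  Abundance-weighted average formulae carry fractional counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from fractions import Fraction

__all__ = [
    "ChemicalFormula",
    "add_formulas",
    "scale_formula",
    "zc",
    "monoisotopic_mass",
    "parse_formula",
    "MONOISOTOPIC_MASS",
    "ADDUCT_MASS",
]

# CODATA/IUPAC monoisotopic isotope masses (Da), single pinned table.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

_ELECTRON_MASS = 0.000548579909

# Parent-ion adducts seen in positive-mode electrospray of polar lipids.
ADDUCT_MASS = {
    "none": 0.0,
    "proton": MONOISOTOPIC_MASS["H"] - _ELECTRON_MASS,          # [M+H]+
    "ammonium": MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"]
    - _ELECTRON_MASS,                                            # [M+NH4]+
}

_ELEMENT_FIELDS = ("c", "h", "n", "o", "p", "s")


@dataclass(frozen=True)
class ChemicalFormula:
    """Element counts plus net charge.

    Counts are non-negative; fractional values are legal and arise from
    abundance-weighted averaging.  ``sulfonic_s`` tags how many of the ``s``
    sulfur atoms sit in a sulfonic-acid group (oxidation state +4).  It
    defaults to ``s`` because sulfonic S is the only sulfur species in
    scope; Z_C computation refuses formulae containing sulfur with no
    assigned oxidation state rather than silently assuming +4.
    """

    c: float | Fraction = 0
    h: float | Fraction = 0
    n: float | Fraction = 0
    o: float | Fraction = 0
    p: float | Fraction = 0
    s: float | Fraction = 0
    z: float | Fraction = 0
    sulfonic_s: float | Fraction | None = None

    def __post_init__(self) -> None:
        for name in _ELEMENT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count")
        if self.sulfonic_s is None:
            object.__setattr__(self, "sulfonic_s", self.s)
        elif not 0 <= self.sulfonic_s <= self.s:
            raise ValueError("sulfonic_s must lie in [0, s]")

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        if not isinstance(other, ChemicalFormula):
            return NotImplemented
        return ChemicalFormula(
            *(getattr(self, f) + getattr(other, f) for f in _ELEMENT_FIELDS),
            z=self.z + other.z,
            sulfonic_s=self.sulfonic_s + other.sulfonic_s,
        )

    def __mul__(self, k) -> "ChemicalFormula":
        if k < 0:
            raise ValueError("cannot scale a formula by a negative factor")
        return ChemicalFormula(
            *(getattr(self, f) * k for f in _ELEMENT_FIELDS),
            z=self.z * k,
            sulfonic_s=self.sulfonic_s * k,
        )

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChemicalFormula):
            return NotImplemented
        return all(
            getattr(self, f.name) == getattr(other, f.name) for f in fields(self)
        )

    def is_integral(self) -> bool:
        """True when every count (and the charge) is a whole number."""
        vals = [getattr(self, f) for f in _ELEMENT_FIELDS] + [self.z]
        return all(v == int(v) for v in vals)

    @property
    def zc(self):
        return zc(self)

    def __str__(self) -> str:
        parts = []
        for name in _ELEMENT_FIELDS:
            v = getattr(self, name)
            if v == 0:
                continue
            v = int(v) if v == int(v) else v
            parts.append(name.upper() + ("" if v == 1 else str(v)))
        body = "".join(parts) or "(empty)"
        if self.z == 0:
            return body
        mag = abs(self.z)
        mag = int(mag) if mag == int(mag) else mag
        sign = "+" if self.z > 0 else "-"
        return body + (sign if mag == 1 else f"{mag}{sign}")


def add_formulas(a: ChemicalFormula, b: ChemicalFormula) -> ChemicalFormula:
    """Component-wise sum of two formulae (charges add)."""
    return a + b


def scale_formula(a: ChemicalFormula, k) -> ChemicalFormula:
    """Multiply every count and the charge by ``k >= 0``."""
    return a * k


def zc(f: ChemicalFormula):
    """Average oxidation state of carbon, (2o + 3n - 5p - 4s - h + Z)/c.

    The -4s term uses the sulfonic-acid sulfur count only; formulae carrying
    sulfur without an oxidation-state assignment are rejected.  Undefined
    (raises) when the formula contains no carbon — e.g. the hydroxyl-hydrogen
    "headgroup" of glycosyl tetraethers.
    """
    if f.c <= 0:
        raise ValueError("Z_C is undefined for a carbon-free formula")
    if f.sulfonic_s != f.s:
        raise ValueError(
            "formula contains sulfur with no assigned oxidation state"
        )
    num = 2 * f.o + 3 * f.n - 5 * f.p - 4 * f.sulfonic_s - f.h + f.z
    if f.is_integral():
        return Fraction(num) / Fraction(f.c)
    return num / f.c


def monoisotopic_mass(f: ChemicalFormula, adduct: str = "none") -> float:
    """Monoisotopic mass in Da, optionally as a proton/ammonium parent ion.

    Rejects fractional element counts: the mass of an abundance-averaged
    formula is not a parent-ion mass.
    """
    if adduct not in ADDUCT_MASS:
        raise ValueError(f"unknown adduct {adduct!r}")
    counts = {el: getattr(f, el.lower()) for el in MONOISOTOPIC_MASS}
    for el, v in counts.items():
        if v != int(v):
            raise ValueError(f"fractional {el} count has no parent-ion mass")
    return (
        sum(MONOISOTOPIC_MASS[el] * int(v) for el, v in counts.items())
        + ADDUCT_MASS[adduct]
    )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# sign with optional magnitude after it ("+", "-", "+2"); a digit before
# the sign is always an element count, never a charge magnitude
_CHARGE_RE = re.compile(r"(?:\^)?([+−-])(\d*)(?:\^)?$")


def parse_formula(text: str, sulfonic: bool | None = None) -> ChemicalFormula:
    """Parse Hill-style formula text such as ``C6H11O5`` or ``C5H14NO3P+``.

    A trailing ``+``/``-`` (optionally with a magnitude on either side) sets
    the net charge.  ``sulfonic=True`` marks all sulfur as sulfonic-acid S;
    the default leaves the dataclass convention (all S sulfonic) in place.
    """
    text = text.strip().replace("−", "-")
    charge = 0
    m = _CHARGE_RE.search(text)
    if m:
        mag = int(m.group(2) or 1)
        charge = mag if m.group(1) == "+" else -mag
        text = text[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula text {text!r}")
        pos = m.end()
        el = m.group(1)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element {el!r}")
        counts[el] = counts.get(el, 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"unparseable formula text {text!r}")
    f = ChemicalFormula(
        c=counts.get("C", 0),
        h=counts.get("H", 0),
        n=counts.get("N", 0),
        o=counts.get("O", 0),
        p=counts.get("P", 0),
        s=counts.get("S", 0),
        z=charge,
    )
    if sulfonic is False:
        f = ChemicalFormula(f.c, f.h, f.n, f.o, f.p, f.s, f.z, sulfonic_s=0)
    return f
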