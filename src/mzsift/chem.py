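"""Elemental-formula arithmetic, ion m/z computation, and biotransformation catalogue.

Small-molecule mass bookkeeping for electrospray LC-HRMS work: monoisotopic
masses of neutral formulas, m/z of (de)protonated species and multimer/adduct
ions such as [2M+2H+Cl]+, the catalogue of biotransformation mass shifts seen
in cytochrome-P450 incubations (carbonyl reduction, hydroxylation, lactam
formation, N,N-dealkylation of a pyrrolidine, ...), and the conventional
"M<mass>T<rt>" feature naming.

Masses are IUPAC monoisotopic (lightest isotope), taken from the NIST table
shipped with :mod:`pyteomics`. Charge bookkeeping uses the proton mass
(1.00727646 Da) for both polarities; electron mass is ignored elsewhere,
which keeps computed m/z within well under 5 ppm of Orbitrap-printed values
for singly charged small molecules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "C13_SPACING",
    "ELEMENT_MASSES",
    "ElementalFormula",
    "IonSpecies",
    "TransformationRule",
    "FeatureName",
    "monoisotopic_mass",
    "ion_mz",
    "builtin_transformations",
    "builtin_adducts",
    "feature_name",
    "parse_feature_name",
]

#: Mass of a proton in Da, used for protonation/deprotonation in both polarities.
PROTON_MASS = 1.00727646

#: 13C minus 12C mass difference in Da (isotopologue spacing for z=1).
C13_SPACING = 1.003355

#: 37Cl minus 35Cl mass difference in Da. The M+2 isotopologue of a
#: chlorine-containing ion is dominated by 37Cl, not by two 13C.
CL37_SPACING = 1.997050

#: Natural 13C abundance per carbon atom; M+1/M ~ n_C * 0.0107.
C13_ABUNDANCE = 0.0107

# Elements accepted in formulas. Monoisotopic (lightest-isotope) masses from
# the NIST table bundled with pyteomics.
_SUPPORTED = ("C", "H", "N", "O", "S", "P", "Cl", "Na", "K", "F", "Br", "I")
ELEMENT_MASSES: dict[str, float] = {
    el: _pmass.nist_mass[el][0][0] for el in _SUPPORTED
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """A neutral elemental composition: element symbol -> count.

    Counts must be non-negative; unknown element symbols are rejected.
    Equality is count-map equality (zero counts are dropped).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in dict(self.counts).items():
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, hill: str) -> "ElementalFormula":
        """Parse a Hill-notation string such as ``"C14H19NO"``."""
        if not hill:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(hill):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
            pos = m.end()
            el = m.group(1)
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unknown element symbol: {el!r}")
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(hill):
            raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
        return cls(counts)

    def hill(self) -> str:
        """Render in Hill order (C, H, then alphabetical)."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el for el in order
        )

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def apply_delta(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Apply a signed element delta; the result must stay non-negative."""
        out = dict(self.counts)
        for el, n in delta.items():
            out[el] = out.get(el, 0) + n
            if out[el] < 0:
                raise ValueError(f"delta removes more {el} than present")
        return ElementalFormula(out)

    def __bool__(self) -> bool:
        return bool(self.counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula.

    Accepts an :class:`ElementalFormula`, a plain count map, or a Hill string.
    The empty formula has mass 0. Mass is additive over disjoint merges.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    elif not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    return sum(ELEMENT_MASSES[el] * n for el, n in formula.counts.items())


@dataclass(frozen=True)
class IonSpecies:
    """An electrospray ion type [nM + pH + X]^z, e.g. [M+H]+ or [2M+2H+Cl]+.

    ``multiplicity`` is the n in [nM...]; ``proton_count`` the signed number
    of protons gained (negative = deprotonation); ``extra_atoms`` a neutral
    elemental delta (e.g. one Cl for a chloride-bearing cluster); ``charge``
    the signed ion charge, never zero.
    """

    name: str
    multiplicity: int = 1
    proton_count: int = 1
    extra_atoms: ElementalFormula = field(default_factory=lambda: ElementalFormula({}))
    charge: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("ion multiplicity must be >= 1")
        if self.charge == 0:
            raise ValueError("ion charge must be nonzero")

    def mz(self, neutral_mass: float) -> float:
        return ion_mz(neutral_mass, self)


def ion_mz(neutral_mass: float, species: IonSpecies) -> float:
    """m/z of ``species`` formed from a neutral of the given monoisotopic mass.

    (n * M + p * m_proton + mass(extra)) / |z|. The proton mass carries the
    charge bookkeeping; electron mass is neglected (sub-ppm for small ions).
    """
    if species.charge == 0:
        raise ValueError("ion charge must be nonzero")
    total = (
        species.multiplicity * neutral_mass
        + species.proton_count * PROTON_MASS
        + monoisotopic_mass(species.extra_atoms)
    )
    return total / abs(species.charge)


# Canonical ion species.
PROTONATED = IonSpecies("[M+H]+", 1, 1, ElementalFormula({}), +1)
DEPROTONATED = IonSpecies("[M-H]-", 1, -1, ElementalFormula({}), -1)
SODIATED = IonSpecies("[M+Na]+", 1, -0, ElementalFormula({"Na": 1}), +1)
DIMER_CHLORIDE = IonSpecies("[2M+2H+Cl]+", 2, 2, ElementalFormula({"Cl": 1}), +1)


def builtin_adducts() -> list[IonSpecies]:
    """Adduct/cluster catalogue matched against a parent's neutral mass."""
    return [
        IonSpecies("[M+Na]+", 1, 0, ElementalFormula({"Na": 1}), +1),
        IonSpecies("[M+K]+", 1, 0, ElementalFormula({"K": 1}), +1),
        IonSpecies("[2M+H]+", 2, 1, ElementalFormula({}), +1),
        DIMER_CHLORIDE,
    ]


@dataclass(frozen=True)
class TransformationRule:
    """A biotransformation (or in-source reaction) as a signed element delta.

    ``mass_delta`` is always derived from ``delta``: monoisotopic mass of the
    gained atoms minus that of the lost atoms.
    """

    name: str
    delta: Mapping[str, int]
    #: Whether the shift is a plausible pHLM metabolic step (False for
    #: ion-source/workup chemistry such as the cyano or imido shifts).
    metabolic: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", dict(self.delta))

    @property
    def mass_delta(self) -> float:
        return sum(ELEMENT_MASSES[el] * n for el, n in self.delta.items())

    def apply_mz(self, mz: float) -> float:
        """Shifted m/z for a singly charged ion of the transformed molecule."""
        return mz + self.mass_delta

    def apply_formula(self, formula: ElementalFormula) -> ElementalFormula:
        return formula.apply_delta(self.delta)


def builtin_transformations() -> list[TransformationRule]:
    """Catalogue of mass shifts relevant to cathinone metabolism in pHLM.

    Metabolic shifts: carbonyl reduction (dihydro-, +H2), hydroxylation
    (HO-, +O), dihydroxylation (di-HO-, +2O), lactam formation (oxo-,
    +O -H2), combinations thereof, and N,N-dealkylation of the pyrrolidine
    ring (-C4H6). Non-metabolic shifts cover in-source/workup chemistry:
    dehydrogenation (dehydro-, -H2), water loss (dehydrate-, -H2O), imide
    formation (imido-, +NH -O), and acetonitrile-derived cyano addition
    (cyano-, +CN -H).

    Note dihydro-oxo- and HO- share the net delta +O; disambiguation is the
    annotation module's job (it flags sub-ppm ties as ambiguous).
    """
    return [
        TransformationRule("dihydro-", {"H": 2}),
        TransformationRule("dehydro-", {"H": -2}, metabolic=False),
        TransformationRule("HO-", {"O": 1}),
        TransformationRule("di-HO-", {"O": 2}),
        TransformationRule("oxo-", {"O": 1, "H": -2}),
        TransformationRule("dihydro-HO-", {"H": 2, "O": 1}),
        TransformationRule("dihydro-oxo-", {"O": 1}),
        TransformationRule("oxo-HO-", {"O": 2, "H": -2}),
        TransformationRule("N,N-dealkyl-", {"C": -4, "H": -6}),
        TransformationRule("imido-", {"N": 1, "H": 1, "O": -1}, metabolic=False),
        TransformationRule("cyano-", {"C": 1, "N": 1, "H": -1}, metabolic=False),
        TransformationRule("dehydrate-", {"H": -2, "O": -1}, metabolic=False),
    ]


_FEATURE_NAME = re.compile(r"^(neg)?M(\d+)T(\d+)$")


@dataclass(frozen=True)
class FeatureName:
    """The conventional feature label "M<rounded m/z>T<rt in s>"."""

    mass_part: int
    rt_part: int

    def render(self) -> str:
        return f"M{self.mass_part}T{self.rt_part}"

    def __str__(self) -> str:
        return self.render()


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def feature_name(mz: float, rt: float) -> FeatureName:
    """Name a feature by its rounded m/z and retention time in seconds.

    Rounding is half-up (217.5 -> 218). Negative inputs are rejected.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if rt < 0:
        raise ValueError(f"retention time must be non-negative, got {rt}")
    return FeatureName(_round_half_up(mz), _round_half_up(rt))


def parse_feature_name(name: str) -> FeatureName:
    """Inverse of :func:`feature_name` rendering; accepts an optional "neg" prefix."""
    m = _FEATURE_NAME.match(name)
    if not m:
        raise ValueError(f"not a feature name: {name!r}")
    return FeatureName(int(m.group(2)), int(m.group(3)))


def ppm_error(observed: float, expected: float) -> float:
    """Signed relative error in parts per million."""
    return (observed - expected) / expected * 1e6
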