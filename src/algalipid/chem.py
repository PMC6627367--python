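"""Elemental compositions, monoisotopic masses and adduct m/z for polar lipids.

The mass arithmetic here is the foundation of the annotation pipeline: every
lipid species is assembled as ``backbone + sum(acyl free acids) - n_acyl * H2O``
and ionised through a small registry of electrospray adducts.  Monoisotopic
atomic masses are fixed constants (CODATA/IUPAC) shipped with the package so
that theoretical m/z values are reproducible to the sub-ppm level required by
accurate-mass identification (< 5 ppm).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "ElementalFormula",
    "FattyAcyl",
    "Adduct",
    "ADDUCTS",
    "LipidClassDef",
    "LipidSpecies",
    "species_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "enumerate_candidates",
    "parse_fa_name",
]

#: Monoisotopic atomic masses in Da (most abundant isotope), IUPAC/CODATA.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

ELECTRON_MASS: float = 0.00054857990907

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts of a neutral molecule.

    Supports element-wise addition and subtraction; subtraction below zero
    raises, because a negative atom count means a malformed assembly rather
    than a meaningful molecule.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for elem, n in self.counts.items():
            if elem not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {elem!r}")
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
            if n:
                clean[elem] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``'C41H76O10'``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = match.end()
            elem, digits = match.groups()
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            new = counts.get(elem, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {elem} count ({new})"
                )
            counts[elem] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return sum(ATOMIC_MASSES[e] * n for e, n in self.counts.items())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        order = sorted(
            self.counts,
            key=lambda e: (e != "C", e != "H", e),
        )
        return "".join(
            f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in order
        )


H2O = ElementalFormula({"H": 2, "O": 1})

_FA_NAME = re.compile(r"^(\d+):(\d+)(?:\s*n\s*-\s*(\d+))?$")


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain, written ``C:N`` (carbons : double bonds).

    ``omega`` records the double-bond position family (3 for n-3, 6 for n-6,
    ...) when known; GC-FAME names such as ``18:1`` without an omega tag keep
    ``omega=None``.
    """

    carbons: int
    double_bonds: int
    omega: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("fatty acyl needs at least 2 carbons")
        if self.double_bonds < 0:
            raise ValueError("double bonds must be non-negative")
        if self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                "unsaturation for the chain length"
            )

    @property
    def formula(self) -> ElementalFormula:
        """Free fatty acid C_c H_(2c-2d) O2."""
        return ElementalFormula(
            {"C": self.carbons, "H": 2 * self.carbons - 2 * self.double_bonds, "O": 2}
        )

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def ketene_mass(self) -> float:
        """Mass of the dehydrated acyl (RCH=C=O), i.e. free acid minus water."""
        return self.mass - H2O.mass

    @property
    def name(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return f"{base}n-{self.omega}" if self.omega is not None else base

    def __str__(self) -> str:
        return self.name


def parse_fa_name(name: str) -> FattyAcyl:
    """Parse shorthand such as ``'18:3n-3'``, ``'20:4 n-6'`` or ``'16:0'``."""
    match = _FA_NAME.match(name.strip().replace("*", ""))
    if not match:
        raise ValueError(f"cannot parse fatty acid name {name!r}")
    c, d, omega = match.groups()
    return FattyAcyl(int(c), int(d), int(omega) if omega else None)


@dataclass(frozen=True)
class Adduct:
    """An electrospray adduct: neutral mass -> singly charged m/z.

    ``mass_shift`` includes the electron mass correction (a protonated ion
    weighs one proton, not one hydrogen atom); at m/z 500-1000 the electron
    alone is ~0.7-1 ppm, which matters against a 5 ppm identification bound.
    """

    code: str
    mass_shift: float
    charge: int  # +1 or -1

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return neutral_mass + self.mass_shift

    def neutral_mass(self, mz: float) -> float:
        return mz - self.mass_shift


_PROTON = ATOMIC_MASSES["H"] - ELECTRON_MASS

ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", _PROTON, +1),
    "[M+NH4]+": Adduct(
        "[M+NH4]+",
        ATOMIC_MASSES["N"] + 4 * ATOMIC_MASSES["H"] - ELECTRON_MASS,
        +1,
    ),
    "[M+Na]+": Adduct("[M+Na]+", ATOMIC_MASSES["Na"] - ELECTRON_MASS, +1),
    "[M-H]-": Adduct("[M-H]-", -_PROTON, -1),
    "[M+CH3COO]-": Adduct(
        "[M+CH3COO]-",
        2 * ATOMIC_MASSES["C"]
        + 3 * ATOMIC_MASSES["H"]
        + 2 * ATOMIC_MASSES["O"]
        + ELECTRON_MASS,
        -1,
    ),
}


def get_adduct(code: str) -> Adduct:
    # tolerate the unicode minus sign used in some exports
    norm = code.replace("−", "-").replace(" ", "")
    try:
        return ADDUCTS[norm]
    except KeyError:
        raise KeyError(f"unsupported adduct code {code!r}") from None


@dataclass(frozen=True)
class LipidClassDef:
    """Definition of a polar lipid class.

    ``backbone`` is the head-group + glycerol scaffold with free hydroxyls,
    so that ``species = backbone + sum(acyl free acids) - n_acyl * H2O``.
    """

    class_code: str
    n_acyl: int
    backbone: ElementalFormula
    reported_adducts: tuple[str, ...]
    rt_window: tuple[float, float] | None = None  # minutes
    diagnostic_fragments: tuple[tuple[float, str], ...] = ()

    def rt_consistent(self, rt: float | None) -> bool | None:
        if rt is None or self.rt_window is None:
            return None
        lo, hi = self.rt_window
        return lo <= rt <= hi


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at the ``class (C:N)`` level, optionally acyl-resolved.

    ``acyl_chains`` is an unordered chain set: MS/MS neutral losses reveal
    which chains are present but not their sn-position, so ``18:1/16:0``
    and ``16:0/18:1`` denote the same species.
    """

    class_code: str
    total_carbons: int
    total_double_bonds: int
    acyl_chains: tuple[FattyAcyl, ...] | None = None

    def __post_init__(self) -> None:
        if self.acyl_chains is not None:
            chains = tuple(
                sorted(
                    self.acyl_chains,
                    key=lambda a: (-a.carbons, -a.double_bonds),
                )
            )
            object.__setattr__(self, "acyl_chains", chains)
            if sum(a.carbons for a in chains) != self.total_carbons:
                raise ValueError("acyl carbons do not sum to total_carbons")
            if sum(a.double_bonds for a in chains) != self.total_double_bonds:
                raise ValueError(
                    "acyl double bonds do not sum to total_double_bonds"
                )

    @property
    def cn_label(self) -> str:
        return f"{self.total_carbons}:{self.total_double_bonds}"

    @property
    def name(self) -> str:
        return f"{self.class_code}({self.cn_label})"

    @property
    def chain_label(self) -> str | None:
        if self.acyl_chains is None:
            return None
        return "/".join(a.name for a in self.acyl_chains)

    def __str__(self) -> str:
        return self.name


def species_formula(
    species: LipidSpecies, class_def: LipidClassDef
) -> ElementalFormula:
    """Neutral elemental formula: backbone + acyls - esterification water.

    For diacyl classes with unresolved chains the formula depends only on the
    (C:N) totals, so a single generic decomposition is used internally.
    """
    if class_def.class_code != species.class_code:
        raise ValueError(
            f"class mismatch: {class_def.class_code} vs {species.class_code}"
        )
    if species.acyl_chains is not None:
        chains: Sequence[FattyAcyl] = species.acyl_chains
        if len(chains) != class_def.n_acyl:
            raise ValueError(
                f"{species.name}: {len(chains)} chains for an "
                f"{class_def.n_acyl}-acyl class"
            )
    else:
        chains = _generic_decomposition(
            class_def.n_acyl, species.total_carbons, species.total_double_bonds
        )
    formula = class_def.backbone
    for acyl in chains:
        formula = formula + acyl.formula
    return formula - class_def.n_acyl * H2O


def _generic_decomposition(
    n_acyl: int, total_c: int, total_n: int
) -> tuple[FattyAcyl, ...]:
    """Any chain split with the right totals; the formula is split-invariant."""
    if n_acyl == 1:
        return (FattyAcyl(total_c, total_n),)
    if n_acyl == 2:
        # put everything feasible on one chain, the minimum on the other
        for c1 in range(2, total_c - 1):
            c2 = total_c - c1
            for d1 in range(0, total_n + 1):
                d2 = total_n - d1
                if d1 <= c1 // 2 and d2 <= c2 // 2:
                    return (FattyAcyl(c1, d1), FattyAcyl(c2, d2))
        raise ValueError(
            f"({total_c}:{total_n}) is not decomposable into two acyl chains"
        )
    raise ValueError(f"unsupported acyl count {n_acyl}")


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of counts x monoisotopic atomic masses, in Da."""
    return formula.mass


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Singly charged m/z of an adduct ion, electron mass included."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return adduct.mz(neutral_mass)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def enumerate_candidates(
    class_def: LipidClassDef,
    acyl_pool: Iterable[FattyAcyl],
    total_c: int,
    total_n: int,
) -> list[LipidSpecies]:
    """All unordered acyl combinations from the pool with the given totals.

    Results are deduplicated and sorted canonically (longest, then most
    unsaturated chain first within a species; species by chain labels).
    """
    pool = sorted(set(acyl_pool), key=lambda a: (a.carbons, a.double_bonds))
    if not pool:
        raise ValueError("acyl pool is empty")
    combos: set[tuple[FattyAcyl, ...]] = set()
    for combo in itertools.combinations_with_replacement(pool, class_def.n_acyl):
        if (
            sum(a.carbons for a in combo) == total_c
            and sum(a.double_bonds for a in combo) == total_n
        ):
            combos.add(
                tuple(sorted(combo, key=lambda a: (-a.carbons, -a.double_bonds)))
            )
    species = [
        LipidSpecies(class_def.class_code, total_c, total_n, combo)
        for combo in combos
    ]
    species.sort(key=lambda s: s.chain_label)
    return species
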