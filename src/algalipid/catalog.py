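"""Load the lipid class catalog and the packaged reference species list.

The class catalog is a human-editable YAML file (element counts of each
backbone, reported adducts, optional retention-time windows and diagnostic
fragments); the reference species list is a tab-delimited table of observed
m/z values with class, (C:N) totals, MS/MS-supported acyl combinations and
the adduct each class was detected as.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .chem import (
    ADDUCTS,
    Adduct,
    ElementalFormula,
    FattyAcyl,
    LipidClassDef,
    LipidSpecies,
    adduct_mz,
    get_adduct,
    monoisotopic_mass,
    parse_fa_name,
    species_formula,
)

__all__ = [
    "load_class_catalog",
    "load_reference_species",
    "build_theoretical_catalog",
    "ReferenceSpecies",
    "CatalogEntry",
    "DEFAULT_ACYL_POOL",
]

#: Acyl chains observed in the reference species list (C14-C20, 0-5 double
#: bonds); used as the default pool for candidate enumeration.
DEFAULT_ACYL_POOL: tuple[FattyAcyl, ...] = tuple(
    FattyAcyl(c, d)
    for c, dmax in [(14, 1), (16, 4), (18, 4), (20, 5)]
    for d in range(dmax + 1)
)


def _data_path(name: str) -> Path:
    return Path(resources.files("algalipid.data") / name)


def load_class_catalog(path: str | Path | None = None) -> dict[str, LipidClassDef]:
    """Read a YAML class catalog into :class:`LipidClassDef` objects."""
    path = _data_path("lipid_classes.yaml") if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    catalog: dict[str, LipidClassDef] = {}
    for code, entry in raw.items():
        frags = tuple(
            (float(mz), str(pol))
            for mz, pol in entry.get("diagnostic_fragments", [])
        )
        rt = entry.get("rt_window")
        catalog[code] = LipidClassDef(
            class_code=code,
            n_acyl=int(entry["n_acyl"]),
            backbone=ElementalFormula(entry["backbone"]),
            reported_adducts=tuple(entry["reported_adducts"]),
            rt_window=tuple(float(x) for x in rt) if rt else None,
            diagnostic_fragments=frags,
        )
    return catalog


@dataclass(frozen=True)
class ReferenceSpecies:
    """One printed reference row: observed m/z plus its species assignment."""

    table: int
    observed_mz: float
    class_code: str
    total_carbons: int
    total_double_bonds: int
    adduct: Adduct
    #: MS/MS-supported unordered acyl combinations (empty when unresolved)
    decompositions: tuple[tuple[FattyAcyl, ...], ...]

    @property
    def species(self) -> LipidSpecies:
        return LipidSpecies(
            self.class_code, self.total_carbons, self.total_double_bonds
        )

    def resolved_species(self) -> list[LipidSpecies]:
        return [
            LipidSpecies(
                self.class_code,
                self.total_carbons,
                self.total_double_bonds,
                chains,
            )
            for chains in self.decompositions
        ]


def _parse_chains(text: str) -> tuple[tuple[FattyAcyl, ...], ...]:
    text = text.strip()
    if not text:
        return ()
    decomps = []
    for combo in text.split(","):
        chains = tuple(parse_fa_name(part) for part in combo.strip().split("/"))
        decomps.append(
            tuple(sorted(chains, key=lambda a: (-a.carbons, -a.double_bonds)))
        )
    return tuple(decomps)


def load_reference_species(
    path: str | Path | None = None,
) -> list[ReferenceSpecies]:
    """Read the packaged (or a user) reference species table."""
    path = _data_path("reference_species.tsv") if path is None else Path(path)
    rows: list[ReferenceSpecies] = []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            expected = {"table", "observed_mz", "class_code", "cn", "acyl_chains", "adduct"}
            if set(header) != expected:
                raise ValueError(f"unexpected reference table header: {header}")
            continue
        rec = dict(zip(header, fields + [""] * (len(header) - len(fields))))
        c, n = rec["cn"].split(":")
        rows.append(
            ReferenceSpecies(
                table=int(rec["table"]),
                observed_mz=float(rec["observed_mz"]),
                class_code=rec["class_code"],
                total_carbons=int(c),
                total_double_bonds=int(n),
                adduct=get_adduct(rec["adduct"]),
                decompositions=_parse_chains(rec["acyl_chains"]),
            )
        )
    return rows


@dataclass(frozen=True)
class CatalogEntry:
    """A candidate for MS1 matching: species + adduct + theoretical m/z."""

    species: LipidSpecies
    adduct: Adduct
    theoretical_mz: float
    class_def: LipidClassDef


def build_theoretical_catalog(
    class_defs: dict[str, LipidClassDef],
    species: list[LipidSpecies] | None = None,
    adducts: dict[str, list[str]] | None = None,
) -> list[CatalogEntry]:
    """Build the (species, adduct, theoretical m/z) list used by annotation.

    With ``species=None`` the packaged reference list is used.  Each class is
    ionised through its reported adduct(s) from the class catalog unless
    ``adducts`` overrides the codes per class.
    """
    if species is None:
        species = [ref.species for ref in load_reference_species()]
    entries: list[CatalogEntry] = []
    seen: set[tuple[str, str]] = set()
    for sp in species:
        key = (sp.name, sp.chain_label or "")
        if key in seen:
            continue
        seen.add(key)
        class_def = class_defs[sp.class_code]
        mass = monoisotopic_mass(species_formula(sp, class_def))
        codes = (
            adducts.get(sp.class_code, class_def.reported_adducts)
            if adducts
            else class_def.reported_adducts
        )
        for code in codes:
            adduct = get_adduct(code)
            entries.append(
                CatalogEntry(sp, adduct, adduct_mz(mass, adduct), class_def)
            )
    return entries
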