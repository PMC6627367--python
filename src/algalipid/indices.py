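"""Lipid unsaturation indices and fatty-acid category summaries.

The double-bond index DBI = sum(weight% x N) / 100 is the abundance-weighted
mean number of double bonds (N) — a standard membrane-unsaturation summary.
It is computed for the total fatty acid pool (from GC-FAME weight percents)
and per lipid class (from within-class relative percentages of molecular
species).  The seasonal relative change is
RC% = (DBI_ref - DBI_other) / DBI_ref x 100.

Category sums partition the itemized FAs into saturated (SFA), mono- (MUFA)
and polyunsaturated (PUFA), with the n-6/n-3, arachidonic/eicosapentaenoic
(AA/EPA) and unsaturated/saturated ratios.  FAs pooled as "Others" (< 0.5%)
carry no defined double-bond count and are excluded from every index.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import FattyAcyl, parse_fa_name
from .quantify import AbundanceMatrix

__all__ = [
    "dbi_fa",
    "dbi_class",
    "relative_change",
    "fa_category_sums",
    "class_dbi_table",
    "FACategorySums",
    "MIN_SPECIES_FOR_CLASS_DBI",
]

#: class DBI is only meaningful with a handful of species contributing
MIN_SPECIES_FOR_CLASS_DBI = 4

AA = "20:4n-6"
EPA = "20:5n-3"


def _itemized(weights: pd.Series) -> pd.Series:
    return weights.drop(index="Others", errors="ignore")


def dbi_fa(weights: pd.Series) -> float:
    """Double-bond index of a total FA profile.

    ``weights`` maps FA shorthand (e.g. ``18:3n-3``) to weight percent; an
    ``Others`` row, if present, is excluded (its unsaturation is undefined).
    """
    item = _itemized(weights)
    total = sum(
        float(w) * parse_fa_name(str(name)).double_bonds
        for name, w in item.items()
    )
    return total / 100.0


def dbi_class(
    percent: pd.Series,
    double_bonds: pd.Series,
    min_species: int = MIN_SPECIES_FOR_CLASS_DBI,
) -> float:
    """Double-bond index of one lipid class.

    ``percent`` holds within-class relative percentages per molecular
    species and ``double_bonds`` the total double-bond count of each.
    Classes with fewer than ``min_species`` species are refused: the index
    is unstable when a couple of species dominate the closure.
    """
    if len(percent) < min_species:
        raise ValueError(
            f"class DBI needs > {min_species - 1} species, got {len(percent)}"
        )
    aligned = double_bonds.loc[percent.index]
    return float((percent * aligned).sum() / 100.0)


def relative_change(dbi_ref: float, dbi_other: float) -> float:
    """Signed percent change of the index relative to the reference group."""
    if dbi_ref == 0:
        raise ValueError("reference DBI is zero; relative change undefined")
    return 100.0 * (dbi_ref - dbi_other) / dbi_ref


@dataclass(frozen=True)
class FACategorySums:
    sfa: float
    mufa: float
    pufa: float
    n6_n3: float | None
    aa_epa: float | None
    unsat_sat: float


def fa_category_sums(weights: pd.Series) -> FACategorySums:
    """Saturation-category sums and ratios over the itemized FAs.

    An FA with unspecified omega family (e.g. GC's ``18:1``) contributes to
    its saturation category but is excluded from the n-6/n-3 ratio; the
    ratio is None when either family sums to zero.
    """
    item = _itemized(weights)
    sfa = mufa = pufa = 0.0
    n6 = n3 = 0.0
    aa = epa = None
    for name, w in item.items():
        acyl = parse_fa_name(str(name))
        w = float(w)
        if acyl.double_bonds == 0:
            sfa += w
        elif acyl.double_bonds == 1:
            mufa += w
        else:
            pufa += w
        if acyl.omega == 6:
            n6 += w
        elif acyl.omega == 3:
            n3 += w
        if str(name) == AA:
            aa = w
        elif str(name) == EPA:
            epa = w
    n6_n3 = (n6 / n3) if n3 > 0 and n6 > 0 else None
    aa_epa = (aa / epa) if aa and epa else None
    unsat_sat = (mufa + pufa) / sfa if sfa > 0 else float("inf")
    return FACategorySums(sfa, mufa, pufa, n6_n3, aa_epa, unsat_sat)


def class_dbi_table(
    abundance: AbundanceMatrix,
    groups: pd.Series,
    reference: str | None = None,
    min_species: int = MIN_SPECIES_FOR_CLASS_DBI,
) -> pd.DataFrame:
    """Per-class DBI per group plus the relative change between two groups.

    ``groups`` maps sample id -> group label (exactly two labels);
    ``reference`` names the group RC% is computed relative to (default: the
    first label in sorted order).  Classes below the species-count threshold
    are flagged (NaN indices) rather than computed.
    """
    within = abundance if abundance.scope == "within_class" else abundance.within_class()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("class DBI table expects exactly two groups")
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference group {reference!r} not in {labels}")
        labels = [reference, next(l for l in labels if l != reference)]
    ref, other = labels
    records = []
    for cls, idx in within.species_meta.groupby("class_code").groups.items():
        block = within.percent.loc[idx]
        dbs = within.species_meta.loc[idx, "double_bonds"]
        row: dict = {"class_code": cls, "n_species": len(idx)}
        if len(idx) < min_species:
            row.update({ref: float("nan"), other: float("nan"), "rc_percent": float("nan")})
        else:
            vals = {}
            for label in labels:
                cols = groups.index[groups == label]
                mean_pct = block[cols].mean(axis=1)
                # re-close the group mean before weighting
                mean_pct = 100.0 * mean_pct / mean_pct.sum()
                vals[label] = dbi_class(mean_pct, dbs, min_species)
            row.update(vals)
            row["rc_percent"] = relative_change(vals[ref], vals[other])
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("class_code")
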