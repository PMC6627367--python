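"""Internal-standard normalisation and percent relative quantification.

LC-MS peak areas are divided by the area of a spiked internal standard (one
per lipid class, mapped in config) in the same sample, then expressed as a
percentage of the per-sample total — either across all annotated species
("global", the matrix the seasonal statistics run on) or within each class
(the per-class profile plots).  GC-FAME areas are normalised to the methyl
nonadecanoate (19:0) standard and expressed as percent of the summed
identified fatty acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedFeature
from .io import FeatureTable

__all__ = [
    "DEFAULT_STANDARD_MAP",
    "AbundanceMatrix",
    "normalize_to_standards",
    "fa_relative_percent",
    "FAProfile",
]

#: Default lipid class -> internal standard mapping.  The standards mix is a
#: phospholipid cocktail; phosphorus-free classes (glycolipids, betaines) are
#: scaled by the closest-eluting proxy standard.  Always config-overridable.
DEFAULT_STANDARD_MAP: dict[str, str] = {
    "PC": "dMPC", "LPC": "dMPC",
    "PE": "dMPE", "LPE": "dMPE",
    "PG": "dMPG", "LPG": "dMPG",
    "PI": "dPPI", "LPI": "dPPI",
    "MGDG": "dMPG", "MGMG": "dMPG", "DGDG": "dMPG", "DGMG": "dMPG",
    "SQDG": "dMPG", "SQMG": "dMPG",
    "DGTS": "dMPG", "MGTS": "dMPG", "DGTA": "dMPG", "MGTA": "dMPG",
}


@dataclass
class AbundanceMatrix:
    """Species x samples relative abundances (percent) plus provenance.

    ``percent`` rows sum to 100 per sample.  ``normalization`` records which
    internal standard scaled each species.  ``species_meta`` carries class
    code and double-bond count per row for downstream indices.
    """

    percent: pd.DataFrame  # index species label; columns sample ids
    normalization: pd.Series  # species label -> standard name
    species_meta: pd.DataFrame  # index species label; class_code, carbons, double_bonds
    scope: str = "global"  # "global" | "within_class"

    def within_class(self) -> "AbundanceMatrix":
        """Re-close percentages within each lipid class."""
        percent = self.percent.copy()
        for cls, idx in self.species_meta.groupby("class_code").groups.items():
            block = percent.loc[idx]
            totals = block.sum(axis=0)
            if (totals == 0).any():
                raise ValueError(f"class {cls} has zero total in some sample")
            percent.loc[idx] = 100.0 * block / totals
        return AbundanceMatrix(
            percent, self.normalization, self.species_meta, scope="within_class"
        )


def normalize_to_standards(
    table: FeatureTable,
    annotations: Sequence[AnnotatedFeature],
    standard_map: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """IS-normalise annotated features and close to percent per sample.

    Each annotated feature's area is divided by the area of its class's
    internal standard in the same sample, then all species are rescaled to
    percent of the per-sample total.  Raises when a mapped standard is
    missing from the table or has zero area in any sample, naming both.
    """
    standard_map = dict(DEFAULT_STANDARD_MAP if standard_map is None else standard_map)
    std_areas: dict[str, pd.Series] = {}
    for fid, std_name in table.is_flags.items():
        std_areas[std_name] = table.areas.loc[fid]
    rows: list[pd.Series] = []
    labels: list[str] = []
    norm_record: dict[str, str] = {}
    meta_rows: list[dict] = []
    for ann in annotations:
        cls = ann.class_code
        if cls not in standard_map:
            raise ValueError(f"no internal standard mapped for class {cls}")
        std_name = standard_map[cls]
        if std_name not in std_areas:
            raise ValueError(
                f"internal standard {std_name!r} (class {cls}) absent from table"
            )
        std = std_areas[std_name]
        zero = std[std <= 0]
        if len(zero):
            raise ValueError(
                f"internal standard {std_name!r} has zero area in sample "
                f"{zero.index[0]!r}"
            )
        label = ann.species.name
        if label in norm_record:
            continue  # one row per species; first annotation wins
        labels.append(label)
        norm_record[label] = std_name
        rows.append(table.areas.loc[ann.feature_id] / std)
        meta_rows.append(
            {
                "class_code": cls,
                "carbons": ann.species.total_carbons,
                "double_bonds": ann.species.total_double_bonds,
            }
        )
    if not rows:
        raise ValueError("no annotated features to quantify")
    norm = pd.DataFrame(rows, index=labels)
    totals = norm.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero total normalised area in some sample")
    percent = 100.0 * norm / totals
    meta = pd.DataFrame(meta_rows, index=labels)
    return AbundanceMatrix(
        percent, pd.Series(norm_record, name="standard"), meta, scope="global"
    )


@dataclass
class FAProfile:
    """Mean weight percent and SD per fatty acid across replicates."""

    mean: pd.Series
    sd: pd.Series
    per_replicate: pd.DataFrame  # fa x replicate percent

    def closure_ok(self, tol: float = 0.5) -> bool:
        return bool(np.all(np.abs(self.per_replicate.sum(axis=0) - 100.0) < tol))


def fa_relative_percent(
    areas: pd.DataFrame,
    internal_standard: str = "19:0",
) -> FAProfile:
    """Percent relative area method for GC-FAME data.

    Per replicate, each identified FA's area is divided by the internal
    standard's area (removing injection/derivatisation variation), then
    expressed as percent of the summed identified FAs — the standard itself
    is excluded from the sum.  Returns mean and SD (ddof=1) across
    replicates.
    """
    if internal_standard not in areas.index:
        raise ValueError(
            f"internal standard row {internal_standard!r} missing"
        )
    std = areas.loc[internal_standard]
    if (std <= 0).any():
        raise ValueError(
            f"internal standard {internal_standard!r} has zero area in a replicate"
        )
    identified = areas.drop(index=internal_standard)
    rel = identified / std
    totals = rel.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero total FA area in a replicate")
    percent = 100.0 * rel / totals
    nrep = percent.shape[1]
    sd = percent.std(axis=1, ddof=1) if nrep > 1 else pd.Series(
        0.0, index=percent.index
    )
    return FAProfile(mean=percent.mean(axis=1), sd=sd, per_replicate=percent)
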