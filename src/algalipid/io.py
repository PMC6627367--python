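"""Readers and writers for the pipeline's plain-text formats.

Feature tables, GC-FAME area tables and sample metadata travel as delimited
text (tab by default); MS/MS spectra travel as Mascot generic format (MGF).
Readers validate rather than coerce: NaN areas, duplicate identifiers or
non-numeric m/z values are errors with the offending line reported, because
silently repaired inputs corrupt downstream statistics.

Retention time is minutes everywhere in the package; MGF RTINSECONDS is
converted on read.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "SampleMeta",
    "FeatureTable",
    "MsmsSpectrum",
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "read_fa_table",
    "write_fa_table",
    "read_sample_metadata",
    "write_sample_metadata",
]

_META_COLUMNS = ("sample_id", "group", "extract", "analytical")


@dataclass(frozen=True)
class SampleMeta:
    """One analytical run: group label, extract and analytical replicate."""

    sample_id: str
    group: str
    extract: int
    analytical: int


@dataclass
class MsmsSpectrum:
    """A product-ion spectrum keyed by precursor m/z and retention time."""

    precursor_mz: float
    precursor_rt: float  # minutes
    polarity: str  # "positive" | "negative"
    mz: np.ndarray
    intensity: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative fragment intensity")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class FeatureTable:
    """MS1 features (m/z, RT, polarity) x samples peak-area matrix.

    ``areas`` is indexed by feature_id with one column per sample;
    ``is_flags`` maps feature_id -> internal-standard name for spiked
    standards (absent or None for biological features).
    """

    features: pd.DataFrame  # index feature_id; columns mz, rt, polarity
    areas: pd.DataFrame  # index feature_id; columns sample ids
    samples: list[SampleMeta] = field(default_factory=list)
    is_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()]
            raise ValueError(f"duplicate feature ids: {sorted(set(dupes))}")
        if list(self.features.index) != list(self.areas.index):
            raise ValueError("features and areas indices differ")
        if self.areas.isna().any().any():
            raise ValueError("NaN peak areas are not accepted")
        if (self.areas.values < 0).any():
            raise ValueError("negative peak areas are not accepted")
        if (self.features["mz"] <= 0).any():
            raise ValueError("feature m/z must be positive")
        if self.samples:
            ids = [s.sample_id for s in self.samples]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids in metadata")
            if list(self.areas.columns) != ids:
                raise ValueError("metadata sample ids do not match area columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.columns)

    def groups(self) -> pd.Series:
        """Sample -> group label series (requires metadata)."""
        if not self.samples:
            raise ValueError("feature table has no sample metadata")
        return pd.Series(
            {s.sample_id: s.group for s in self.samples}, name="group"
        )


def read_feature_table(
    path: str | Path,
    dialect: str = "tab",
    metadata: Sequence[SampleMeta] | None = None,
) -> FeatureTable:
    """Read a delimited feature table.

    The header must name ``feature_id``, ``mz``, ``rt`` and one column per
    sample; an optional ``polarity`` column ("positive"/"negative") and an
    optional ``internal_standard`` column (standard name or empty) are
    recognised.
    """
    sep = {"tab": "\t", "comma": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = {"feature_id", "mz", "rt"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if raw["feature_id"].duplicated().any():
        dupes = raw.loc[raw["feature_id"].duplicated(), "feature_id"]
        raise ValueError(f"duplicate feature ids: {sorted(set(dupes))}")

    for col in ("mz", "rt"):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"non-numeric {col} value {raw.loc[bad.idxmax(), col]!r} "
                f"on line {line}"
            )
        raw[col] = parsed

    meta_cols = ["feature_id", "mz", "rt"]
    polarity = raw["polarity"] if "polarity" in raw else pd.Series(
        ["positive"] * len(raw)
    )
    if "polarity" in raw:
        meta_cols.append("polarity")
    is_flags: dict[str, str] = {}
    if "internal_standard" in raw:
        meta_cols.append("internal_standard")
        for fid, flag in zip(raw["feature_id"], raw["internal_standard"]):
            if isinstance(flag, str) and flag.strip():
                is_flags[fid] = flag.strip()

    sample_cols = [c for c in raw.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError("no sample columns found")
    areas = raw[sample_cols].apply(pd.to_numeric, errors="raise")
    areas.index = raw["feature_id"]
    features = pd.DataFrame(
        {
            "mz": raw["mz"].values,
            "rt": raw["rt"].values,
            "polarity": polarity.values,
        },
        index=pd.Index(raw["feature_id"], name="feature_id"),
    )
    return FeatureTable(
        features, areas, list(metadata) if metadata else [], is_flags
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.features.copy()
    out["internal_standard"] = [
        table.is_flags.get(fid, "") for fid in out.index
    ]
    out = pd.concat([out, table.areas], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file into sorted-peak spectra (RT converted to minutes)."""
    text = Path(path).read_text()
    if text.count("BEGIN IONS") != text.count("END IONS"):
        raise ValueError("unterminated BEGIN IONS block")
    spectra: list[MsmsSpectrum] = []
    if not text.strip():
        return spectra
    with _mgf.MGF(_io.StringIO(text)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError("spectrum without PEPMASS")
            charge = params.get("charge")
            polarity = "positive"
            if charge and str(charge[0]).startswith("-"):
                polarity = "negative"
            rt = params.get("rtinseconds")
            spectra.append(
                MsmsSpectrum(
                    precursor_mz=float(pepmass[0]),
                    precursor_rt=float(rt) / 60.0 if rt is not None else np.nan,
                    polarity=polarity,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    lines: list[str] = []
    for spec in spectra:
        lines.append("BEGIN IONS")
        if spec.title:
            lines.append(f"TITLE={spec.title}")
        lines.append(f"PEPMASS={spec.precursor_mz:.6f}")
        if not np.isnan(spec.precursor_rt):
            lines.append(f"RTINSECONDS={spec.precursor_rt * 60.0:.3f}")
        lines.append("CHARGE=1" + ("+" if spec.polarity == "positive" else "-"))
        for mz, inten in zip(spec.mz, spec.intensity):
            lines.append(f"{mz:.6f} {inten:.4f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_fa_table(path: str | Path, dialect: str = "tab") -> pd.DataFrame:
    """Read a GC-FAME area table: rows keyed by FA shorthand, one column per
    sample; the internal-standard row (e.g. ``19:0``) is kept as a row.
    """
    sep = {"tab": "\t", "comma": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    if raw.index.duplicated().any():
        raise ValueError("duplicate fatty acid rows")
    areas = raw.apply(pd.to_numeric, errors="raise")
    if areas.isna().any().any():
        raise ValueError("NaN areas are not accepted")
    if (areas.values < 0).any():
        raise ValueError("negative areas are not accepted")
    areas.index = areas.index.astype(str).str.strip()
    areas.index.name = "fa"
    return areas


def write_fa_table(areas: pd.DataFrame, path: str | Path) -> None:
    areas.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_metadata(path: str | Path, dialect: str = "tab") -> list[SampleMeta]:
    sep = {"tab": "\t", "comma": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = set(_META_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"missing metadata columns: {sorted(missing)}")
    if raw["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            group=row.group,
            extract=int(row.extract),
            analytical=int(row.analytical),
        )
        for row in raw.itertuples()
    ]


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "extract": s.extract,
                "analytical": s.analytical,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
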