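"""Rule-based assignment of lipid species to MS1 features.

Identification follows the three accurate-mass-era criteria: (i) precursor
m/z within a ppm tolerance of a theoretical adduct ion, (ii) retention time
consistent with the class's elution window (the only handle separating the
isomeric betaine pairs DGTS/DGTA and MGTS/MGTA on HILIC), and (iii) MS/MS
evidence — head-group diagnostic ions and the per-chain neutral losses of
each fatty acyl as the free acid (RCOOH) and as the ketene (RCH=C=O).

Evidence levels: MS1_ONLY < HEADGROUP < ACYL_RESOLVED.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from enum import IntEnum
from typing import Iterable, Sequence

from .catalog import CatalogEntry, DEFAULT_ACYL_POOL
from .chem import (
    FattyAcyl,
    LipidClassDef,
    LipidSpecies,
    enumerate_candidates,
    ppm_error,
)
from .io import FeatureTable, MsmsSpectrum

__all__ = [
    "Evidence",
    "AnnotatedFeature",
    "FragmentMatch",
    "match_ms1",
    "resolve_acyls",
    "rank_and_filter",
    "annotate_features",
    "annotations_to_frame",
    "frame_to_annotations",
]

DEFAULT_MS1_TOL_PPM = 5.0
DEFAULT_MS2_TOL_PPM = 10.0
#: absolute floor on the fragment tolerance, Da; MS/MS is acquired at lower
#: resolving power than MS1, so a pure ppm tolerance is too tight at low m/z
DEFAULT_MS2_TOL_DA = 0.01
#: diagnostic head-group ions are configured at one-decimal precision
#: (e.g. the betaine ion at m/z 236.1), so they match at +/- 0.1 Da
DIAGNOSTIC_TOL_DA = 0.1


class Evidence(IntEnum):
    MS1_ONLY = 0
    HEADGROUP = 1
    ACYL_RESOLVED = 2


@dataclass(frozen=True)
class FragmentMatch:
    """One matched MS/MS peak and the rule that explains it."""

    kind: str  # NEUTRAL_LOSS_FA | NEUTRAL_LOSS_KETENE | DIAGNOSTIC_ION
    chain: FattyAcyl | None
    expected_mz: float
    observed_mz: float

    @property
    def error_da(self) -> float:
        return self.observed_mz - self.expected_mz


@dataclass(frozen=True)
class AnnotatedFeature:
    """A feature with one candidate species assignment."""

    feature_id: str
    mz: float
    rt: float
    entry: CatalogEntry
    ppm: float
    rt_consistent: bool | None
    evidence: Evidence = Evidence.MS1_ONLY
    #: acyl decompositions supported by MS/MS (all kept on ties)
    decompositions: tuple[tuple[FattyAcyl, ...], ...] = ()
    fragments: tuple[FragmentMatch, ...] = ()
    ambiguous: bool = False

    @property
    def species(self) -> LipidSpecies:
        return self.entry.species

    @property
    def class_code(self) -> str:
        return self.entry.species.class_code


def match_ms1(
    table: FeatureTable,
    catalog: Sequence[CatalogEntry],
    tol_ppm: float = DEFAULT_MS1_TOL_PPM,
) -> list[AnnotatedFeature]:
    """Match every feature against the theoretical catalog at ``tol_ppm``.

    A feature may carry several candidates (isobaric species, isomeric
    classes); all are emitted, with ``rt_consistent`` recording whether the
    feature's retention time falls inside the candidate class's window
    (``None`` when the class has no window configured).
    """
    if not catalog:
        raise ValueError("empty theoretical catalog")
    out: list[AnnotatedFeature] = []
    for fid, row in table.features.iterrows():
        for entry in catalog:
            if entry.adduct.polarity != row["polarity"]:
                continue
            ppm = ppm_error(row["mz"], entry.theoretical_mz)
            if abs(ppm) <= tol_ppm:
                out.append(
                    AnnotatedFeature(
                        feature_id=str(fid),
                        mz=float(row["mz"]),
                        rt=float(row["rt"]),
                        entry=entry,
                        ppm=ppm,
                        rt_consistent=entry.class_def.rt_consistent(row["rt"]),
                    )
                )
    return out


def _tol_da(mz: float, tol_ppm: float, tol_da_floor: float) -> float:
    return max(mz * tol_ppm * 1e-6, tol_da_floor)


def _find_peak(
    spectrum: MsmsSpectrum, mz: float, tol: float
) -> float | None:
    """Closest observed peak within tolerance, else None."""
    if len(spectrum.mz) == 0:
        return None
    idx = int(np.argmin(np.abs(spectrum.mz - mz)))
    if abs(spectrum.mz[idx] - mz) <= tol:
        return float(spectrum.mz[idx])
    return None


def resolve_acyls(
    annotation: AnnotatedFeature,
    spectrum: MsmsSpectrum,
    acyl_pool: Iterable[FattyAcyl] = DEFAULT_ACYL_POOL,
    frag_tol_ppm: float = DEFAULT_MS2_TOL_PPM,
    frag_tol_da: float = DEFAULT_MS2_TOL_DA,
) -> AnnotatedFeature:
    """Upgrade an MS1 annotation using MS/MS fragment evidence.

    For every candidate acyl decomposition of the species' (C:N) totals, the
    spectrum is searched for the per-chain neutral-loss peaks
    ``precursor - RCOOH`` and ``precursor - ketene``; a decomposition is
    supported when every distinct chain shows at least one of its two losses.
    All supported decompositions are kept — MS/MS cannot rank isobaric chain
    combinations, and published assignments list all of them.  Head-group
    diagnostic ions alone yield HEADGROUP evidence.
    """
    if spectrum.polarity != annotation.entry.adduct.polarity:
        raise ValueError(
            "spectrum polarity does not match the annotated adduct"
        )
    class_def = annotation.entry.class_def
    fragments: list[FragmentMatch] = []

    # head-group diagnostic ions
    headgroup = False
    for frag_mz, pol in class_def.diagnostic_fragments:
        if pol != spectrum.polarity:
            continue
        hit = _find_peak(spectrum, frag_mz, DIAGNOSTIC_TOL_DA)
        if hit is not None:
            headgroup = True
            fragments.append(
                FragmentMatch("DIAGNOSTIC_ION", None, frag_mz, hit)
            )

    # acyl neutral losses per candidate decomposition
    supported: list[tuple[FattyAcyl, ...]] = []
    if class_def.n_acyl >= 1:
        candidates = enumerate_candidates(
            class_def,
            acyl_pool,
            annotation.species.total_carbons,
            annotation.species.total_double_bonds,
        )
        precursor = annotation.mz
        for cand in candidates:
            chain_hits: list[FragmentMatch] = []
            all_chains_seen = True
            for chain in set(cand.acyl_chains or ()):
                losses = (
                    ("NEUTRAL_LOSS_FA", precursor - chain.mass),
                    ("NEUTRAL_LOSS_KETENE", precursor - chain.ketene_mass),
                )
                seen = False
                for kind, frag_mz in losses:
                    hit = _find_peak(
                        spectrum,
                        frag_mz,
                        _tol_da(frag_mz, frag_tol_ppm, frag_tol_da),
                    )
                    if hit is not None:
                        seen = True
                        chain_hits.append(
                            FragmentMatch(kind, chain, frag_mz, hit)
                        )
                if not seen:
                    all_chains_seen = False
                    break
            if all_chains_seen and chain_hits:
                supported.append(cand.acyl_chains)
                fragments.extend(chain_hits)

    if supported:
        evidence = Evidence.ACYL_RESOLVED
    elif headgroup:
        evidence = Evidence.HEADGROUP
    else:
        evidence = annotation.evidence
    return replace(
        annotation,
        evidence=evidence,
        decompositions=tuple(supported),
        fragments=tuple(fragments),
    )


def annotate_features(
    table: FeatureTable,
    catalog: Sequence[CatalogEntry],
    spectra: Sequence[MsmsSpectrum] = (),
    tol_ppm: float = DEFAULT_MS1_TOL_PPM,
    frag_tol_ppm: float = DEFAULT_MS2_TOL_PPM,
    precursor_tol_ppm: float = 10.0,
    precursor_rt_tol: float = 1.0,
    acyl_pool: Iterable[FattyAcyl] = DEFAULT_ACYL_POOL,
) -> tuple[list[AnnotatedFeature], list[AnnotatedFeature]]:
    """MS1 match, MS/MS upgrade and ranking in one pass.

    Each MS1 candidate is paired with the closest-precursor spectrum of the
    right polarity within ``precursor_tol_ppm`` (and ``precursor_rt_tol``
    minutes when both retention times are known) before ranking.
    """
    pool = tuple(acyl_pool)
    annotations = match_ms1(table, catalog, tol_ppm)
    upgraded: list[AnnotatedFeature] = []
    for ann in annotations:
        best: MsmsSpectrum | None = None
        best_dmz = float("inf")
        for spec in spectra:
            if spec.polarity != ann.entry.adduct.polarity:
                continue
            dmz = abs(spec.precursor_mz - ann.mz)
            if dmz > ann.mz * precursor_tol_ppm * 1e-6:
                continue
            if (
                not np.isnan(spec.precursor_rt)
                and abs(spec.precursor_rt - ann.rt) > precursor_rt_tol
            ):
                continue
            if dmz < best_dmz:
                best, best_dmz = spec, dmz
        if best is not None:
            ann = resolve_acyls(ann, best, pool, frag_tol_ppm)
        upgraded.append(ann)
    return rank_and_filter(upgraded)


def rank_and_filter(
    annotations: Sequence[AnnotatedFeature],
) -> tuple[list[AnnotatedFeature], list[AnnotatedFeature]]:
    """Per feature, keep the best-supported candidate(s).

    Ranking: highest evidence level, then retention-time consistency
    (``True`` or unknown beats ``False``), then smallest absolute ppm.
    Candidates tied on all three are all kept and flagged ambiguous; the
    second return value lists them for the sidecar report.
    """
    kept: list[AnnotatedFeature] = []
    ambiguous: list[AnnotatedFeature] = []
    keyfunc = lambda a: a.feature_id
    for _, group in itertools.groupby(
        sorted(annotations, key=keyfunc), key=keyfunc
    ):
        cands = list(group)

        def rank(a: AnnotatedFeature) -> tuple:
            rt_ok = 1 if a.rt_consistent is not False else 0
            return (int(a.evidence), rt_ok, -round(abs(a.ppm), 6))

        best = max(rank(a) for a in cands)
        winners = [a for a in cands if rank(a) == best]
        if len(winners) > 1:
            winners = [replace(a, ambiguous=True) for a in winners]
            ambiguous.extend(winners)
        kept.extend(winners)
    return kept, ambiguous


def annotations_to_frame(annotations: Sequence[AnnotatedFeature]):
    """Serialise annotations to the pipeline's TSV layout."""
    import pandas as pd

    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature_id,
                "mz": a.mz,
                "rt": a.rt,
                "class": a.class_code,
                "species_CN": a.species.cn_label,
                "acyl_chains": ", ".join(
                    "/".join(c.name for c in decomp)
                    for decomp in a.decompositions
                ),
                "adduct": a.entry.adduct.code,
                "ppm": a.ppm,
                "evidence": a.evidence.name,
                "rt_consistent": a.rt_consistent,
                "ambiguous": a.ambiguous,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class _LoadedAnnotation:
    """Minimal annotation reconstructed from a TSV (for quantification)."""

    feature_id: str
    species: LipidSpecies
    class_code: str
    evidence: Evidence


def frame_to_annotations(frame) -> list[_LoadedAnnotation]:
    out = []
    for _, row in frame.iterrows():
        c, n = str(row["species_CN"]).split(":")
        cls = str(row["class"])
        out.append(
            _LoadedAnnotation(
                feature_id=str(row["feature_id"]),
                species=LipidSpecies(cls, int(c), int(n)),
                class_code=cls,
                evidence=Evidence[str(row["evidence"])],
            )
        )
    return out
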