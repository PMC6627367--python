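"""Synthetic LC-MS, MS/MS and GC-FAME data with known ground truth.

The generator emulates the two-season study design the pipeline targets:
two groups (winter / spring) with three lipid extracts x two analytical
replicates each (N = 6 per group), one MS1 feature per catalog species at
its theoretical adduct m/z perturbed by Gaussian ppm noise, log-normal
abundances with a nested noise model (an extract-level random effect shared
by the two analytical replicates of an extract, plus analytical-level
noise), group fold-effects on a chosen species subset, spiked internal
standards, and MS/MS spectra carrying the per-chain RCOOH / ketene neutral
losses and head-group diagnostic ions.

Everything is driven by one integer seed; identical configs regenerate
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    CatalogEntry,
    ReferenceSpecies,
    build_theoretical_catalog,
    load_class_catalog,
    load_reference_species,
)
from .chem import (
    Adduct,
    LipidClassDef,
    LipidSpecies,
    adduct_mz,
    get_adduct,
    monoisotopic_mass,
    species_formula,
)
from .io import FeatureTable, MsmsSpectrum, SampleMeta

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_feature_table",
    "simulate_msms",
    "simulate_fa_table",
    "internal_standard_entries",
    "balanced_effect_set",
]

#: species called out as the most abundant of their class; they get a fixed
#: abundance boost so simulated rank structure resembles real profiles
MOST_ABUNDANT = {
    "MGDG(38:8)", "DGDG(38:8)", "MGMG(18:4)", "DGMG(18:3)", "DGMG(18:1)",
    "SQDG(34:1)", "SQMG(16:0)", "PC(36:2)", "PC(36:3)", "LPC(18:1)",
    "PG(34:4)", "PG(34:3)", "PG(36:2)", "LPG(16:1)", "PI(34:1)", "PI(34:2)",
    "PE(40:8)", "DGTA(32:1)", "DGTA(32:2)", "MGTA(18:1)", "MGTA(18:2)",
    "DGTS(32:1)", "MGTS(16:0)",
}

#: internal standards of the spiked mix that the default class->standard
#: mapping uses, as (name, class_code, chains, adduct_code)
_STANDARD_SPECS = (
    ("dMPC", "PC", (14, 14), "[M+H]+"),
    ("dMPE", "PE", (14, 14), "[M-H]-"),
    ("dMPG", "PG", (14, 14), "[M-H]-"),
    ("dPPI", "PI", (16, 16), "[M-H]-"),
)

#: default elution apex per class (min) for classes without a configured
#: window; values spread classes across a 30-min HILIC-style gradient
_DEFAULT_RT = {
    "MGDG": 3.0, "MGMG": 4.5, "DGDG": 11.0, "DGMG": 12.5,
    "SQDG": 13.0, "SQMG": 14.0, "PC": 20.0, "LPC": 22.0,
    "PE": 18.0, "LPE": 19.0, "PG": 10.0, "LPG": 11.5,
    "PI": 23.0, "LPI": 24.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``sigma_extract`` and ``sigma_analytical`` are log-scale (natural log)
    SDs of the nested noise components; their quadrature sum is the total
    per-measurement noise level (defaults combine to 0.2).  ``effects`` maps
    species name -> fold change of the second group relative to the first.
    """

    seed: int = 0
    n_extracts: int = 3
    n_analytical: int = 2
    groups: tuple[str, str] = ("winter", "spring")
    sigma_extract: float = 0.12
    sigma_analytical: float = 0.16
    effects: dict[str, float] = field(default_factory=dict)
    ppm_noise_sd: float = 2.0
    rt_jitter_sd: float = 0.2
    internal_standard_area: float = 1e6
    internal_standard_cv: float = 0.05
    #: log-abundance spread across species (natural log)
    mu_spread: float = 1.0
    abundant_boost: float = 2.0


@dataclass
class SimResult:
    """A simulated feature table plus its generating truth."""

    table: FeatureTable
    truth_species: dict[str, str]  # feature_id -> species name
    truth_effects: dict[str, float]  # species name -> fold change
    catalog_entries: list[CatalogEntry]


def balanced_effect_set(
    names: list[str],
    n_effects: int = 20,
    fold: float = 4.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Pick a share-balanced set of fold effects.

    Relative quantification closes each sample to 100%, so an effect set
    that changes the expected total abundance drags every non-effect
    species' percentage with it and the "null" species stop being null in
    the analysed quantity.  Balancing the expected share change requires
    ``fold`` down-regulated species (x 1/fold) per up-regulated one
    (x fold), because a species' expected share gain is (fold - 1) going up
    but only (1 - 1/fold) going down.  Species carrying the fixed
    most-abundant boost are excluded so equal baseline shares can cancel in
    expectation.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    eligible = [n for n in names if n not in MOST_ABUNDANT]
    if n_effects > len(eligible):
        raise ValueError("not enough eligible species for the effect set")
    n_up = max(1, round(n_effects / (1.0 + fold)))
    chosen = rng.choice(len(eligible), size=n_effects, replace=False)
    return {
        eligible[i]: (fold if k < n_up else 1.0 / fold)
        for k, i in enumerate(chosen)
    }


def internal_standard_entries(
    class_defs: dict[str, LipidClassDef] | None = None,
) -> list[tuple[str, CatalogEntry]]:
    """Catalog entries for the spiked internal standards."""
    defs = load_class_catalog() if class_defs is None else class_defs
    out = []
    for name, cls, (c1, c2), adduct_code in _STANDARD_SPECS:
        from .chem import FattyAcyl

        sp = LipidSpecies(cls, c1 + c2, 0, (FattyAcyl(c1, 0), FattyAcyl(c2, 0)))
        adduct = get_adduct(adduct_code)
        mass = monoisotopic_mass(species_formula(sp, defs[cls]))
        out.append(
            (name, CatalogEntry(sp, adduct, adduct_mz(mass, adduct), defs[cls]))
        )
    return out


def _class_rt(class_def: LipidClassDef) -> float:
    if class_def.rt_window is not None:
        lo, hi = class_def.rt_window
        return (lo + hi) / 2.0
    return _DEFAULT_RT.get(class_def.class_code, 15.0)


def simulate_feature_table(
    config: SimConfig,
    species: list[ReferenceSpecies] | None = None,
    class_defs: dict[str, LipidClassDef] | None = None,
) -> SimResult:
    """Generate an MS1 feature table under the configured study design.

    One feature per catalog species at its class's primary adduct.  Areas
    are log-normal: per-species baseline mu, an extract-level random effect
    shared within each extract, analytical noise per run, and the group fold
    effect for species listed in ``config.effects`` (applied to the second
    group).  Internal-standard features are appended with small log-normal
    area variation around ``internal_standard_area``.
    """
    rng = np.random.default_rng(config.seed)
    defs = load_class_catalog() if class_defs is None else class_defs
    refs = load_reference_species() if species is None else species
    entries = build_theoretical_catalog(
        defs,
        [r.species for r in refs],
        adducts={code: [d.reported_adducts[0]] for code, d in defs.items()},
    )

    samples: list[SampleMeta] = []
    for group in config.groups:
        for ext in range(1, config.n_extracts + 1):
            for rep in range(1, config.n_analytical + 1):
                samples.append(
                    SampleMeta(f"{group}_e{ext}_a{rep}", group, ext, rep)
                )

    feat_rows = []
    area_rows = []
    truth_species: dict[str, str] = {}
    is_flags: dict[str, str] = {}

    mus = {
        e.species.name: 10.0
        + rng.normal(0.0, config.mu_spread)
        + (config.abundant_boost if e.species.name in MOST_ABUNDANT else 0.0)
        for e in entries
    }

    def sample_areas(mu: float, fold_by_group: dict[str, float]) -> list[float]:
        areas = []
        extract_eff = {
            (g, e): rng.normal(0.0, config.sigma_extract)
            for g in config.groups
            for e in range(1, config.n_extracts + 1)
        }
        for s in samples:
            log_area = (
                mu
                + np.log(fold_by_group[s.group])
                + extract_eff[(s.group, s.extract)]
                + rng.normal(0.0, config.sigma_analytical)
            )
            areas.append(float(np.exp(log_area)))
        return areas

    for i, entry in enumerate(entries):
        name = entry.species.name
        fid = f"F{i + 1:04d}"
        mz = entry.theoretical_mz * (
            1.0 + rng.normal(0.0, config.ppm_noise_sd) * 1e-6
        )
        rt = _class_rt(entry.class_def) + rng.normal(0.0, config.rt_jitter_sd)
        fold = config.effects.get(name, 1.0)
        fold_by_group = {config.groups[0]: 1.0, config.groups[1]: fold}
        feat_rows.append(
            {
                "feature_id": fid,
                "mz": mz,
                "rt": max(rt, 0.1),
                "polarity": entry.adduct.polarity,
            }
        )
        area_rows.append(sample_areas(mus[name], fold_by_group))
        truth_species[fid] = name

    for j, (std_name, entry) in enumerate(internal_standard_entries(defs)):
        fid = f"IS{j + 1:02d}"
        mz = entry.theoretical_mz * (
            1.0 + rng.normal(0.0, config.ppm_noise_sd) * 1e-6
        )
        feat_rows.append(
            {
                "feature_id": fid,
                "mz": mz,
                "rt": _class_rt(entry.class_def),
                "polarity": entry.adduct.polarity,
            }
        )
        area_rows.append(
            list(
                config.internal_standard_area
                * np.exp(
                    rng.normal(
                        0.0,
                        np.log1p(config.internal_standard_cv),
                        size=len(samples),
                    )
                )
            )
        )
        is_flags[fid] = std_name

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    areas = pd.DataFrame(
        area_rows,
        index=features.index,
        columns=[s.sample_id for s in samples],
    )
    table = FeatureTable(features, areas, samples, is_flags)
    return SimResult(table, truth_species, dict(config.effects), entries)


def simulate_msms(
    species: LipidSpecies,
    class_def: LipidClassDef,
    adduct: Adduct | str,
    ppm_noise_sd: float = 0.0,
    n_noise_peaks: int = 0,
    rng: np.random.Generator | None = None,
    rt: float | None = None,
) -> MsmsSpectrum:
    """Ideal (optionally noised) product-ion spectrum of a resolved species.

    Contains the precursor, the neutral-loss peaks ``precursor - RCOOH`` and
    ``precursor - ketene`` for every acyl chain, the class's diagnostic
    head-group ions, and optionally random low-intensity noise peaks.
    """
    if species.acyl_chains is None:
        raise ValueError("MS/MS simulation needs resolved acyl chains")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    rng = np.random.default_rng(0) if rng is None else rng
    precursor = adduct_mz(
        monoisotopic_mass(species_formula(species, class_def)), adduct
    )
    peaks: list[tuple[float, float]] = [(precursor, 20.0)]
    for chain in set(species.acyl_chains):
        peaks.append((precursor - chain.mass, 100.0))
        peaks.append((precursor - chain.ketene_mass, 60.0))
    for frag_mz, pol in class_def.diagnostic_fragments:
        if pol == adduct.polarity:
            peaks.append((frag_mz, 80.0))
    mzs = np.array([p[0] for p in peaks])
    if ppm_noise_sd > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, ppm_noise_sd, size=len(mzs)) * 1e-6)
    intens = np.array([p[1] for p in peaks])
    if n_noise_peaks > 0:
        noise_mz = rng.uniform(100.0, precursor - 5.0, size=n_noise_peaks)
        noise_int = rng.uniform(0.5, 5.0, size=n_noise_peaks)
        mzs = np.concatenate([mzs, noise_mz])
        intens = np.concatenate([intens, noise_int])
    return MsmsSpectrum(
        precursor_mz=precursor,
        precursor_rt=rt if rt is not None else _class_rt(class_def),
        polarity=adduct.polarity,
        mz=mzs,
        intensity=intens,
        title=f"{species.name} {species.chain_label}",
    )


def simulate_fa_table(
    targets: pd.DataFrame | pd.Series | None = None,
    n_replicates: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    internal_standard: str = "19:0",
    is_area: float = 1e5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GC-FAME area table whose relative percentages hit the target profile.

    ``targets``: weight-percent vector (Series) or fa x group DataFrame;
    defaults to the packaged seasonal reference profile (both groups).
    Returns (areas with the internal-standard row included, target percent
    table used as truth).  With ``noise_sd = 0`` the percent relative area
    method recovers the targets exactly.
    """
    rng = np.random.default_rng(seed)
    if targets is None:
        path = Path(resources.files("algalipid.data") / "fa_seasonal_profile.tsv")
        prof = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        targets = pd.DataFrame(
            {"winter": prof["winter_mean"], "spring": prof["spring_mean"]}
        )
    if isinstance(targets, pd.Series):
        targets = targets.to_frame(name="group")
    # printed reference profiles carry rounding (e.g. a column summing to
    # 100.02), so closure is enforced with the same 0.5 slack the profile
    # invariant uses
    if (targets.sum(axis=0) > 100.0 + 0.5).any():
        raise ValueError("target weight percents must sum to <= 100")
    if internal_standard in targets.index:
        raise ValueError("targets must not contain the internal standard")
    cols: dict[str, pd.Series] = {}
    for group in targets.columns:
        for rep in range(1, n_replicates + 1):
            mult = np.exp(rng.normal(0.0, noise_sd, size=len(targets)))
            areas = is_area * (targets[group].values / 100.0) * mult
            col = pd.Series(areas, index=targets.index)
            col.loc[internal_standard] = is_area
            cols[f"{group}_{rep}"] = col
    out = pd.DataFrame(cols)
    out.index.name = "fa"
    return out, targets
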