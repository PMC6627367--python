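# Methods

`algalipid` implements a desk-scale reimplementation of a polar-lipidomics
workflow for brown macroalgae: rule-based annotation of LC-MS/MS feature
tables, internal-standard relative quantification, membrane-unsaturation
indices, and a two-group (seasonal) statistical stack. This note records the
models, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Lipid chemistry

Every lipid species is assembled from a class backbone (head group +
glycerol, free hydroxyls) plus fatty acyl chains:

    formula(species) = backbone(class) + Σ acyl free acids − n_acyl · H₂O

with the free acid of a C:N chain being C_c H_(2c−2d) O₂. Backbones for the
eighteen classes (MGDG/MGMG, DGDG/DGMG, SQDG/SQMG, PC/LPC, PE/LPE, PG/LPG,
PI/LPI, DGTS/MGTS, DGTA/MGTA) are derived from the standard structures —
galactosyl-, digalactosyl- and sulfoquinovosyl-glycerol, the
glycerophospho-head-group scaffolds, and the two betaine ethers
(trimethylhomoserine; hydroxymethyl-trimethyl-β-alanine). The two betaine
families are constitutional isomers: identical elemental composition,
distinguished only chromatographically.

Monoisotopic masses use fixed IUPAC/CODATA atomic constants shipped with the
package (tests cross-check them against an independent mass library to
1e-6 Da). Adduct m/z values include the electron mass — a protonated ion
weighs a proton, not a hydrogen atom — because at m/z 500–1000 the electron
alone is ~0.7–1 ppm against a 5 ppm identification bound.

Validation: the packaged 159-row reference table (observed m/z, class, C:N,
MS/MS-supported chain combinations) reproduces theory within 5 ppm for 157
rows. Two printed observed values (SQDG(32:0) 793.5099 and PI(34:3)
831.4984) sit 5.3 and 5.4 ppm from theory while every neighbouring homologue
is well inside the bound; we treat these as last-digit printing defects in
the source table and deliberately do not repair them, so the per-table
maximum |ppm| reported by the acceptance machinery is 5.32 (table 1) and
5.42 (table 2) rather than < 5. One further printed value carried a stray
space ("976. 5997") and is stored repaired as 976.5997 (0.5 ppm from
theory).

## Annotation

A feature is annotated when (i) its m/z is within `tol_ppm` (default 5) of a
theoretical adduct ion of matching polarity, (ii) optionally, its retention
time falls in the class elution window, and (iii) optionally, MS/MS evidence
confirms head group and acyl chains. Evidence is ordered MS1_ONLY <
HEADGROUP < ACYL_RESOLVED.

Acyl resolution searches the product-ion spectrum for the two neutral
losses of every chain of every candidate decomposition of the (C:N) totals:
loss of the free fatty acid (RCOOH) and of its ketene (RCH=C=O, acid −
H₂O). A decomposition is supported when each of its distinct chains shows
at least one loss; all supported decompositions are kept, because
collision-induced dissociation cannot rank isobaric chain combinations and
published assignments list all of them. sn-positions are never asserted;
chain sets are unordered and displayed longest/most-unsaturated first.

Numerical tolerances: fragment matching uses 10 ppm with a 0.01 Da floor
(product-ion spectra are acquired at lower resolving power than MS1);
diagnostic head-group ions are configured at one-decimal precision (the
betaine ion at m/z 236.1), so they match at ±0.1 Da. Retention-time windows
default to ±2 min around the betaine class apexes (DGTS 6, MGTS 9, DGTA 16,
MGTA 27 min) and are config-overridable; RT inconsistency demotes a
candidate in ranking but never deletes it, since gradients differ between
laboratories. Ranking is evidence level, then RT consistency, then |ppm|;
exact ties are all kept and flagged ambiguous.

The diagnostic-ion list ships only the betaine head-group ion; other classes
rely on neutral losses plus their class-specific adduct and polarity.
Additional ions can be added through the YAML catalog without code changes.

## Quantification

LC-MS: each annotated species' area is divided by the area of its class's
internal standard in the same sample, then closed to percent of the
per-sample total. The class → standard mapping is explicit configuration
(default: PC/LPC→dMPC, PE/LPE→dMPE, PG/LPG→dMPG, PI/LPI→dPPI, glycolipids
and betaines→dMPG as the closest-eluting proxy) because the spiked standard
mix does not itself define the mapping. Both a global closure (the matrix
the statistics run on) and a within-class closure (per-class profile
output) are produced and labelled; closure to 100 ± 1e-9 per sample is a
tested invariant, as is invariance to per-sample global scaling.

GC-FAME: the percent relative area method — each identified fatty acid's
area over the methyl nonadecanoate (19:0) internal standard, then percent
of the summed identified FAs (standard excluded), mean ± SD across
replicates.

## Indices

DBI = Σ(weight % × N)/100 where N is the double-bond count; computed for
the total FA pool and per lipid class (within-class percentages, classes
with more than three species only — the index is unstable when one or two
species dominate the closure). Relative change between groups:
RC% = (DBI_ref − DBI_other)/DBI_ref × 100.

FAs pooled as "Others" (< 0.5% each) have no defined N and are excluded
from every index and category sum, while remaining in the closure check.
With this convention the packaged winter profile gives DBI 1.66 exactly;
the spring profile computes to 1.49 from the itemized FAs, whereas the
source prints 1.53 — the printed spring value is not reproducible from the
itemized data alone, so it is not asserted anywhere. A chain with
unspecified omega family (GC's "18:1") counts toward MUFA but is excluded
from the n-6/n-3 ratio. Unsat/Sat = (MUFA + PUFA)/SFA over itemized FAs.

## Statistics

* glog: g(x) = log₂((x + √(x² + λ))/2), λ > 0, default λ = 1 on the
  percent scale. The transform is finite at zero and asymptotically log₂.
  λ is configuration, not estimation: the upstream tooling this mirrors
  does not print its value, so we declare a default rather than guess.
* Autoscaling: per-species mean-centering and unit variance (ddof = 1);
  zero-variance species are dropped with a warning.
* PCA: SVD of the column-centered samples × species matrix; deterministic
  sign convention (largest-magnitude loading positive per component);
  variance shares sum to 100. Cross-checked against scikit-learn in tests.
* Mann–Whitney U: exact two-sided permutation null whenever both groups
  have n ≤ 8 and the pooled values are tie-free (at the design size of
  6 vs 6 the null has 924 arrangements, so the smallest attainable
  two-sided p is 2/924 ≈ 0.0022); mid-ranks with the tie-corrected normal
  approximation otherwise. Benjamini–Hochberg step-up q-values across the
  full species list per dataset; flags at q < 0.05 and q < 0.01.
* Clustering: Ward linkage on Euclidean distances in both conventions. The
  default is the historical "unsquared" convention (ward.D): scipy's Ward
  is fed √d and the resulting heights are squared, which reproduces the
  Lance–Williams recurrence applied directly to unsquared distances (an
  independent from-scratch agglomerator verifies the heights in tests).
  The heatmap export is difference-from-species-mean on the transformed
  scale, with top-k selection by q-value.

## Synthetic data

The generator reproduces the study design the pipeline assumes: two groups
(winter/spring) × 3 lipid extracts × 2 analytical replicates (N = 6 per
group). One MS1 feature per catalog species at its class's primary adduct,
with Gaussian m/z noise (default SD 2 ppm). Abundances are log-normal with
a nested noise model — an extract-level random effect shared by the two
analytical replicates of an extract (SD 0.12) plus analytical noise
(SD 0.16), combining to a total log-scale SD of 0.2 — because analytical
replicates of one extract are not independent and tests must reflect that
correlation structure. Species named as the most abundant of their class
receive a fixed log-abundance boost so simulated rank structure resembles
real profiles. Internal standards are appended with 5% CV. MS/MS spectra
contain the precursor, both neutral losses per chain, the class diagnostic
ions, and optional noise peaks. The GC generator produces areas whose
relative percentages equal a target profile (default: the packaged
seasonal reference) plus multiplicative noise; at zero noise the percent
relative area method recovers the target exactly.

Group effects are fold changes on a configured species subset. Because the
quantification closes each sample to 100%, an effect set that changes the
expected total abundance shifts every non-effect species' percentage — the
nulls stop being null. The default effect set is therefore share-balanced:
for fold f, f down-regulated species (× 1/f) per up-regulated one (× f),
drawn from non-boosted species, which cancels the expected total change.
This is a deliberate idealisation: real compositional data offers no such
guarantee, and percent-scale "null" species in real studies can show
closure-induced shifts. Passing round-trip tests therefore demonstrate
correctness of the machinery under the declared noise model, not robustness
to compositional imbalance, chromatographic drift, missing features,
isotopic interference or matrix effects, none of which are simulated.

## Problem sizes

The stochastic suites run at: null FDR control, 50 simulations × 200
species of 6 vs 6 log-normal data (mean fraction of q < 0.05 species must
stay ≤ 0.05); power, 20 simulations × 200 species with 20 four-fold effect
species each (≥ 90% of effect species at q < 0.05); exact-test oracle
agreement over all group sizes ≤ 5 by full enumeration. The complete test
suite runs in about half a minute on one CPU.

## Known limitations

* Acyl-chain columns left blank in the reference table (several PC, all
  LPC/LPG/LPI rows, DGDG(34:4), DGTA(30:2)) are stored unresolved; whether
  MS/MS evidence was absent or merely unreported upstream is unknowable.
* Sodiated betaine ions contribute to two printed DGTA rows upstream; only
  the protonated values are validated, though [M+Na]+ is available for
  matching.
* Per-class DBIs of the source's seasonal comparison are not reproducible
  without the per-species abundance appendix that was never deposited; the
  class-DBI machinery is therefore validated on synthetic data only.
* Whether percentages should close globally or within class is ambiguous in
  the upstream description; both are computed and labelled.
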