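# Methods

## Chain architecture model and notation

A polyubiquitin chain is modeled as a rooted tree of Ub moieties. Edges
are directed distal → proximal: the distal unit's C-terminal G76 forms an
isopeptide bond with a lysine (K6, K11, K27, K29, K33, K48, K63) or, for
linear chains, a peptide bond with the M1 amine of the proximal unit.
M1 linkages are ordinary edges on site "1" even though they are
chemically peptide rather than isopeptide bonds; chains mixing M1 with
lysine linkages are handled uniformly. Constraints enforced at
construction: one edge at most per (unit, site); a site removed by a
K→R substitution cannot accept an edge; a C-terminally truncated unit
(no G76) cannot be distal; edges form a tree with a unique root (the
proximal-most moiety).

The ASCII notation reads distal → proximal, left → right:

```
chain  := arms? unit ( "-[" sites "]" arms? unit )*
arms   := ( "(" chain ")" INT? )+
unit   := "Ub" ( "{" mod ("," mod)* "}" )?
mod    := K<n>R | 1-<m> | 1-<m>-<TAG> | <TAG> | 15N
sites  := label ("," label)*      label ∈ {1,6,11,27,29,33,48,63}
```

A parenthesized group before `-[s1,…,sk]` lists the distal arms attached
at those sites of the following unit; a repetition count `(X)n` expands
eagerly at parse time (the tree, not the text, is the source of truth).
Compact homotypic forms (`48Ub3`) and prefix repetitions
(`63(Ub-[48]Ub)2`, two K48 dimers joined head-to-tail by K63) are
accepted, as are common print renderings with unicode dashes and
superscripts. Arms are stored unordered and canonicalized by site label,
so formatting is a complete tree invariant: two architectures are
isomorphic (up to unit-id relabeling) iff their canonical notations are
equal. The notation grammar is this package's own defined dialect;
published renderings vary in edge cases, and the parser accepts them on
a best-effort basis only.

Enumeration of branched trimers places two monoUb arms on distinct sites
of one root — C(k, 2) architectures for k admissible sites, 28 for the
full set of 8. In-silico cleavage removes a set of edges and returns the
connected components; the unit multiset is conserved and |cuts| + 1
fragments result.

## Mass engine

Masses are computed from the canonical 76-residue human Ub sequence with
elemental data from pyteomics (`std_aa_comp`/`nist_mass`). A variant's
sequence is built by truncation, K→R swaps and tag concatenation, then
summed as residues + water; [M+H]⁺ adds one proton. The default mode is
**average** mass: an intact ~8.5 kDa protein in reflectron mode is an
unresolved isotope envelope, and the reference values match average
[M+H]⁺ within a fraction of a dalton (computed wild-type Ub: 8565.76;
the assay's printed control value is 8565.7). Monoisotopic mode is
retained for testing. Computed masses are compared with published ones
at ±0.3 Da — published values may be instrument-calibrated empirical
numbers rather than theoretical ones.

Uniform ¹⁵N labeling is applied element-wise: nitrogen count of the
variant × per-N shift, where the shift is m(¹⁵N) − ⟨m(N)⟩ (average mode,
0.9934 Da/N) or m(¹⁵N) − m(¹⁴N) (monoisotopic). Canonical Ub has 105
nitrogens (76 backbone + 29 side chain), giving a +104.3 Da shift and a
standard [M+H]⁺ of 8670.07, i.e. 8,670 rounded. The empirical
calibration reference 8,669.470 m/z is kept as the default calibration
target; the ~0.6 Da offset between it and theory is absorbed by the
internal calibration and is well inside the ±2 Da assignment tolerance.

Chain mass is Σ moiety masses − (edges × water), one condensation per
(iso)peptide bond.

Substrate design searches all injective assignments of pool variants to
skeleton positions (admissibility: truncations only at the root;
substitutions must preserve sites that carry arms) and maximizes the
minimum pairwise m/z gap over the moieties plus the internal standard,
with a deterministic lexicographic tie-break. Exhaustive search is
exact and instantaneous at realistic pool sizes (≤ 6–8 variants). The
default distinguishability threshold is 20 Da: the default substrate's
moiety set is spaced ≥ 28 Da, well above the ~8.5 Da envelope FWHM at
this mass, and the printed four-moiety assay set has a minimum gap of
47.8 Da.

The identities of two of the published moiety masses (8,181.3 and
8,729.9) are given only in supplementary material; the package's default
branched Ub₄ substrate therefore uses its own four distinct variants
(wild type; K48R; K48R+K63R; 1–72 root), spacing the released species
and the standard by ≥ 28 Da.

## Synthetic data generators

All generators are pure functions of their inputs and a seed.

**Reaction.** Each linkage is cleaved independently with its per-edge
fraction f. Product expectations are computed by exact enumeration of
cut patterns (≤ 2³ for a tetramer); a moiety is released as monoUb with
probability Π f over its incident edges. Default concentrations follow
the assay's stop-solution arithmetic: 1.2 µM substrate in 10 µl + 2.5 µl
stop solution containing 4 µM ¹⁵N standard → 0.96 µM substrate and
0.8 µM standard final. Only the ratio enters the quantification.
Polymeric residual species (≥ 16 kDa) fall outside the 7,820–9,200 m/z
window and are flagged undetectable.

**Spectrum.** Peaks are Gaussian envelopes with FWHM = m/R, R = 1,000 by
default (FWHM ≈ 8.5 Da at 8.5 kDa) — the published work gives no
resolution figure, so this is the package's choice for an unresolved
intact-protein envelope. Areas are concentration × response factor; the
baseline is an offset plus exponential decay; noise is additive
Gaussian; a constant calibration offset δ shifts every peak (this is the
miscalibration the internal standard corrects). Metastable-ion
satellites default to one per parent at 0.985 × parent m/z with 5%
relative amplitude — published spectra mark such artifact peaks but not
their positions, so these defaults are synthetic placeholders and
configurable. Isolated noise-free peak areas integrate to within 1% of
nominal at the default 0.2 m/z sampling step.

**Pulldown matrices.** Four chain-type groups × 4 replicates. A fraction
(default 6.5% of 2,000 proteins, ≈ 130 — the scale of the published
significant-hit list) is differential, assigned round-robin to six
binding-preference clusters whose profiles are binary
binds/does-not-bind patterns over the four chain types scaled by the
binding contrast. The default contrast is 3 log2 units = 6 × the
between-replicate sd (0.5): a specific binder's enrichment against a
non-binding chain type is a presence/absence-scale difference in
pulldown DIA data. Missingness is logistic in the true log2 intensity
(low-abundance entries more often missing) — exactly the left-censoring
assumed by downshift imputation. Unique-peptide counts are 1 + Poisson,
so a small fraction of proteins is removed by the ≥2-peptide filter.

What the generator does *not* emulate: peptide-level quantification and
roll-up, correlated protein complexes (co-pulldown of whole assemblies),
batch effects, heavy-tailed intensity noise, and missingness that is not
intensity-driven. Passing tests therefore demonstrate the statistical
machinery is correct under its stated assumptions, not that real
pulldowns meet those assumptions.

## Spectral processing and quantification

The vendor peak picker (SNAP, averagine-based) is proprietary; the
package substitutes a documented surrogate preserving the stated
contract — smoothing, baseline subtraction, S/N-thresholded detection,
centroiding and area integration:

1. **Savitzky–Golay smoothing**, window 2 × (expected FWHM / step) + 1
   points, order 3: preserves polynomial traces of degree ≤ 3 exactly
   and envelope areas to filter tolerance.
2. **Top-hat baseline**: trace minus its grey opening; the structuring
   element (85 Da default) is wider than any envelope, so peaks survive
   with < 5% area distortion while offsets and slow decay map to ~0.
3. **Peak detection**: local maxima on the processed trace, measured
   from its median (an opening maps noise onto a non-negative band, so
   zero is not the background). Noise is the standard deviation of the
   peak-free region after MAD-based clipping — the smoothed trace's
   noise is correlated, and a plain MAD underestimates its spread.
   Candidates require height AND prominence ≥ S/N threshold (default 5)
   × noise, separation ≥ 2 × expected FWHM (two envelopes closer than
   that are unresolvable at this resolution), and a measured FWHM within
   0.5–1.5 × the expected FWHM (= m/R; the width-validation surrogate
   for an averagine envelope check — smoothing broadens true envelopes
   to ≈ 1.25 × m/R, while correlated-noise bumps are wider).
   A candidate ≥ 20 × smaller than a neighbor within 3 expected FWHMs is
   discarded as a flank artifact of that neighbor's baseline
   subtraction. Centroids are intensity-weighted means over ± 2 expected
   FWHM; areas are trapezoidal integrals over the same support. At the
   default settings, noise-only traces produce ≈ 0.3–0.4 false peaks
   per 100 traces (18 in 5,000 measured).
4. **Internal calibration**: single-point constant offset bringing the
   largest-area peak within ±5 Da of the reference (default 8,669.470)
   exactly onto it. Only one standard exists in the window, so a
   constant shift is the only identifiable model. A spectrum without a
   standard candidate is rejected with an explicit error — never passed
   through. Calibration is idempotent.
5. **Assignment**: nearest theoretical moiety m/z within ±2 Da
   (≪ minimum table gap, ≫ centroid jitter at the stated S/N); the
   assignment refuses tables whose minimum gap is ≤ 2 × tolerance. Two
   peaks on one moiety: the larger area wins, the other is logged.
6. **Quantification**: percent = (area_moiety / area_standard) ×
   ([standard]/[substrate]) × 100. A moiety with no assigned peak
   quantifies as 0. Values above 100 are retained and flagged — the
   formula can exceed 100 under response-factor mismatch, and clipping
   would hide that.

Panel normalization divides each enzyme's values by its control
substrate's percent, or by the percent of the homotypic K48 trimer's
distal moiety; a missing or zero reference flags the row rather than
dropping it. Replicate aggregation keeps all individual points alongside
the mean.

End-to-end, across cleavage fractions {0, 0.25, 0.5, 0.75, 1.0},
calibration offsets in [−2, +2] Da and 20 seeds per fraction at S/N ≥ 10,
recovered percentages stay within ±3 points of truth (the tests assert
±5).

## Binder-profiling statistics

Preprocessing removes proteins with fewer than two unique peptides,
log2-transforms, and centers each sample at its observed median.
Imputation draws each sample's missing entries from
N(median − 1.8·σ, (0.3·σ)²), with median and σ from that sample's
observed values only; observed entries are never altered, and a sample
with fewer than 3 observed values is an error (σ undefined).

Differential binding uses classic fixed-effects one-way ANOVA per
protein across chain-type groups — no Welch correction and no variance
moderation (no S0 fudge factor): the reference workflow states "ANOVA"
with BH correction and nothing more, so the simplest faithful reading is
implemented and the ambiguity is noted here. P values are adjusted by
Benjamini–Hochberg step-up across proteins (cutoff 0.05). Degenerate
rows: zero between-group variance → F = 0, p = 1; zero within-group
variance with signal → p = 0.

Z scores standardize each protein's profile across all samples
(mean 0, sd 1; constant rows are an error). Clustering is agglomerative
on pairwise Euclidean distances for proteins and for samples. k = 6 is
an explicit parameter (matching the published six binding-preference
groups), with no automatic selection — the cluster count is
presentational. The linkage criterion is genuinely unspecified in the
reference workflow; the package defaults to **Ward**: under a flat
k-cluster cut, average and complete linkage tend to spend clusters on
outlier singletons (false-positive proteins with unstructured profiles),
merging genuine groups — on the default generator over 10 seeds, average
linkage scores ARI 0.73–0.95 against ground truth while Ward scores
0.86–0.98. Average/complete/single remain available. Z scores for the
published-style heat map are computed on the significant subset;
full-matrix Z-scoring is available separately.

## Problem sizes and numerical choices

Test and acceptance runs use: 0.2 m/z sampling (≈ 6,900 points per
spectrum); 100 spectra for the recovery grid; 1,000 noise-only traces
for the false-peak rate (a sub-1% rate needs that many to estimate);
2,000-protein matrices for the default profiling run and 300-protein
matrices × 200 simulations for the null-FDR check; 20,000 draws for
imputation-distribution checks. These sizes give stable estimates while
keeping a full run in seconds.

Seeds: every stochastic component takes an explicit seed;
`scripts/acceptance.py` derives all sub-seeds from its `--seed`
argument. Floating-point ties in substrate design are broken
lexicographically; arm order is canonicalized by site, making every
pipeline output deterministic given inputs and seed.

## Known limitations

- The nomenclature dialect is defined here, not transcribed from a
  published grammar; exotic nestings may render differently elsewhere.
- No isotope fine structure, adducts other than +H, multiple charging,
  or PTMs beyond the modeled substitutions/truncations/tags/¹⁵N.
- The peak-detection surrogate is not SNAP; it reports intensity-weighted
  centroids, which may differ from a fitted average mass on asymmetric
  real envelopes.
- Cross-spectrum normalization beyond the internal standard (e.g.
  response-factor drift between moieties) is out of scope; a
  response-factor mismatch shows up as flagged > 100% values, not as a
  correction.
- The ANOVA assumes equal within-group variances and independent
  replicates; the generator satisfies these by construction, real data
  need not.
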