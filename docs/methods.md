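# Methods

## Scope and data model

`glycoflav` implements the computational core of a UV-B stress study on
flavonoid-rich plant leaves: annotation of glycosylated flavonoids from
positive-mode LC-MS/MS fragmentation, multivariate prioritization of
untargeted signals, time-course fold-change analysis, and the
expression-side statistics (RPKM, differential-gene filters, pathway rich
factors, qPCR relative expression). Raw instrument and sequencing data for
such studies are typically not deposited, so a first-class synthetic-data
module generates every input with known ground truth; the packaged
54-metabolite table (name, RT, precursor m/z, main fragments, transcribed
once and checksum-frozen) is the only measured surface the package carries.

## Mass arithmetic

Monoisotopic atomic masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.9949146196, S 31.971971, P 30.97376163 Da) back a small `Formula` type.
`[M+H]+` arithmetic adds a proton at 1.00728 Da; the electron mass
(~0.00055 Da) is neglected, three orders of magnitude below the fragment
tolerance. Nominal loss masses are `round(monoisotopic)` — this matches the
integer "amu" loss arithmetic used in practice (449 → 329 is a 120 loss).
The 96- and 150-Da hexose cross-ring losses are carried as nominal-only
catalog entries: the literature does not agree on their elemental
composition, so they are always matched with a Da tolerance.

Default tolerances are 10 ppm for precursors and 0.5 Da for fragments
(printed fragment m/z values carry one decimal, precursors four). No
instrument tolerance was available to inherit; these are package defaults
and both are configurable.

## Annotation algorithm

For each dictionary aglycone the precursor budget is decomposed into ≤ 2
sugars + ≤ 1 acyl (an acyl group must decorate an O-linked sugar; a
structure never carries more than 3 modification units, the largest
observed). Each decomposition expands into linkage templates drawn from the
observed chemical classes; by default the O-sugar space is
{hexose, deoxyhexose} and the C-sugar space {hexose, pentose}, reflecting
the chemotaxonomy of the emulated system, where pentoses occur C-linked and
O-glycosides are hexosides. Both spaces are configuration, not hard-coded
chemistry.

Each template predicts ions: the free aglycone (only for bare/O-only
structures — a C-linked sugar never detaches completely), whole-unit losses
for every sub-multiset of O-linked units, cross-ring partials of C-sugars
from the precursor and from the C-core ion, combined pairwise partials when
two C-sugars are present, successive water losses (≤ 3 × 18.0106 Da) from
precursor and core for C-glycosides, and acyl marker ions (feruloyl
177.0546, coumaroyl 147.0441; malonyl is evidenced only through loss
arithmetic, 86 alone or 248 with its hexose).

Scoring: aglycone ion 3, whole-residue loss 2, acyl marker 2, partial loss
1 (halved for the 90/120 losses shared by the hexose and pentose series),
water 0.5; −1 per unexplained precursor-to-fragment loss above 40 Da
(smaller losses are common neutrals and in-ring fragmentation); −0.5 per
missing primary expectation (aglycone ion for O-only templates, full-O-loss
core for C,O-templates, and per C unit with no partial trace, −0.25 if only
ambiguous ones); −2 per Da of disagreement between the precursor and the
candidate's exact composition, which separates near-isobaric aglycones
(e.g. 0.036 Da apart) that the fragment tolerance alone cannot. Scores are
quantized to 3 decimals so that floating-point dust on truly isobaric
candidates cannot defeat the deterministic tie-break (score, then fewer
events, then alphabetical aglycone). Annotations differing only in
isobaric aglycones are merged into one result carrying the ranked candidate
set.

**Isobaric structures.** Fragmentation cannot cleave a C-glycosidic bond,
so the C-core (aglycone + C-sugars) is a mass-opaque block: a C-hexosyl
core on one aglycone is indistinguishable from a C-pentosyl core on its
+CH2O homolog (both C21H20O10 for the apigenin/chrysoeriol pair — the
packaged table indeed contains two compounds at m/z 771.21 with identical
printed fragment lists, distinguished in the original work only by RT and
standards). The `names_equivalent` comparator therefore treats structures
as equivalent when class, O-side events, and total C-core composition
coincide; for bare aglycones this reduces to formula equality
(quercetin/tricetin, chrysoeriol/methylluteolin, apigenin/resokaempferol).

**Mass-inconsistent records.** A handful of printed precursor masses
(e.g. 286.98 for a compound whose composition implies 287.09) cannot be
`[M+H]+` values of any structure in the chemical space. The annotator flags
spectra whose precursor is not reconstructable within 0.1 Da
(`is_mass_consistent`, name-blind) and falls back to nominal-Da reasoning;
the fixture audit uses a name-aware screen (`fixture_mass_screen`) that
compares each record's printed precursor with the mass its own printed name
implies, and excludes "derivative" rows whose names are not complete
structures. One audited record is knowingly misclassified: a compound named
as a di-C,C-glycoside whose printed fragments show a whole 162-Da loss
followed by cross-ring losses from that ion — the textbook C,O-pattern —
so the rule set scores C,O-di higher; it is reported as a listed failure.

## Chemometrics

Intensities are log-transformed (LC-MS intensities are near log-normal;
zeros are offset by half the smallest positive value) and Pareto-scaled:
mean-centred, divided by the square root of the feature standard deviation;
zero-variance features are dropped with a log entry. PCA is computed by SVD
with explained fractions σ²ᵢ/Σσ² and signs fixed so each component's
largest-magnitude loading is positive.

OPLS-DA codes the two classes ±1 (centred), removes `n_ortho` orthogonal
components by the standard sequence (w ∝ Xᵀy; orthogonal weight
p − (wᵀp)w; deflation), then fits one predictive PLS component on the
deflated matrix; `n_ortho=0` reduces exactly to PLS1. The default
`n_ortho=1` is the customary single-orthogonal-component choice for
two-class metabolomics. VIP is computed over the predictive component
(orthogonal components explain no class variance by construction):
VIPⱼ = √(p·wⱼ²/‖w‖²), so mean(VIP²)=1 identically; the VIP > 1 filter uses
a strict inequality.

## Time course and clustering

Per feature and time point, log2(mean treated / mean control); when only
the control mean is zero a pseudocount of half the smallest positive matrix
value keeps the ratio finite, and two zero means give 0. Per-cell
significance uses Welch's two-sided t-test (three biological replicates, no
evidence for equal variances). Trajectories are clustered agglomeratively —
default complete linkage on Euclidean distances over log2 fold changes, the
settings being configurable since the original visualization tool does not
document its own — via `scipy.cluster.hierarchy`, with an O(n³) brute-force
linkage serving as the test oracle. Optional per-row z-scoring before
clustering is available but off by default. Dendrograms serialize to
Newick.

## Expression statistics

RPKM = 1e9·counts/(library·length). Benjamini–Hochberg is the step-up
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1, order-preserving, cross-checked in
tests against statsmodels and a brute-force implementation. Two
significance filters coexist: the transcriptome-wide criterion (linear fold
change ≥ 2 in either direction AND FDR < 0.05) and the pathway-screen
criterion (p < 0.05 AND |log2FC| strictly > 1). The rich factor is
|DEGs ∩ pathway| / |pathway|; an optional hypergeometric tail probability
is an extension, off by default. qPCR relative expression is
2^−((ΔCt)ₜᵣ − (ΔCt)ᶜᵗˡ) with control replicates averaged into the
calibrator.

Count-model dispersion estimation and differential testing proper are out
of scope: the module consumes per-gene log2FC and p-values from file or
from the generator.

## Synthetic data: what it emulates, what it does not

Defaults are fixed to the emulated study design: ~1000 features, two groups
× 3 biological replicates, 10% informative features shifted by 2
within-group standard deviations on the log scale (log-normal noise,
sd 0.25 log-units; feature baselines spread with sd 1.5 log-units),
negative-binomial counts (dispersion 0.1) with planted 4-fold differential
genes, and qPCR Ct noise of 0.1 cycles. Spectra are generated from the same
fragmentation rules the annotator scores — the master inverse property
(annotate ∘ generate = identity on class, event multiset and aglycone
isobar class over the whole structure grid) is therefore a consistency
check of the rule set, not evidence about instrument data. Mass jitter is
Gaussian in ppm; decoy peaks are placed uniformly but never within twice
the fragment tolerance of a true diagnostic ion, keeping ground truth
well-defined. Count-table "true statistics" use median-of-ratios size
factors (total-count scaling is biased when a planted fraction is regulated
in one direction) and a negative-binomial Wald test at the generator's own
dispersion.

Not emulated: chromatographic peak shapes, isotope envelopes, co-elution,
adducts other than `[M+H]+`, negative-mode chemistry, instrument drift, and
real biological covariance between metabolites. Passing the synthetic
suites shows the algorithms implement their definitions and recover planted
structure under the stated noise; it does not certify performance on any
particular instrument's data.

## Numerical and degenerate-input choices

Deduplication of the signal library is greedy in descending s/n (ties by
lexicographic id), matching within 0.01 Da and 0.1 min by default; library
size is monotone non-increasing in both quality thresholds. Correlation
distance raises a named error on constant rows. BH rejects p-values outside
[0, 1]. `cut_clusters` relabels clusters 1..k by left-to-right leaf order.
All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; per-structure spectrum streams derive from a
CRC32 of the structure description, so they are stable across processes.

## Known limitations

Positional isomers (6-C vs 8-C, 5-O vs 7-O) are not resolvable from mass
and never emitted. Tri-glycosylated structures beyond C+O+acyl are outside
the template space. The acyl marker set covers feruloyl and coumaroyl only.
RT is carried through I/O but unused by scoring; an RT library hook is the
natural extension for resolving isobaric candidate sets.
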