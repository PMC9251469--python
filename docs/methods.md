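# Methods

## Clonality model

A two-lesion patient is modelled as two leaves of a clonal process.  Under
intrahepatic metastasis (IM) both lesions descend from one transformed
clone: mutations acquired before divergence (the *trunk*) appear in both
lesions, later ones are private.  Under multicentric occurrence (MO) the
lesions transform independently and share essentially nothing; any shared
call is coincidence or technical artifact.  The statistic is the Jaccard
index over genomic variant keys `(chromosome, position, ref, alt)` —
annotation fields (gene symbol, functional class) are excluded from
identity so the call cannot drift with annotator versions.  Chromosome
labels are compared after stripping a `chr` prefix; coordinates are
1-based inclusive throughout.

Decision rule: `J < 0.01 → MO`, `J ≥ 0.01 → IM`.  The boundary itself is
called IM so the better-prognosis MO label requires strictly sub-threshold
sharing; the threshold and the tie direction are configurable.  By default
the index is computed over **all** somatic variants (SNVs and indels), not
only non-silent ones — total mutation catalogs are what clonal ancestry
shares — with a non-silent-only mode available.

The pair phylogeny is combinatorially determined for two lesions: topology
`(Normal, (A, B))`, trunk branch length = shared count, leaf branch
lengths = private counts, emitted as newick.  No parsimony search is
implemented or needed.  Genes carried on the trunk are reported as
candidate early drivers.

The reported clinical statistics these defaults mirror contain an
internal inconsistency: a metastatic worked example reports 82 shared of 107 total
mutations (76.6%, J = 0.766) while the metastatic group's index range is
given as 0.08–0.7.  Either the 107 is not the union or the index used a
different variant subset; this package computes J on the union and simply
notes the discrepancy.

## Burden metrics

- **TMB** = (count of variants in the nine non-silent classes —
  Splice_Site, Splice_Region, Missense_Mutation, Nonstop_Mutation,
  Nonsense_Mutation, Frame_Shift_Ins/Del, In_Frame_Ins/Del) / `cds_mb`.
  Default `cds_mb = 36.0` (Agilent V6 exome CDS).  Note that a reported
  cohort mean of 77 non-synonymous mutations alongside "3.5 per Mb"
  disagrees under a 36-Mb denominator (77/36 ≈ 2.14); the formula here is
  the stated one, with the denominator configurable.
- **Segment states**: AMP iff total_cn > 2 × ploidy, DEL iff
  total_cn = 0, else NEUTRAL.  At ploidy 2 this reduces to AMP ⇔ cn ≥ 5.
- **CNV score** = Σ over segments with total_cn ≠ round(ploidy) of
  length(Mb) × w, with the default weight w = |total_cn − ploidy| / ploidy.
  The "relative average altered weight" is not defined in the source; the
  relative-deviation weight was chosen because it is unitless, zero for
  ploidy-neutral segments, and symmetric in gains and losses.  The weight
  function is a pluggable parameter.  The score is additive, hence exactly
  invariant under splitting segments of equal copy number.
- **Gene-level CNV**: a gene takes the state of the segment covering its
  midpoint (single unambiguous call for boundary-straddling genes); genes
  covered by no segment are NEUTRAL.
- **MSI**: MSI-H iff score > 20 (strict), else MSS.

## Mutational signatures

SNVs are binned into 96 trinucleotide contexts ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G) then 5′ base then 3′ base; purine-reference
SNVs are reverse-complemented first (pyrimidine convention), so the context
of a variant equals that of its reverse-strand representation by
construction.  A mismatch between the stated ref allele and the reference
sequence raises rather than silently mis-binning.

Exposures solve min‖p − S·e‖₂ subject to e ≥ 0 (scipy NNLS), where p is
the normalized 96-spectrum and S the signature matrix.  Exposures below
`min_exposure = 0.06` (the conventional default of reference-fitting
tools) are zeroed and the NNLS is **refit on the surviving support**, then
normalized to proportions.  Because lowering the cutoff can only enlarge
the support, the refit residual is monotone non-increasing in
`min_exposure` — a property the tests assert.  The fit is deterministic;
no iterative forward selection is used, which at the reported granularity
(five groups) changes nothing.

Exposures are reduced to {sig1, sig3, sig6, sig10, others} by default; the
named set is configurable (e.g. {1, 3, 6, 22}).

**Reference matrix.**  The bundled `signatures_synthetic_v1.tsv` is a
synthetic, deterministic 96 × 30 catalogue
(`signatures.synthetic_signature_matrix`, fixed seed): signature 1 is a
CpG-C>T deamination spectrum, 3 near-flat, 6 broad C>T, 10
T[C>A]T-dominated, the rest sparse random spectra.  It reproduces the
*structure* the analysis needs (distinguishable, column-stochastic
spectra), not measured human signature values; any 96 × K TSV with
labelled context rows can be supplied instead.

## Pathology arm

Tiles are square RGB patches (2048 px at 0.5 µm/px in production; the
geometry is size-invariant and tests use 256–512 px) cut on a
non-overlapping grid, keeping tiles with ≥ 50% of pixels inside the
cancer-region mask when one is given.

**Macenko normalization.**  OD = −log₁₀((I+1)/256); pixels with all three
OD channels ≥ 0.15 are stained tissue.  The two stain vectors are the 1st
and 99th percentile extremes of pixel angles in the plane of the top-two
singular vectors of the stained-pixel OD cloud; hematoxylin is the
red-absorbing column.  Concentrations (non-negative least squares) are
rescaled so their 99th percentiles match the reference tile's and
recombined with the reference stain matrix.  Two deliberate choices: the
OD residual outside the two-stain plane is carried through unchanged
(normalizing a tile against itself is then the identity, and stain-free
texture survives), and background pixels are passed through untouched.  A
tile with no stained pixels passes through with a warning.

**Segmentation.**  The per-tile hematoxylin concentration (from the same
stain estimate, luminance fallback if degenerate) is smoothed (Gaussian,
σ = 1 px) and thresholded hierarchically: 2-class Otsu separates tissue
from background, then 3-class Otsu within the stained pixels yields two
refined cut levels.  All three candidate cuts are labelled and the cut
retaining the most components in the 10–500 µm² size window wins (tighter
mask on ties) — this keeps homogeneous nuclei whole while excluding
weakly stained cytoplasm.  Survivors are relabelled 1..K.

**Features.**  Per nucleus: area (µm²), circularity 4πA/P², solidity,
channel means (rmean/gmean/bmean), grayscale std, and mean/max/min
centroid distance to the other nuclei of the tile (µm; zero for a
single-nucleus tile rather than dropping it).  The ten features are a
fixed, non-configurable list so vectors are comparable across runs.  Per
focus (nuclei pooled over all tiles): for each feature a 10-bin histogram
over **fixed global ranges** (per-image ranges would make bins
incomparable between foci) normalized to sum 1, plus mean, population
std, Fisher skewness, excess kurtosis, and base-2 Shannon entropy of the
histogram — 150 values.  Zero-variance features get skewness/kurtosis 0
by convention so vectors stay finite.  A 100-value histogram-bins-only
subset is exposed for compatibility with feature counts quoted elsewhere
(the 10 × 15 arithmetic yields 150; both views are available).

**Inter-focus correlation.**  Pearson correlation of the two foci's
feature vectors after feature-wise standardization against cohort
mean/std (zero-variance features dropped); raw and Spearman modes exist.
Correlation of a vector with itself is 1 by construction; zero-variance
vectors raise.

## Cohort statistics

Mann-Whitney U (exact enumeration when pooled n ≤ 12 and untied, else
normal approximation with tie correction) for burden comparisons, Welch
t-test as the parametric alternative, Fisher's exact test (two-sided,
sample odds ratio ad/bc with the ∞ convention) for per-sample gene
frequency 2×2 tables — the exact test appropriate for classification
counts, used deliberately in place of a rank test.  Kaplan-Meier curves
and the log-rank test come from lifelines.  Concordance is percent
agreement between molecular and pathology calls over patients with a
definite pathology call ("unknown" excluded on either side, which keeps
the measure symmetric); reported rounded to one decimal.

scipy and lifelines provide these standard tests behind the module
surface; the test suite checks them against independent brute-force
oracles (full hypergeometric enumeration for Fisher, hand-computed
product-limit values, closed-form Welch arithmetic, null simulations).

## Synthetic cohorts — what they emulate and what they do not

Defaults encode the study conditions: 17 patients with prop_im = 7/17
(exact-count allocation, order shuffled by seed); IM pairs draw
trunk ~ Poisson(82) and per-lesion private ~ Poisson(12.5) (expected
union 107, ≈ 77% shared); MO lesions draw Poisson(94.5) mutations each —
the same expected total burden as an IM lesion, so TMB is comparable
between groups — plus Poisson(0.1) coincidental shared calls.  The 0.1
rate gives an expected MO Jaccard ≈ 5 × 10⁻⁴, twenty-fold below the
decision threshold, while still producing occasional single shared calls
of the kind observed in real independent-primary pairs; rarer two-call
coincidences can legitimately push a small-union MO pair over the 0.01
threshold, which is a property of the classifier, not the generator.
Variant positions are drawn without replacement cohort-wide from a
deterministic seeded reference genome (10 × 100 kb contigs, generated at
run time and written as FASTA), so trinucleotide contexts are computable
offline and coincidental overlap is injected explicitly rather than
arising from uncontrolled birthday collisions.  Indels are 18% of calls.
TP53 and ARID1A carry group-specific patient-level mutation
probabilities (0.55/0.05 and 0.28/0.10 for IM/MO), placed on the trunk
for IM pairs and on one random lesion for MO pairs; passenger genes come
from a 500-symbol pool that excludes the modelled drivers.  Copy-number
segments are Poisson in number (18 IM / 12 MO) with exponential lengths
(mean 15 Mb) and a categorical copy-number distribution, giving IM the
higher expected CNV score.  Survival is exponential (median 24 months IM,
60 MO) with uniform censoring on [0, 84] months — closed-form medians
serve as test oracles.  The pathologist's call flips the truth with
probability 0.3.

Rendered tiles place non-overlapping ellipses (radius ~N(5, 0.8) µm,
eccentricity 0.75–1) with dark blue-purple cores inside eosin-pink
cytoplasm halos on a light-pink background, with Gaussian pixel noise;
ground truth (pixel-exact areas, centroids, channel means) is computed
from the label mask independently of any segmentation code.  IM focus
pairs share one morphology parameter draw; MO pairs draw independently,
with a divergence knob scaling the hyper-prior spread.

What the generator does **not** emulate: positional hotspots, subclonal
VAF structure, FFPE artifact spectra, real H&E texture, touching or
overlapping nuclei, and measured COSMIC signature values.  Passing tests
therefore demonstrate correctness of the computations and recoverability
under the stated clonal model — not performance on real slides or real
exomes.

## Problem sizes and numerical conventions

Acceptance-level measurements use: 1,000 random set pairs for the
Jaccard oracle, 500 simulated pairs for label recovery, 50 × 5,000
mutations for signature recovery, all 2×2 tables with row margins ≤ 30
(246,015 tables, exact integer enumeration) for Fisher, and 20 rendered
tiles with 5–50 nuclei for segmentation.  Sub-seeds are spawned from the
single CLI seed via `numpy.random.SeedSequence`.  Other conventions:
duplicate variant keys within a lesion collapse with a warning; an
all-empty pair of variant sets is an error (the call is undefined);
exposures, histograms and reduced signature groups are validated to sum
to 1 within 1e-6; percent agreement is rounded to one decimal only for
reporting.

## Known limitations

Only two-lesion patients are supported (the pair tree is not a general
phylogeny); purity is carried but not used to adjust copy number; the
MSI score is consumed, not computed from reads; signature fitting assumes
the 30-column reference spans the observed spectra; and the pathology arm
operates on pre-extracted tiles, not whole-slide pyramids.
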