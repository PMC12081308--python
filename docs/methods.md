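# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic data do and do not
emulate, and the design decisions taken where the underlying procedure
left room for interpretation.

## Isotopologue envelopes and the turnover statistic

Peptidoform elemental formulas are the sum of standard residue
compositions (from pyteomics' amino-acid table) plus one water and fixed
modification deltas (acetyl +C2H2O; mono/di/tri-methyl +CH2/+C2H4/+C3H6).
The heavy-arginine spike-in label changes isotopes, not the formula, and
is carried as a flag.

Aggregated (nominal-mass) isotopologue probabilities come from iterated
convolution of per-element isotope distributions (IUPAC 2013 abundances
for C, H, N, O, S), with exponentiation-by-squaring on arrays truncated
to the requested length — exact for the reported terms, since convolution
never moves probability toward lower mass. The truncated tail mass is
returned alongside. A brute-force enumeration over all atom isotope
states serves as the test oracle for molecules with at most ten
polyisotopic atoms.

The de novo acetylation statistic assumes: (i) the peptidoform is singly
acetylated, so one ¹³C₂-acetyl shifts the precursor exactly +2 Da;
(ii) control samples are unlabelled, so their M2/M ratio ρ is purely
natural abundance; (iii) noise is multiplicative, which motivates taking
ρ as the mean of per-replicate ratios rather than the ratio of means.
The corrected M2' = M2ᵗ − ρ·Mᵗ subtracts the natural M2 expected from
the observed M; this is the only reading of the correction with
consistent units and a zero expectation under no labelling. Negative
corrections (noise overshoot) are clipped to zero and logged. On
noise-free simulated mixtures the statistic inverts the generator
algebra exactly: with envelope p and label fraction f, Mᵗ = (1−f)p₀ and
M2ᵗ = (1−f)p₂ + f·p₀, so M2' = f·p₀ and the reported percentage is
100f.

Spike-in factors are the log-space median across heavy standards of the
standard's area divided by its geometric mean across samples. Log-space
makes the median coherent for multiplicative factors (an even number of
standards averages geometrically, e.g. ratios {2, 8} give 4); the
geometric-mean anchor makes the factors scale-free; the median tolerates
one aberrant standard. All rows of a sample, standards included, are
divided by the factor, which makes the operation idempotent and drives
heavy-standard cross-sample variation to zero on clean data.

Isobaric MS1 peaks are split by the mean of each species' unique MS2
fragment areas, normalized across species; the split conserves the MS1
area exactly. When every species' fragments are zero the peak is
reported unresolved (missing), never divided evenly. Three fragments per
species are expected; fewer warns, zero errors. Relative abundances are
percentages of the summed MS1 area over all observed forms of the same
backbone sequence (missed-cleavage variants are distinct backbones);
zero backbone totals yield missing percentages, not zeros.

Open order-of-operations question: whether deconvolution preceded
abundance calculation in the original workflow is not documented; the
pipeline runs deconvolution → normalization → abundance, and each step is
a pure function so any order can be composed.

## Single-cell stages

QC retains cells with mitochondrial fraction ≤ 0.15 and total counts
≥ 7,000 (a 5,000 floor suits shallower runs); mitochondrial genes are
recognized by a configurable "MT-" prefix, and the criterion is skipped
with a warning when no such gene exists. LogNormalize is
ln(1 + 10⁴·count/cell total). The HTO transform is the centred log-ratio
per cell on ln(x+1).

Demultiplexing approximates cluster-based hashtag classifiers: per tag,
cells split into background and positive groups by 1D 2-means on CLR
values, and a cell is positive when its log tag count exceeds the
background group's mean + 3 sd of log counts. The threshold deliberately
uses counts, not CLR: an ambient-only cell's CLR is near zero, which is
*above* the strongly negative CLR of cells dominant in another tag, so a
CLR threshold would call ambient cells positive; its counts, however,
stay at the ambient level. Zero positive tags → negative, one → singlet,
several → doublet. Doublets of two cells sharing the same hashtag are
indistinguishable by construction and are counted as singlets of that
tag; this bounds attainable doublet recall but not singlet precision at
the simulated 5% doublet rate. Exact reproduction of any particular
published demultiplexer's counts is a non-goal.

Module scoring follows the binned-control scheme that has become the de
facto standard behind per-cell gene-set scores: genes are ranked by mean
expression and cut into 24 equal-frequency bins; each signature gene
contributes 100 control draws (with replacement, fixed seed) from its
bin; the score is mean(signature) − mean(control pool). Signature genes
are processed in sorted order so the score is invariant to listing
order. A random gene set drawn from the full gene universe scores zero
in expectation; note that drawing candidates from a restricted pool
(e.g. excluding mitochondrial genes) while control bins span all genes
introduces a small systematic offset — the exclusion bias — which is why
the null checks sample from the full universe. The TE maturity score is
score(pTE) − score(mTE) over the two built-in 25-gene signatures
(shipped as package data). Gene symbols match case-sensitively after
whitespace stripping; no alias resolution is attempted.

Stage labels transfer by Euclidean kNN (k = 3) in a 2D embedding; vote
ties fall back to the single nearest neighbor, and equidistant reference
points resolve in reference order (stable argsort). Consolidation of a
cell's label multiset: strict majority wins; exactly two labels at
exactly half each form a composite in fixed developmental order (E5 <
E6 < E7 < ...), so "E6/E7" never appears reversed; empty multisets are
"unassigned"; everything else — including exact three-way splits — is
"ambiguous".

## Imaging

Scenes are single-plane 2D rasters; z-stacks are reduced by summing the
n central slices (window left-biased when off-center by one). Masks use
0-based row-major pixel coordinates with label 0 reserved for
background. When no aggregate mask is supplied it is derived from the
polarity channel by Otsu threshold, largest connected component and hole
filling.

Outer/inner classification replaces the manual selection of the original
workflow with a geometric rule: a nucleus is outer when its centroid
falls outside the aggregate eroded by the median nucleus equivalent
diameter (configurable). The rule is invariant to translation and 90°
rotation.

The apical rim is the aggregate minus the filled morphological closing
of the nuclear union (closing radius: median nucleus radius), tightened
by the convex hull of the closed region. Closing alone leaves inward
scallops between neighboring outer nuclei that leak interior pixels into
the rim and bias the polarity ratio low by roughly 15–25% at 2–4-fold
enrichment; the hull removes them for convex aggregates (bias ~5%), and
can be disabled for markedly non-convex ones. Nuclear pixels are
excluded from the denominator ("non-nuclear signal"). The three regions
— nuclei, apical, remaining — partition the aggregate mask pixel-exactly
by construction.

Nuclear intensities are per-label means, optionally background-subtracted
(mean outside the aggregate, clipped at zero) and normalized either to
each nucleus's own background-subtracted DAPI mean or to the outer-layer
mean (whose normalized average is then exactly 1).

## Metabolomics

Normalized area = analyte area / mapped internal-standard area in the
same sample, which cancels any per-sample multiplicative factor.
Calibration is ordinary least squares of normalized area on known
concentration with fitted intercept (through-origin selectable);
non-positive slopes reject the analyte's calibration, and samples
outside the calibrated range are flagged. Protein normalization divides
by per-sample protein micrograms. Fold changes are mean(treated) /
mean(control) — the control-group average is the reference — with
two-sided unpaired t-tests (equal-variance Student by default, matching
common graphing-software defaults; Welch selectable). Missing or zero
areas propagate as missing, never imputed; analytes with fewer than two
finite values in a group are skipped. No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as a flag.

## Synthetic data: what it emulates and what it does not

Generation starts at the processed level the quantification consumes
(peak tables, count matrices, label masks); raw spectra, reads and
microscope formats are out of scope. Noise magnitudes were not reported
for the original measurements, so defaults are chosen for testability:
5% multiplicative (lognormal) peak-area noise, 20% spike-in CV, 10%
metabolomics CV. Within each domain the defaults are:

- **MS**: a 14-peptidoform H3/H4 panel with one coeluting isobaric pair
  at a 60/40 true mixing share; envelopes follow each formula's
  theoretical natural distribution, mixed with a +2 Da copy at the true
  label fraction (default 0.2) in treated samples; 3 control + 3 treated
  samples; two heavy-arginine standards at constant amount.
- **scRNA-seq**: gamma-Poisson counts (dispersion 0.1) with lognormal
  gene means; signature shifts act on log-means (δ = 1 by default for
  the polar/mural populations, 500 cells each); mean depth 12,000 with
  30% CV; ten "MT-" genes receive a Beta(2, 20) per-cell count share
  (mean ≈ 9%), so default data straddle the QC thresholds; HTO counts
  are Poisson ambient (mean 5) with a 50× dominant-tag multiplier;
  doublets (5%) sum two cells and carry both tags.
- **Imaging**: 192² scenes, aggregate radius 70 px, rim width 5 px, 18
  outer nuclei of radius 7 px tangent to the rim plus 5 inner nuclei
  placed by bounded rejection sampling; the polarity channel is exactly
  a·b in the rim and b elsewhere inside, so the true ratio is a by
  construction; Gaussian read noise optional.
- **Metabolomics**: areas = concentration × response × sample factor ×
  noise with the same factor and noise model on the internal standards;
  a six-level dilution series; an optional protein confound multiplies
  treated samples' material and protein together.
- **Reference embeddings**: one Gaussian cluster per stage; queries and
  per-cell neighborhood memberships with recorded truth.

Identical configurations (seed included) give identical outputs; each
domain draws from an independent stream derived from the master seed.
Passing tests therefore demonstrate correct recovery under known,
well-behaved generative models — multiplicative noise, ideal peak
integration, perfectly registered masks, bimodal hashtag distributions —
not robustness to chromatographic drift, segmentation errors, ambient
RNA contamination or batch effects, none of which are simulated.

## Problem sizes and tolerances

The validation suite uses 50 random formulas against the enumeration
oracle (≤10 polyisotopic atoms); 200 simulated labelling experiments at
5% CV (mean absolute error required < 2 percentage points); 1,000 random
isobaric splits; exhaustive consolidation enumeration (multisets ≤ 5
over 4 stages); 1,000 cells for maturity AUC (> 0.95) and 200 random
25-gene draws for the null check (within 3 Monte-Carlo SEs of zero); 50
scenes per enrichment level a ∈ {1, 2, 4} (mean within 10%, monotone,
layer accuracy ≥ 95%); 500 fold-change simulations (|bias| < 2%) and
10,000 null analytes (type-I error in [0.03, 0.07] at α = 0.05).
Exact identities (area conservation, percentage sums, region partition,
noise-free recovery) are asserted at 1e-9–1e-12; floating-point
associativity is the only slack.
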