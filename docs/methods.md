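# Methods

This note documents the quantification procedures, the synthetic-data
models behind the test suite, the numerical choices, and the limitations.
Section order follows the analysis modules.

## SG screen scoring

The screen statistic for a gene with per-siRNA SG-containing-cell counts
`c_1..c_k` is `score = (Σ c_i) · #{i : c_i ≥ causing_min}`: the first factor
captures phenotype strength, the second its reproducibility across
independent siRNAs.  "Causing" is operationalised as `c_i ≥ causing_min`
with default 1 (any SG-positive cell); the threshold is configurable because
imaging setups differ in false-positive counts.  Candidates require
`score > 10` with ≥ 2 causing siRNAs or `score > 40` with exactly one, both
strict.  Replicate wells for the same (gene, siRNA) are summed before
scoring, since the score is defined on totals over all of a gene's wells.
Scores use raw counts; an optional per-1,000-seeded-cells rescaling exists
but is off by default.  Ranking ties break lexicographically by gene id so
output tables are deterministic.

*Simulator.*  ~1,000 genes × 4 siRNAs; counts are Binomial(cells_per_well,
rate), with rate `hit_sg_rate` (default 0.05, the level at which validated
hits are typically scored) when the gene is a hit **and** that siRNA is
effective (penetrance 0.75 by default), else `background_sg_rate`.  The
background default (1.5 × 10⁻⁴ per cell, 2,000 cells/well) was calibrated
once so that non-hit genes average an SG score of ~2, matching the level
reported for nontargeting controls in published SG screens.  What the model
omits: plate/edge effects, imaging miscounts, off-target siRNA phenotypes —
so passing recovery tests demonstrates correctness of the scoring rule, not
robustness to plate artifacts.

## Polysome profiles

Quantification is a ratio of trapezoid AUCs on the baseline-corrected
trace; the polysome region starts at the first local minimum after the 80S
peak, the practical automation of a boundary usually drawn by hand.  Choices:

- **Baseline**: default `linear-endpoints` (line through the means of the
  first/last 1% of samples, subtracted, clipped at 0); `rolling-min` and
  `none` are available.  Raw-recorder behaviour is `none`.
- **Peak detection**: `scipy.signal.find_peaks` by prominence (default 2%
  of dynamic range) on a Savitzky–Golay-smoothed copy (window ≈ 2% of the
  trace, polyorder 2); integration always uses the unsmoothed trace.  The
  80S peak is the most prominent maximum within the first 40% of the
  elution range (configurable window; gradient layouts vary); ties go to
  the earlier peak.  The boundary minimum must clear the same prominence
  bar, so noise dips on a flank cannot pose as the inter-peak valley.  A
  manual boundary override is available.
- **Total AUC** starts at the trace start by default; `total_from` can move
  it (e.g. to the 40S onset) since published percentages differ in whether
  the pre-40S region counts toward "total".  Neither choice is asserted to
  be the published one; defaults are this package's.
- **Fold changes**: paired designs use the mean of per-pair ratios and a
  one-tailed paired t test; unpaired or unequal-n designs the ratio of arm
  means and Welch's test.  Identical paired arms (all differences exactly
  zero) are reported as t = 0, p = 0.5 — the continuity limit of the paired
  statistic — rather than an error, because "no change at all" is a
  legitimate observation at the workflow level even though the bare t test
  is undefined there.
- **qPCR**: relative amount per fraction is `E^−(Ct_f − Ct_spike,f)` with
  amplification efficiency E = 2 by default (configurable; no efficiency is
  asserted for the original assays), reported as percent of the target's
  total so rows sum to 100.

*Simulator.*  Gaussian peak mixture (40S/60S/80S + ≥1 polysome peaks) over
a linear baseline with additive Gaussian noise and a rigid alignment
offset; truth records each peak and the analytic polysomal fraction (area
of polysome peaks over total peak area).  The default layout yields 70.3%
polysomal, typical of proliferating cells.  Not modelled: peak asymmetry,
gradient compression, detector saturation.  At noise ≤ 2% of peak height
the estimator recovers truth within 2 percentage points in ≥ 95 of 100
draws; the residual estimator-vs-truth discrepancy (~0.5 pp) comes from the
tails that the boundary split assigns differently than the analytic
per-peak decomposition.

## Ribosome density

**Trimming.**  The 3′ adapter is located by its longest prefix (≥ 6 nt)
occurring in the read, then 4 random nucleotides are stripped from each
end; inserts outside 15–45 nt are rejected with a reason.  Reads without an
adapter match keep their full length (flagged) before random-nt stripping.

**Alignment stand-in.**  An exact-match (0-mismatch) seed-and-verify
substring index replaces a short-read aligner: the computation of record
here is counting and normalization, and synthetic references make exact
matching sufficient.  Mismatch tolerance is deliberately out of scope;
externally aligned/classified reads can be imported instead.

**Classification** is hierarchical — tRNA, then rRNA, then the joint
human+yeast mRNA transcriptome, else unmapped — mirroring the practice of
filtering abundant contaminant classes first.  All transcriptome hits are
retained with a within-ORF flag (read interval fully inside the CDS,
0-based half-open: the strictest reading of "ORF-spanning").

**Counting.**  A read increments gene *g* iff every hit is within-ORF and
all hit transcripts share gene symbol *g*; multi-gene or partly-UTR reads
go to a discard ledger (multi-isoform single-gene reads count once).  Two
conservation identities hold exactly and are asserted in tests:
class totals sum to trimmed reads, and counted + discarded = transcriptome
reads.

**Spike-in normalization.**  Scale factor per sample = yeast ORF total of
the reference sample (first control) over the sample's own, computed
separately for footprint and input assays.  Input normalization by the
yeast *input* counts is the default (`spike_input=False` reproduces the
variant where only footprints are spike-scaled; the equal spike mass in the
lysate justifies symmetric treatment).  A `library-size` mode normalizes by
total counted reads instead — it exists to demonstrate that depth
normalization erases genuine global shifts, and the acceptance suite checks
exactly that contrast.

**RD.**  `RD = FP_norm / input_norm` per human gene, requiring raw input
counts ≥ `min_input` (default 10) in both conditions and nonzero footprints;
no pseudocounts — underpowered genes are filtered, not imputed.  The
summary reports the unweighted gene-mean RD per condition (primary) and the
pooled ΣFP/Σinput aggregate over the same genes, because "average RD" can
denote either estimator; on uniform suppression both recover the same
factor.  Categories are labelled with precedence TOP > IRES > mito-RP >
other; per-category output is the median log2 ΔRD plus a descriptive
two-sample KS distance against "other" (no p-value is attached).
Median-of-ratios size factors (`s_j = median_g k_gj / geomean_j' k_gj'`,
over genes nonzero everywhere, no rescaling) are provided for
depth-normalized per-gene comparisons; negative-binomial differential
testing is out of scope.

*Simulator.*  Two-species transcriptome (default 300 human + 20 yeast
mRNAs, single isoform each, uniform-random sequence; 3 rRNA + 5 tRNA human
contaminants), lognormal expression (σ = 0.75), categories drawn at
fractions TOP 0.15 / IRES 0.10 / mito-RP 0.05.  Footprint reads: Gaussian
lengths (mean 29, sd 1.5, clipped to the 25–35 size selection), 5′ ends
inside the CDS with frame-0 probability 0.8 (remainder split evenly);
input reads uniform over the transcript.  Every read is wrapped with 4
random nt per end plus a fixed 12-nt adapter and constant Phred+33 quality.
Yeast weights are scaled so yeast mRNA reads are 2% of the control
condition's total, expressing the spike as a read fraction rather than a
lysate amount.  Treatment multiplies human footprint rates by
`global_suppression` (× `top_extra_suppression` for TOP genes); input and
yeast rates are condition-invariant.  Presets: `null` (1, 1),
`cdk1i-global` (0.5, 1), `cdk1i-top` (0.5, 0.4).

*Precision floor.*  With a 2% spike, each sample contributes only ~0.02 × N
yeast reads to its scale factor, so the factor carries ~N_yeast^−1/2
relative noise; at 8 × 10⁴ reads/sample the four factors combine to ~5%
noise on the mean ΔRD — visible in null-preset runs.  Category median
*differences* are immune (factors cancel within a run).  Acceptance-scale
runs use 2 × 10⁵ footprint + 2 × 10⁵ input reads per condition (global
recovery) and 8 × 10⁴ each for the category-shift contrast at 200 genes;
these sizes keep the whole validation in minutes on one CPU while leaving
the recovery tolerances dominated by the statistics above, not runtime.
Not modelled: sequence composition bias, ligation bias, P-site offsets,
isoform complexity, UMI collisions.

## SILAC phospho ratios

Orientation: H/L is kept when the treated condition carried the heavy
label, inverted when it was light (the label swap in the replicate is the
control for labeling bias; a double float inversion is the only numerical
cost, ≤ 1 ulp).  Multiple phosphopeptides per site are aggregated by median
before orientation.  Protein normalization divides the oriented phospho
ratio by the oriented total-protein ratio, exactly cancelling protein-level
abundance changes; sites lacking a protein ratio stay in the output flagged
unnormalized.  Replicate concordance pairs sites present in both replicates
and reports Pearson's r of log ratios.  Hit calling — a quantification
choice of this package, since no published threshold exists for this assay
family — requires every replicate ≤ 1/fold_cut (down) or ≥ fold_cut (up),
fold_cut = 2 by default, reporting the geometric mean.  An important
consequence of the concordance rule: when the true effect sits exactly at
the cutoff, unbiased measurement noise puts each replicate on the wrong
side with probability ½, so sensitivity at the boundary is ~25% with two
replicates while the false-positive rate stays near zero.  The rule is
deliberately conservative (specificity over sensitivity); effects clearly
beyond the cutoff are recovered with high recall.

*Simulator.*  10% of sites carry a true phospho effect (default ratio 0.5);
per-site lognormal protein effects (σ = 0.2) multiply both measurements and
must cancel; independent lognormal measurement noise (σ = 0.1) on phospho
and protein ratios; replicate 1 treated-heavy, replicate 2 treated-light.
Not modelled: missing values, intensity-dependent noise, site-localization
ambiguity.

## Imaging

Nucleus segmentation is a global threshold (Otsu or fixed), 8-connected
components, minimum-area filter, raster-order labels.  Cell ROIs grow from
nucleus seeds across the eIF3B-foreground mask by nearest-nucleus-pixel
assignment (Euclidean distance transform), so ROIs are disjoint and contain
exactly one nucleus; border-touching cells are dropped by default (standard
practice; configurable).  Abutting nuclei merge — a documented limitation
of global thresholding, exercised by a fixture.  Per-ROI mean puromycin
intensities are averaged per condition and divided by the control mean
(exactly scale-equivariant); per-ROI values are retained for dispersion
reporting.  Background subtraction is off by default.  Lane densitometry:
trapezoid integrals of the signal and Ponceau profiles, normalized =
signal/loading, optionally relative to a control lane.

*Simulator.*  Concentric nucleus/cell disks placed by rejection sampling
with a no-overlap guarantee (error after bounded attempts); puromycin
intensity = condition mean × per-cell lognormal factor (σ = 0.1) over a
constant background; additive Gaussian noise on all channels.  Not
modelled: intensity gradients, out-of-focus light, irregular cell shapes —
so recovery tests validate the measurement arithmetic and seeded growth,
not shape-robust segmentation.

## Statistical tests

Welch (unequal variance, Welch–Satterthwaite df), paired t, and ratio
paired t (natural log — the base cancels in the statistic — of values
relative to a control set to 1, one-sample t against 0).  All one-tailed
with an explicit, mandatory direction; p ∈ (0, 1]; zero-variance inputs
raise a degenerate-variance error rather than returning NaN.  No
multiple-testing correction is applied (these are figure-level tests of a
handful of replicates).

## Determinism

Every generator is a pure function of (config, seed) via
`numpy.random.default_rng`; outputs are bit-reproducible.  All tie-breaks
(ranking, peak ties, contested segmentation pixels) are documented and
deterministic.
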