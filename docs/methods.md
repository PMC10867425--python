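# Methods

## Variant screen

Protein-level HGVS notation is parsed over the dialect that population
database exports actually use: optional `p.` prefix and parentheses, one-
and three-letter amino-acid codes, and the classes stop-gain (`Q1012*`,
`Gln1012Ter`), frameshift (`L7Qfs*21`), start loss (`M1?`), missense and
synonymous. Anything else (in-frame indels, extensions) is classed `other`
with a warning rather than rejected, since such records should survive a
screen untouched rather than abort it. Truncation arithmetic follows HGVS
semantics: a stop at position p retains p−1 wild-type residues; `fs*N`
retains p−1 wild-type residues plus N−1 novel-frame residues before the
new stop.

The prevalence filter nominates a variant when its consequence is
truncating (stop-gain or frameshift) and it is carried by at least
`min_individuals` people (default 2). Carriers are counted as het + hom
*individuals*, not alleles. Because cohorts from different databases can
overlap (a genome may appear in more than one aggregation), carrier counts
are **never summed across sources by default**; the filter uses the
maximum single-source count, and pooling is an explicit opt-in
(`sum_sources=True` / `--sum-sources`). Whether the original screen pooled
or not is not derivable from its description, so both behaviours are
exposed and labelled. Likewise the filter requires the *same* variant
(gene + normalized notation) in two individuals, the stricter of the two
possible readings of "in at least two individuals".

Allele frequency is the standard diploid estimate
(het + 2·hom) / (2·n_individuals). Outputs are canonically sorted by
(gene, residue position, class) so that re-runs are byte-identical.

## Kozak alternative-start scanning

Only in-frame downstream ATGs are candidate rescue sites: an out-of-frame
start cannot produce an N-terminally truncated isoform of the reference
protein. Context strength follows the initiation hierarchy: purine at −3
AND G at +4 ⇒ strong; exactly one ⇒ adequate; neither ⇒ weak. The full
`(gcc)gccRccAUGG` consensus contributes a reported similarity score but
not the strength call. Default stringency is `strong`. Coordinates are
1-based and CDS-relative with the A of ATG at +1, so codon c sits at
nt 3(c−1)+1 — codon 152 ⇔ nt 454, codon 275 ⇔ nt 823. Context positions
that fall off the sequence ends are counted as mismatches.

Predicted masses use average (not monoisotopic) residue masses with one
water per chain, minus one water per fusion junction — the right scale for
comparison against gel migration, which is itself only accurate to a few
kDa.

## Kinetochore quantification

Detection operates on the reference (centromere-marker) channel:
Gaussian-smoothed Sobel gradient magnitude at `edge_sigma` (default 1 px),
Otsu threshold on the edge response (absolute override available), binary
closing, per-component hole filling, and removal of components outside
[`min_size_px`, `max_size_px`] (defaults 4 and 200 px). The upper bound is
applied to the raw edge contours as well: the cell outline is itself a
strong closed edge and would otherwise flood-fill into a cell-sized
component that swallows every spot. Finally each component is refined to
its half-maximum support on the *unsmoothed* image (pixels above
floor + 0.5·(peak − floor), floor taken as the median of a surrounding
margin). This refinement serves two purposes: it decouples the photometry
mask from the width of the edge response (the edge ring of a Gaussian spot
has a detector-dependent radius, which would bias mean intensities), and
it splits components in which two nearby spots — sisters at minimum
separation — were bridged by the closing step.

The cytoplasm proxy is a ring: the cell mask (Otsu on the smoothed
measurement channel, largest component, holes filled) eroded by
`erode_outer_px` minus the same mask eroded by `erode_inner_px`
(defaults 5/15 px), with all detected particle pixels excluded. Camera
background is the modal rounded intensity outside the cell, and the
per-particle readout is (mean_meas − bg) / (ring_mean − bg), which is
invariant under affine camera rescaling when the background is
re-estimated. Background subtraction can be disabled to reproduce the
alternative convention.

**Z handling.** Stacks are reduced to 2D by **mean projection** by default.
The camera model is Poisson shot noise plus Gaussian read noise; a maximum
projection rectifies that noise, inflating flat regions (cytoplasm,
background) by roughly 0.85σ while leaving spot centres — where one plane
dominates — unshifted, which biases the measured ratio low by ~10% at
SNR 10. The mean is linear, so the shift cancels identically between
numerator and denominator; with it the pipeline recovers the generator's
ratio within ~1.5% at SNR 10. `projection="max"` remains available for
display and for data where read noise is negligible.

Crescent scoring maps each kinetochore's ratio to none/low/medium/high via
a monotone step function whose default thresholds are the quartiles of a
user-supplied control (wild-type) ratio distribution.

## Tracking and inter-centromere stretch

Linking is greedy mutual-nearest-neighbour between consecutive frames with
a hard displacement cap and no gap closing: at the spot densities of a
mitotic cell (~24 kinetochores, spacing ≥ 10 px) this is exact whenever
per-frame displacement is below half the minimum spacing, which the tests
verify against generator identities. Sister pairing is mutual nearest
neighbour with separation inside a physiological window, default
0.5–2.5 µm, bracketing published metaphase inter-kinetochore distances;
the window is a package default, not a measured quantity, and is
configurable. T₀ — the unstretched state — is taken as the
minimum-distance frame (earliest on ties) by default, with `mode="first"`
provided for sensitivity analysis since "unstretched" is an operational
rather than formal notion. n(T₀) = 1 holds exactly by construction.

## Timing statistics

t50 reads the empirical cumulative step function at 0.5 **without
interpolation**, honouring the acquisition grid (6-min frames): it is the
smallest observed duration t with (#completers ≤ t)/n ≥ 0.5. Cells that
never reach the event stay in the denominator by default, matching
cumulative-frequency curves that plateau below 100%; `completers_only`
restricts the denominator. Cells not finishing within the imaging window
(default 10 h) are censored as non-completers. Event fractions are
computed per replicate and then averaged (dots-per-experiment convention),
with pooled fractions reported alongside.

Hypothesis tests delegate to scipy behind one surface: two-sided
Mann-Whitney U (exact null for n ≤ 8 without ties, otherwise normal
approximation with tie correction), Pearson χ² without continuity
correction, paired t, and Dunnett's many-to-one comparison. The test
suite checks the Mann-Whitney p against an independent exhaustive
enumeration of the U distribution for all n₁, n₂ ≤ 6.

## Synthetic data

The image generator renders a disk cell (flat cytoplasm level + integer
camera offset) containing sister-spot pairs: isotropic 2D Gaussians
(σ = 1.5 px, diffraction-limited at 100×/0.1 µm pixels) per Z plane with a
Gaussian z-attenuation (3 planes, 0.6 µm apart), pair separation
d(t) = 1.2 + 0.3·sin(2πt/8) µm, optional drift and linear ratio fade,
Poisson noise on the signal, then Gaussian read noise, then the offset.
Spot amplitudes are set so that the mean intensity over the spot's
half-maximum footprint, after mean projection and background subtraction,
equals the configured kinetochore/cytoplasm ratio exactly; the truth table
carries per-frame centroids, identities, pair memberships, d(t), true
ratios and the FWHM footprints. SNR is defined as measurement-spot
amplitude over read-noise σ. Defaults (24 kinetochores, 6-min frames,
ratios ~1–3) mirror a metaphase acquisition.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate — includes: realistic PSF physics (Airy rings,
z-asymmetry), deconvolution artefacts, spot clustering at high density,
uneven illumination, photobleaching beyond the optional linear fade,
cytoplasmic texture, and neighbouring cells. Detection and ratio-recovery
figures on real movies will be worse than the synthetic ones in proportion
to these effects.

The variant generator draws minor-allele frequencies from Beta(0.5, 10)
truncated to (0, 0.05] (rare LoF regime) and genotype counts from the
F-adjusted frequencies, reproducing the excess homozygosity of cohorts
with elevated parental relatedness; F = 0 reduces to Hardy–Weinberg
(verified by goodness of fit) and F = 1 eliminates heterozygotes. The
timing generator supports exponential, lognormal and degenerate duration
distributions, rounded *up* to the frame grid (an event is first seen at
the frame after it happens) and censored at the window.

A note on the t50 validation: with n = 500 cells the empirical 50%
quantile of an exponential with median 60 min has a sampling sd of ~4 min,
so individual seeds can land two frames (12 min) from the median even
though the median across seeds sits within one frame; the acceptance test
asserts exactly that (median error ≤ one frame, worst case ≤ one frame
plus a 3σ quantile excursion).

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable statistics: 200×200 px, 3-Z, 2-channel stacks
with 24 kinetochores over 3–10 frames (5 seeds at SNR 10), 50 particles ×
30 frames × 20 seeds for linking, 100 random 200-row tables for the filter
oracle, 1,000 random CDSs for the scanner oracle, and 20 × 500 cells for
timing. All randomness flows from explicit seeds; identical configs give
bit-identical outputs (OME-TIFFs embed a content-derived UUID for this
reason).

## Known limitations

- No 3D segmentation or tracking; Z is reduced before analysis.
- No gap closing in linking (an optional 1-frame gap is the only planned
  extension); occlusions fragment tracks.
- Consequence calling from genomic coordinates is out of scope: variant
  ingestion requires protein-level annotations (`HGVSP` INFO key for VCF).
- The Kozak scan models initiation context only — no ribosome profiling,
  uORFs, or nonsense-mediated-decay modelling; it predicts candidate
  starts, not isoform abundance.
- Sister pairing assumes metaphase-like geometry; prometaphase clouds with
  inter-kinetochore distances outside the window will pair sparsely.
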