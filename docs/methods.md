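# Methods

This note documents the models and procedures implemented in `polarquant`,
the parameters that matter, the design choices made where the underlying
measurement conventions are not fully standardized, and what the synthetic
data do and do not establish about real data.

## Snapshot quantification of polar fluorescence

**Cell geometry.** A segmented cell is its set of labelled pixels plus two
pole anchors: the extremal pixels along the cell's principal axis (PCA of
the pixel coordinates), with near-ties broken toward the medial axis so that
anchors sit on the cell midline rather than at cap corners. Coordinates are
0-based (row, col); pixels are treated as half-open unit squares.

**Pole regions.** The search domain for polar clusters is the set of cell
pixels whose projection onto the long axis lies within a configurable
fraction (default 0.2) of the cell length from each pole. The 20% default
keeps the two regions disjoint while covering the pole caps where polarly
localized proteins cluster; the quantity being measured (total cluster
fluorescence) is insensitive to the exact fraction as long as the region
contains the cluster.

**Cytoplasmic background.** The cytoplasmic mean μ and standard deviation σ
are computed per cell, from the cell pixels outside both pole regions, in a
single pass with no iterative re-estimation. This is deterministic and
unbiased by cluster brightness. Cells with fewer than 10 cytoplasmic pixels
are flagged unquantifiable and skipped. σ is a population (ddof = 0)
standard deviation.

**Cluster calling.** Per pole, the candidate is the 4-connected component
of supra-threshold pixels (pixel value > μ + 2σ) containing the pole
region's brightest pixel. It is accepted as a polar cluster when its mean
exceeds μ + 2σ and it spans at least 3 pixels; in time-lapse mode the mean
must additionally exceed 2μ. At most one cluster per pole. The pixel-level
threshold that *delimits* the candidate is a design choice (the acceptance
rule constrains only the component's mean); using the same μ + 2σ level for
both makes accept/reject decisions invariant under affine intensity
transforms of the whole image — except that the time-lapse 2μ rule is
invariant only under purely multiplicative transforms, since an additive
offset shifts the mean and twice the mean by different amounts.

**Asymmetry index and binning.** For each cell with at least one cluster,
ω = (F₁ − F₂)/(F₁ + F₂) with F₁ ≥ F₂ the total (summed) cluster
fluorescence at the two poles; one cluster gives F₂ = 0 and hence ω = 1.
Patterns: unipolar ω > 0.9, bipolar asymmetric 0.2 < ω ≤ 0.9, bipolar
symmetric ω ≤ 0.2, diffuse when no cluster is detected. The class
boundaries 0.9 and 0.2 themselves are assigned to the less extreme class (a
tie-break the strict inequalities of the binning convention leave open).
Per-cell fractions f_pole1 + f_pole2 + f_cyto = 1 are computed against the
total cell fluorescence; the population summary reports pattern percentages
over all quantifiable cells and fluorescence means over the cells with
clusters, matching how snapshot scatter plots are conventionally drawn.

## Time-lapse tracking and the dynamic asymmetry index

**Linking.** Greedy nearest-centroid matching with a displacement gate
(default: half the mean cell length per frame). Ambiguous matches (two
candidates within the gate) terminate the involved tracks rather than guess;
tracks are never merged across gaps. Pole identities a/b are propagated by
nearest-pole matching and are *not* relabeled at reversals.

**Reversals.** Per-interval centroid displacement is projected onto the
cell's long axis; a reversal is a sign change between consecutive
*significant* runs, where a run is significant when its cumulative absolute
displacement exceeds a gate (default: a quarter of the axis length,
approximately one cell width for a 4:1 aspect rod). The gate suppresses
single-frame jitter; sub-gate backsteps between same-direction runs are
ignored. The event frame is the first frame moving in the new direction.
Reversal frequency is reported as the event count in the first full
reporting window (600 s for pili-driven motility, 900 s for gliding); a
track shorter than the window is excluded. A cell counts as moving when its
median per-interval speed exceeds 0.5 px/interval (no standard threshold
exists; this default is well below typical gliding speeds and well above
centroid quantization noise).

**Dynamic ω.** Pole roles (leading/lagging) are derived from the gated run
structure, so they swap exactly at detected reversals. Per frame,
ω_dyn = (F_leading − F_lagging)/(F_leading + F_lagging) ∈ [−1, 1], with
−1 meaning unipolar at the lagging pole. A frame enters pooled statistics
only when the cell moved for ≥ 3 successive frames without reversing,
excluding the first frame after and the last frame before a reversal, and
only when F_leading + F_lagging > 0. Per-pole fluorescence is the accepted
cluster's summed intensity (consistent with the snapshot ω), zero when no
cluster passes the time-lapse rule at that pole.

**Statistics.** Welch's unequal-variance t statistic and the
Welch–Satterthwaite degrees of freedom are implemented directly (only the
tail probability comes from scipy's t distribution), and cross-checked in
the test suite against scipy's independent implementation to 1e−10.

## GTPase assay kinetics

**Coupled assay.** The regenerative coupled assay reads GTP hydrolysis as
NADH oxidation (1:1) at 340 nm. The rate is the OLS slope of A340 vs time
over the full 60-minute trace by default — the published quantities are
1-hour activities, so a full-window fit rather than an initial slope is the
faithful estimator; a configurable window is available, and traces reaching
NADH depletion (A340 ≤ 0.05) are truncated before the depleted points. The
specific activity is

rate = (slope_background − slope_sample) / (ε·l) · 3600 / [E],

in GTP per enzyme per hour, with ε₃₄₀ = 6220 M⁻¹cm⁻¹ and a configurable
effective path length (default 0.5 cm — the plate-reader path depends on
well volume and no standard value exists). A background steeper than the
sample clamps the rate to zero with a flag. Replicates are averaged with a
standard error (technical-replicate convention).

**Malachite endpoint.** A590 standards are fitted by OLS; released Pi of a
sample is read off the line and converted to a rate by dividing by the
enzyme concentration and incubation time (default 1 h). Samples above the
top standard are flagged as extrapolated.

**Titrations.** GAP titration curves are fitted to the hyperbola
activity(x) = A₀ + A_max·x/(K + x) by nonlinear least squares. "Saturation
concentration" is operationalized as the smallest *tested* concentration
whose fitted activity reaches 95% of the fitted plateau (A₀ + A_max); with
no criterion in common use this definition is explicit and reproducible. A
series with an overall decreasing trend violates the model and is flagged
without fitting.

## Co-occurrence profiling

Profiles are boolean presence vectors over genomes. The default similarity
is the Jaccard index n₁₁/(n₁₁ + n₁₀ + n₀₁), which ignores genomes where
both genes are absent — the right behaviour when the genes of interest occur
in a small minority of a ~1600-genome panel, where counting shared absences
would make every pair look similar. The phi coefficient is available as an
option. Rankings are descending by score with alphabetical tie-breaks, and
the pairwise table reports per-phylum/class/order presence fractions. No
phylogeny-aware correction for lineage non-independence is attempted.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their spec (seed included); identical
specs give bit-identical outputs.

**Snapshot scenes.** Cells are axis-aligned rods (rectangles with
semicircular caps, default 30 × 8 px) on a non-overlapping grid —
pole geometry, not cell curvature, is what the analysis consumes, and
axis-aligned rods make the ground-truth pole anchors exact. Cytoplasm is
Gaussian (mean 100, sd 5 by default) plus optional global Gaussian imaging
noise; there is no PSF convolution or shot noise. Cluster pixels replace
cytoplasm values at the pole tips. For two-cluster cells the dim pole gets a
minimum-size cluster at the full cluster intensity (default 3× the
cytoplasm mean, detectable by construction) and the bright pole's cluster
grows in pixel count — with its value fine-tuned continuously — so the raw
cluster-sum ratio realizes the target ω exactly. Default intended-ω ranges
(unipolar exactly 1 via a single cluster; bipolar asymmetric 0.25–0.75;
bipolar symmetric 0–0.15) sit inside the classification bins so that modest
noise cannot move a cell across a bin boundary, and the 0.75 upper end keeps
the bright cluster small enough to fit inside the pole cap. Pattern classes
are drawn per cell from the mixture (multinomial), so realized class counts
fluctuate binomially around the mixture — tests and recovery targets budget
for that.

**Time-lapses.** Each cell glides along its long axis in its own lane at
N(speed_mean, speed_sd) px/interval; reversals follow a Poisson process
(exponential interarrivals) and flip the direction instantaneously at the
next frame boundary — no pause states, no lane changes, no divisions. Two
latent events landing in the same interval cancel; the ground truth
therefore records both the raw Poisson count and the effective per-frame
reversal list that the rendered movie actually shows. Pole clusters follow
the leading/lagging role with a swap lag of zero frames, at intensities
given by the pole rule (default: lagging pole 300, leading pole none,
emulating a lagging-pole protein).

**Kinetics.** Coupled traces are exactly linear (ideal regeneration, excess
coupling enzymes) plus optional Gaussian noise and a linear background
drift; there is no coupled-lag phase or NADH-depletion curvature, which is
why the round-trip recovery of the turnover is exact at zero noise.
Malachite plates are exactly linear in Pi.

**Presence/absence matrices.** The reference gene's profile is
Bernoulli(0.5) over genomes; each other gene matches the reference value
per genome with its co-occurrence probability and takes the complement
otherwise. Taxon labels cycle through a fixed five-lineage palette.

Because the generators realize the analysis' own assumptions exactly,
passing recovery tests demonstrates the *correctness of the computations*
(thresholds, partitions, unit conversions, detectors), not robustness to
real-microscopy nuisances (segmentation errors, photobleaching, uneven
illumination, drift) — those are explicitly out of scope.

## Problem sizes and numerical choices

Recovery checks use the study-scale problem sizes: 200-cell snapshot
populations, 60-minute traces sampled every 15 s, 6-point standard curves,
15-minute/30-s time-lapses with tens of cells, and co-occurrence panels of
a few hundred to ~1600 genomes. The full test suite runs in well under a
minute on one CPU. Ties anywhere (brightest pixel, pole anchors, rankings)
are broken deterministically (lexicographically or alphabetically), so all
outputs are exactly reproducible for a fixed seed.

## Known limitations

* The reversal detector is a stated stand-in: field practice computes
  reversal counts but rarely publishes the detection rule; the gated
  sign-change detector is robust to jitter but misses events whose
  flanking runs are shorter than the gate.
* Cytoplasmic σ is per cell, not per image; dim cells with few cytoplasmic
  pixels have noisier thresholds (cells under 10 cytoplasmic pixels are
  refused).
* No sub-pixel cluster localization, no multi-channel colocalization, no
  lineage tracking through division, no phylogenetic correction in the
  co-occurrence ranking.
* There is no dedicated "weak polar signal" class: a dim cluster either
  passes the detection rule or the cell is diffuse.
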