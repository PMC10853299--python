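# Methods

## Overview

rimsift implements a lesion-wise analysis of normalized 3D T1 intensities
in multiple sclerosis: deeply hypointense voxels are characteristic of
phase-rim lesions (PRLs), and the 5th-percentile (p5) intensity of each
lesion supports a simple, highly specific threshold classifier. Because
the package ships no patient images, a synthetic phantom generates every
input the analysis consumes; the phantom's defaults *are* the study
conditions the tests check against.

## The phantom

A cubic grid (default 96³ voxels at 0.5 mm isotropic; all four volumes
share one diagonal affine) of normal-appearing tissue is seeded with
non-overlapping lesions. Placement is rejection sampling (up to 1000
attempts per lesion) with a one-voxel Chebyshev gap enforced around each
lesion, so every planted lesion is its own 26-connected component and
component-level ground truth is unambiguous. Lesions are rasterized
spheres (voxel centers within the radius; radii uniform in 1.5–3 mm by
default), which keeps their volumes checkable against an exhaustive grid
scan. Per subject the default plants 60 nPR-WMLs, 25 PRLs, 3
contrast-enhancing and 3 sub-1 mm³ lesions; the published cohort's
lesion-level class imbalance (39 PRLs vs 1075 nPR-WMLs) is a pooled
multi-patient count, not a per-volume load, and enters the tests through
the split-arithmetic check instead.

Voxel intensities are drawn on an already-normalized 0–100 scale:

* **nPR-WML**: a sharp Gaussian core N(64.8, 3.0) carrying 90% of the
  mass plus a broad co-centered Gaussian pedestal N(64.8, 24.2) carrying
  10%. The sum is unimodal at 64.8. The pedestal width is calibrated
  analytically so the class mass below intensity 25 is 0.50%
  (24.2 ≈ 39.8 / z₀.₀₅). A single Gaussian cannot satisfy both targets:
  putting 0.5% of its mass below 25 forces σ ≈ 15.5, and the resulting
  flat-topped histogram lets the detected mode wander several intensity
  units at 10⁵ samples.
* **PRL**: a two-component mixture — 14% hypointense N(0.9, 3.0) and 86%
  lesional N(60.2, 3.5). The fraction below 25 is then 14.0% to three
  decimals, since each component's leak across the cutoff is negligible.
  Within a sphere the hypointense draws are assigned to the outermost
  voxels first (rim-like); the per-voxel hypo probability stays 14%
  regardless of geometry, which is the only quantitative constraint the
  analysis uses — rim thickness is deliberately uncalibrated.
* **Background**: N(50, 21.5). The standard deviation puts the
  brain-wide p1/p99 landmarks analytically at ≈ 0/100, so an undistorted
  phantom already lives on its own standard scale and normalization is
  close to the identity — the reference point for the distortion-recovery
  tests.
* **Enhancing lesions** are nPR-WML-like pre-contrast and N(90, 3)
  post-contrast; all other tissue is identical in the pre- and
  post-contrast volumes. **Tiny lesions** are 1–7 voxel clusters
  (< 1 mm³ at 0.5 mm isotropic), filled in a fixed 2×2×2 order so every
  prefix is 26-connected.

Optional distortions give normalization something to undo: a
multiplicative bias field 1 + a·f (f a sum of three low-order cosine
modes, max |f| = 1; amplitude default 0) and a global affine intensity
distortion s·x + b. All randomness flows from one integer seed through a
single `numpy` generator; equal specs give bit-identical volumes.

What the phantom does **not** model: brain anatomy, partial-volume
effects, Rician noise, susceptibility/phase contrast, within-class
intensity correlation between neighboring voxels, patient-level
clustering of lesions. Passing tests therefore demonstrate correctness
of the *analysis machinery* and recoverability of the calibrated
intensity structure — not clinical performance on real MRI.

## Normalization

Two-phase piecewise-linear histogram matching. Landmarks are the deciles
anchored by p1/p99 (the method's canonical configuration; the published
workflow delegates the exact configuration to its normalization package,
so this choice is documented rather than asserted as identical). Training
maps each cohort image's landmarks affinely so p1/p99 hit 0/100 and
averages across images — invariant to per-image affine intensity
transforms. Application interpolates linearly between an image's own
landmarks and the template values and **extrapolates** linearly beyond
p1/p99: clipping would destroy the deep-hypointense tail the entire
analysis depends on. The normalization mask is the brain mask (all
nonzero voxels in phantoms). Percentiles everywhere use the linear
interpolation estimator at fractional index (n−1)·p/100, pinned once in
`rimsift._stats` and reused by every module.

Degenerate inputs are rejected explicitly: masks with fewer distinct
values than landmarks, non-monotone landmark vectors (constant images),
and non-monotone cohort averages all raise errors rather than producing
a silently invalid template.

## Lesion tabulation

The nPR-WML map is `total AND NOT prl`. Components are labeled at
26-connectivity by default (the 3D default of the common cluster
utilities; 6 and 18 are available) and relabeled deterministically by
first voxel in C-order. Features: voxel count, volume (count × voxel
volume), mean normalized post-contrast intensity, p5 of normalized
pre-contrast intensities. Filters are strict inequalities, applied
volume-rule first: volume < 1 mm³ removes a lesion (so an 8-voxel lesion
at 0.5 mm isotropic, exactly 1 mm³, is kept), and mean post-contrast
intensity > 80 removes it (80.0 is kept). Removal counts are reported
per rule.

## Voxel-wise histograms and mode detection

Group histograms use uniform right-open bins of width 0.1 from
floor(min), with heights in percent of the group's voxels so unequal-n
groups overlay directly. Mode detection smooths with a centered moving
average (window 5 bins) and takes local maxima by topographic prominence
(`scipy.signal.find_peaks`). A candidate counts as a mode when its
prominence is at least half its own smoothed height and at least 5% of
the tallest bin; the two most prominent candidates spanning at least
five bins are kept, ties broken toward the taller then the
lower-intensity peak. The own-height criterion is what separates a
genuine small mode (the deep-hypointense PRL mode stands on its full
height) from a sampling bump riding the flank of a dominant mode (whose
prominence is near zero however tall it is); pure height ranking
demonstrably fails at fine bin widths. The inter-mode minimum is the
lowest smoothed bin strictly between the two modes. A consequence of the
0.5-prominence rule: a bimodal density whose valley is shallower than
half the smaller peak is reported as unimodal.

At 10⁵ samples the detected mode locations have a sampling scatter of a
few tenths of an intensity unit (the small hypointense mode is the
noisiest; it can occasionally miss its generative mean by slightly more
than one unit). Deep-voxel fractions count values strictly below the
cutoff (default 25, the inter-mode minimum of the published group
histograms).

The Wilcoxon rank-sum test uses midranks; the null is enumerated exactly
(polynomial recursion) when m + n ≤ 20 without ties, otherwise a
tie-corrected normal approximation with continuity correction is used,
two-sided by doubling the smaller tail.

## Classifier

Stratified lesion-level split (default 50%, odd class counts favor
training — 39 PRLs split 20/19). Candidate cutoffs are midpoints between
consecutive sorted unique training p5 values plus two finite sentinels:
the minimum p5 (all-negative rule) and the maximum p5 + 1 (all-positive
rule); finite sentinels keep the selected cutoff finite while realizing
both degenerate classifications, and make the all-negative rule (speci-
ficity 1) always admissible. Prediction is strictly `p5 < cutoff`: a
lesion exactly at the threshold is called negative. The default
specificity constraint is 0.95; the published workflow prioritized
specificity without printing the constraint, and 0.95 is consistent with
its achieved test specificity of 0.959. Confusion metrics are exact
rational identities on the counts; ratios with zero denominators are
reported as undefined (None) and flagged, never coerced to 0. Reported
metrics round half-up to 3 decimals. The Fisher exact p on the confusion
matrix is two-sided (sum of same-margin tables no more probable than the
observed one), computed by `scipy.stats.fisher_exact` and verified
against full hypergeometric enumeration in the tests.

The split is lesion-level, mirroring the published design; with real
multi-lesion patients this leaks patient identity across the split, a
caveat that applies equally here.

## Problem sizes and verification

The test suite runs each stochastic check at the size its result needs:
10⁵ voxels per class for voxel-wise recovery (binomial SE of the 14%
deep fraction ≈ 0.11 percentage points), a 4-subject default-size
phantom cohort for bias/affine distortion recovery (pooled PRL voxels
≈ 4×10⁴; recovered modes within one intensity unit of the generative
means), and one default phantom subject (~9×10⁵ voxels, 91 lesions) for
the end-to-end run. Oracle-equivalence suites compare implementation
against independent brute force: sort-based percentiles, breadth-first
flood fill for components (200 random masks), exhaustive cutoff search
(200 instances ≤ 30 lesions), hypergeometric enumeration for Fisher
(all 2×2 tables with margins ≤ 10), and full rank-assignment enumeration
for the exact Wilcoxon path (all m, n ≤ 5).

`scripts/acceptance.py` recomputes the four headline voxel-wise numbers
(deep-fraction percentages and mode locations per class) from fresh
draws of 10⁵ voxels at a user-supplied seed.

## Known limitations

* Phantom classes separate far more cleanly than clinical lesions, so
  end-to-end classifier metrics on phantoms approach 1.0 and say nothing
  about real-world sensitivity.
* The inter-mode minimum of a well-separated mixture is a wide, nearly
  flat valley; its exact location is noise-dominated and is reported but
  not asserted against a fixed value.
* Normalization can undo per-image affine distortions exactly and mild
  multiplicative bias fields approximately; strong spatial bias
  (amplitude ≳ 0.2) shifts landmarks beyond what a global intensity map
  can correct.
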