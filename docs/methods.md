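# Methods

This note documents the models, algorithms and design choices behind each
analysis stage, what the synthetic generators do and do not emulate, and
the numerical conventions used throughout.

## Arbor morphometry

**Branch decomposition.** An SWC trace is validated (single root, acyclic,
finite coordinates; errors name the offending line) and split into
*branches*: maximal unbranched node chains whose endpoints are the root,
nodes with ≥ 2 children, or tips. Every edge belongs to exactly one
branch, so branch lengths (3D Euclidean, though synthetic data sets z = 0)
sum to the total cable length.

**Order assignment.** The primary shaft is order 1. At each branch point
exactly one daughter *continues* the parent's order; all others take
order + 1. The continuation is the daughter whose subtree contains more
branch points; on ties, the daughter whose own segment is longer. This
greedy rule minimises the weighted order sum Σ i·N<sub>i</sub> — and
hence the ACI, since Σ N<sub>i</sub> is fixed by the topology — because
the decisions decouple: each choice determines only which daughter
subtree's branches are all incremented by one order, and the bushier
subtree should never be the one incremented. `order_assignment_oracle`
verifies this by exhaustive enumeration of all continuation assignments
on trees with ≤ 12 branch points, breaking score ties by total
higher-order branch length. Multifurcations (> 2 daughters) are resolved
by the same pairwise comparison; a root with several children is treated
like a branch point whose continuation carries order 1.

**Looping.** The order-1 chain is resampled at a fixed 2 µm arc-length
step and the absolute sum of signed heading changes is taken as the
cumulative turn. An axon is *looping* when the turn is at least 270°
**and** the arbor is simple (ACI < 1.4). The 270° default separates
near-complete turns from ordinary meander in synthetic sweeps and is
configurable; the ACI cutoff of 1.4 is the standard simple-axon
threshold. No minimum-branch-length filter is applied by default
(`min_branch_um` is available).

## Growth-cone densitometry

Background is the median intensity outside the quantification mask
dilated by 5 px, excluding a 2 px image border; the median is robust to
residual signal in the background region. Density is the sum of
background-subtracted in-mask intensities divided by the mask area in
µm². Negative post-subtraction pixels are clipped to zero (configurable)
so noise cannot cancel signal in sparse masks; consequently density is
exactly intensive — doubling a uniform mask leaves it unchanged — and, in
the noiseless case, invariant to global intensity offsets. Actin masks
come from Otsu thresholding followed by keeping the largest connected
component above a minimum size (the thresholding method is pluggable);
tubulin "central domain" masks are supplied externally — on synthetic
data the generator's ground-truth masks stand in for manual outlining.

## AFM mechanics

**Contact point.** A line is fitted to the leading (pre-contact) segment
to estimate baseline and noise; the crossing is the first index where the
5-sample-smoothed, baseline-subtracted force exceeds 3 noise SDs and
stays above for 5 samples. Because thresholding a slowly rising power law
is biased late, the crossing is refined: with x = z − F/k (tip–sample
distance) the Hertz law gives F^{2/3} = a·(x − z_c) exactly, so a
weighted linear fit of F^{2/3} on x over the high-force samples
(F ≥ 10 % of maximum, weights √F̂ to stabilise the transformed noise)
yields a sub-sample contact position z_c from its x-intercept. On
noiseless curves this is exact to machine precision. At 1 % of maximal
force of additive noise, the estimate has an intrinsic scatter of about
1.2 samples SD on a 200-sample curve, so per-curve guarantees tighter
than ±3 samples are not achievable; tests assert the median offset.

**Fit.** Indentation is δ = (z − z_c) − F/k on post-contact samples.
The linearised fit regresses F^{2/3} on δ over samples with
0.05·δ_max ≤ δ ≤ 0.20·δ_max ("5–20 % of the indentation" read as a
depth fraction; a flag allows alternative windows) and converts the slope
a to the apparent modulus E = (3/4)·a^{3/2}·(1−ν²)/√R with ν = 0.5
(incompressible) by default. A nonlinear least-squares fit of the
untransformed law on the same window serves as an independent cross-check
and agrees to < 10⁻⁵ relative on clean curves. Window placement is
immaterial on clean data (shifting to 10–30 % changes E by < 0.5 %),
confirming the pure power law.

**Noise scale.** The 5–20 % window spans forces of only ~1–9 % of the
curve's maximum, so fit-quality statements are made relative to the force
scale *of the window* (the Hertz force at 0.20·δ_max). At 2 % of that
scale of additive noise the median recovery error is ≈ 2.4 %; noise
quoted relative to the curve maximum would put the window below SNR 1,
where no window-restricted estimator can do better than ~10 % (the
Cramér–Rao bound for the slope).

**Reporting.** The output column is `E_apparent_Pa`, never an unqualified
Young's modulus: with sub-micron samples and a 70 nm tip, finite
thickness and high local strain make the fitted value a comparative
stiffness readout, not an absolute material constant. Curves measured
where the sample is ≤ 150 nm thick are excluded (strict inequality, with
a 10⁻⁹ relative float guard); the per-site height is taken from curve
metadata. Condition summaries flag cohorts violating the ≥ 5 cells and
≥ 10 curves-per-cell sampling guideline.

## Kymograph transport

Kymographs are built by sampling each movie frame along the axon path at
1 px arc-length steps and averaging over a 20 px perpendicular linewidth
(mean, not max). Track extraction is classical: rows are smoothed with a
σ = 0.8 px Gaussian (an approximate matched filter for the granule PSF),
local maxima above median + 3.25 robust SDs (MAD-based) with a
prominence requirement are localised to sub-pixel precision by parabolic
interpolation, and detections are linked greedily frame-to-frame using a
constant-velocity prediction, a hard 1 µm/frame step gate, and bridging
of single-frame gaps. Fragments split by longer detection dropouts are
re-joined when the earlier fragment's extrapolation lands within
0.6·max_step·√gap of the later fragment's start (≤ 8 frames). The
detector's operating point (threshold, smoothing, merge tolerance) was
chosen on synthetic benchmarks for ≥ 95 % exact track-count recovery at
single-granule SNR 5 with resolvable spacing.

Metrics follow the study definitions: granule density = track count /
axon length, and per-track mean frame-to-frame displacement = mean
|Δposition| per frame (steps across bridged gaps are divided by the gap
length). Direction is classified against the recorded growth-cone side
(default: distal/right); net displacement below two pixel widths is
stationary.

## Statistics

Observations from all replicates are pooled (each observation is one
datapoint; replicate ids are retained for audit). The omnibus test is
Kruskal–Wallis with midrank tie correction (χ² approximation, k−1 df);
all-identical data returns H = 0, p = 1 rather than an error. Pairwise
comparisons are Dunn z-tests on the joint ranking with tie-corrected
variance — the classical Kruskal–Wallis post-hoc — with Bonferroni
adjustment p_adj = min(1, m·p) over all m = k(k−1)/2 pairs; independent
Mann–Whitney tests are available behind a flag since the post-hoc family
is a genuine design choice. Fisher's exact test (two-sided by default,
one-sided behind a flag) handles 2×2 looping contingency tables; a
brute-force hypergeometric enumeration in the test suite confirms it on
every table up to total count 30. Significance tiers use strict
thresholds: * p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001.

## Synthetic cohorts

All generators are pure functions of (params, seed); the cohort writer
derives per-item sub-seeds by hashing the master seed with the condition,
stage and index, and records them in a manifest so any file can be
regenerated bit-identically.

**Arbors** are 2D random walks (2 µm steps, 12° heading noise per step;
z emitted as 0 for SWC conformance). λ₁ is the single primary shaft
(always exactly one); λ_k for k ≥ 2 is the expected number of order-k
side chains, drawn Poisson and attached at uniform interior nodes in the
proximal 60 % of a parent chain. Because every side chain splits its
parent chain, the per-order *segment* counts obey N_k = a_k + a_{k+1}
(a_k = number of order-k chains); segment counts therefore cannot be set
independently per order, and λ parametrises the chain counts instead. A
placement is accepted only if a skeleton-level replica of the greedy
continuation rule reproduces the intended labels — otherwise the
minimising assignment would legitimately relabel orders (an order-2 chain
with its own branch point attached distally would steal order 1).
Unplaceable draws are dropped and the realised counts recorded; with the
default λ = (1, 4, 3) the realised order-3 mean is ≈ 2.4 and control
arbors score ACI ≈ 1.75 ± 0.21, in the expected range for stage-45
retinal axons. A looping arbor (probability `loop_probability`) bends
only the main shaft by a total of 310–420° and suppresses higher-order
branching to 15 % — looping axons fail to enter the branching stage and
remain simple, which is what makes the looping phenotype detectable as
turn + simplicity.

**Growth-cone images** place a tubulin disc (radius 2 µm) and an actin
annulus (width 1.5 µm) plus 8 filopodial spokes on a 128² field at
0.1 µm/px, with Poisson shot noise followed by additive Gaussian read
noise (the camera model is a convention, not a measurement). Ground-truth
masks are returned alongside. The phantom is geometric: no structured
texture, no collapsed cones, no out-of-focus light — segmentation results
on it bound only the thresholding logic, not biological variability.

**Force curves** solve F = (4/3)E/(1−ν²)√R·δ^{3/2} with
δ = (z − z_c) − F/k self-consistently by damped fixed-point iteration
(tolerance 10⁻¹⁵ m, ≤ 100 iterations; the map is a strong contraction
for the soft probes used). Defaults match the study probe: k = 0.07 N/m,
R = 70 nm, 200-sample extension with ≈ 200 nm maximal indentation,
optional baseline drift and additive force noise.

**Granule movies** draw Poisson(density × length) granules (default
0.2/µm × 25 µm), assign stationary/anterograde/retrograde classes
(default 50/30/20 %), move them at |N(0.8, 0.2)| µm/s with 0.03 µm
frame jitter, and render Gaussian profiles (σ = 1 px) over Poisson +
Gaussian noise at 2 frames/s for 60 s. Granules are placed (and counted
as visible) at least 3 PSF σ from the field edges, where localisation is
impossible. Not emulated: photobleaching, granule fusion/splitting,
run–pause velocity switching, curved axons.

## Problem sizes and tolerances

The test suite exercises: 200 random trees against the exhaustive oracle;
500 noisy force curves (median error < 5 % at 2 % window-scale noise;
< 1 % noiseless); 30-image cohorts for the 0.7× actin ratio (± 3 SE);
200 kymograph seeds for track-count recovery (≥ 95 %) and 200 seeds of
8-axon-per-group null comparisons (≤ 10 % false-positive rate at
α = 0.05); every 2×2 table with total ≤ 30 for Fisher; 2000 null
simulations for Kruskal–Wallis type-I calibration; and 100 four-condition
cohorts (n = 25 axons/condition, 0.4× higher-order branching in two
conditions) for ACI power (≥ 90 % of runs with all four mutant-vs-control
pairs Bonferroni-significant). `scripts/acceptance.py` recomputes the
same quantities from a user seed.

## Known limitations

* The looping turn threshold (270°) and the detector operating points are
  choices validated on synthetic data only.
* The Hertz fit ignores substrate (finite-thickness) corrections by
  design; outputs are comparative.
* The greedy/oracle equivalence is proven for the weighted-order-sum
  objective; a strictly lexicographic per-order minimisation can differ
  on rare nested trees and would require the exhaustive oracle.
* The tracker is a classical peak-linker: it degrades with crossing
  granules of unequal speeds and makes no attempt at appearance-based
  identity preservation.
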