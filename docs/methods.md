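# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `isletnet`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Geometry

All geometry lives in a 2D, y-down image frame with continuous μm
coordinates (pixel row index × pixel size; 0.5 μm/px for the imaging
stage).  Cell positions are nucleus centres; no cell radii are modelled,
so every distance in the package is centre-to-centre.

The signed distance to the islet rim is **negative inside, positive
outside, zero on the boundary**.  This single convention is used by every
module, so "the islet enlarged by m" always reads `signed_distance ≤ m`.
Region dilation is polygon buffering with round joins at 16 segments per
quarter-circle; at the largest margin used (60 μm) the chord error is
≈ 0.07 μm, an order of magnitude below one image pixel.  "A random point
at rim distance d" means a point drawn uniformly *by arc length* on the
offset curve at d — uniform-in-angle sampling about the centroid would
over-represent concave stretches of non-circular rims.

The half-islet split plane passes through the **rim-polygon centroid**
(the area centroid, not the bounding-box midline — the choice is a
convention, and centroid splits are stable under rim re-vertexing).
Cells exactly on the plane go to the left/lower half, a deterministic
tie-break.

## Staging

Insulitis degree is n_T/n_β counted over cells with signed distance
≤ 60 μm (the `degree_margin`).  Stage cutoffs: early [0, 0.51),
intermediate [0.51, 1.25], late (1.25, ∞).  Both boundary values are
assigned to the intermediate bin: "late" is defined strictly above 1.25,
and 0.51 is assigned upward so the three bins strictly partition [0, ∞).
Size classes: small [0, 7,000) μm², medium [7,000, 20,000] μm², large
above.  The degree margin (60 μm) and the network membership margin
(20 μm) are distinct configuration keys on purpose; conflating them is a
common implementation error.

Islets with no β-cells in the counting region have undefined degree and
are excluded from the spectrum (logged); islets flagged as lying at the
tissue edge are excluded before any polarity analysis because part of
their surroundings is missing.

## Networks

Links are heterotypic only, with inclusive distance comparison
(d ≤ threshold).  Membership: endocrine cells inside the rim
(signed distance ≤ 0), immune cells with signed distance ≤ 20 μm.  The
same membership rule is applied to experimental and randomized networks
so null comparisons are like-for-like.  Neighbor search uses a k-d tree;
a brute-force O(n²) path is retained behind `method="brute"` and serves
as the oracle in the test suite — the two are asserted equal on hundreds
of random islets.  K_avg for a type with zero members is NaN (logged),
and every cohort-level statistic drops such islets listwise.

Three-cell analyses (α, β, one immune type) are represented as the
β-partition of one network rather than separate graph objects: β-cells
are α-linked iff they have ≥ 1 considered α-cell within the threshold.
In the outer-ring analysis both α and β are first restricted to
|signed distance| ≤ 20 μm; restricting the α donors as well avoids
crediting ring β-cells for core α neighbours they do not share exposure
with.

## Randomization null model

Immune cells are split into inside (signed distance ≤ 0; a cell exactly
on the rim counts as inside) and outside (> 0) groups.  For each
non-empty group a **literal pool of 1,000 draws** from
N(mean, sample sd) of the group's signed distances is materialized —
keeping the intermediate pool, rather than sampling the normal directly,
makes the procedure auditable and exactly reproducible.  Each cell then
receives a uniform pool draw, rejected and redrawn (≤ 100 times) if it
falls on the wrong side of the rim or deeper than the rim's erosion
allows; after 100 failures the cell falls back to its own empirical
distance (logged).  Placement is uniform by arc length on the offset
curve at the drawn distance.  Group counts are therefore conserved
exactly in every seed, and the seed-averaged distance to the rim tracks
the empirical group mean.

Per-islet, per-seed random streams derive from
`SeedSequence([master_seed, crc32(islet_id), seed_index])`, so ensembles
are stable under cohort reordering and fully deterministic.

The null preserves each group's *distance distribution* only through a
fitted normal.  It is therefore calibrated when the true rim-distance law
of immune cells is approximately normal, and miscalibrated when it is
not: for example, immune cells placed uniformly *by area* in a band have
markedly more near-rim mass than a moment-matched normal, and the null
then under-counts random links, inflating the type-I error of the
experimental-vs-random comparison several-fold.  This sensitivity shaped
the synthetic generator's design (below) and is the main caveat when
interpreting the comparison on real data whose distance profiles deviate
strongly from normality.

## Synthetic islet generator

The generator emulates the features of NOD-mouse islets that the
analysis relies on, with one ground-truth knob for immune attraction.

* **Rim**: star-shaped 24-gon with smoothed radial jitter (±25% before
  smoothing) around `islet_radius` (default 60 μm → ≈ 11,000 μm², a
  medium islet).
* **Endocrine cells**: dart-throwing with a 10 μm minimum nucleus
  spacing (a typical islet-cell diameter, so the 15/20/25 μm link
  thresholds correspond to one–two cell diameters).  Default 40 β-cells;
  30% of endocrine cells are α.
* **α-cell architecture**: α labels are weighted toward the rim
  (`mantle_bias`, default 0.8 — the α-mantle of mouse islets) and
  modulated by a cosine about a random pole (`alpha_polarity`, default
  0.8), producing the α-rich and α-poor sectors seen in sections; with
  polarity 0 the mantle is angularly homogeneous and there is nothing
  for an attraction bias to act on.
* **Immune cells**: T count = round(target T/β ratio × n_β); macrophage
  and myeloid counts default to 8 each.  A cell is inside with
  probability `inside_fraction` (default 0.2; early insulitis is mostly
  peri-insulitis).  Rim distances are truncated normal — outside
  N(peri_band/2, peri_band/6) on (0, peri_band] with peri_band = 40 μm,
  inside depth N(R/3, R/6) truncated to feasible depths — and positions
  are uniform by arc length on the offset curve at the drawn distance,
  i.e. the same placement mechanism the null model uses.  This choice is
  deliberate: the null fits a normal to the observed distances, so a
  generator whose distance law is (truncated) normal with negligible
  truncated mass is the regime in which the experimental-vs-random
  comparison is supposed to be calibrated, and the package verifies that
  calibration.  The σ = band/6 width keeps the mass lost to truncation
  at zero below 0.2%, making the null's refit-and-re-truncate step
  essentially bias-free.
* **Attraction bias**: a placement is accepted with probability
  ∝ (1 + λ·ρ_α(x)), where ρ_α is the count-weighted Gaussian-kernel
  α-cell density with kernel sd 25 μm (comparable to the link
  threshold).  λ = 0 reduces exactly to unbiased placement; λ = 10 makes
  α-rich sectors several-fold more attractive and is the "strong bias"
  condition in the validation suite.
* **Cohorts**: default 44/46/44 islets over the early/intermediate/late
  ratio ranges (0.03–0.51, 0.51–1.25, 1.25–5), target ratios log-uniform
  within each range (the ranked degree spectrum is then roughly
  exponential, as observed in real cohorts).  A drawn ratio is redrawn
  if count quantization (round(r·n_β)/n_β) would land it in a different
  stage bin, so a cohort always round-trips its intended stages.  Islets
  are assigned round-robin to 11 mice.

What the generator does **not** emulate: cell death and β-mass loss over
real time, vasculature and ducts, irregular/lobed rims, spatial
correlation between the three immune types beyond their shared α
attraction, segmentation noise, and any 3D structure.  Passing tests
therefore show that the *pipeline* is correct and calibrated under its
stated model, not that real tissue satisfies that model.

## Colocalization stage

Order matters and is fixed: bleed-through subtraction → median filter →
Manders analysis.  Bleed-through subtraction zeroes the target channel
wherever the source (e.g. insulin) channel exceeds a mask threshold
(default: Otsu on the source).  The median filter uses a disc footprint
(radius 2 px) with nearest-edge padding.

The automatic threshold steps T down through the *sorted distinct*
channel-1 intensities (deterministic and resolution-adaptive; a fixed
decrement would depend on the intensity scale), computing at each step
the Pearson correlation over pixels with P1 < T **and** P2 < aT + b, and
returns the largest T with r ≤ 0 (discrete data cannot hit exactly
zero).  Steps with fewer than 3 sub-threshold pixels or zero variance
are skipped; if r never reaches 0 the minimum intensity is returned with
a warning flag.  The regression P2 ≈ a·P1 + b is fitted over **all**
pixels once, not re-fitted per step.  M1 sums channel-1 intensity above
T; M2 sums channel-2 intensity above aT + b.

One structural caveat, verified by the test suite: for channels with *no*
true overlap the fitted slope a is negative, aT + b drops below zero at
high T, and M2 saturates near 1 regardless of the data — with this
threshold construction only M1 is informative for anti-associated
channels.  The synthetic image generator keeps non-shared spots ≥ 6σ away
from the other channel's spots so that its `overlap_fraction` is the true
colocalized fraction.

## Statistics

Paired t (two-sided), Wilcoxon matched-pairs signed-rank, simple linear
regression, and repeated-measures one-way ANOVA with Geisser–Greenhouse
correction plus Tukey HSD over condition means are delegated to
scipy/pingouin.  Conventions: complete pairs/rows only (listwise
deletion, counts reported); fewer than 3 observations → "underpowered",
no p-value; zero-variance differences return the analytic answer (t = 0,
p = 1 for identical samples) instead of NaN.

The half-islet polarity regression uses **one point per islet** (the
first half's proportions): the second half's proportions are exact
complements, so including both would duplicate every point mirrored
about (0.5, 0.5) and understate the slope standard error by √2,
invalidating the confidence level.  The per-islet output still reports
both halves.

## Validation problem sizes

The acceptance-level checks run at the following sizes, chosen to give
stable Monte-Carlo estimates on a single CPU:

* oracle equivalence: 50 random islets (≤ ~220 cells) × 3 thresholds;
* null-model contract: one islet, 100 seeds;
* type-I calibration: 200 replicate cohorts of 40 early-stage islets,
  λ = 0, 20 seeds per ensemble, nominal α = 0.05;
* bias recovery: 100 replicate cohorts at λ = 10 (paired t, and
  one-sided Wilcoxon on the outer-ring α-linked comparison);
* polarity: one λ = 10 cohort for the positive slope, 30 λ = 0 cohorts
  for confidence-interval coverage;
* determinism: the default 134-islet pipeline run twice, byte-compared.

`scripts/acceptance.py` uses scaled-down replicate counts (100 calibration
/ 40 power replicates) to stay within a few minutes while keeping
binomial standard errors below ~0.06.

## Known limitations

* 2D sections only; no 3D reconstruction or vasculature.
* The null model's normal approximation (see above) — on real data,
  inspect the distance histograms before trusting the calibration.
* The level-set placement discretizes offset curves (buffering), with a
  sub-0.1 μm placement error; irrelevant at 15–25 μm thresholds but
  worth knowing for μm-scale reanalysis.
* CD3⁺ T-cells are treated as one population; helper/cytotoxic subsets,
  and functional (e.g. calcium-coupling) networks, are out of scope.
* Manders M2 is uninformative for anti-associated channel pairs under
  the automatic threshold construction (see the colocalization section).
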