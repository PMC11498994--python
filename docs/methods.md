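# Methods

## Problem setting

A multi-batch herbal preparation is characterized by a chromatographic
fingerprint (peak retention times and areas per batch) and by per-batch
bioactivity indices. The package estimates which common peaks drive the
activity by combining two complementary statistics — grey relational
analysis (GRA), which ranks peaks by profile similarity to the activity
without assuming a model, and single-response OPLS, which fits a latent
linear model and attributes importance (VIP) and direction (coefficient
sign) — and then applies a joint screening rule.

## Common-peak matching

Peaks from all batches are pooled and sorted by retention time, then
partitioned into the fewest contiguous segments such that every member
lies within the time window (default 0.1 min) of its segment's median
retention time. The partition is found by dynamic programming, so the
result depends only on the pooled retention-time multiset — batch order
and within-batch peak order cannot change it. Ties between minimal
partitions are resolved toward a shorter last segment; within a
cluster, a batch contributing two peaks keeps the one nearer the
cluster median (earlier retention time on an exact tie, logged).
Clusters present in at least `min_occupancy` (default 1.0, the
definition of a common peak) of batches are kept and labelled 1, 2, …
in retention-time order.

The window-to-median criterion, rather than nearest-neighbour chaining,
was chosen because chaining can leak a cluster across an arbitrary
distance through a dense run of peaks, and because the median anchor
makes the above invariance exact. Retention-time correction, when raw
runs are misaligned, is a user-anchored piecewise-linear remap
(`multipoint_rt_correction`); anchor choice is left to the user because
no universal anchor rule is defensible across instruments.

## QC statistics

RSD is `100 × sample SD (n−1) / mean`. The sample-SD convention was
fixed by validating against the packaged reference table, which it
reproduces within 0.22 percentage points on 13 of 14 non-reference
rows from 3-decimal-rounded inputs (population SD is several points
off). One published row's RSD is inconsistent with its own published
values under either convention; the tests document it.

Similarity defaults to the cosine of two common-peak area vectors
(selectable: mean-centred correlation, or cosine on chromatograms
linearly resampled to the union grid at the finest input step). Cosine
is the conventional fingerprint-similarity score and is invariant to
uniform scaling of either batch, i.e. to injection-amount differences.
The consensus fingerprint is the component-wise median across batches
(mean selectable), robust to a single aberrant batch.

## Assay computations

DPPH scavenging (517 nm): `100 × [1 − (A_sample − A_control)/A_standard]`,
where the control well corrects for sample colour. T-AOC (593 nm):
`((A_sample − A_blank) − intercept)/slope × dilution`, inverting an OLS
calibration line; the default dilution factor 34 encodes the plate
layout 180 µL reaction mixture + 18 µL water + 6 µL sample. The kit's
internal computation is proprietary, so the generic linear calibration
is the documented model. Values outside their physical range (rates
outside [0, 100] %, negative capacities) are flagged in logs but never
clamped, so the multivariate stages always see the raw numbers.

## Grey relational analysis

Parent sequences (one per activity index) and subsequences (one per
peak) are mean-normalized (divided by their own mean; alternatives:
initial-value, min–max). With Δᵢ(k) = |x₀(k) − xᵢ(k)| and two-level
extrema m = min over all peaks and batches, M = max over all peaks and
batches of one parent's run:

    ξᵢ(k) = (m + ρM) / (Δᵢ(k) + ρM),   ρ = 0.5 by default

The relational degree is the unweighted mean of ξᵢ(k) over batches;
rank 1 is the highest degree, ties broken by peak index and logged.
Two-level extrema (shared across all 15 subsequences of one run, one
run per assay) were chosen over per-child extrema because degrees are
then comparable across peaks within a run; the parent is normalized
with the same method as the children. Degrees lie in (0, 1], equal 1
exactly when a subsequence matches the parent after normalization, are
invariant to positive rescaling of any series and to batch
relabelling, and are componentwise nondecreasing in ρ.

The default input is the reference-relative area matrix, since that is
what QC produces; raw areas are accepted. The two conventions give
different degrees, and published degree tables computed with
third-party software are reproduced only to ~±0.17 on the reference
dataset, because that software's input version and extrema convention
are not published; the bound that all degrees exceed 0.5 is robust to
the convention and is asserted.

## OPLS

All variables are unit-variance scaled (mean-centred, divided by the
sample SD; y likewise). Constant columns cannot be scaled; they are
dropped with a warning and reported downstream with coefficient and
VIP exactly 0 — the natural fixture has a constant reference-peak
column, so this path is first-class. For each of `n_orthogonal`
(default 1) components:

    w = Xᵀy/‖Xᵀy‖,  t = Xw,  p = Xᵀt/tᵀt
    w⊥ = (p − (wᵀp)w)/‖·‖,  t⊥ = Xw⊥,  p⊥ = Xᵀt⊥/t⊥ᵀt⊥,  X ← X − t⊥p⊥ᵀ

then one NIPALS PLS component on the filtered X with q = yᵀt/tᵀt.
Coefficients on the scaled scale are mapped through the orthogonal
filter, b = [∏(I − w⊥p⊥ᵀ)]·w·q, so they apply to the original scaled
variables; a raw-scale back-transform is available. Orthogonal scores
satisfy t⊥ᵀy = 0 exactly by construction. VIP is computed over the
predictive component only — importance *for the response*, excluding
removed variation — giving VIPⱼ = √p·|wⱼ| and ΣVIP² = p(retained).
Q² is k-fold cross-validated (default min(7, n) folds, per-fold
rescaling, fold assignment seeded); the orthogonal-component count is
capped at rank−1 per training fold.

A consequence worth knowing: removing y-orthogonal components never
changes Xᵀy, so the predictive weight direction — and therefore VIP —
is identical for any `n_orthogonal`. Orthogonal removal changes scores,
loadings, R²Y and interpretability, not the VIP ranking. This is a
property of the algorithm, not an implementation shortcut, and it
drives the screening-reliability limitation below.

## Screening rule

Per assay, candidates are peaks with VIP > `vip_threshold` (default
1.0, the conventional cut) and a positive scaled coefficient. The core
set is the intersection across assays, sorted by minimum-across-assays
VIP. Peaks with positive coefficient and VIP within `near_miss_slack`
(default 0.1) below the threshold are reported as near-misses, kept
disjoint from the core set, so the expert-judgement step that typically
follows (promoting a near-miss with strong support elsewhere) operates
on explicit numbers rather than silently. GRA degrees and ranks are
carried alongside in the report but never thresholded: no principled
cut exists for relational degrees, and on the reference dataset all of
them clear 0.5 anyway.

## Synthetic data generator

`SyntheticSpec` defaults mirror the reference study conditions: 10
batches, 15 peaks at the reference retention-time layout (scaled to a
15-min reference peak), log-normal area variation with σ = 0.45
(relative-area RSDs of roughly 40–70%), retention-time jitter SD 0.02
min (well inside the 0.1-min matching window, with ≥ 0.4-min peak
spacing), three active peaks of unit standardized effect, and activity
noise derived so the active signal explains `target_r2` = 0.8 of the
activity variance.

Activities are linear in the *standardized* areas of the active subset,
so effect sizes are scale-free and directly comparable to OPLS's scaled
coefficients. Two nuisance latents share the
`orthogonal_confounder_strength` parameter (default 0.5): a batch
latent loading on the inactive peaks' log-areas only (structured
X-variation orthogonal to the signal — what the orthogonal component
exists to remove, and what distinguishes OPLS from plain PLS on these
data), and a structured activity-noise term residualized against the
active standardized areas so it cannot alias the true signal. The
DPPH-style index is placed in (0, 100) by an affine map (target mean
70 %, SD 8 %) recorded in the ground truth; the T-AOC-style index is
mapped to mean 1.3, SD 0.3 µmol/mL. Everything derives from one seed
and regenerates bit-identically.

What the generator does *not* emulate: peak overlap and tailing,
detector saturation, heteroscedastic integration error, correlated
constituent chemistry (areas are independent given the latents), or
batch-level dilution effects. Passing ground-truth tests therefore
demonstrates the statistical machinery, not robustness to
chromatographic pathology.

## Reliability of the screening rule at small n

Because VIP reduces to √p·|r|/‖r‖ in sample-correlation terms, the
VIP > 1 cut sits only ~1.5–1.7 null-correlation SDs above zero at 30
batches with 15 peaks. Spurious candidates — inactive peaks whose
sample correlation with the realized activity crosses the cut — are
therefore expected in a sizeable fraction of 30-batch datasets, and
since all assays share one fingerprint matrix, requiring candidacy in
both assays discounts them less than independence would suggest. The
ground-truth tests and `examples/synthetic_recovery.py` measure this
directly: exact core-set recovery of 3 planted actives occurs in
roughly 55–65% of 30-batch replicates and ~98% at 100 batches. Core
sets from small batch panels should be treated as ranked hypotheses
for confirmatory work, not as conclusions.

## Numerical choices and degenerate inputs

- CSV dialect pinned (UTF-8, comma, '.' decimal, mandatory header);
  peak-table and activity writers emit full-precision floats and the
  readers parse round-trip, so rerunning a seeded pipeline is
  bit-identical through files.
- Packaged reference tables are verified against pinned SHA-256
  checksums and structural invariants (reference-peak rows exactly
  1.000) at load.
- Zero-variance responses, all-constant matrices, zero-norm similarity
  vectors, zero reference areas (named by batch), non-monotone
  correction anchors, and mismatched batch sets all raise labelled
  errors; pipeline stages wrap failures with the stage name.
- Exact ties (rank degrees, equidistant peaks in matching) break by
  index/earlier retention time and are logged, never silent.
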