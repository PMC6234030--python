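# Methods

## The counting model

The unit of annotation is the polyadic synapse: one presynaptic T-bar
ribbon with 1–9 postsynaptic densities (PSDs) on partner neurites.  All
quantities downstream are counts, ratios and percentages over one
expansion rule: **one PSD = one directed contact** from the T-bar's body to
the PSD's body.  A T-bar with *k* PSDs therefore contributes *k* contacts;
these are coordinately linked (one release site) but counted separately,
which is how connectivity matrices for these volumes are tabulated.
T-bars with no annotated PSD are dropped before any counting, and the
volumetric synapse density is (T-bars with ≥ 1 PSD) / neuropile volume.

Autapses (pre body = post body) are retained and land on the matrix
diagonal.  Contacts whose pre or post neurite cannot be resolved to the
cell table are attributed to a reserved orphan sentinel and logged, never
dropped, so contact totals are always conserved.  *Identified* orphan
fragments are different: they appear in the cell table with class
`orphan`, keep their own ids, and can enter the matrix like any other
body.

### Inclusion criterion

The matrix covers bodies with "more than 50 contacts".  Two readings are
implemented behind `count_mode`: `"total"` (pre + post ≥ 51, the default)
and `"either"` (≥ 51 pre *or* ≥ 51 post).  The combined-total reading is
the default because it is the weaker criterion consistent with both
phrasings in the source material; the flag makes the choice explicit
rather than baked in.

### Undefined ratios

PSDs-per-T-bar is undefined for a body with no T-bars, and the pre:post
ratio for a body with no postsynaptic contacts.  Both are emitted as NaN
(never infinity) so tables serialize cleanly; class means skip them, and
class-aggregate ratios (sum of pre over sum of post) are reported
alongside per-cell means because they are robust to these gaps.

## Reciprocity

For every unordered pair {a, b} with any contact, the pair table records
forward (a→b) and backward (b→a) counts and their ratio.  A pair is
*reciprocal* when both directions carry at least `min_each` contacts
(default 3 — the minimum to acknowledge a pathway, chosen because weaker
connections are at the scale of proofreading error).  *Strong reciprocity*
constrains the ratio to a band (default the closed interval [0.25, 4]).
Because the source material supports two opposite readings of the band —
ratio inside [0.25, 4] (neither direction more than four times the other)
versus at least 4:1 imbalance — both are implemented (`band_mode =
"within" | "outside"`), with `"within"` the default; the deposited-matrix
acceptance check is the natural adjudicator once that file is available.
The percentage universe is also configurable: by default, pairs whose
*stronger* direction reaches `min_each` ("pairs having > 2 contacts"
cannot be reconciled exactly with any single pairing rule, so the
implementation exposes the universe definition instead of guessing).

Class-pair summaries report, per unordered class pair, the share of
qualifying pairs that are reciprocal, the class that is presynaptic in the
majority of reciprocal pairs (ties counted in neither direction), and the
mean ratio oriented dominant-class-pre over the other direction.

## Class flows and the ratio classifier

Flow percentages are shares of the grand total of contacts among included
bodies — the published class-flow percentages sum to 100% across all class
pairs, which identifies the grand total (not per-class output) as the
denominator.

The ratio classifier assigns ORN / LN / PN from the pre:post ratio alone.
Default thresholds: ratio ≥ 2.5 → ORN, 0.6 < ratio < 2.5 → LN, ratio ≤
0.6 → PN; NaN → unclassifiable.  The thresholds sit between the printed
class ratios (ipsilateral ORNs 3.9 ± 0.6, contralateral 5.3 ± 1.5, LNs
≈ 1, mPN1 0.4 ± 0.03) — roughly the midpoints between adjacent class
clusters on a log scale — and are exposed in `ClassificationRules`.
Predictions within ±20% of a threshold carry a `near_boundary` note.

An optional relabelling pass splits LN bodies into LN2L vs LN1 by whether
they make or receive any ORN contact (`min_orn_contacts`, default 1, since
no exact contact threshold is documented for this distinction).

## Synapse-cloud segmentation

Glomerular borders appear in whole-lobe synapse point clouds as local
rarefactions of density.  The mapper bins T-bar positions into a regular
grid (default 1 µm bins — 125 voxels of 8 nm data per side) and smooths
with a Gaussian kernel (default σ = 2 bins).  The grid pads the point
bounding box by ⌈3σ⌉+1 bins and smoothing uses a reflecting boundary, so
raw histogramming conserves the point count exactly and smoothing
conserves total mass to floating-point accuracy.  Voxelization is
half-open (`origin + i·bin ≤ p < origin + (i+1)·bin`) and the origin
tracks the data minimum, making density and segmentation equivariant
under joint translation of points and origin.

Segmentation is threshold-plus-watershed:

1. *cores* — voxels whose smoothed density reaches the quantile threshold
   (default the 60th percentile of smoothed density over voxels containing
   at least one point; restricting to occupied voxels keeps the smoothing
   halo of near-zero values from dragging the quantile down), grouped by
   26-connectivity;
2. *extension* — a watershed on inverted density grows each core outward
   over voxels above a low capture threshold (default the 5th percentile
   of the same distribution), so region boundaries fall at density minima
   between glomeruli while each region still captures the bulk of its
   glomerulus' points.

Setting `capture_quantile=None` gives plain threshold-components
segmentation, for which region size is monotone non-increasing in the
threshold.  Regions with fewer than `min_region_points` raw points
(default 30) are merged to background; labels are numbered by descending
contained point count with first-voxel tie-break, so labelling is
deterministic and independent of point order.  ROI assignment is a pure
voxel-label lookup; points outside the grid are excluded with a warning.

The original glomerulus demarcation was visual inspection plus a manual
ROI tool; the quantile threshold and watershed extension are this
package's own operationalization of "borders from local rarefactions" and
are flagged as engineering choices (both quantiles are exposed).

## The synthetic generator

`SynthConfig` defaults encode study-scale conditions:

| parameter | default | meaning |
| --- | --- | --- |
| census | 51 / 56 / 18 / 56 / 5 / 6 | ORN_ipsi / ORN_contra / PN / LN / other / orphan bodies (192 total) |
| n_tbars | 11,144 | expected T-bar total |
| psd_mean, psd_max | 3.4, 9 | PSDs per T-bar: 1 + Poisson(λ) truncated to ≤ 9 |
| flow_targets | see below | % of all contacts per ordered class pair |
| ipsi_share | 0.70 | ipsilateral share of ORN presynaptic output |
| ipsi_post_share | 0.75 | ipsilateral share of ORN-targeted contacts |
| nb_dispersion | 80 | negative-binomial dispersion of per-cell T-bar counts |
| minor_tbar_mean | 25 | T-bars per minor/orphan body |
| minor_redirect_rate | 0.0175 | PSDs rewired to minor/orphan bodies |
| autapse_rate | 0.01 | per-PSD autapse probability for PN T-bars |
| tail_alpha | 5.0 | Pólya-urn reinforcement per assigned contact |
| partner_shape | 100 | gamma shape of static partner attractiveness |
| neuropile_volume_um3 | 4,858 | glomerulus neuropile volume |
| spatial | 1 centre, σ = 4.5 µm, 50,000 points | T-bar / point-cloud geometry |

Flow targets (percent of all contacts): ORN→PN 39.5, ORN→LN 14.5,
ORN→ORN 5.9, LN→PN 10.4, LN→ORN 7.8, LN→LN 9.6, PN→LN 6.4, PN→PN 4.1,
PN→ORN 1.8.  T-bars are allocated to presynaptic classes in proportion to
the row sums of this table (identical PSD-count law across classes makes
T-bar shares equal contact shares in expectation), and each PSD draws its
target class from the row conditional on its presynaptic class.  The
Poisson rate of the PSD-count law is tuned numerically (root-finding on
the analytic truncated mean) rather than hard-coded, so changing
`psd_mean` or `psd_max` re-calibrates automatically.

Partner choice within the target class is a Pólya urn per (presynaptic
cell, target class): partner weights start at a static gamma-distributed
attractiveness and grow by `tail_alpha` with each assigned contact,
producing heavy-tailed per-pair strengths.  Self-draws are rejected so
autapses arise only through the explicit PN autapse channel (~1% of PN
output).  The ORN pool's attractiveness is tilted so ipsilateral axons
receive `ipsi_post_share` of ORN-targeted contacts, matching the printed
ipsi/contra pre:post ratios (≈ 3.9 vs ≈ 5.3).

Minor cells and orphan fragments sit outside the three-class flow table: a
small fraction of all PSDs (`minor_redirect_rate`) is rewired to them, and
their own modest T-bar output targets classes in proportion to the
column sums of the flow table.  The defaults give every minor body
comfortably more than 50 contacts, so the default census yields exactly
192 included bodies.

Calibration (20 seeds at defaults, a fixed pre-registered simulation whose
outcomes the test tolerances were frozen from): 192 included bodies on
every seed; empirical PSDs per T-bar 3.40 ± 0.02 (extremes 3.37–3.43);
realized class-flow shares within 1 percentage point of targets
(test tolerance ±3); P(strength ≥ 3 | connected) 37.7 ± 0.6% against the
0.37 configuration target (test tolerance ±3 points); connected ordered
pairs 8460 ± 90; pairs with > 10 contacts 753 ± 23; ratio-classifier
recovery of generator-truth classes 0.94 ± 0.013 with minimum 0.906 (test
thresholds: 20-seed mean ≥ 0.90, per-seed ≥ 0.85).  `tail_alpha`,
`partner_shape` and `nb_dispersion` were chosen once in that simulation
study to jointly reproduce the selectivity profile (≈ 8,400 connected
pairs, ≈ 37% of them ≥ 3 contacts, ≈ 750 above 10) while keeping
per-class ratio clusters as tight as the printed per-class dispersions.

A single seeded NumPy generator drives every draw in a documented order
(T-bar counts → volumes → T-bar positions → PSD counts → per-PSD class,
partner, offset), so a seed and config identify the dataset exactly.

### What the generator does not emulate

Reciprocity in the generator is incidental: forward and backward pair
strengths are drawn independently, with no mechanism favouring mutually
connected pairs, so reciprocal-pair counts on synthetic data sit well
below those of a real glomerulus and the reciprocity module is validated
against brute-force oracles and (when available) the deposited matrix, not
against the generator.  Likewise absent: neurite geometry (PSD positions
are isotropic 150 nm offsets from the T-bar), subtype-level propensity
structure (uniform within class), bidirectional synapses, and any spatial
correlation between connectivity and position.  Passing tests on synthetic
data therefore demonstrate counting, filtering and calibration
correctness — not biological realism of pair-level motifs.

## Problem sizes

Tests run the generator at study scale (≈ 11,000 T-bars) for calibration
checks and at ≈ 1/10 scale for structural checks; oracle-equivalence
suites use 1,000 random matrices up to 20×20; segmentation checks use
5,000–15,000-point clouds and the uniform-density check 10⁵ points.  The
acceptance script runs one study-scale pipeline plus a 10,000-point
two-glomerulus segmentation, completing in a few seconds.

## Known limitations

* The deposited 192-cell matrix reproduction (8398 connected pairs, 442
  reciprocal, etc.) requires the supplementary spreadsheet under `data/`;
  without it the corresponding acceptance test fails by construction.
* The 87.9% synapse-assignment rate of the original study measures
  assignment against the *entire* annotated volume (including
  sub-threshold and orphan neurites) and is not computable from a matrix
  or from desk-scale synthetic data; it is intentionally not reported.
* Segmentation assumes glomeruli are density plateaus separated by
  rarefactions; touching glomeruli with no rarefaction between them merge
  into a single core and are not split.
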