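# Methods

This note documents the models and procedures implemented in `ntquant`,
the design choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Coordinate and unit conventions

Pixel coordinates are 0-based with the origin at the top-left and y
increasing downward; in transverse sections the image top is dorsal.
Intensities are in arbitrary units throughout: only ratios and normalized
values are meaningful downstream, and every statistic the package reports
is invariant under affine intensity rescaling (normalized values) or under
gain with co-scaled background (junction ratios).

## Nuclear quantification and two-anchor normalization

A nucleus's reporter readout is the arithmetic mean of the reporter
channel over its label mask; shape descriptors (centroid, full major/minor
axis lengths, orientation) come from the second central moments of the
binary mask, the standard moments-ellipse construction. Segmentation is an
input, not a responsibility of the package.

Normalization maps v to v' = (v − b)/(m − b). The background anchor b is
the mean raw intensity of HuCD⁺ nuclei in the included region — justified
by the observation that pharmacological Notch blockade drives the reporter
down to neuron level, i.e. neurons measure pure background. The progenitor
anchor m is the mean over HuCD⁻ included nuclei, with the roof-plate and
motor-neuron-domain analogue zones excluded from both anchors (these
regions have atypically low activity and would bias m). Normalized values
are deliberately not clipped: single nuclei legitimately fall below the
neuron mean or above the progenitor mean. Anchors are estimated per
acquisition session by default (the closest reproducible unit; whether the
original background unit was the embryo or the section is not knowable
from the record), overridable to per-image by fitting a model per image.

Cross-session scale factors use the mean background-subtracted intensity
of HuCD⁺ nuclei on the non-electroporated side as an internal reference:
f_s = r₁/r_s, first session unit. Limitation: if the reference set
coincides exactly with the background-estimation set, r_s is identically
zero and no scale is defined; the implementation raises an explicit error
in that degenerate case rather than returning an unstable factor.

The color-coded map redraws each nucleus as its fitted ellipse, filled by
the bin of its normalized value. The default palette uses 8 equal-width
bins over [−0.2, 1.4] plus under/overflow bins (the bin edges of the
original macro are not recorded anywhere, so this range — covering the
bulk of observed normalized values with headroom — is a package choice),
bin edges lower-inclusive, excluded-zone nuclei drawn in a dedicated color,
and later labels overpainting earlier ones.

## Populations and rates

Population labels under cumulative S-phase labeling: EdU⁺/HuCD⁻ cycling
progenitor, EdU⁻/HuCD⁻ prospective neuron, EdU⁻/HuCD⁺ neuron. EdU⁺/HuCD⁺
double positives are biologically possible (a cell that cycled after
labeling and then differentiated) but are not part of the three-population
scheme; they are flagged "inconsistent", excluded from rates, and counted
in the log. Differentiation (proliferation) rate = transfected HuCD⁺
(EdU⁺) over all transfected cells. The neighbor differentiation rate pools
counts within a section — the union of non-transfected cells adjacent to
any transfected HuCD⁺ cell, each counted once — rather than averaging
per-cell ratios, because the section is the reported unit of analysis.

The dorsal restriction keeps nuclei whose centroid lies in the dorsal
two-thirds of the section height, measured from the dorsal-most tissue
pixel (y = 0 in the simulated sections); this is the simplest reproducible
reading of "dorsal two thirds" given that the motor-neuron domain
differentiates much earlier and would contaminate rate comparisons.

The cumulative-labeling curve reports EdU⁺ and HuCD⁺ fractions of the
labeled cohort per timepoint. The plateau estimate is the mean EdU⁺
fraction over timepoints ≥ 12 h (configurable onset; cumulative labeling
saturates once every cycling cell has passed S phase, observed by ~12 h in
this system), with the max-minus-min flatness of the plateau points
reported as a diagnostic. Monotonicity of per-cell EdU/HuCD status is a
hard validity check: a decrease marks a corrupt table.

## Apical metrics

Adjacency: two footprints are neighbors when ≥ 3 four-connected pixel
pairs straddle their shared border (a diagonal point contact is not a
junction). "One cell row away" is operationalized as graph distance
exactly 2; among ring-2 non-transfected candidates the four nearest by
centroid distance are chosen, ties broken by ascending id (the original
criterion for choosing among more than four eligible neighbors is
unrecorded; this convention is deterministic and scale-free). When fewer
than four ring-2 candidates exist, ring-1 non-transfected cells complete
the set with the ring recorded per neighbor; fewer than four in rings 1–2
combined excludes the cell with a logged count.

The "apical circumference" is the 2-pixel inner boundary band of the
footprint (band width is a free parameter; 2 px matches the painted band
of the simulator). The junction background is a per-image statistic taken
from non-junctional pixels (median intensity of cell interiors ≥ 3 px from
any border). The sister-pair filter removes transfected cells adjacent to
another transfected cell, symmetrically: with sparse mosaic transfection,
adjacency at one timepoint is a usable proxy for post-division pairs, at
the cost of a small false-removal rate equal to the adjacency probability
of independently transfected cells. The small/large split thresholds every
condition at the median of the control condition's area ratios, with
equality assigned to "large" (the boundary assignment is a documented
convention; the underlying definition of small as below-median leaves
equality open).

## Statistics

Parametric: two-sample Student t (pooled variance by default — the classic
default of the point-and-click package used for such analyses — Welch
optional) and one-way ANOVA with Tukey HSD. Nonparametric: two-sided
Mann-Whitney U, exact whenever combined n ≤ 20 — tie-free cases via the
standard exact distribution, tied cases by full enumeration of all
C(n, n_A) assignments of the pooled midranks, doubling the smaller tail —
and the tie-corrected normal approximation for larger samples;
Kruskal-Wallis with Dunn's pairwise z tests (tie-corrected rank variance),
adjusted by Bonferroni (default, Prism-compatible) or Holm. Stars:
ns p > 0.05, * p < 0.05, ** p < 0.01, *** p < 0.001, boundaries mapped to
the less significant label. The unit of analysis (cell vs section) is the
caller's responsibility and is never inferred.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
microscopy physics.

*Sections.* Nuclei are non-overlapping random ellipses (rejection sampling
with bounded retries against conservative bounding-circle overlap; an
explicit packing error names the achieved count when the request is
infeasible). Each nucleus draws a class from the configured proportions
(defaults 0.5/0.2/0.3 progenitor/prospective/neuron) and a nucleus-mean
reporter intensity from its class distribution — lognormal by default
(fluorescence intensity distributions are right-skewed; the actual
distribution shape is unrecorded, so normal is available as config),
moment-matched so the requested mean/sd are the arithmetic moments.
Defaults put neurons at the background level (100 ± 20 a.u.), progenitors
broad and high (600 ± 250), prospectives intermediate (500 ± 150), with
additive Gaussian pixel noise (sd 10). Fractional y-bands (defaults
0–0.06 and 0.72–0.86) mark the roof-plate and motor-neuron-domain
analogues. The DAPI-analogue channel is the binary nucleus mask. Marker
calls follow the class (neuron → HuCD⁺, progenitor → EdU⁺), with
transfection restricted to the electroporated (left) half.

*Mosaics.* Seed points sit on a jittered hexagonal lattice (jitter 0.18 of
the spacing): epithelial packing is far more regular than a Poisson point
process, and the low cell-area variance keeps the focal/mean-of-four-
neighbors ratio a nearly unbiased estimator of the constriction scale.
Footprints are the discrete Voronoi partition of the pixel grid (exact
partition: areas sum to the field area by construction). A differentiating
cell keeps exactly round(s·A) of its pixels nearest its seed; freed pixels
are absorbed by the nearest non-differentiating cell, so neighbor areas
respond as in a real epithelium. Junction intensity is painted on each
cell's 2-pixel inner boundary band at background + baseline × factor; with
a pixel partition the bands of adjacent cells are disjoint (each side of a
junction belongs to its own cell), which keeps the painted factor exactly
recoverable by the band measurement.

*Cohorts.* Each labeled cell exits the cycle at t0 with the configured
probability. Cycling cells re-enter S phase after a truncated-normal delay
(6 ± 2 h, capped at 8 h so that labeling saturates by the 12 h plateau
onset, as in the emulated protocol) and turn EdU⁺ at the first pulse at or
after entry (pulses at 3 h then every 4 h); exiting cells turn HuCD⁺ after
a normal differentiation delay (14 ± 4 h).

All randomness flows from one seed through a single `numpy` generator per
call; identical parameters reproduce outputs bit-exactly.

What the generator does **not** emulate: interkinetic nuclear migration,
point-spread blur, bleaching or illumination gradients, segmentation
errors, cell division and tracking over time, or any actual Notch
signaling dynamics. Passing recovery tests therefore demonstrates that the
measurement procedures are unbiased and correctly implemented under the
assumed statistical structure — not that they are robust to segmentation
or optical artifacts in real data.

## Problem sizes and numerical choices

Simulated checks use sizes chosen to keep Monte-Carlo error well inside
the assertion bands: 120–240 nuclei per 256–360 px section, 150–200-cell
mosaics at 300–360 px, 500-cell cohorts, 50-seed fold-change replications
and 1,000-repeat null calibrations at n = 10 per group (where the exact
Mann-Whitney path applies). Anchor identities are asserted to 1e-9;
recovery tolerances are stated per test (±0.08–0.1 for ratio recovery, 2–3
binomial/Monte-Carlo sd for proportions and fold changes). Degenerate
inputs fail loudly: empty anchor sets, m ≤ b, zero cross-session
reference, zero transfected cells, non-monotone cohort tables, fewer than
four eligible neighbors.
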