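# Methods

## Signal model of the synthetic assay

The generator emulates adherent cells carrying a two-colour splicing
reporter, imaged in three channels (Hoechst, GFP, RFP). Each cell is a
pair of concentric discs — nucleus of radius ~N(5.5, 0.6²) px (clipped to
[3, 7.3]) inside a cytoplasm disc 1.8× larger — with homogeneous
intensity, reflecting the assumption that both reporter proteins
distribute evenly through the cell. Per cell the generator draws:

* `transfected ~ Bernoulli(transfection_rate)`;
* an exon-inclusion fraction `psi ~ Beta(mean·c, (1−mean)·c)` with
  condition mean `inclusion_mean` and concentration `c`;
* an expression level `expression ~ LogNormal(log_mean, log_sd)` in
  detector counts.

A transfected cell contributes `expression·(1−psi)` to GFP and
`expression·psi` to RFP over its cytoplasm disc, so green + red is
conserved across splice outcomes and the ideal per-cell ratio is
G/R = (1−ψ)/ψ. Untransfected cells contribute nothing to the reporter
channels. Every cell (transfected or not) carries channel-specific
autofluorescence (default 15 counts in GFP/RFP, 8 in Hoechst); nuclei
carry 600 counts of Hoechst. Fields add a constant background (100/80/80
counts), a smooth first-order polynomial gradient (amplitude 20 counts,
random orientation per field), and i.i.d. Gaussian noise (σ = 5), then
quantise to 16 bits.

Cells are placed by rejection sampling so nuclei never overlap (centre
distance ≥ sum of nucleus radii + 1 px) and whole cells fit in the field;
an explicit error is raised when a field is too crowded to place. Defaults
are 360×360 px fields and 100 cells per field (≈0.08 cells/100 px², about
24% cytoplasm coverage). The literature behind the assay does not state
plating densities per field; these defaults were chosen as a typical
subconfluent 20× field and are a declared choice, not derived. Cytoplasm
discs *may* overlap (only nuclei are constrained), which reproduces a real
artifact of dense plating: reporter signal from one cell spills into a
neighbouring ROI. Quantitative parameter-recovery experiments therefore
use moderate density (60 cells/field, ~14% coverage), consistent with the
assay's own guidance to balance seeding density against robust detection.

What the generator does **not** emulate: point-spread-function blur,
photobleaching, nuclear/cytoplasmic partitioning of the reporters,
non-circular morphology, debris, or spatial plate-position effects.
Passing tests therefore demonstrate that the analysis chain is correct
under the stated signal model, not that it is robust to every real-world
imaging artifact.

## Segmentation

Harmony-style "find nuclei" is reimplemented as an auditable chain:
Gaussian smoothing (σ = 2 px) → global Otsu (or fixed) threshold → hole
filling → distance-transform watershed split of touching objects (seed
peaks ≥ 5 px apart on a lightly smoothed distance map, which breaks
plateau ties) → area filter (30–1000 px²) → optional border exclusion.
Otsu makes the object count invariant to global additive offsets.

ROIs grow each nucleus by `roi_expansion_radius` (default 5 px, covering
the default cytoplasm) with nearest-nucleus assignment of contested
pixels, so ROIs are disjoint and partition the union of dilations. The ROI
includes the nucleus by default (homogeneous-signal assumption); an
annular variant (`exclude_nucleus=True`) is available. The cell-free mask
is the complement of the ROIs dilated by a safety margin (default 4 px); a
local-variance texture filter was considered and rejected as equivalent on
this signal model. Fields with < 1% cell-free pixels raise an explicit
"background not estimable" error.

Coordinates are 0-based, row-major, pixel-centre; areas in px².

## Intensity and background

Background is estimated **per field and per channel** as the **median** of
the cell-free pixels — per field to tolerate illumination drift between
fields, median for robustness to debris and hot pixels (the estimator is
not otherwise constrained by the assay description). Corrected per-cell
means are `max(raw − background, 0)`; the floor keeps the ratio stage's
inputs physical. Because the background is re-estimated from the same
frame, corrected intensities are invariant (to < 1 count) under a global
additive offset.

## Gating and classification

Gates are `mean + k·SD` (k = 3) of the corrected intensities of cells in
untransfected negative-control wells, per channel, requiring ≥ 50 control
cells; the assay description says only that control wells defined the
threshold, so the 3σ rule is this package's concrete choice. A cell is
transfected when `corr_g ≥ gate_g` **or** `corr_r ≥ gate_r`.

The per-cell ratio is regularised as `(G + ε)/(R + ε)` with ε = 1 count so
it stays finite at zero red signal while matching G/R to ~1% for typical
intensities (hundreds of counts). Classification against K = 2 and J = 5
assigns boundary values (ratio exactly K or J) to the dual class — the
source inequalities are strict on both sides, leaving boundaries
unassigned, and dual is the conservative bucket.

Well summaries compute % transfected over **all** cells and the three
class percentages over **transfected** cells (the three always sum to
100). The median G/R is taken over transfected cells by default — a median
over all cells would be dominated by untransfected noise — with
`median_over="all"` available. Wells with no (transfected) cells report
NaN with `valid=False` rather than silent zeros.

## Quality control and dose-response

Z′ is implemented in its standard form, `Z′ = 1 − 3(σn+σp)/|µn−µp|`, the
only form consistent with a theoretical maximum of 1.0 at zero noise;
verdicts: ≥ 0.6 robust, ≥ 0.4 sufficient. The printed source formula for
the SNR is internally inconsistent and was not followed. The plate-level
readout is the per-well mean corrected RFP with WT-reporter wells as
negative and mutant-reporter wells as positive controls (per-well means,
not per-cell values, are the replicates). Condition comparisons use the
Welch t-test (robust to unequal variances; ANOVA is out of scope) with
Bonferroni adjustment `min(1, p·m)`.

Dose-response tables pair each treated (condition, dose) group with
scramble-control wells at the same dose and report treated-minus-control
class-percentage deltas; since each well's percentages sum to 100, the
three deltas sum to ~0 by construction.

## Densitometry

Lane profiles (position, intensity) are the input; 2-D gel images and lane
finding are out of scope. Migration follows `position ≈ a·log10(bp) + b`
fitted by least squares on ≥ 3 ladder rungs. The baseline is a grey-scale
morphological opening (window 61 px by default); because the opening rides
the lower noise envelope, the residual is re-centred on its median before
rectification — without this, band areas inflate by ~2σ·support. Peaks are
detected by prominence and integrated between flanking minima. Amplicon
assignment takes the nearest expected size within 10% relative tolerance
(reporter set 300/207/650 bp; endogenous set 368/275/650 bp), erroring on
a missing actin band or two bands competing for one amplicon. Within-lane
isoform percent `E10+/(E10+ + E10−)·100` is invariant to lane scaling
(actin cancels); the actin-normalised levels are retained for cross-lane
fold-changes.

## Numerical and scale choices

* Seeds are mandatory in all stochastic operations; plates derive
  independent per-well/per-field child seeds from a root `SeedSequence`,
  so results are byte-identical under a fixed seed.
* Test-suite experiments run at desk scale: unit tests on 200×200 px
  fields with ~40 cells; recovery experiments on 10–40 fields (2,000+
  transfected cells where a population estimate is being checked). These
  sizes give class-percentage sampling noise of ~1 point, comfortably
  inside the ±3-point recovery tolerance.
* Condition defaults mirror the biology: WT-like reporter
  `inclusion_mean = 0.35`, mutant-like (N279K) `0.85`; dose-response
  knockdown spans `0.72 → 0.37` with Beta concentration 3 so the red-class
  reduction is graded (~−5 to ~−47 points vs scramble) rather than
  saturated; recovery experiments use a U-shaped ψ (concentration 0.1) so
  classes are cleanly separated.

## Known limitations

* Scalar per-field background only; no flat-field correction or spectral
  unmixing.
* The gate is a global per-plate threshold; plates with strong per-well
  autofluorescence differences would need per-well gating.
* Watershed seeding can over-split very elongated nuclei (not generated
  here); the area filter bounds the damage.
* Densitometry assumes well-separated bands; co-migrating species are
  reported as a single band or an assignment conflict, never silently
  summed.
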