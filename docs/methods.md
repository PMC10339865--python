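# Methods

## Problem and signal

Weaned pigs rest most of the day, and the moments when *every* animal in a
pen lies down (group recumbency) carry management information: they reflect
thermal comfort and group health. Detecting those moments per animal from
overhead cameras is unreliable because small pigs overlap when lying.  This
package instead detects group recumbency from a single group-level signal,
the **cumulative group velocity**

    v = Δp / Δt ,

where Δp is the sum of frame-to-frame Euclidean displacements of all
animals the tracker flags as standing, and Δt the frame interval.  Per-pair
velocities are averaged over 5-minute windows; a window is classified
"all recumbent" (code 0) when its velocity does not exceed a fitted cutoff,
"some animal standing or sitting" (code 1) otherwise.

## Pipeline

1. **Tracking input / synthetic generator** — per-frame positions and
   detected-standing flags per pen.
2. **Blur QC** — frames are scored by the variance of the 3×3 discrete
   Laplacian over valid interior pixels; scores below a cutoff (default
   1000 on 8-bit intensities) mark blurred frames (dirty lenses), which are
   excluded together with their labels.
3. **Binary coding** — two observers code each sampled image 0/1; percent
   agreement is reported and discrepancies are resolved by an explicit
   adjudication table (a human discussion cannot be computed).
4. **Linking** — each consensus-coded image joins the velocity window
   containing its timestamp, by pen and time.
5. **Threshold fit** — the cutoff maximizing training accuracy over all
   decision boundaries (midpoints of consecutive distinct velocities plus
   one candidate below the minimum and one above the maximum).
6. **Evaluation** — seeded 10-fold cross-validation; sensitivity,
   specificity and accuracy per fold and unweighted fold averages; a Welch
   t-test of velocity by class.

## Conventions and numerical choices

* **Velocity.** "Average sum of displacements" is read as: sum
  displacements over standing-flagged animals per frame pair, divide by
  Δt, then average per-pair values within the window.  The standing flag
  is taken from the later frame of each pair; animals missing from either
  frame contribute zero (both are fixed, testable conventions the
  measurement chain leaves open).  Windows are half-open
  `[start, start+300 s)` aligned to the stream's first timestamp, which is
  deterministic without time-zone metadata.  Velocities stay in SI m/s
  even though typical magnitudes are 1e-4…1e-2.
* **Blur score.** Kernel center −4 with +1 four-neighbors; variance is the
  population variance over valid (unpadded) interior responses;
  intensities are promoted to float before convolution.  Because kernel,
  border mode and intensity scale all move the score, the cutoff is
  configuration, not a portable constant.  Boundary semantics: kept iff
  `score ≥ cutoff`.
* **Classification boundary.** A velocity exactly at the threshold is
  classified recumbent.  The detector's purpose is to surface only images
  in which all animals truly lie, so the boundary favors the negative
  class.
* **Tie-breaking in the fit.** Among cutoffs tying on training accuracy,
  the one with higher sensitivity wins, then the smaller cutoff.  Since
  sensitivity is non-increasing in the cutoff, this amounts to the
  smallest optimal cutoff.  One consequence worth knowing: on data where
  "classify everything as standing" ties with an interior cutoff, the
  all-standing cut (a candidate below the minimum velocity) is selected.
  When the minimum observed velocity is 0 that candidate is negative; it
  simply encodes "everything standing".
* **Stepwise (loop) fitter.** The narrative procedure — raise the cutoff
  in fixed steps while the count of active-coded samples above it keeps
  strictly decreasing, then, if the result is below the highest
  recumbent-coded velocity, restart from that velocity — is kept as a
  secondary implementation.  Its step size and stopping rule admit several
  readings; the exhaustive fitter is canonical because it is what
  "maximize accuracy" requires.  Step size and the initial value are
  configurable.
* **Mean + SD rule.** The screening threshold available before labels
  exist: mean of recumbent-class velocities plus one *sample* standard
  deviation (ddof = 1).
* **Cross-validation.** One seeded shuffle, k folds with sizes differing
  by at most one (scikit-learn `KFold`), threshold refitted per fold.
  A per-fold metric whose denominator is zero (a test fold missing one
  class) is *undefined*, logged, and excluded from that metric's
  unweighted average — never reported as 0.
* **t-test.** Welch (unequal variances), two-sided.  The two classes are
  grossly unbalanced in size and spread (typically ~90:10), which rules
  out the pooled-variance variant.
* **Seeds.** Default seed 123.  All randomness flows through
  `numpy.random.default_rng`; identical config + seed reproduces every
  artifact byte for byte.  Equivalence with any other RNG lineage is not
  promised.

## The synthetic generator

The generator emulates the tracker's output, not pig ethology.  Behavior
is generated at group level because the unit of analysis is the group
code: a schedule alternates `all_recumbent` and `some_active` states.

* During `all_recumbent`, every animal takes a random-direction step whose
  magnitude is drawn from the recumbent jitter distribution — this models
  tracker detection noise, since real recumbent frames still carry nonzero
  measured velocities — and is flagged standing only at a configurable
  false-detection rate.  Whether a fully recumbent pen yields an empty
  standing set or occasional false detections is not fixed by the
  measurement chain, so the rate is a config parameter (default 0.1 per
  animal-frame).
* During `some_active`, a per-segment subset of `n_active_when_active`
  animals takes steps from the active speed distribution and is flagged
  standing.
* Positions are continuous meters with origin at a pen corner
  (2.55 m × 3.20 m, 18 animals by default); out-of-pen coordinates are
  reflected back inside and counted.  No pixel-to-world calibration is
  modeled — the tracker is the abstraction boundary.

Default magnitudes: recumbent jitter N(3e-4, 2e-4) m/s clipped at 0 and
active speed N(5e-3, 1.2e-3) m/s, chosen so the recumbent-class window
velocities sit near the ~6e-4 m/s decision boundary observed in real
rearing data and the two classes form the clearly bimodal histogram the
threshold method presumes.  The direct window-level sampler
(`sample_velocity_dataset`) draws recumbent windows from |N(0, 2e-4)| and
active windows from N(5e-3, 1.2e-3) with a ~10.4% recumbent share, the
class imbalance of a blur-adjusted rearing dataset.  For this mixture the
analytic best-achievable (Bayes) accuracy of any cutoff is computed by
maximizing π₀·P(|N(0,σ₀)| ≤ t) + π₁·P(N(μ₁,σ₁) > t) over a fine grid; the
cross-validated classifier is expected to come within ~2 points of it.

What the generator does **not** model: realistic pig shapes, occlusion
resolution, identity switches, camera optics, diurnal rhythm, or per-animal
ethograms.  Synthetic images are random-ellipse scenes whose only relevant
property is a controllable sharpness ladder.  Passing tests therefore
demonstrate the correctness of the measurement-to-decision chain under the
stated statistical structure, not field performance on farm footage; the
published real-data metrics (accuracy ≈ 94%, sensitivity ≈ 98%,
specificity ≈ 61%) depend on a dataset that is not publicly distributable
and are out of reach of desk-scale reproduction.

## Problem sizes

Test and acceptance runs use deliberately modest sizes: 2–4 pens,
2–4 hours of footage at 2–5 s frame intervals, images every 10 min,
mixture datasets of n = 4000, and 10-fold cross-validation — enough for
the statistical checks (cluster-mean recovery within 3 standard errors,
CV accuracy within 2 points of the Bayes ceiling, binomial bounds on coder
disagreement) to be sharp while each suite finishes in seconds.

## Known limitations

* The exhaustive fitter optimizes plain accuracy; with ~90:10 imbalance a
  cost-sensitive criterion could trade sensitivity against specificity
  differently.
* The stepwise loop fitter inherits the ambiguity of its narrative source;
  it is provided for comparison, not as the default.
* Agreement is raw percent (the coding design reports no chance-corrected
  kappa).
* `link` assumes one image per (pen, window) at most matches one window;
  duplicate labels are rejected rather than resolved.
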