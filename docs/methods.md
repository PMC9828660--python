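# Methods

`muscan` implements the computational core of ultrasound-guided motor-unit
scanning EMG: (i) a chord-geometry simulator quantifying how needle-path
placement biases motor-unit (MU) diameter estimates, (ii) a synthetic
generator of stimulus-locked scan archives with known ground truth, and
(iii) the measurement pipeline that turns scan archives into drift-corrected
territory estimates. This note records the models, the defaults and why they
were chosen, the numerical conventions, and the known limitations.

## 1. Chord geometry of territory outlines (`muscan.shapesim`)

**Model.** An EMG needle transect through a MU cross-section is a chord of
the territory outline. For an outline `S` with maximal (Feret) diameter
`D_max`, the standardized underestimate of a transect of length `L` is
`100·L/D_max`. A *blind* insertion samples chords uniformly over
perpendicular offset and orientation; a *targeted* insertion (ultrasound
guidance) restricts to chords whose line passes through the shape center.
For a circle the blind median has the closed form: the median offset over
`d ~ U[-r, r]` is `r/2`, giving a chord `2·sqrt(r² − r²/4) = sqrt(3)·r`,
i.e. `sqrt(3)/2 ≈ 0.866` of the diameter.

**Enumeration.** Shapes are rasterized on a `size_px × size_px` grid
(default 500; a pixel is inside when its center satisfies the interior
inequality). Rather than re-rasterizing a rotated shape, the *sampling
direction* is rotated over [0°, 180°) in 1° steps — mathematically the
same operation, free of interpolation artifacts. For each orientation,
parallel lines at 1 px perpendicular offsets covering the rotated bounding
box are sampled at 1 px spacing; a sample is in-shape when its nearest
pixel is. Chord length is (in-shape sample count) × (sample step): pure
integer arithmetic with error ≤ 1 px per segment. Lines with no in-shape
sample are not chords and are excluded. A chord "passes the center" when
its perpendicular distance to the shape center is ≤ 0.5 px (one half-pixel,
the natural discretization of "traverses the center"). Multi-limb
crossings count the sum of the in-shape runs — the gap between limbs is
discounted.

**Shape geometry defaults.** Only shape *names* are prescribed by the
protocol being modeled, so the ratios are package choices, exposed in
`ShapeSpec`: wide ellipse 2:1, narrow ellipse 6:1, pennate = two parallel
rectangular limbs inclined at 60°, width 0.28 and gap 0.18 of the bounding
box. The headline circle percentages are geometry-free; the ellipse and
pennate percentages depend on these ratios and are therefore validated by
*ordering* (targeted ≥ blind for every shape; narrower ⇒ smaller blind
median), not by absolute value.

**Numerical notes.**
- Medians with even counts take the mean of the two central values.
- Percentages are kept at full precision and rounded to integers only for
  standardized reporting. At 500 px the blind circle median measures
  86.4% (the longest enumerated chord, 501 px, normalizes the 433 px
  median), rounding to 86; the continuous limit is 86.6%.
- `max_feret_diameter` uses the convex hull of in-shape pixel centers
  (the diameter of a point set is attained on the hull) with a brute-force
  fallback for degenerate masks; the standardized table normalizes by the
  longest *enumerated* chord so numerator and denominator share units.
- Raster limitation: a line grazing the pixel staircase near tangency can
  fragment into several short runs, so `n_segments > 1` occurs even for
  convex shapes near `|offset| ≈ r`. Lengths (sums of runs) are unaffected;
  segment counts are meaningful away from tangency and for the deliberate
  two-limb geometry.
- Resolution stability: doubling `size_px` moves every standardized
  percentage by well under one point (tested 200 vs 400).

## 2. Synthetic scan archives (`muscan.synth`)

The generator emulates the *statistical structure* of hand-stepped,
stimulus-locked scans — not muscle biophysics. A volume-conductor
simulation is out of scope; waveform shapes are stylized templates.

**Acquisition geometry.** The needle starts deep to the unit (position 0)
and is withdrawn along a straight trajectory inclined 40° (configurable
30–45°) to the skin, in-plane with the probe. Commanded steps are
`N(1.85, 1.07²)` mm, floored at 0.3 mm — the measured hand-step statistics
of the protocol. **Stiction:** tissue drags with the needle until the
accumulated commanded displacement exceeds a yield threshold (default
1 mm), then slips by a configurable fraction of the pending displacement;
any residue is released at the final position, so realized steps are
non-negative and sum exactly to the commanded total. Realized positions,
not commanded ones, place the needle relative to the MU.

**Signal model.** Each sweep is
`stimulus artifact + (fired ? MUP : 0) + white Gaussian noise`:

- *MUP template*: three alternating lobes (`sin(3πx)` on an open interval)
  with a center-weighted envelope deepening the main negative deflection;
  normalized so peak-to-peak equals the target amplitude exactly and the
  onset-to-end span of non-baseline samples equals the requested duration
  to within one sample. "Duration" is that span (matching the analysis
  module's onset/end rule), not a count of super-threshold samples — the
  waveform crosses zero inside its support.
- *Depth envelope*: peak-to-peak amplitude follows a Gaussian of the
  distance from the territory center (σ = extent/3), truncated to zero
  outside the territory. The edge thus sits at ≈ 32% of the peak: with the
  default 220 μV peak (the cohort mean maximal amplitude is 219 μV), edge
  positions (~71 μV) stay above the 50 μV validity rule while the noise
  floor (range of ~1000 baseline samples at SD 5 μV ≈ 32 μV) stays below
  it — i.e. the measurable territory coincides with the ground-truth
  territory under defaults, as it must for parameter-recovery testing.
- *Cannula potential*: positions in the deepest `cannula_fraction`
  (default 0.3) of the territory emit an inverted, 1.6×-broadened copy of
  the template — the diffuse shaft pick-up seen when the tip is beyond the
  active fibers. It is normalized to the same envelope amplitude so
  ground-truth peak-to-peak stays exact.
- *All-or-nothing alternation*: per sweep, a Bernoulli draw (default
  p = 0.9) either inserts the full-amplitude MUP at
  `latency + N(0, 0.2 ms)` jitter or nothing. No graded responses exist.
- *Stimulus artifact*: a deterministic biphasic transient in the first
  1 ms after the stimulus (t = 0), amplitude 300 μV, identical in every
  sweep; the analysis blanks it.
- Noise SD (5 μV) and jitter SD (0.2 ms) are stated assumptions — the
  source protocol shows but does not quantify them — and are config
  fields.

**Ground truth** records the per-position true amplitudes/latencies/
durations, per-sweep firing flags, realized steps, per-step drift, and the
territory extent defined as the span of nonzero-amplitude positions along
the trajectory (0 when fewer than two positions fall inside).

**Image coordinates.** The track reports needle-tip and three
fascial-landmark positions in pixels (0.1 mm/px default; y grows with
depth). Probe drift is a per-step 2-D Gaussian translation (SD 1.5 px)
applied *identically* to needle and landmarks — the situation the landmark
correction can undo exactly. Independent per-landmark labeling noise is
deliberately absent from the defaults: with it, the mean-of-three
correction is only approximately exact, which would entangle two error
sources in recovery tests. Coordinates are kept at float (sub-pixel)
precision.

**Cohort factory.** `generate_table2_cohort` draws per-recording latency
(4.3–37 ms), peak amplitude (101–520 μV), extent (1.5–12 mm) and duration
(2.8–10.2 ms) uniformly from the published cohort's ranges, widening the
scan when a drawn territory needs more positions. All randomness flows
through one seeded `numpy` generator: identical config + seed ⇒
bit-identical archives.

## 3. Measurement pipeline (`muscan.analysis`)

**Drift correction.** Per step, the drift estimate is the mean over the
three landmarks of their coordinate change between consecutive positions;
the corrected needle position subtracts the *cumulative* sum of these
per-step means, anchored at the first position. The per-step difference
alone would not remove accumulated probe motion; the cumulative form makes
the correction exactly invariant to any common translation of needle and
landmarks at any step (property-tested). Distances derive from corrected
needle coordinates times the pixel spacing — never from commanded steps.

**Detection.** Replaces manual trace marking with a reproducible rule.
A sweep is *fired* when its peak-to-peak amplitude inside the response
window (2–100 ms post-stimulus; first 1 ms blanked for the artifact)
exceeds the validity threshold (50 μV, the scanning-EMG convention). A
fired sweep's onset is the first run of ≥ 5 consecutive samples deviating
from the pre-stimulus baseline mean by more than
`max(3·baseline_SD, 2 μV)`; the end is the last sample of the last such
run. The 2 μV absolute floor keeps the rule defined on noise-free records
where the baseline SD is exactly zero. A *position* is valid when ≥ 3
sweeps fired (of 20) **and** their onset latencies agree within SD ≤ 1 ms
(synchronicity — random noise crossings are not one motor unit). How many
of the 20 sweeps must fire is not specified by the source protocol;
3 is the package's assumption, configurable. Position-level amplitude is
the **max** over fired sweeps (the convention for scan amplitude); latency
and duration are medians over fired sweeps (robust to jitter).

**Extent and summaries.** Territory extent is the Euclidean mm distance
between corrected needle positions of the outermost valid traces; with
≤ 1 valid position it is 0 with an explicit flag (3-position transects are
legitimate, so degenerate scans must not fail). Transect summaries report
max amplitude / longest duration / earliest latency over valid positions.
Cohort summaries average numeric columns, add a median for position counts,
and average mm:ss durations on seconds.

## 4. What passing tests do and do not show

The synthetic generator reproduces the *mechanisms* the pipeline must
handle — alternation, depth-dependent amplitude, inverted deep potentials,
artifact, stiction, drift — but not real muscle: no motion artifact of the
probe in the sweep data, no amplifier saturation, no vascular pulsation,
no spatially correlated noise, no MUP shape change across the territory
beyond the cannula flip, and drift that is a pure translation (no tissue
shear, which the three-landmark mean would only partially correct).
Recovery results on synthetic scans therefore validate the *algorithms*
(and their exactness under their own assumptions), not clinical accuracy.
The in-vivo recordings behind the published cohort are not publicly
deposited; the published per-recording summary rows are embedded as a
reference dataset and their cohort statistics are recomputed, while
signal-level claims are exercised on synthetic data only.

## 5. Problem sizes used in the shipped checks

Full-resolution chord enumeration (500 px, 1°/1 px ≈ 90,000 chords per
shape) runs in seconds and is used for the headline percentages; smaller
grids (200–400 px) back the property tests (rotation invariance on the
500 px circle, where the ±1 px rasterization jitter is below the 1%
tolerance). Territory-recovery statistics use 50 seeded scans of 8–12
positions × 20 sweeps × 1300 samples.
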