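# Model and methods

`barrelmap` simulates how a map of whisker-deflection direction can organise
itself in layer 2/3 (L2/3) of rat barrel cortex, driven purely by the
statistics of tactile input. This note documents the model, its parameters,
the synthetic stimulus generator, the analyses, and the numerical and design
choices the implementation makes.

## The model

**Whisker field and stimuli.** 25 whiskers sit on a 5x5 grid with unit
spacing. A tactile contact is a half plane: a line through a random point
(uniform over the whisker bounding box expanded by `origin_margin = 0.5`
grid units per side) with outward normal along a movement direction
`theta_s`. Whiskers the plane has swept over (signed projection <= 0;
boundary points count as swept) are deflected; each deflected whisker's
direction is an independent Von Mises draw centred on `theta_s` with
concentration `kappa`. `kappa = 0` gives uniform directions, `kappa = inf`
(an explicit branch, never a large float, so the limit is exact) makes every
deflection equal `theta_s`. Events deflecting no whisker are rejected and
resampled (cap: 1000 tries). The movement direction itself is uniform, or
Von Mises with concentration `direction_anisotropy` about `direction_mean`
(default pi/2) when input anisotropy is studied.

**Layer 4.** Each whisker drives one barrel of 25 direction-tuned units.
Unit MEDs (maximally effective directions) are drawn once, uniformly on the
circle, and stay fixed. A deflected whisker's unit fires at a half-wave
rectified cosine of the angle between deflection and MED (half-height width
120 deg, reflecting the broad tuning of barrel neurons); undeflected barrels
are silent. A raised-cosine variant `(1 + cos)/2` and a sharpening exponent
are available for sensitivity analysis; the rectified curve is the default
because it keeps counter-driven units silent, which lets Hebbian learning
separate directions.

**Cortical sheet.** L2/3 is a square sheet divided into one supra-barrel per
whisker. Each neuron receives (i) an afferent field: one weight per unit of
its own barrel (barrel-to-supra-barrel connectivity is all-to-one), (ii) a
fixed excitatory field from itself and its 8 neighbours, and (iii) a plastic
inhibitory field from every neuron within a window four supra-barrel widths
across, centred on it and clipped at the sheet edge. All fields are
initialised to uniform random weights normalised to sum to 1; border fields
are renormalised over their surviving connections.

A stimulus is processed in four stages: the afferent drive (weighted sum of
barrel rates) is computed and held fixed; the lateral dynamics settle for 9
synchronous steps through a piecewise-linear sigmoid with lower threshold
`delta` and saturation `beta`; the afferent and inhibitory fields of active
neurons are updated by Hebbian learning with divisive normalisation
(`w' = (w + alpha pre post) / sum(w + alpha pre post)`, with
`alpha = c / N_CF` for a field of `N_CF` connections, fields normalised
separately); activity is reset. Divisive normalisation redistributes
synaptic resources instead of saturating them, so weights stay nonnegative
and each field sums to exactly 1 after every update.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `kappa` | 3 | Von Mises concentration of per-whisker direction noise (headline training condition) |
| `origin_margin` | 0.5 | extension of the origin box beyond the whiskers, grid units |
| `supra_size` | 21 | neurons per supra-barrel side (105x105 sheet) |
| `settling_steps` | 9 | synchronous lateral settling iterations |
| `delta`, `beta` | 0.187, 1.015 | sigmoid lower threshold and saturation point |
| `gamma_E`, `gamma_I` | 1.31, 3.68 | lateral excitatory / inhibitory gain |
| `c_A`, `c_I` | 0.35, 0.1 | learning-rate numerators; `alpha = c / N_CF` |
| tuning exponent | 2 (training/measurement) | sharpening applied to the rectified cosine by the experiment layer |
| threshold | 0.33 | pinwheelness classification threshold (the angular-angular correlation reported for the biological map) |

The sigmoid thresholds, lateral gains and learning rates are not uniquely
determined by the model description; they were fixed once by pilot
calibration against the behaviour the model is meant to produce: settled
activity condensing into discrete bubbles smaller than one supra-barrel,
bubbles sitting at the leading edge of the stimulated region (sign test on
centroid displacement), settling that stabilises within the 9 steps on
trained networks, and direction maps that actually organise (pinwheels
forming over training, counter-clockwise dominance under correlated input).
The calibration also favoured a constant (rather than random) excitatory
kernel and a rectified-cosine tuning curve sharpened with exponent 2 at the
experiment level; the low-level tuning-curve functions keep exponent 1 as
their own default so the canonical broad curve stays the reference. All
values live in `Architecture` and are recorded in every checkpoint; nothing
is hard-coded.

## Analyses

Maps are measured feed-forward: each whisker is deflected through 16 evenly
spaced directions with lateral interactions and learning off; each neuron is
labelled by the direction evoking the largest afferent response (argmax ties
break to the lowest direction index and are counted), with selectivity the
resultant length of response-weighted direction vectors. Each supra-barrel
map is compared with the ideal somatotopic pinwheel template
`atan2(y, x)` about the supra-barrel centre (centre cell excluded) using the
Fisher-Lee angular-angular correlation, computed via its O(n)
trigonometric-moment identity and cross-checked in the tests against the
literal pairwise double loop. |r| is the supra-barrel's pinwheelness;
`r > 0.33` counts as a counter-clockwise, somatotopically correct pinwheel,
`r < -0.33` as clockwise/inverted. The circular mean of (map - template) is
the alignment offset; the circular standard deviation `sqrt(-2 ln R)` of
CCW offsets summarises global alignment. Map anisotropy is the mean
resultant length of all neurons' preferred-direction unit vectors.
Weight-direction coupling is the Pearson correlation between every lateral
inhibitory weight and the circular absolute difference of the two neurons'
preferred directions.

## Reduced scale

The published campaign trains 20 networks x 5,000 patterns per condition on
the 105x105 sheet. The package supports that scale (`scale="paper"` in
`Campaign`), but its default test and acceptance scale is smaller so that
complete condition sweeps run on a single CPU in minutes: a 65x65 sheet
(13x13 supra-barrels, inhibitory window 52x52 — all architectural ratios
preserved), 1,500 training patterns, and 3-5 replicate networks per
condition. Every emitted table carries the scale label so reduced-scale and
paper-scale numbers are never conflated. Map statistics at the reduced scale
are qualitatively identical but noisier; fractions are computed over
75-125 supra-barrels instead of 500.

## What the generator does and does not emulate

The stimulus generator reproduces the statistical structure assumed to
matter for map formation: locally contiguous whisker subsets swept by large
moving objects, and the coupling between the swept subset and the deflection
directions. It does not model whisker biomechanics, deflection amplitude or
velocity, temporal structure within a contact, or active whisking; passing
tests therefore show that the mapped statistics suffice for the simulated
organisation, not that real rat pups experience exactly these statistics.

## Numerical choices

* Settling is the computational bottleneck (up to 7,056 inhibitory
  connections per neuron). The compiled kernel switches per step between a
  sparse gather over the active-neuron list and a dense streaming gather
  over a single-precision mirror of the inhibitory weights; the switch
  depends only on the active count, so runs are bit-reproducible for a
  fixed seed. Master weights, learning and all statistics are double
  precision; connection-field sums hold 1.0 to 1e-9 after every update.
* A pure-NumPy reference implementation of the settling dynamics is kept in
  the package and the test suite asserts the kernel matches it on small
  sheets.
* One master seed per network spawns independent child streams for the
  stimulus sequence, weight initialisation and MED assignment.
* Argmax ties in map measurement break to the lowest direction index; tied
  (unselective) neurons are counted in `DirectionMap.n_ties`.
* Degenerate statistics raise or mark explicitly: zero angular variance
  raises `UndefinedCorrelationError`, a vanishing resultant makes the
  circular standard deviation infinite and per-location circular means NaN;
  supra-barrels with undefined correlation (e.g. fully collapsed or
  deprived ones) are scored as `None`/unconstrained and excluded from
  fraction denominators.

## Known limitations

* **Pinwheel fractions saturate well below the target regime.** The model
  reproduces every qualitative phenomenon it is built around — activity
  bubbles migrate to the leading edge (sign test p << 0.01), direction maps
  are smooth and develop over training, somatotopically correct
  (counter-clockwise) pinwheels dominate inverted ones under correlated
  input, the rotation sense is balanced under uncorrelated input, exact
  direction-location correlation degrades pinwheel quality, and the
  shuffling/decorrelation controls abolish global alignment — but the
  *fraction* of supra-barrels crossing the 0.33 pinwheelness threshold
  saturates around 15-30% rather than the 76-90% regime the simulated
  experiments aim for. The cause was isolated with an oracle experiment:
  driving the Hebbian rule with idealized leading-edge bubbles (compact
  blobs at supra-relative angle theta_s in boundary-adjacent supra-barrels)
  produces fully somatotopic pinwheels in every supra-barrel within 1,000
  patterns, so the stimulus model, afferent encoding, learning rule and
  analyses are all sufficient. The gap is in the settling dynamics: because
  the inhibitory connection field is initialised uniform-random, its
  expected profile is flat across the whole window, and the spatial
  resolution with which "least net inhibition" can select a bubble location
  is on the order of half the window — two supra-barrel widths. Winner
  selection below that scale is decided by frozen weight noise rather than
  by the stimulus boundary, which caps how precisely bubbles can track the
  boundary within a supra-barrel. Several hundred parameter combinations
  (grid pilots plus random search, including searches scored directly on
  the overlap between settled activity and the oracle bubbles) did not find
  a regime of these dynamics that escapes the cap.
* Settling on *untrained* sheets retains a sizeable flicker at the final
  synchronous step; the near-stationarity expected of settled activity
  (final-step change below a fifth of the first-step change) is reached
  only after lateral learning has structured the weights.
* Inhibitory plasticity is a sensitive dial: with `c_I` around 1 or larger
  the potentiation among co-active neurons runs away, total activity
  collapses to ~1% of the sheet, and neurons end up tuned to the *rare*
  stimulus directions (the anisotropy of maps trained under a fixed
  stimulus direction inverts). The default `c_I = 0.1` keeps the
  decorrelating effect mild.
* Supra-barrel size must be odd so the template centre falls on a neuron.
* The checkpoint container stores full double-precision inhibitory fields;
  at the full 105x105 scale a checkpoint is ~600 MB.
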