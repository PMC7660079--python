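# Methods

`wormvib` models an automated *C. elegans* lifespan machine augmented with a
plate-level vibration stimulus, and quantifies how much that stimulus improves
automated live/dead scoring. Because no plate-image archive is publicly
deposited for this kind of rig, the package pairs the analysis pipeline with a
synthetic imaging and behaviour simulator whose defaults encode the published
operating point of such machines; every downstream stage is tested against the
simulator's ground truth.

## Imaging model

A 55 mm Petri plate is imaged from above, 30 frames at 1 fps once per day per
plate. Active lighting holds the background at grey level 48, so a *fixed*
segmentation threshold of 33 separates worm pixels (rendered at grey 15) from
background with no per-image tuning. Small wall-shadow arcs covering 5% of the
plate area are rendered below threshold; a worm whose body touches them is
hidden from view, which is the machine's real hidden-worm failure mode.
Optional sensor-noise pixels alternate between dark and background grey every
frame.

Rendering is deliberately anti-alias-free (hard grey levels) so threshold
segmentation is exact and every detection-stage property can be asserted
bit-for-bit. The plate is scaled to fit the configured image (default
512x512; the test/CI scale used throughout the tests and the acceptance
script is 256x256, i.e. ~229 um/pxl effective). Worms are rendered as
10-point centrelines dilated to the canonical 3 px body width regardless of
scale; physical quantities (motility in px^2 at the machine's nominal
30 um/pxl) are converted through millimetres to the effective pitch.

## Behaviour model

Per worm, per calendar day:

* **Lifespan** — death days are drawn from a Gompertz distribution
  discretised to days. Shape `a = 0.25/day` and scale
  `b = a ln2 / (e^{14a} - 1)` put the continuous median exactly at day 14
  (mean ~13.5), matching wild-type N2 on FUdR; a point-mass family is
  available for exact-arithmetic tests. A worm is alive on day `k` iff
  `k < death_day`.
* **Spontaneous stillness** — a live worm shows no detectable movement during
  a 30 s inspection with probability given by a piecewise-linear curve: 2% up
  to day 5, 15% at day 9, 29% at day 21 and beyond. Draws are independent
  across days (no lethargy persistence parameter exists in the model).
* **Vibrotaxis** — on a stimulation day the worm responds (moves during the
  post-vibration sequence) with weekly probability 0.99 / 0.98 / 0.93,
  multiplied by a habituation factor `(1 - 0.005)^{n_stimuli}` that resets
  when the stimulus duration changes. Each prior stimulation day also shaves
  1% off the movement amount.
* **Motility** — a young adult sweeps 1200 px^2 per 30 s (at 30 um/pxl),
  decaying linearly with the fraction of life lived. In-sequence crawl
  distance is half the swept length (tortuosity) with a 2 px floor so that a
  moving worm is always resolvable; the overnight step is `4 sqrt(area)` px
  with a 4 px floor. Movement is a heading-persistent random walk with a
  drift back toward the central bacterial lawn (worms forage on the lawn;
  wall excursions are transient), reflected at the plate wall. Worms keep a
  minimum separation along their whole step path, so synthetic blobs never
  merge and motion pixels are never credited to a neighbour; overlapping-worm
  behaviour is exercised only in constructed scenes and documented as a
  limitation of blob counting.

**Timing convention.** All of a worm's movement on day `k` (in-sequence
displacement plus the overnight step) happens while it is alive on day `k`,
and the overnight step is taken only if it survives day `k+1`: a moribund
worm makes no movement between its last inspection alive and the next. This
makes the dead-or-alive criterion exact under daily acquisition — in the
clean limit (no stillness, no occlusion) the automatic curve equals ground
truth exactly, which is asserted in the tests. Deaths that fall inside a
multi-day acquisition gap (weekends) are intrinsically scored alive at one
extra inspection by the criterion (the corpse lies at a new position);
automatic and reference curves share this lag, so it cancels from the error
statistics.

## Detection and scoring

Each frame is thresholded at grey 33; each pixel of the aligned binary stack
is classified by its temporal signature: all black = constant dark, all
white = constant white, otherwise the count of black/white transitions
separates sensor noise (>= 8 transitions per 30 frames, configurable — only
the ordering "noise switches more often than motion" is fixed by the machine)
from genuine motion. Worm blobs are connected components of the last frame's
black mask (noise pixels removed) within plausible size bounds; frame
alignment is integer-pixel translation by phase cross-correlation (a no-op
for the simulated rigid camera, so the pipeline presets skip it).

A worm is scored **alive** on an inspection day if it moved within any of the
day's sequences (the post-vibration sequence counts), or its centroid moved
more than one worm width (3 px) since the previous inspection, or its blob
mask changed by more than 5% relative symmetric difference. Both tolerances
are package choices — the criterion itself ("no change in shape and position
between consecutive inspection days") fixes no numbers. Day-to-day identity
is greedy nearest-neighbour linking with a gate equal to the largest
plausible daily displacement; since the cohort size is fixed by design
(FUdR-sterilised worms), leftover detections are folded onto leftover tracks
before any new track is created.

Two curves come out of the same detections:

* the **automatic curve** `SA(k)` applies the criterion causally day by day
  and is left unrectified (it dips when a live worm is briefly still or
  hidden and rises when it moves again);
* the **reference curve** `SM(k)` emulates expert manual counting with
  regressive rectification: reviewing each identified worm's history, the
  expert keeps it alive through its last observed change, and a worm first
  seen late (it had been hidden) is recovered back to day 1. The reference is
  therefore non-increasing by construction, pointwise >= the automatic curve,
  and equals ground truth in the clean limit. `rectify_curve` (reverse
  running maximum) is the same rectification at the count level and is
  exposed and tested separately; triple-inspection mode takes the most
  favourable evidence across three daily inspections before rectifying.

## Error statistics

With `SM`/`SA` summed over a condition's plates, per-day error
`e(k) = |SM(k) - SA(k)|` and total error `eT = mean_k e(k)`, reported as a
percentage of the initial cohort `n0` (the normaliser is a package choice;
only the percentage form of eT is fixed). Signed plate errors
`eP = x - X` (measured minus reference) are taken **per plate per acquisition
day** and pooled: a single per-plate summary cannot produce an error
*distribution* per plate with near-zero mean and a spread of about one
individual, whereas the daily plate errors do. Their dispersion is
`sigma = sqrt( sum eP^2 / (N - 1) )` — the uncentred form, implemented
literally; a conventional centred SD sits behind a flag. Equality of error
variances between conditions is tested with a two-sided variance-ratio F
test by default (Levene's test as the robust alternative; the choice of test
is a package decision), cross-checked against a permutation oracle in the
tests. Kaplan-Meier estimation and the log-rank test delegate to lifelines
and are verified against hand-computed product-limit values, a brute-force
O-E computation and a permutation reference. Cox regression is deliberately
not implemented.

## What the simulation shows — and what it cannot

Running the full pipeline on the simulated lifespan-error experiment
(2 x 8 plates x 15 worms NV, 8 plates V_d5-t3, weekday acquisition over a
21-day horizon, 256x256 rendering, 10 seeds — the problem size used by the
tests and the acceptance script) reproduces the *structure* of the
stimulation benefit: the stimulated cohort's total curve error and
plate-error spread drop to roughly half the non-stimulated values or below,
the mean signed plate error stays near zero, and the NV-vs-V variance test
rejects equality in essentially every replicate.

The absolute error magnitudes are smaller than on a real rig. Synthetic
frames have controlled lighting, no condensation, no reflections and no
focus drift, so the only error sources are the behavioural ones the model
encodes (spontaneous stillness and hidden worms). Real-machine errors also
include imaging artefacts that a human supervisor corrects; those cannot be
derived from the published behavioural parameters and are deliberately not
injected, so the simulated eT and sigma should be read as the
behaviour-driven floor of the machine's error, not as a calibrated replica
of any particular rig's numbers.

## Numerical and degenerate-input conventions

Threshold boundary: intensity <= 33 is black (the comparison direction is a
package choice). Identical samples give p = 1 in both the variance and
log-rank wrappers; two zero-variance error lists are "equal" by convention.
Blank frames align with zero shift and a warning. A plate with no worms
yields empty detection lists and all-zero curves; `response_index` is NaN
(flagged, excluded from aggregates) when no live worms remain. Occluded
worms are excluded from response denominators — they cannot be assessed.
Determinism: every stochastic stage draws from `numpy` generators seeded
from the experiment seed, so identical configuration and seed give
bit-identical images, ground truth and statistics.

## Known limitations

* Overlapping worms form one blob; the simulator's separation constraint
  sidesteps this, real plates do not.
* Habituation is a single multiplicative decrement with full reset on
  duration change — a deliberate minimal model of the observed recovery.
* The mapping from movement amount (px^2) to response probability is not
  modelled; they are independent knobs.
* The swept-area speed conversion `(A/w) * scale / T` gives 0.167 and
  0.40 mm/s for 500 and 1200 px^2 at 30 um/pxl and 3 px width; published
  equivalents of 0.14/0.34 mm/s for the same inputs imply an unstated
  effective scale or formula. The transparent formula is implemented and the
  discrepancy documented rather than silently matched.
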