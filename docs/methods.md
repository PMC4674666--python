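# Methods

`clutchkit` re-implements, on synthetic data, the measurement and analysis
pipeline of a brood-parasitism field experiment on European blackbirds
(*Turdus merula*): does disrupting the spatial arrangement of a clutch
change how hosts respond to a foreign egg?  Three treatment groups are
compared — *control* (no egg added, clutch untouched), *constant* (a
non-mimetic model egg added at the cup edge without deliberate
rearrangement) and *rearranged* (eggs shuffled by hand, then the model egg
added) — and the host's response (ejection/acceptance/desertion) and
latency to ejection are analysed.  The original photographs and nest
records were never deposited, so the package generates data with the same
structure and validates the pipeline by parameter recovery instead of
reproducing field coefficients.

## Arrangement metrics (geometry)

Each egg is annotated by its blunt-pole and sharp-pole image coordinates;
the nest-cup center is annotated per photograph.  Four metric families:

* blunt pole distance `d_i = ||b_i - c||` (px),
* blunt pole angle: polar angle of `b_i - c`, directional, period 360°,
* blunt pole orientation: angle of the long axis (line through both
  poles), axial, period 180°,
* adjacent angles: with eggs ordered clockwise around the cup, the axial
  angle from egg *N*'s long axis to egg *N+1*'s, cyclic (N angles for N
  eggs).

Conventions the source protocol leaves open, fixed here and used
consistently:

* **Coordinates.** Annotations are image coordinates (origin top-left, y
  down); angle computations flip to mathematical y-up, so "positive x
  axis" and "counter-clockwise" read conventionally.  Clockwise on screen
  therefore means descending mathematical polar angle.  Ties in the
  clockwise ordering are broken by blunt-pole distance, then egg id.
* **Vector direction.** The blunt-pole angle uses the vector *from* the
  center *to* the blunt pole.
* **Axial vs directional.** A long axis is undirected, so orientation and
  adjacent angles live on a 180° circle; the blunt-pole angle is a true
  direction on a 360° circle.

### Before/after change scores

Per nest, each metric's change is summarised by a two-point SD over the
{before, after} pair of each host egg, then averaged over host eggs:

* linear (distance): sample SD of two values, `|Δ|/√2`;
* directional angles: Mardia's circular SD `√(−2 ln R)` in degrees, where
  for two angles `R = |cos(Δ/2)|`;
* axial angles: angles doubled, circular SD computed, result halved.

Exactly antipodal angle pairs (`R = 0`) are capped at `R = 1e-12`
(≈ 420° axial SD) so scores stay finite; with continuous noise this case
has probability zero.  The per-egg-then-average choice (rather than
pooling all eggs into one SD) is a documented decision, not a claim about
the original macro.  Adjacent-angle pairs are matched by fixing the
*before* clockwise sequence and reusing that cyclic sequence (through the
egg matching) for the after phase, so each pair compares the same two
eggs.  Host eggs are matched by egg id when ids are shared, otherwise by
nearest-centroid assignment (Hungarian algorithm); the added model egg has
no "before" state and is excluded from all paired metrics (it *is*
rendered in masks).

## Mask dissimilarity

Binary clutch silhouettes (before vs after) are compared in three steps:

1. **Registration** — translation so foreground centroids coincide,
   isotropic rescale so foreground areas match (nearest-neighbour
   resampling).  Rotation is deliberately not searched: overhead cup
   photographs share an orientation and rotating one mask onto the other
   would cancel genuine arrangement change.  This restriction must be
   revisited if the pipeline is ever applied to unconstrained photographs.
2. **Tolerance matching** — a pixel of either mask is matched when the
   other mask's Euclidean distance transform there is ≤ `tolerance_px`.
3. **Score** — unmatched pixels of both masks divided by the union of the
   registered foregrounds, giving a proportion in [0, 1] that is
   independent of frame size, 0 for identical silhouettes, monotone
   non-increasing in the tolerance.

For the score the two masks are registered into a *shared* canvas (both
centroids to the canvas center, both areas to the geometric mean of the
two), which makes the value exactly symmetric in its arguments.  The
default `tolerance_px = 2` at the default synthetic resolution of 2 px/mm
(0.5 mm/px) absorbs resampling and annotation error; it is a parameter
because the original script chain does not state one.  Grayscale input
masks are binarized by Otsu's threshold unless a threshold is given.

## Synthetic data generator

The generator emulates the study conditions; its defaults are the
experiment's:

| parameter | default | basis |
|---|---|---|
| group sizes | 19 / 30 / 30 | field design |
| clutch size | 4 or 5, equiprobable | typical for the population |
| host egg | 29 × 21 mm | typical blackbird egg (not printed in the study) |
| model egg | 22.40 × 16.89 mm | printed model-egg dimensions |
| cup radius | 50 mm | typical blackbird cup |
| photographic jitter | 1.0 mm, 3° (SD) | free; see below |
| handling noise | 0.8 mm, 4° (SD) | free; see below |
| shuffle intensity | 1.0 (full redraw) | models the figure-eight shuffle |
| resolution | 2 px/mm | convenient raster scale |

Eggs are placed without overlap (checked on exact ellipse polygons) inside
the circular cup, long axes roughly radial with blunt poles outward —
the arrangement reported for incubating thrushes.  *Control* applies
photographic jitter only, so with zero jitter control is an exact
identity.  *Constant* applies jitter plus handling noise and inserts the
model egg at the cup perimeter (tangential orientation), pushing aside any
host egg in its way; the insertion contact is what makes the constant
group measurably — but mildly — different from control, matching the
study's observation that simply adding the egg changed the arrangement to
some extent.  *Rearranged* redraws host positions and orientations (scaled
by the shuffle intensity) before adding the model egg.  The jitter and
handling magnitudes are free parameters (no quantitative value is printed
anywhere); they were fixed once at values giving realistic sub-egg-width
displacements and are reported with all results.

Behavioural outcomes follow the analysis model: desertion is
treatment-independent with probability 0.127 (the pooled observed rate
10/79); non-deserted parasitized nests eject with
`logit p = 1.34 + 0.74·[rearranged]` (the observed 79.2% / 88.9% rates);
ejectors draw latency from an NB2 model with
`log μ = 0.37 + 0.74·[rearranged] − 1.12·[clutch of 5]` and dispersion
0.5 — the coefficient values of the published latency model; the
dispersion is free.  Latencies are resampled (not censored) into the 0–6
day monitoring window; same-day ejection is 0.  Covariates (nest age
~ N(4.65, 3.7²) days, truncated at 0; laying date ~ U(0, 60)) carry no
behavioural effect, matching the final published models.

What the generator does **not** emulate: egg appearance (only silhouettes),
camera perspective and lens distortion, nest material occluding egg
outlines, rotation/framing differences between photographs, multi-day
arrangement drift, and any dependence of behaviour on arrangement change
(behaviour and geometry are simulated independently, as the study's null
result suggests).  Passing tests therefore demonstrate that the pipeline
measures and analyses correctly, not that it would segment real
photographs.

## Statistical stage

* **Rates.** Desertion uses whole groups as denominators; ejection uses
  non-deserted parasitized nests with a scored eject/accept response.
* **Fisher exact test** (desertion, control vs parasitized pooled):
  enumeration p sums conditional hypergeometric probabilities ≤ the
  observed table's; the Monte-Carlo p uses 100,000 conditional draws with
  the add-one estimator `(1 + #{p(sim) ≤ p(obs)})/(reps + 1)`.  The odds
  ratio is the conditional MLE (solving `E_ψ[X] = x` in Fisher's
  noncentral hypergeometric model) with an exact central CI — the
  convention of R's `fisher.test`.
* **Response model**: binomial GLM, logit link, on non-deserted
  parasitized nests (controls cannot eject an absent egg, so treatment is
  the 1-df constant-vs-rearranged contrast).  **Latency model**: ejectors
  only, NB2 GLM with log link and ML dispersion.  The source description
  says "mixed models" for latency but lists no random term and has one
  row per nest, so a fixed-effects NB GLM is the identifiable equivalent
  and is what this package fits.
* **Per-term inference**: likelihood-ratio χ² from single-term deletion.
  CIs are Wald intervals with a Bonferroni family-wise adjustment over the
  reported terms ("approximate family-wise" intervals without a named
  method; Bonferroni is the conservative default).  Pseudo-R² is
  Nagelkerke's.  VIF is the `1/(1−R²)` closed form per predictor.
* **Backward elimination** drops the unprotected term with the largest
  p > α (default 0.05), refits, and stops when all remaining unprotected
  terms are significant; the treatment term is never dropped.  Both full
  and final models are reported.

Degenerate inputs are handled explicitly: perfect separation flags the
response model and reports lightly L2-penalized estimates with inference
suppressed; NB dispersion collapsing to zero (or a failed NB fit) falls
back to a Poisson GLM with a note; terms constant or exactly collinear in
an analysis subset are dropped with a note (and count as least significant
during elimination).

## Validation strategy and problem sizes

The published coefficient table cannot be reproduced without the field
data, so the models are validated by simulation: 95% Wald coverage of the
binomial treatment effect (β = 2) and the NB clutch-size effect (−1.12)
over 1,000 replicates of n = 400; LR type-I error of the treatment term
under β = 0 (±2% bands); elimination behaviour over 600 replicates
(treatment always retained; null covariates dropped ≈ 95% of the time —
backward selection inflates retention slightly above α, hence a 0.92–0.99
band).  The treatment-ordering check (control < constant < rearranged in
group means of the dissimilarity and all four SD metrics) uses 200
simulated nests per group.  These sizes give Monte-Carlo standard errors
well inside the asserted bands while keeping a full test run to a few
minutes.

## Known limitations

* The two-point circular SD saturates for near-antipodal angle changes;
  rank orderings among highly disrupted clutches are still meaningful, the
  absolute SD values less so.
* Registration is translation + area scaling only (above) and clips
  content that would cross the frame origin when areas differ by much
  more than one egg — irrelevant for before/after pairs of the same nest.
* The conditional-MLE odds ratio differs from the sample odds ratio by
  construction; for the study's desertion table it is ≈ 0.77.
* Model-egg insertion resolves collisions by iterative pushing; with
  pathological configurations small residual contacts between eggs can
  remain (real eggs touch, so masks and metrics remain valid).
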