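# Methods

`odfkit` models the in vitro characterisation of orodispersible films
(ODFs) — postage-stamp-sized polymer films that must disintegrate in the
mouth within the 180 s Pharmacopoeial limit. Four single-polymer films are
packaged: C1 and C2 (sodium carboxymethylcellulose, 395 and 725 kDa, 1 %
w/v) and P1 and P2 (polyvinyl alcohol, 39 and 197 kDa, 5 % w/v), all
nominally 30 × 20 mm. Three bench methods are represented: a shaken Petri
dish with a stopwatch endpoint, an oral cavity model (OCM — a silicone
tongue and acrylic palate performing 2 s compression cycles under simulated
salivary fluid, filmed top-down at 30 fps), and a reciprocating soft
bio-tribometer (BTM — acrylic palate on silicone tongue, 1 Hz, 7.5 mm
stroke, 1 N load, force channels logged at 100 Hz).

Because no raw videos or force traces from the physical study are public,
every analysis stage is driven by a scripted synthetic generator whose
ground truth is known exactly, and validated by parameter recovery.

## Disintegration endpoint definition

Disintegration is operationalised as the moment a film splits from one
single structure into two distinct objects. In the video pipeline this
becomes: the earliest frame at which the segmented film has ≥ 2 retained
fragments for at least `persistence_frames` consecutive samples (default 5,
≈ 0.17 s at 30 fps). The persistence requirement exists because PVA films
tear transiently and re-coalesce — those tears must not register. If no
persistent split occurs before the 180 s cap the endpoint is right-censored
and rendered `>180.0`, never averaged.

## Synthetic scenario generator

Each `FilmScenario` couples a film, a method, a duration, an ordered event
schedule, and (for BTM) a friction signature. The packaged parameter table
(`src/odfkit/data/scenarios.json` — deliberately data, not code) scripts:

* **Endpoints** equal to the packaged per-cell mean disintegration times,
  with censored markers for cells that never disintegrate within 180 s.
* **Event archetypes** interpolated from the observed behaviours: P1-OCM
  detaches a ~18 % fragment at 24 s which drifts off the tongue while the
  remnant shrinks; P2-OCM opens transient corner tears at 70/80/95 s and a
  long vertical tear over 105–160 s, each later coalescing with full area
  recovery; C1/C2-OCM only swell (the palate-adhesion behaviour, visible in
  plan view as slow dilation); Petri and BTM cells tear persistently at the
  scripted endpoint.
* **Friction signatures**: CMC films hold an initial coefficient of
  friction and decline rapidly (over `decline_s` = 2 s) onto a lower
  plateau at the scripted endpoint; PVA films fluctuate
  (decrease–increase–decrease) about their initial value before dropping to
  the plateau. Plateau levels order the films by molecular weight
  (C2 < C1 < P2 < P1), matching the observed lubricity ranking. Gaussian
  noise sd 0.02 on μ is the default.

A transient tear reads as two objects for only `split_s` = 0.1 s before a
thin bridge re-forms in plan view; this is how "fragments that later
coalesce" can dip the measured area without constituting disintegration
under the persistence rule.

Rendering uses a fixed camera convention: 640 × 480 px, 0.1 mm/px (film =
300 × 200 px), pink film (Sulforhodamine-B-like, RGB 214/46/122) on a pale
silicone background, per-pixel Gaussian sensor noise sd 4 (8-bit units).
Method artifacts are injected deliberately so the profiler has something to
be robust against: a 15 % white haze during the first 0.15 s of every 2 s
OCM compression, and a moving specular band (the reciprocating acrylic) for
BTM. Frames are lazy and depend only on (scenario, seed, frame index), so
renders are bit-reproducible and a 180 s video never sits in memory.

What the generator does **not** emulate: fluid dynamics of the salivary
film, gradual translucency of a dissolving film, lighting drift, camera
shake, perspective, or out-of-plane motion (the observed palate adhesion is
represented only by its plan-view swelling). Passing tests therefore show
the pipeline recovers known geometry under controlled noise — not that it
would segment arbitrary laboratory footage.

## Video profiling

Segmentation is chromaticity-based: pixels with saturation ≥ 0.20, value ≥
0.15 and hue in the magenta window [0.80, 1) ∪ [0, 0.05] are film. If the
fixed thresholds find nothing, an automatic Otsu threshold on saturation is
tried, guarded by bimodality checks so a film-free frame still reads empty.
A gradient (Sobel + Otsu) edge mode is config-switchable. Masks get a 3 × 3
morphological opening and hole filling, restricted to the film's bounding
box for speed.

Fragments are 8-connected components of at least 0.5 % of the initial film
area (`min_fragment_frac`); smaller specks are segmentation noise.
Perimeter is the outer contour traced through boundary-pixel centres of
retained components (holes excluded): a filled 10 × 10 px square measures
36.0. Area fractions are normalised to frame 0 (exactly 1.0 there). A
temporal median filter (window 7 frames) suppresses single-frame
compression artifacts; alternatively `ocm_phase_sampling` analyses one
decompressed-phase frame per 2 s compression cycle.

## Friction analysis

Sample-level μ is the Euclidean resultant of the two in-plane friction
channels over the normal force (the two transducers are treated as
orthogonal axes). Samples with normal force below 0.1 N are dropped, as are
samples outside the central 60 % of each traversal, where sliding speed
vanishes at the turnarounds and instantaneous μ is ill-defined. One stroke
= one full reciprocation cycle (1 s at 1 Hz); strokes with fewer than 5
valid samples are flagged invalid (NaN), never silently dropped.

The endpoint detector fits piecewise-constant models with 0, 1 and 2
change-points to the per-stroke μ series by exact least squares (exhaustive
over placements, prefix-sum costs) and selects by BIC,
`n·ln(SSE/n) + (2k+1)·ln(n)` with an SSE floor of 1e-12 so noiseless ties
resolve toward parsimony. The reported time is the start of the terminal
segment — the plateau onset — which covers both the decline-plateau and
fluctuate-plateau shapes without modelling the pre-transition morphology.
A winning 0-change-point model means no disintegration signature: censored.

Group comparisons use one-way ANOVA with Tukey HSD on replicate-level
summaries (per-replicate mean CoF, per-replicate endpoints), with censored
endpoints excluded. Zero within-group variance (possible with deterministic
synthetic replicates) is special-cased: F = ∞/p = 0 when means differ,
pairwise p ∈ {0, 1} by mean equality.

## Rheology

The generator emits exactly 30 shear rates, logarithmically ascending over
[0.01, 100] 1/s, with multiplicative log-normal noise. Power-law fits
(η = K·γ̇ⁿ⁻¹) are ordinary least squares in log-log space; Cross fits
(η = η∞ + (η0 − η∞)/(1 + (λγ̇)ᵐ)) minimise log-viscosity residuals —
matching the multiplicative error model; a linear-space objective leaves η∞
poorly identified — with initialisation from the data extremes (η0 from the
lowest-shear point, η∞ from the highest, λ from the mid-decay shear rate,
m = 1). Near-Newtonian data (plateau separation within the 0.02
shear-thinning tolerance) are flagged degenerate rather than force-fitted;
genuine non-convergence raises with the residual. `viscosity_at`
interpolates log-log between bracketing points and refuses to extrapolate.
The packaged per-film flow-curve parameters are plausible stand-ins chosen
to reproduce the qualitative record (CMC thins throughout, C2 ≫ others at
low shear, PVA plateaus, P1/P2/C1 similar near 50 1/s); no numerical flow
data are published, so they are never treated as ground truth.

## Orchestration and determinism

`run_toolbox` expands a single seed to per-replicate seeds (`seed + r`),
runs every film × method × replicate cell (Petri → simulated stopwatch
observation; OCM → video profiling; BTM → friction change-point, plus mean
CoF), and aggregates into a cross-method table with censoring notation. A
cell failure is recorded on the cell and the run continues. Summary JSON is
byte-identical between reruns of the same config; provenance carries the
seed list and a SHA-256 config hash.

## Problem sizes

Defaults match the bench protocol (30 fps, 640 × 480, 100 Hz, full
durations). The test suite renders most video at quarter resolution
(160 × 120, 0.25 mm/px) and 6–10 fps, which preserves every scale-free
property; full-resolution 30 fps recovery is exercised on the P1-OCM
(30 s window × 3 seeds) and C2-OCM (full 180 s, decompressed-phase
sampling) scenarios. `scripts/acceptance.py` recomputes the headline
quantities at full resolution and frame rate, including the complete
5400-frame C2-OCM censoring run.

## Known limitations

* Scenario event geometry is parameterised in pixels at the default camera
  scale; rendering at other scales changes fragment kinematics slightly.
* The friction endpoint is the terminal plateau onset; if a film's CoF
  plateaus for reasons other than disintegration the detector cannot tell
  the difference — on real traces it should be corroborated by the video.
* The Petri observation model (zero-mean truncated-normal latency with the
  packaged per-film spread) reproduces replicate scatter, not operator
  bias.
* Segmentation thresholds are tuned to the synthetic colour convention;
  real footage will need config adjustment (or the edge mode).
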