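# Methods

## Model

The analysis treats controlled sonication of an amyloid fibril sample as a
pure fragmentation process. A fibril of length *x* (nm) divides with hazard

    B(x) = (α·x)^γ   [s⁻¹]

into two fragments *p·x* and *(1−p)·x*; nucleation, elongation and
depolymerisation are assumed negligible on the perturbation time scale.
Consequences used throughout: total fibril mass (summed length) is
conserved; particle number is non-decreasing; and the cross-sectional
structure of a fibril — its AFM height, which labels the polymorph — is
unchanged by division, so height distributions are stationary in time
while length distributions decay. γ sets how steeply breakage rates fall
as fibrils shorten (higher γ ⇒ short fragments are disproportionately
stable); α (nm⁻¹) sets the overall magnitude, with α·x dimensionless
inside the power.

At long times the length distribution becomes self-similar and the mean
length obeys μ(t) = C·t^(−1/γ), preceded by a plateau while the initial
distribution relaxes; the piecewise law is continuous at the plateau time
t_s. Under self-similarity the identity dN/dt = α^γ·N·∫x^γ f(t,x) dx
combined with N ∝ t^(1/γ) gives

    α_t = (γ · t · ∫ x^γ f(t,x) dx)^(−1/γ),

which is time-independent in the self-similar regime. This is the moment
estimator implemented here: α is the arithmetic mean of α_t over the
post-plateau time points. The published form of this estimator is typeset
ambiguously; the reading above is the unique one consistent with the
dynamics, and the simulator-recovery tests confirm it returns the true α.

### Breakage kernel

The observable decay law constrains only B(x), not where along the fibril
the break occurs. The kernel is therefore a modelling choice: uniform
p ~ U(0,1) by default, with a symmetric Beta(a, a) option for sensitivity
checks. Both are symmetric about ½, so binary breakage conserves length by
construction. Inference results in this package do not depend on the
kernel shape beyond second-order effects on the distribution tails.

## Solvers

**Stochastic.** Because fragments evolve independently, the exact
continuous-time Markov process factorises over lineages. The simulator
draws each segment's exponential waiting time directly (generation by
generation, vectorised) and reconstructs snapshots from segment lifetimes,
so it is exact — no time-step tolerance — and the observation grid cannot
perturb the event sequence. Fragments are clamped to a floor of 10⁻³ nm to
avoid floating-point zero lengths; a configurable cap on total segments
(default 5·10⁶) aborts runaway regimes with a clear diagnostic.

**Deterministic.** The binary-breakage population balance equation is
discretised with the fixed-pivot technique (each fragment apportioned
linearly between neighbouring grid pivots so that particle number and mass
are both conserved exactly per event) on a log-spaced length grid of ≥200
nodes, and integrated with LSODA (rtol 1e-8). The smallest pivot is
treated as unbreakable to close the mass budget on the finite grid; runs
whose mass drifts more than 0.5% (e.g. because the solution piles up at
the grid floor) raise an error advising a wider grid. The two solvers
agree within Monte-Carlo error (3 ensemble SEs over 20 seeds) on N(t) and
μ(t), and both reproduce the self-similar slope −1/γ to well under 1%.

## Synthetic AFM imaging

The generator emulates what the measurement stage must be robust to, with
the imaging geometry of the source experiments: 2048×2048 px frames over
10×10 µm (≈4.9 nm pixels) by default.

- **Deposition**: each fibril becomes a discrete worm-like chain (heading
  variance step/ℓp per step, ℓp = 2000 nm default — order of the
  persistence length of amyloid fibrils on mica), placed uniformly.
  Setting `deposition_margin` ≥ half the longest fibril draws centres from
  a field extending beyond the frame, so long fibrils cross the frame edge
  with exactly the probability the bias correction later undoes. A
  `clustering_strength` knob concentrates placements near earlier fibrils
  to emulate sticky polymorphs; it has no quantitative anchor and defaults
  to 0. A `min_separation` option rejects overlapping placements to build
  deliberately isolated validation scenes.
- **Topography**: ridges with Gaussian cross-section (σ = 6 nm,
  emulating tip dilation; peak = fibril height), combined across overlaps
  by per-pixel maximum because AFM records the top surface, not cumulative
  material. Scanner background is per-line offsets and tilts plus a
  frame-wide quadratic bow (defaults 2, 1 and 5 nm), the minimal model
  that makes flattening non-trivial; pixel noise is i.i.d. Gaussian
  (0.15 nm). Tip-shape deconvolution, helical-twist modulation and drift
  artifacts are out of scope.

What the generator does **not** emulate — real tip geometry and its
length-dependent dilation, surface-chemistry-dependent deposition,
operator-dependent tracing — means a passing round trip validates the
measurement code against the stated image model, not against microscope
physics.

## Quantification

- **Flattening**: two-pass per-line polynomial subtraction (order 2 by
  default); pass 2 masks pixels >3 robust SD above the pass-1 residual so
  fibrils do not bias the baseline. Idempotent to <10⁻³ nm; exact on
  polynomial backgrounds.
- **Tracing**: threshold at max(1 nm, 5× robust noise SD), connected
  components (8-connectivity), skeletonisation, 1-px spur pruning,
  end-to-end ordering. Components touching the border or retaining branch
  points are flagged and excluded: the method measures individual
  particles, and disentangling crossings is deliberately out of scope.
- **Contour length**: the raw chain-code length (1/√2-weighted pixel
  steps) is retained as `chain_length`, but the reported `contour_length`
  is the Euclidean length of the spine after a 5-point moving-average
  smoothing with pinned endpoints. The chain-code rule alone overestimates
  smooth curves by up to ~8% at intermediate angles (the classic
  staircase bias); smoothing removes this while leaving axis-aligned and
  45° chains exactly unchanged. Semicircular-arc oracles confirm ≤5%
  error, orientation-averaged scenes ≤2%.
- **Height**: the measured cross-section is near-Gaussian, so its log is
  quadratic in the perpendicular offset. At every other interior spine
  pixel, three exact grid samples along the rounded normal are fit with a
  log-parabola whose vertex recovers the ridge peak regardless of the
  skeleton's sub-pixel offset from the crest; the fibril height is the
  mean of these per-point peaks (falling back to the profile mean/max for
  very short spines). This removes the ~0.2 nm crest-sampling bias a
  plain profile mean incurs at ~5 nm pixels with σ = 6 nm ridges.
- **Bias correction**: a fibril is only measured if fully inside the
  frame. For a rigid rod of length x uniformly placed and oriented in a
  square of side S the fully-inside probability is
  P = 1 − (4/π)(x/S) + (1/π)(x/S)², the orientation average of
  ((S−x|cosθ|)(S−x|sinθ|))/S²; measured counts are weighted by 1/P. The
  form is validated against a Monte-Carlo placement oracle in the tests.
  Contour length stands in for the planar span, an upper bound for curved
  fibrils (≈1% overcorrection at ℓp = 2000 nm, x ≤ 1500 nm). Fibrils
  with x ≥ 0.9·S are rejected — they are excluded upstream as
  edge-touching anyway.
- **Distributions**: 25 nm histogram bins (≈5 px), fixed across time
  points so panels share scales. Weighted density integrates to 1; μ(t)
  is the weighted mean; heights are summarised per particle, unweighted.
  Fewer than 10 particles at a time point attaches a warning and excludes
  the point from decay fitting.

## Fitting choices

- **t_s selection**: grid search over candidate plateau times (0 = no
  plateau, or any observed time leaving ≥3 later points). Candidates are
  scored by the residual SD per degree of freedom of the **full piecewise
  model** (plateau branch included) over all points — scoring only the
  post-plateau line cannot distinguish a true plateau from a shortened
  fit, since the point at t_s lies on both branches. The winner must have
  a negative slope; ties go to the smaller t_s. Noiseless piecewise data
  are recovered exactly.
- **Jackknife unit = time point**: the sampled sonication durations are
  the natural exchangeable unit of the decay series; each leave-one-out
  refits γ (with t_s reselected) and then α. log α is jackknifed rather
  than α, matching how the uncertainty is reported.
- **α averaging**: arithmetic mean of the per-time α_t (the alternative,
  log-space averaging, differs by <2% in all regimes exercised here).
- All reported logarithms are base 10.

## Scales used in validation

The validation suites run at reduced but faithful scales chosen so each
check is sharp: imaging round trips use 1024² px frames at 5×5 µm —
preserving the experimental 4.9 nm pixel — with ~370 isolated fibrils
pooled over 8 frames; the height-stationarity course uses 512² px frames,
4 per time point, ~200 measured particles per time; parameter recovery
uses 2000-fibril populations over the 5–640 s schedule with 10 seeds.
Recovery at these scales: γ within ~2%, α within ~2% (median), imaging
mean-length error ~1–2%, mean-height error ≤0.05 nm, height-mean range
≤0.1 nm across the time course.

## Known limitations

- The moment estimator assumes the self-similar regime; series still
  relaxing from their initial distribution give time-trending α_t (their
  spread is visible in the per-time values the fit reports).
- Heavily clustered scenes lose most particles to the branch-point
  exclusion; the pipeline reports counts so starved time points are
  visible, but it does not disentangle clusters.
- The bias correction is first-order geometric: it ignores curvature
  (small here) and any chemistry-driven, length-dependent deposition
  efficiency, which real samples may have.
- With four or fewer usable time points the jackknife cannot run (each
  leave-one-out subset must still support a 3-point line plus plateau
  search); the full 5–640 s schedule is recommended.
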