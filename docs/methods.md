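# Methods

This note documents the models, defaults and numerical choices behind
`replispan`, and what the synthetic-data generator does and does not
emulate.

## Mortality model and lifespan sampling

Lifespans are counted in whole divisions: a cell with lifespan `g*`
completes `g*` divisions and dies during the following, incomplete
generation. The survivor function is matched **exactly at integer
generations**: a uniform draw `u` is inverted through the continuous
survivor law and rounded up,

    exponential:  g* = max(1, ceil(−ln u / α))
    Gompertz:     g* = max(1, ceil(ln(1 + (β/α)(−ln u)) / β))

which is equivalent to inverse-CDF sampling of the discrete death mass
`S(g−1) − S(g)`. In particular the exponential case is geometric with
per-generation death probability `p = 1 − e^(−α)` rather than the
small-`α` approximation `p ≈ α`; this keeps `P(g* > g) = S(g)` exact at
every integer `g`. The floor at one generation reflects that observed
cells complete at least one division before their death can be scored.
All closed forms use `expm1`/`log1p` so the Gompertz expressions
degenerate smoothly to the exponential ones down to `β = 1e-9`.

Defaults (wild-type configuration): exponential with `α = 0.02` — a
constant ~2% chance of death per cell per generation, the non-aging
regime characteristic of fission yeast.

## Growth law

Within a generation, length grows piecewise linearly with a single rate
change at NETO (new end take-off), the switch from monopolar to bipolar
tip growth at `neto_fraction = 0.3` of the cycle. `monopolar_rate_share`
is the fraction of the generation's total extension accrued before NETO;
its default 0.20 makes the pre-NETO rate ≈ 0.58× the post-NETO rate
(slow-then-fast), qualitatively matching monopolar growth at roughly half
the bipolar rate. A share equal to `neto_fraction` would mean no rate
change at all, and a larger share would invert it, so the share must sit
below 0.3 for NETO to be detectable as a slope increase.

Per-generation draws (truncated normals, redrawn implicitly through the
truncated distribution so values stay physical):

| parameter | default | units |
|---|---|---|
| birth length | 8.3 ± 1.5 | µm |
| division length | 16 ± 2.2 | µm |
| doubling time | 2.05 ± 0.45 | h |
| division asymmetry (septum position fraction) | 0.5 ± 0.02, truncated to (0.4, 0.6) | — |
| sampling interval | 2 | min |

At division, the retained old-pole cell restarts at the septum-position
fraction times the division length (medial fission; the spread of the
asymmetry is a modelling choice — it is not well quantified for real
cells). Dying cells implement one of two terminal phenotypes with
probabilities 0.72 / 0.28: **short** cells die partway through the cycle
(uniform fraction 0.3–0.8 of a drawn doubling time) below the division
length; **elongated** cells complete the cycle without dividing and keep
extending at the bipolar rate for 3.2–4.5 mean doubling times in total,
the signature of a division-checkpoint failure.

Last-sibling fates (never divided / divided once / divided multiple
times) default to 0.66/0.14/0.20 and are drawn independently of
replicative age — the generator implements the age-independence null.
Nucleolar (rDNA) segregation defect classes for ordinary divisions default
to 7.4% total defects, split so that multi-focal events are the rare
class; terminal divisions carry ~40% defects. The per-class allocations
between `multi`, `unequal` and `bridge` are approximate (chosen to be
consistent with the aggregate defect rates and with bridges/asymmetric
events being the 78-event majority class); only the aggregate rates are
treated as calibrated quantities.

## Image rendering

Frames are 64×384 px at 0.2 µm/px. The cell is a dark rod (intensity 80
on a 200 background) anchored at the notch on the channel centerline;
static device geometry — channel walls, the notch ridge, and PDMS post
marks away from the channel — gives drift registration stationary
structure in both axes. A darker band (intensity 25) marks the nascent
septum in the two frames straddling each division, clipped to the cell
extent. The scene is blurred with a Gaussian PSF (σ = 1 px, emulating the
slightly defocused contrast used to visualise septa), then per frame an
integer stage jitter (uniform in ±`max_jitter`, recorded as ground truth)
is applied with wrap-around, then the fixed field rotation, then additive
Gaussian noise. Frame geometry is validated so the longest cell fits
inside the frame.

What the generator does **not** emulate: fluorescence photophysics,
uneven illumination, focus drift, neighbouring cells in the central
trench, sub-pixel stage motion, and cell-shape irregularity (bending,
width changes). Passing round-trip tests therefore demonstrate
correctness of the geometry/registration/tracing logic, not robustness to
every artifact of real microscopy.

## Quantification

* **Rotation correction**: `skimage` rotation by the negative measured
  angle, bilinear interpolation, shape preserved.
* **Registration**: integer per-frame shift against frame 0 by FFT
  cross-correlation (`phase_cross_correlation`, plain normalization).
  Sub-pixel registration is deliberately not attempted — the synthetic
  jitter is integer-valued and plain cross-correlation is the standard
  approach.
* **Kymograph**: the centerline pixel row from the notch toward the
  trench, stacked time-down-rows. Pixel coordinates are 0-based
  (row, column) with row 0 at the top.
* **Annotation / tracing**: programmatic annotation finds, per kymograph
  row, the far edge of the dark run containing the pole (median filter
  width 3, threshold at the intensity midpoint); lengths are
  `(septum − pole) × pixel_size`. Sparse (per-division) annotations are
  linearly interpolated to the grid when supplied instead.
* **Division calling**: the length trace is a rising sawtooth, so
  divisions are called where the moving-median-smoothed trace (window 5 =
  10 min) drops below 0.72× its running maximum since the previous
  division, taking the local minimum of the drop. Minima closer than
  `min_generation_time = 0.5 h` merge, keeping the deepest. The default
  is half of the conventional "half a mean doubling time" guard because
  the drop-based detector only needs the merge window to span a single
  division reset (minutes); a 1.0 h window would silently censor the ~1%
  of genuine cycles shorter than an hour at the configured doubling-time
  spread. Replicative age = number of accepted minima.
* **Ejection screening**: any between-frame length change above 35% of
  the current length is suspect unless it is division-consistent — a drop
  to 42–58% of the pre-drop length (±4 σ of the division-asymmetry
  spread) within one frame of an accepted minimum. Flagged cells are
  excluded downstream and logged with a reason code.
* **NETO detection**: continuous two-segment piecewise-linear least
  squares on a normalized single generation; the breakpoint is grid-
  searched (step ~0.005) and refined by bounded scalar minimization.
  Slopes differing by < 5% of their mean are reported as unidentifiable
  (a pure line has no NETO point).

## Survival statistics

Kaplan–Meier estimation uses `lifelines`; with complete data (the
default — lost/ejected cells are excluded rather than censored, and a
censoring-aware mode exists behind a flag) the estimate equals the
empirical survivor fraction, which the tests exploit as an independent
oracle and the bootstrap uses as a fast equivalent path.

Weighted fits use `scipy.optimize.curve_fit` with `sigma = sqrt(S)`
(equivalent to weights `1/S`), points with `S = 0` excluded, `α` bounded
in (1e-10, 10) and `β` in (1e-9, 5); a fitted `β ≤ 1e-8` is reported as
exactly 0. Initial `α` comes from a log-linear regression of the curve.
Adjusted r² is `1 − (1 − r²_w)(n − 1)/(n − p − 1)` with `r²_w` computed
on weighted residuals about the weighted mean. Model selection takes the
higher adjusted r², with ties within 1e-4 resolved to the exponential
model. Confidence intervals are percentile bootstrap over cells
(default 1000 resamples; resamples whose fit fails are dropped). Hazard
fold-changes between strains are ratios of fitted `α` with
ratio-of-paired-resamples CIs. An Anderson–Darling normality screen is
reported alongside distribution comparisons but gates nothing.

A selection subtlety worth knowing: with `1/S` weighting the deep tail
(last few survivors) carries large weight, and the nested Gompertz model
can buy small but non-negligible adjusted-r² gains by tilting into tail
noise. On constant-hazard cohorts of a few hundred cells the exponential
model therefore wins the raw selection in a clear majority — but not an
overwhelming one — of replicates; the aging verdict additionally checks
whether the Gompertz `β` bootstrap CI reaches zero, which restores a
≥90% non-aging call rate. This is why `classify_aging` is the recommended
entry point rather than `select_model` alone.

## Aging analyses

* RLS contours evaluate the closed-form median RLS densely over the
  (α, β) plane, with the β = 0 column taking the exponential limit.
* Death-aligned ("post-synchronized") distributions index each cell's
  completed generations backwards from death (k = 1 is the last);
  sequential bins are compared by two-sample KS with `*`/`**` at
  p < 0.05/0.01 and no multiplicity correction, mirroring common
  practice; a Holm-corrected column is reported alongside.
* Terminal phenotypes: `elongated` if the terminal generation exceeds
  three mean doubling times; otherwise `short` if the terminal length is
  below the normal division length (16.2 µm). When both criteria hold,
  `elongated` wins (hyper-elongation is the marked phenotype); a cell
  meeting neither — it reached normal division length within a normal
  cycle time but never divided — is also called `elongated` as a
  checkpoint-type death. This resolves a boundary the source analyses
  leave implicit.
* Sibling-fate tables bin old-pole age at death into quartiles by
  default, with cell-level bootstrap SDs and a global chi-square test of
  fate × age-bin independence.
* Defect tallies use event-level proportions (a cell contributing several
  divisions contributes several events); fold-enrichment is the terminal
  defect rate over the overall defect rate, reported as NaN when the
  overall rate is zero. Per-class lethality uses Clopper–Pearson CIs.

## Problem sizes and determinism

The test suite and acceptance script size their simulations for a
single-CPU desk run: 10,000-cell cohorts for curve-level checks,
200 × 440-cell replicates for parameter-recovery and verdict-rate Monte
Carlo (bootstrap 120–150 resamples inside each), a 200-cell cohort with
mean lifespan ~5 generations (α = 0.2) for the full image round trip, and
1,000 trajectories for division-detection statistics. One master seed
drives everything; per-cell streams derive from
`SeedSequence([master, cell_index])`, so cohorts are reproducible and
order-independent.

## Known limitations

* The bilinear NETO growth law is a stand-in; real within-cycle growth
  is only approximately piecewise linear, and the monopolar share is not
  a measured quantity.
* Division asymmetry is modelled as a narrow truncated normal about the
  midpoint; its real distribution is not quantified.
* The ejection screen keys on single-frame length discontinuities; slow
  partial ejections would evade it.
* Registration is integer-pixel; real stages drift sub-pixel.
* The aging verdict is calibrated for cohort sizes of a few hundred
  cells; at much larger n the β CI narrows and the verdict becomes
  sensitive to any true miscalibration of the generator, as it should.
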