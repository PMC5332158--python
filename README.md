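# replispan

Replicative-lifespan (RLS) analysis for symmetrically dividing fission
yeast (*Schizosaccharomyces pombe*), built as a tested, fully synthetic
pipeline: simulate single-cell lineages in microfluidic catch channels,
quantify their kymograph image stacks into length-and-division traces, fit
survival and hazard models, and classify populations as aging or
non-aging.

It is aimed at researchers analysing single-cell lifespan data from
mother-machine-style devices, and at anyone who wants a self-contained
testbed for survival-model inference on replicative-age data: every
downstream stage can be exercised against a generator with complete ground
truth.

## The model

A cell's replicative lifespan is the number of divisions it completes
before dying. With `S(g)` the probability of being alive after generation
`g` and `λ(g)` the per-generation hazard, the pipeline fits two nested
survivor laws:

    exponential (non-aging):  S(g) = e^(−αg)           λ(g) = α
    Gompertz (aging):         S(g) = e^((α/β)(1 − e^(βg)))   λ(g) = α·e^(βg)

`α > 0` scales the age-independent risk; `β ≥ 0` is the age-dependent
acceleration, with `β → 0` recovering the exponential law. The median RLS
has closed forms:

    RLS = ln 2 / α                      (exponential)
    RLS = ln(1 + β ln 2 / α) / β        (Gompertz)

Fits are weighted nonlinear least squares on the Kaplan–Meier estimates at
integer generations with weights `1/S(g)` (so the old-age tail is not
swamped), models are compared by adjusted r², and coefficient and RLS
uncertainty comes from cell-level bootstrap resampling. A population is
called **non-aging** when the exponential model wins the adjusted-r²
comparison or the Gompertz `β` is statistically indistinguishable from
zero.

Upstream of the statistics, the package quantifies synthetic catch-channel
image stacks exactly the way such data are processed in practice: field
rotation correction, cross-correlation drift registration, kymograph
construction along the channel centerline, length tracing, division
calling at the local minima of the smoothed length trace, and screening
for cell-ejection artifacts.

## Worked example

```python
import replispan as rs

# simulate a wild-type cohort: constant 2%/generation hazard
model = rs.MortalityModel("exponential", alpha=0.02)
table = rs.sample_lifespans(model, n_cells=10_000, seed=1)

curve = rs.km_estimate(table)                 # Kaplan-Meier, no censoring
fit = rs.select_model(curve)                  # exponential vs Gompertz
print(fit.model.kind, round(fit.model.alpha, 4), round(fit.rls, 1))
```

prints

```
exponential 0.0201 34.5
```

i.e. the model-selection step chooses the non-aging exponential law, the
fitted hazard is ~2.0% per generation (the generating value), and the
median RLS is ~34.5 generations (ln 2 / 0.02 = 34.7 up to sampling noise).

The same cohort can be pushed through the image pipeline:

```python
growth = rs.GrowthParams()                    # 8.3 -> 16 um, 2.05 h cycles
imaging = rs.ImagingParams(max_jitter=3, noise_sd=6.0)
traj = rs.simulate_trajectory(growth, lifespan=5, phenotype="short", seed=3)
stack = rs.render_kymograph_stack(traj, imaging, seed=11)
trace, divisions = rs.quantify_stack(stack, imaging.pixel_size,
                                     imaging.notch_col,
                                     imaging.channel_center_row)
print(divisions.generation_count)             # -> 5, the true lifespan
```

There is also a thin CLI over the same functions:

```
replispan simulate --config config.yaml --out run/
replispan quantify --config config.yaml --out run/
replispan fit      --config config.yaml --out run/
replispan report   --config config.yaml --out run/
```

Each stage writes plain CSV/JSON outputs plus a manifest with SHA-256
hashes; re-running with the same config and seed reproduces the tables
byte for byte.

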