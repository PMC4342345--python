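# permeascape

Segment-based inference of landscape permeability to gene flow.

In fragmented landscapes, the intervening matrix between habitat
patches filters animal movement: some land-cover classes carry gene
flow, others block it. When spatially explicit genetic clustering
delineates populations within a study cell and assigns each map pixel a
posterior probability of population membership *q*, the geometry of
those clusters holds information about which land covers did the
filtering. `permeascape` turns that information into regression
estimates:

1. **Segments.** Straight-line corridors between sample sites are
   classified **B** (between populations: the minimum-distance site
   pair of two populations lying closer than the median
   within-population site distance — clustering despite proximity
   implies a barrier) or **W** (within a population: one pair per
   population whose length best matches the joining B segment, 776 m
   fallback). Each segment is widened to rectangles of 3–1000 m and
   the proportional area of nine land-cover classes is extracted per
   width, along with the mean modal membership probability q̄.
2. **Models.** Per width, a logistic regression of segment category
   (B = 0, W = 1) and a linear regression of arcsin(√q̄) on the eight
   land-cover proportions (agriculture excluded as the reference
   matrix), each with stepwise-AIC selection inside a 1000-resample
   bootstrap; variables retained in ≥900 iterations are "selected". A
   positive coefficient means the class is associated with
   within-population habitat — it carries gene flow; a negative one
   marks a barrier.
3. **Validation.** Repeated 20% subsamples inside each bootstrap
   iteration score classification accuracy (W iff fitted probability
   > 0.5) and 95% prediction-interval coverage.

The package also provides the standard population-genetic summaries
around such an analysis (observed/unbiased expected heterozygosity,
rarefied allelic richness, permutation F_IS intervals, pairwise
Weir–Cockerham F_ST with permutation significance, simple Mantel
isolation-by-distance on F_ST/(1−F_ST)), a deterministic
assignment-surface stand-in for spatial Bayesian clustering output, and
a synthetic-landscape generator with known ground-truth effects so the
entire chain is testable end to end. See `docs/methods.md` for the full
model description and design choices.

## Worked example

Simulate 140 segments whose B/W category is driven by true liability
coefficients (forest +2.5, grassland +8.5) with moderate boundary
noise, then run the bootstrap-stepwise harness and validation:

```python
import permeascape as ps

df = ps.simulate_segment_dataset(n_segments=140, noise_sd=1.0, seed=7).assign(width=3.0)
design = ps.design_from_table(df, "logistic", width=3.0)
boot = ps.bootstrap_models(design, B=200, retain=180, seed=1)
print(boot.variable_table().round(2).to_string(index=False))
print("selected:", boot.selected)
print("fit:", {k: round(v, 2) for k, v in boot.fit_summary().items()})
rep = ps.validate(boot, design, fraction=0.2, reps=200, seed=2)
print(f"accuracy {rep.proportion_correct:.3f} [{rep.ci_lower:.3f}, {rep.ci_upper:.3f}]")
```

prints

```
          variable  retention  mean_beta  se_beta  ci_lower  ci_upper  mean_p  selected
         intercept        200      -2.18     1.43     -5.04      0.98    0.04     False
            forest        188       5.42     1.82      2.58      9.16    0.01      True
non_treed_corridor         49      -6.41    20.41    -37.46     34.92    0.09     False
              road        163     -33.99    14.66    -71.86    -16.36    0.07     False
         grassland        200      11.40     2.66      6.94     17.34    0.00      True
         shrubland         38      28.91     9.92     14.96     50.99    0.13     False
    treed_corridor         40     -10.37    24.24    -33.49     59.58    0.08     False
             urban         87       4.25     2.28     -3.10      8.25    0.05     False
             water         50       0.47     3.63     -5.20      6.16    0.06     False
selected: ['forest', 'grassland']
fit: {'mean_aic': 130.0, 'mean_residual_deviance': 119.85, 'mean_null_deviance': 175.13, 'mean_percent_deviance': 31.57}
accuracy 0.784 [0.784, 0.785]
```

The two classes that truly carry gene flow — and only those — are
retained above the threshold, with positive coefficients; retention
counts for the six no-effect classes stay far below it. The fitted
models explain ~32% of the null deviance and classify about 78% of
held-out-within-iteration segments correctly at this noise level.

## Full pipeline and CLI

A run is configured in YAML (see `examples/demo.yaml`) and covers
scenario generation (or file inputs: ESRI ASCII land-cover grid, sites
CSV, genotypes CSV, partition CSV), per-cell genetic summaries and
membership surfaces, pooled segments, models, and validation:

```bash
permeascape all examples/demo.yaml --seed 7 --output runs/demo
```

Subcommands `simulate`, `summaries`, `surface`, `segments`, `fit`,
`validate` stop after the named stage. Outputs are tidy CSVs plus a
`manifest.json` with content hashes; reruns with the same config and
seed are bit-identical.

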