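# methdep

**Spatial dependency of DNA methylation, one individual and one chromosome
at a time.**

Methylation levels at neighboring CpG sites are correlated along the
genome ("co-methylation"). Most analyses of this dependency pool CpG pairs
across a whole dataset and therefore cannot ask whether the *strength* of
the dependency differs between people. `methdep` is built for exactly that
question: it removes the cross-sample population mean and variance at each
CpG, models the per-individual residuals on each autosome as a latent 1-D
Gaussian random field with exponential (Matern, λ = 0.5) covariance plus
white measurement noise, and then analyzes how the fitted dependency
parameters vary with technical batches (bisulfite conversion plate,
BeadChip) and biology (zygosity, sex, age) in a twin cohort.

The model per individual × autosome, for residuals `y_p` at base-pair
position `p`:

```
y_p | μ_p, σ₀²  ~  N(μ_p, σ₀²)            μ = β + ξ
ξ               ~  N(0, Q⁻¹(τ, κ))         Cov(ξ(p₁), ξ(p₂)) = σ² e^{-κ|p₁-p₂|}
σ₀, τ, κ        ~  vague priors            r = √(8λ)/κ,   σ² = 1/(2κτ²)
```

`κ` sets the decay of correlation with distance (interpreted through the
range `r`, the distance of ≈0.1 correlation), `τ` the precision of the
field (smaller `τ` → more spatially structured variation), and `σ₀²` is
the noise nugget. Because the λ = 0.5 field is a Markov (Ornstein–
Uhlenbeck) process, the likelihood is computed *exactly* in O(n) through a
tridiagonal precision matrix — no SPDE/finite-element machinery — and the
3-D hyperparameter posterior is integrated on an adaptive grid. The
dependency model is compared to a plain independence model
`y_p ~ N(β, σ₀²)` with a marginal-deviance DIC, and per-(sample,
chromosome) posterior means feed the cohort statistics: ICC across
chromosome replicates, squared-difference `D` statistics under four
pairing schemes (true co-twins, random, plate-matched, plate+chip-matched),
one-sided Mann–Whitney tests combined across chromosomes with an extended
Fisher's method for correlated tests, relative-range chromosome profiles
and age-group contrasts.

Access-controlled cohort data is not required: a forward simulator
generates a full synthetic twin cohort (clustered CpG positions, bimodal
population means, twin/batch/age structure) with ground truth for every
parameter, and the entire pipeline runs end to end on it.

## Worked example

Simulate a small twin cohort, preprocess, fit every (sample, chromosome)
track and run the cohort statistics:

```
$ methdep simulate --seed 3 --config sim_small.yaml --out out/sim
simulated 400 probes x 10 samples -> out/sim

$ methdep preprocess --matrix out/sim/matrix.tsv --out out/prep
retained 400/400 probes; residuals -> out/prep/residuals.tsv

$ methdep fit --residuals out/prep/residuals.tsv \
              --manifest out/sim/manifest.csv --out out/fit
fitted 20/20 tracks in 9.7s -> out/fit/fits.csv

$ methdep report --fits out/fit/fits.csv --out out/rep
methdep run summary
===================
fits: 20 (samples: 10, chromosomes: 2)
dependency model favored (dDIC > 4): 100.0%
median range: 2140 bp
median marginal sd sigma: 0.914
median variance explained: 0.914
boundary-flagged fits: 1
```

(`sim_small.yaml` here holds `n_families: 5`, `n_chromosomes: 2`,
`sites_per_chromosome: 200`, `island_count: 7`, `missing_rate: 0.0`.)
Reading the summary: every track decisively preferred the spatial model
over independence (ΔDIC > 4); the typical fitted correlation range is
~2.1 kb — neighboring CpGs within a couple of kilobases share signal —
and the spatial field absorbs ~91% of the residual variance the plain
model would call noise. One of the twenty fits carries a boundary flag
(posterior mass near the grid edge; at 200 sites per track the noise
nugget can be weakly identified) and deserves a skeptical eye. `out/fit/fits.csv` holds the per-track posterior
summaries (`post_mean_logtau`, `post_mean_logkappa`, `range_bp`, `sigma`,
`sigma0sq`, `dic_dep`, `dic_plain`, `var_explained`, ...). The `stats`
subcommand then produces the cohort report (ICCs, the eight pairing
contrasts, relative-range profiles, age contrasts) — at this toy size the
contrasts are underpowered; the defaults (200 families, 5 chromosomes,
400 sites) are sized so that plate, chip, zygosity, sex and age effects
are all detectable.

The same pipeline is available as library calls
(`methdep.fit_chromosome`, `methdep.fit_plain`, `methdep.table1_analogue`,
`methdep.simulate_cohort`, ...); see `docs/methods.md` for the model,
priors, quadrature and simulator details.

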