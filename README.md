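# pinedrought

Analysis toolkit for drought-timing experiments on conifer saplings.  The
scientific question: when a hot drought hits early in the growing season —
during needle elongation — rather than late, what happens to growth, water
use, and the tree's response to the *next* drought?  The package implements
the full measurement-to-inference chain for a greenhouse experiment on Scots
pine (*Pinus sylvestris*) with four treatments (control, early, late, and
early+late hot drought), and ships a synthetic-data generator that emulates
the experiment so every stage is testable without any data download.

It is intended for plant ecophysiologists analysing dendrometer, sap-flow
and phenology time series, and for method developers who need a controlled,
truth-bearing test bed for such pipelines.

## The methods at its core

**Needle growth cessation** — needle length L(t) on day-of-year t follows a
continuous piecewise-linear ("truncated") regression

```
E[L(t)] = b1 · min(t, T) + b2 · max(0, t − T),    L ~ Normal(E[L], σ²)
```

with elongation rates b1, b2 (mm day⁻¹) and cessation threshold T (DOY),
fitted by random-walk Metropolis MCMC (50,000 iterations, 40,000 burn-in,
3 chains, broad uniform priors).  Convergence is checked with the
Gelman-Rubin R̂ (< 1.1); treatments differ significantly when their 95%
credible intervals for T are disjoint.  An exhaustive grid-search ML oracle
(`grid_mle`) validates the sampler.

**Zero-growth partitioning** — a dendrometer signal d(t) splits into
irreversible growth (the increase of the running maximum d_max) and
reversible tree water deficit TWD(t) = d_max(t) − d(t) ≥ 0, also expressed
per basal area, (π/4)(d_max² − d²) mm².

**Sap-flow baselining** — stem heat-balance signals (ΔT = 4 K) are corrected
by a baseline interpolated through zero-flow anchors: nights whose mean VPD
is below 0.2 kPa, anchored at the night's minimum signal.  Corrected power
becomes flux via P/(c_w·ΔT), and cumulative transpiration E_tree (litres) is
its time-integral.

**Bootstrap contrasts** — treatment-vs-control differences (growth, TWD,
transpiration, leaf-area proportions) are resampled with replacement, 1,000
iterations; a contrast is significant when the 95% percentile interval of
mean differences excludes zero.  One-way ANOVA + Tukey HSD letters and a
pooled slope test cover the end-of-season biomass tables.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## A worked example

```python
import pinedrought as pdr

design = pdr.ExperimentDesign(rng_seed=3)          # the four-treatment scenario
params = pdr.default_params()

fits = {}
for tr in ("early", "control"):
    obs = pdr.gen_needle_obs(design, params, treatments=(tr,))
    fits[tr] = pdr.fit_truncated_mcmc(obs, onset=118.0, seed=3)

cmp_ = pdr.compare_thresholds(fits["early"], fits["control"])
```

Running this (it is `examples/02_fit_needle_cessation.py`) prints:

```
early    cessation day: median 182.1 [180.1, 184.3], max R-hat 1.003
control  cessation day: median 204.4 [202.5, 206.1], max R-hat 1.004
early - control difference: -22.2 days [-24.1, -20.4]
credible intervals disjoint (significant): True
```

Needle elongation in early-stressed trees stops around DOY 182 versus ~204
in controls — about three weeks earlier, with non-overlapping credible
intervals: the early hot drought ends leaf growth for the season.  The other
examples cover the scenario generator (`01`), dendrometer partitioning
(`03`), sap-flow transpiration (`04`, early trees transpire ~40% less over
the season) and biomass statistics (`05`).

The full pipeline also runs from the shell:

```bash
pinedrought run-all --seed 42 --out run    # simulate → fit → dendro → sapflow → bootstrap
```

writing CSV artifacts and a `report.json` that aggregates thresholds,
windowed growth contrasts, peak-day water deficits, cumulative transpiration
and biomass letters.

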