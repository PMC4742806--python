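# reefocc

Trait-dependent occurrence modelling for Indo-Pacific coral reef fishes:
survey quality control, per-species boosted regression trees, trait-level
AICc multimodel inference, within-range permutation nulls, and
critical-threshold detection — plus a synthetic survey generator with a
known, recoverable effect structure.

## The problem

Visual-census compilations of reef-fish presence/absence span hundreds of
locations and hundreds of species, and the question they can answer is
not just *how many* species occur where, but *which* species persist
under which conditions.  The analysis this package implements asks, for
each species, how much of its occurrence pattern is explained by four
competing hypothesis families —

* **biogeography** (distances to land, shelf edge, range margin, the
  Coral Triangle; relative position within range),
* **habitat area** (reef area and perimeter, reef/shelf area in 10–50 km
  kernels),
* **energy** (SST and chlorophyll means and seasonality),
* **human pressure** (threat classes, a cumulative human-impact index,
  ocean-health scores),

— then models those per-species answers as functions of body size and
geographic range size, and locates critical stressor thresholds.  The
headline ecological pattern it is built to detect: human pressure and
temperature seasonality bear disproportionately, and negatively, on
large-bodied fishes with relatively small ranges.

## The method in brief

For species *s* with presence/absence \(y_{s\ell}\) over locations
\(\ell\) inside its range hull, a stochastic gradient-boosted tree
ensemble (binomial deviance, logit link; tree complexity 3, learning
rate 0.01, bag fraction 0.5) is fit with the tree count selected by
k-fold cross-validation.  Outputs per species: cross-validated percent
deviance explained \(D_s\), per-correlate contributions (split-gain
shares, summing to 100%), and partial-dependence curves.  Contributions
are summed within hypothesis families, and each of the five responses
(total \(D_s\) + four family shares) is modelled over species as

\[\log(y_s + \varepsilon) = X_s\beta + u_{\mathrm{family}(s)} +
u_{\mathrm{genus}(s)} + e_s,\]

with candidate predictors entering a two-stage AICc model set (singles
vs null; survivors, pairs, interactions) and predictions model-averaged
with Akaike weights \(w_i \propto \exp(-\Delta_i\mathrm{AICc}/2)\).
Class-averaged partial effects are tested for a slope change at an
unknown breakpoint (Davies bound over a candidate grid) and, where
significant, the threshold \(T\) is estimated by segmented regression
with delta-method or bootstrap standard errors.  A within-range
permutation null (presences shuffled uniformly inside each species'
range) verifies that none of this structure arises by chance.  Survey
quality is screened first: a binomial mixed-model analysis of the
detection proportion *P* (fraction of replicate samples with a
detection, given presence), false-absence rates along a
fishing-intensity gradient, PERMANOVA for data-source effects, and a PCA
check that missing data are not clustered in correlate space.

## A worked example

```bash
python examples/03_occurrence_brts.py
```

prints, for a 40-species × 150-location synthetic compilation:

```
converged: 17/40 species (tree counts 125-500)
CV deviance explained: mean 8.5%, range -1.2 to 19.9%
null (labels permuted within range): mean -2.1% — chance-level, as it should be

mean contribution (%) of each hypothesis by body-size class:
            biogeography  area  energy  human_pressure
size_class
16-50               20.6  16.3    18.4            44.7
<=15                28.0  34.0    15.9            22.1
>50                 26.4  15.6    16.6            41.4
```

Read: real fits explain deviance, permuted fits do not, and the
human-pressure share of explained deviance grows from the smallest to
the larger size classes — the planted vulnerability of large-bodied
fishes, recovered from noisy replicate-level survey records.  The other
examples cover the generator (`01`), detectability QC (`02`), trait
model sets and model-averaged surfaces (`04`), threshold estimation
(`05`) and the one-command pipeline (`06`).

The full pipeline is also runnable from the shell:

```bash
reefocc run --seed 11 --out runs/demo        # all stages
reefocc brt --seed 11 --out runs/demo        # one stage, from prior outputs
```

Each run directory holds per-stage CSV/JSON outputs, a `manifest.json`
per stage (seed, config hash, row counts) and an aggregated
`report.json` that is identical across reruns of the same config + seed.

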