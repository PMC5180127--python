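# photoid

Resight analysis and migration-detection power simulation for
photo-identification catalogues of wildlife aggregations.

Photo-ID studies catalogue individual animals (here, whale sharks identified
by their natural spot-and-stripe flank patterns) across several seasonal
aggregation sites. Two questions drive the analysis:

1. **What do the catalogues show?** Yearly unique-individual counts, new vs.
   resighted proportions, how many years individuals keep returning, sex
   composition, and — the headline — whether any individual has been
   photographed at more than one site.
2. **What could they show?** If a fraction MR of a *source* site's population
   migrated to a *sink* site each year, how many individuals would have to be
   identified yearly at the sink before such a migrant would be spotted with
   a desired probability DP? Failing to find migrants is only informative if
   the sampling effort had the power to find them.

For the second question the package evaluates the kernel

```
N_sink(MR) = DP · (P_sink + MR·P_source) / (MR · N_source)
```

where `N_source` is the number of individuals identified per year at the
source, and `P_source`, `P_sink` are the source and sink population sizes.
Migrants form a fraction `MR·P_source / (P_sink + MR·P_source)` of the sink
pool and a fraction `N_source/P_source` of them are already catalogued, so
each sink identification hits a catalogued migrant with probability
`MR·N_source / (P_sink + MR·P_source)`; demanding `DP` expected hits gives
the kernel. Uncertainty in `N_source`, `P_source`, `P_sink` is propagated by
Monte Carlo draws from normal distributions with the empirical means and
standard errors; the *detection threshold* is the smallest MR at which the
median required effort does not exceed the effort actually achieved.

Because real multi-site databases are rarely shareable, the package also
ships a synthetic-world generator (closed per-site populations, yearly
sighting probabilities, permanent migration, left/right/both flank capture,
male-biased sex mixes) with full ground truth, plus the inferential tests
used on such catalogues: one-way permutational ANOVA on Euclidean distances
with unrestricted permutation, pairwise permutation tests, and pooled
chi-square contingency tests on years-returned distributions.

## Worked example

How detectable is immigration from the Seychelles (population 513, 95% CI
469–557, 59 individuals identified per year) into Ningaloo Reef (population
380, 95% CI 320–440, 104 identified per year), demanding an 80% detection
probability?

```python
from photoid import (REFERENCE_SITES, PowerSimConfig,
                     detection_threshold, monte_carlo_power_curve)

src, snk = REFERENCE_SITES["seychelles"], REFERENCE_SITES["ningaloo"]
cfg = PowerSimConfig(dp=0.8,
                     p_source=src["population"], p_sink=snk["population"],
                     n_source_mean=src["yearly_ids"],
                     n_sink_obs=snk["yearly_ids"],
                     n_draws=10_000, seed=7)
curve = monte_carlo_power_curve(cfg)
thr = detection_threshold(curve, cfg.n_sink_obs)
print(curve.to_frame().iloc[[1, 9, 19, 29]].to_string(index=False))
print(f"threshold: {100*thr.mr_interp:.1f}% per year")
```

prints

```
  mr     median       p2.5      p97.5
0.01 522.929210 409.147475 678.105663
0.05 110.144382  86.741376 142.392213
0.10  58.578059  46.446087  75.390753
0.15  41.394131  32.995257  53.078342
threshold: 5.3% per year
```

Reading: to have an 80% chance of catching a 1%-per-year migration, about 523
Ningaloo sharks would need identifying each year (more than the estimated
population — hopeless); a 5% rate needs about 110 per year, right at the 104
actually achieved. The solved threshold says migration of roughly 5.3% of the
Seychelles population per year (or more) would have been detected; anything
slower could have gone unnoticed.

The same stages are available from the shell:

```sh
photoid simulate --config world.yaml --out catalogue.csv --truth truth.tsv
photoid metrics  --catalogue catalogue.csv --outdir out/ --side LB
photoid tests permanova --catalogue catalogue.csv --out permanova.tsv --seed 7
photoid power --source seychelles --sink ningaloo --dp 0.8 --seed 7 --out power.tsv
```

All outputs are TSVs with a comment header recording version, seed and a
configuration hash, and re-running with the same seed reproduces them
byte-for-byte.

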