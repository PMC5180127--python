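# Methods

## Sighting model and flank views

A catalogue row is one photo-identified encounter: individual, site, date,
sex (male / female / indeterminate) and which flank(s) were photographed.
Left and right flank patterns are independent marks, so an individual
photographed only on the left can never be matched to right-only photographs
of itself. Every analysis therefore runs on two views: **LB** (records whose
photographs include the left flank) and **RB** (right-inclusive). A
both-flank record belongs to both views, giving the accounting identity
`|LB| + |RB| − n_both = n_records`. When LB and RB test results fall in the
same significance category the LB result is reported (left-based catalogues
are conventionally the larger sample); discordant results are flagged for
manual review rather than silently resolved.

A *resight* is strictly across years: an individual counted in a site-year
is a resight if it was recorded at the same site in any earlier sampled
year. Repeat encounters within a year never count, and each site's first
sampled year is excluded from resight proportions since no resight is
possible there.

## Resight metrics

- **Site-year summaries** — unique individuals per site-year split into
  first-ever identifications and resights (`n_unique = n_new + n_resight`).
- **Years-observed distributions** — over a six-consecutive-year window per
  site (windows need not be identical across sites, only fully sampled),
  the count of individuals seen in 1, 2, … 6 distinct years; the top two
  categories are pooled ("5–6") before contingency testing so the
  expected-count assumption can hold on sparse tables.
- **Mean years observed** (± SE over individuals), **maximum consecutive-year
  runs** (per individual at a single site; runs do not bridge sites), **sex
  composition** over unique individuals (sex is treated as fixed per animal;
  the first non-indeterminate record wins and conflicts are logged), and
  **cross-site matches** — individuals recorded at two or more sites, with
  the elapsed days of the first site change measured from the last sighting
  at the original site to the first at the new one, and an implied minimum
  straight-line speed when a distance is supplied.

## Inferential tests

The one-way permutational ANOVA computes a pseudo-F from the Euclidean
distance-matrix partition (SS_total from all pairs, SS_within from
within-group pairs); on univariate responses this is algebraically the
classical ANOVA F, which the tests exploit as an independent oracle. The
null distribution comes from unrestricted permutation of the raw
observations, 999 permutations by default, with p = (b+1)/(m+1) so a sampled
null never reports exactly zero. An exhaustive mode enumerates all distinct
assignments (feasible below 200 000) and is then exact and seed-free. Zero
total variance is reported as p = 1 with an undefined statistic rather than
an error. Pairwise follow-up tests use the same statistic on two groups and
are reported unadjusted by default (a Holm option exists) — matching the
common practice of raw pairwise p-values after a significant omnibus test.

Chi-square contingency tests on years-returned tables use the Pearson
statistic without continuity correction (a 4×5 pooled table has df = 12,
where a corrected form would be inappropriate); the expected-count rule
(more than 80% of cells above five) is recorded on the result rather than
enforced, so a violation is visible but does not block computation.

## Power kernel and its orientation

The kernel

    N_sink(MR) = DP · (P_sink + MR·P_source) / (MR · N_source)

demands DP *expected* catalogued-migrant identifications per year at the
sink. A alternative algebraic arrangement of the same quantities —
DP·(N_source/P_source·MR·P_source)/(P_sink+MR·P_source) — is the per-
identification match probability scaled by DP; it has no units of
individuals, is everywhere below one and *increases* with MR, so it cannot
be a required sample size. The package implements the orientation above
(which reproduces all four published detection limits) and keeps the other
behind a `printed_form` debug flag for comparison.

DP enters multiplicatively, i.e. as an expected-match criterion. The
probability of *at least one* match is smaller (≈ 1 − exp(−E) for expected
matches E), so "DP = 0.8" in this convention corresponds to roughly a 55%
chance of one-or-more matches. The agent-based oracle
(`simulate_detection_oracle`) realises the scenario with explicit
individuals and reports both the empirical ≥1-match probability and the mean
match count, quantifying that gap instead of hiding it; the mean match count
agrees with the hypergeometric expectation
N_sink·MR·N_source/(P_sink+MR·P_source) by construction.

## Monte Carlo propagation

Per direction, 10 000 draws (default; minimum 1000) of (N_source, P_source,
P_sink) are taken from normal distributions with the empirical means and
standard errors. Draws at or below zero are rejected and resampled —
truncation, not clamping, since clamping would bias the median; a
configuration whose rejection rate would exceed 50% is refused as
degenerate. One draw set is shared across the whole migration-rate grid
(default 0.5%–25% in 0.5% steps), which makes every percentile of the curve
exactly non-increasing in MR and halves the noise in threshold solving. The
curve reports median, 2.5th and 97.5th percentiles per MR; the detection
threshold is the smallest grid MR whose median falls at or below the
observed yearly identification count, refined by linear interpolation
between the bracketing grid points. A curve that never crosses is flagged
"not detectable on grid" — a finding, not an error.

Parameter defaults and their reasoning:

- **Population SEs** come from published 95% CIs as (hi − lo)/(2·1.96),
  assuming symmetric normal intervals — the only dispersion the sources
  print. The Maldives interval "77–98.5" is read as a 95% CI by default; if
  it is instead the pair of researcher/public point estimates the mean
  (87.75, reported as 88) is unchanged but the SE is not, so
  `PopulationEstimate` accepts an explicit `se` override.
- **N_source SE** has no published value; the default is 10% of the mean
  (year-to-year variation of identification effort), overridable. Threshold
  medians are insensitive to this choice because the perturbation is
  symmetric around the mean.
- A site without a published population estimate (Mozambique) cannot enter a
  power run implicitly; an explicit user-supplied estimate is required.
- An explicit `se = 0` is allowed on a `PopulationEstimate` and collapses
  the Monte Carlo to the deterministic kernel — the degenerate limit used in
  validation.

## Synthetic worlds

`simulate_world` draws closed per-site populations with fixed per-individual
sex; each year (after the first) every configured source→sink route moves a
Binomial(current source size, MR) set of individuals permanently (a
fixed-count mode exists as a deterministic oracle), then each individual
present at a site is sighted with the site's annual probability, with flanks
drawn per sighting. Permanent relocation matches the power kernel's sink
pool `P_sink + MR·P_source`; return migration is not modelled. Everything is
deterministic under a fixed seed, byte-for-byte through CSV serialization.

What the generator does *not* emulate — and hence what passing recovery
tests do not establish about real data: open populations (births, deaths,
recruitment), effort that varies across years or observers, sighting
heterogeneity between individuals, within-year movement or seasonality
beyond a uniform sighting date, and photo-matching errors. The
`naive_split_ids` transform reintroduces one failure mode (an individual
photographed left-only and right-only becoming two identities) to exercise
the double-counting hazard the LB/RB protocol guards against: with equal
left/right capture and no both-flank photographs, an individual sighted k
times yields 2 − (1/2)^(k−1) identities in expectation.

In recovery tests, the fraction of the *population* resighted per year in a
closed site converges to the annual sighting probability (the fraction of
*sighted* individuals that are resights instead converges to 1, since
eventually everyone has been seen before); pipeline-level detection of a
planted migration is compared against the closed-form probability
1 − (1 − MR·p_src·p_snk)^P_source implied by the same one-step migration
model the power analysis uses.

## Validation problem sizes

The bundled checks run the Monte Carlo at 10 000 draws, the agent-based
oracle at 2000–4000 replicates per grid point, permutation calibration at
500 null datasets × 199 permutations, and pipeline recovery at 200 replicate
worlds of a few hundred individuals — sizes at which the Monte Carlo error
bands used in the assertions (3 MC SEs, binomial 95% CIs, KS bands) are
already narrow relative to the effects being checked.

## Known limitations

- The kernel's DP is an expected-match target, not a ≥1-match probability
  (see above); thresholds quoted at DP = 0.8 are optimistic if read as the
  latter.
- Normal sampling of strictly positive quantities is an approximation;
  rejection keeps draws positive but skews means slightly upward when the
  CI is wide relative to the mean.
- Permutational ANOVA here is univariate one-way only (no factorial or
  multivariate designs, no dispersion test), which is all the catalogue
  summaries require.
- Cross-site distances are user-supplied straight-line figures; no
  geodesic computation is attempted unless coordinates are provided by the
  caller.
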