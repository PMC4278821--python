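# Methods

## Data model and coordinate conventions

A detection record is one identified echolocation call sequence (a bat
pass). Timestamps are minutes from the start of the fixed nightly
recording window (21:30–05:30), so all time arithmetic happens on a single
`[0, 480)` axis regardless of date; wall-clock input is converted on read,
with times after midnight assigned to the night that began the previous
evening. All time intervals are half-open `[start, end)`. This makes the
96 five-minute activity bins (`[5k, 5(k+1))`) and the three temporal
patterns — full night `[0, 480)`, first 4 h `[0, 240)`, dusk/dawn split
`[0, 120) ∪ [360, 480)` — partition cleanly, with every valid timestamp
falling in exactly one bin and boundary times never double-counted.

Species whose calls cannot be separated acoustically (*Plecotus auritus* /
*austriacus*, *Nyctalus noctula* / *leisleri*, *Eptesicus serotinus* /
*nilssoni*) are collapsed to genus-level groups before richness analyses
and each group counts as one taxon; the mapping is configurable and the
operation idempotent. Guilds (short-/middle-/long-range echolocators)
classify taxa by echolocation range and clutter resistance; order-level
records ("Chiroptera") carry no guild and are excluded from guild activity
and richness counts — summaries report them separately so the exclusion is
auditable.

Reported percentages round half-up: two decimals in community tables
(shares of the guild-assignable total, order-level rows excluded), one
decimal in text-style summaries (shares of the grand total).

## Activity index

Activity per site-night is the number of distinct 5-minute bins containing
at least one sequence of the focal taxon or guild (maximum 96). Raw
sequence counts are a poor activity measure because one foraging bat can
trigger hundreds of recordings; bin occupancy saturates that behaviour.
The per-night guild table is the module's final product — mixed-model
analysis of those counts is deliberately left to general-purpose
statistical tools, since the statistic and the sampling design, not the
model fit, are what this package contributes.

## Accumulation curves

Sampling effort is detector-nights. For a sampling unit (a plot or cell
under one scheme) the incidence matrix records taxon × night presence,
pooled over the unit's retained sites; nights with zero detections remain
as all-zero columns because a sampled night without bats is still effort.
The night set defaults to nights with at least one record in the unit
before temporal filtering (so a night emptied by the 4-h filter still
counts); completely silent sampled nights are invisible in a record file
and can be supplied explicitly.

The permutation estimator randomizes night order (default 1000 times,
seeded) and averages cumulative richness. Its exact expectation has the
closed hypergeometric form `E[S(t)] = Σ_i [1 − C(T−n_i, t)/C(T, t)]`,
implemented independently as an oracle; the test suite checks their
agreement within Monte-Carlo error at a family-wise 3σ level
(Bonferroni-adjusted across the ~400 simultaneous curve points compared —
a naive per-point 3-SE bound would reject a correct estimator in most
runs). The exact implementation was additionally validated against an
established community-ecology implementation of the same estimator, whose
values on a toy matrix are frozen into the tests.

Presence is pooled before permutation (night is the resampling unit);
combining units with unequal night counts happens at the fit stage by
parameter averaging, not by pooling unequal curves.

## Clench extrapolation

The Clench model `S(t) = a·t/(1+b·t)` (initial accumulation rate `a`,
shape `b`, asymptote `a/b`) is fitted to the permutation-mean curve by
unweighted nonlinear least squares (optionally `1/sd`-weighted),
initialized at `a₀ = S(1)`, `b₀ = a₀/S(T)` so the starting asymptote
equals the observed maximum — a starting point that is already close for
saturating curves and avoids the `b → 0` ridge. Parameters are bounded
positive; convergence tolerance is 1e-8 on the parameter step with at
most 10 000 function evaluations; failure flags the fit (or raises in
strict mode) and flagged fits are refused by the averaging step, which
names the offending units. Degenerate constant curves drive `b` large
with `a/b` at the constant, which the tests accept only if the asymptote
is within 1 % of it.

Scheme-level fits average `a` and `b` arithmetically across units. Note
`mean(a)/mean(b)` is generally not the mean of per-unit asymptotes; the
convention is documented by an explicit test case. Effort to reach a
fraction `q` of the asymptote is exact: `t_q = q/((1−q)·b)`, reported both
raw and rounded up to whole nights (effort is integral nights).

## Cost model

Total invested time is `T_t = T_f + T_a`: field-management time `T_f` is
an input (from the campaign's own logistics accounting), and analysis
time `T_a = N_n·N_p·X_s·A` scales with nights, plots, the mean sequences
recorded per plot-night `X_s`, and the per-sequence identification time
`A`. The default `A` is 20 s/sequence (1/180 h), an average over manual
verification and filter development for large batches. `T_a` is rounded
half-up to 0.1 h and the rounded figure feeds the labor arithmetic —
the convention under which the packaged scenario table is internally
exact. Labor prices field hours at 50 €/h (technician) and analysis hours
at 100 €/h (expert); equipment is one 1645 € detector per sampled
microhabitat per plot. Per-scheme dispersion across plot counts is the
sample standard deviation (n−1); a single scenario reports an undefined
dispersion, not zero.

The six packaged scenarios cover the two schemes that reach the 90 %
richness threshold at the plot scale — full-night sampling of all three
microhabitats (`X_s = 2069`) or of gap + ground (`X_s = 1524`) — at 2–4
plots. No single-plot scenario exists because one plot never reaches the
required richness; feasibility is an upstream (accumulation/fit) question
the cost module does not decide.

## Synthetic surveys

The generator emulates the structure of a stratified forest campaign:
8 cells × 4 plots × 3 microhabitat sites, 6–12 nights per cell, with all
plots of a cell sharing calendar nights (one cell equipped at a time).
Counts per (site, night, species) are Poisson with mean
`base_rate × abundance_weight × affinity(species, microhabitat)` — the
log-linear structure matching the Poisson treatment of activity counts —
and timestamps follow a two-Gaussian mixture truncated to the window,
emulating bimodal post-dusk/pre-dawn activity.

Default parameters: 16 taxa in three guilds with abundance weights and
microhabitat shares shaped like a central-European lowland forest
assemblage (one species at ~87 % of sequences; gap-skewed long/middle-range
echolocators, ground-leaning gleaners); affinities are the per-species
microhabitat shares × 3, so a preference-free species has affinity 1
everywhere and the plot-level rate is preference-independent;
`base_rate = 690` makes a three-detector plot record ≈ 2070 sequences per
night, the magnitude of a productive campaign and consistent with the
packaged cost scenarios' `X_s`. Activity peaks sit at 60 and 420 minutes
(≈ 22:30 and 04:30) with 70-min spread and dusk weight 0.65 (0.45 for the
long-range guild, which flies more at dawn). Per-species nightly rates
are illustrative of such an assemblage, not estimates of any real system.
Temperature and weather effects are omitted (field protocols already
exclude cold/rainy nights); a per-night rate-multiplier hook exists for
users who want them.

What the generator does *not* emulate: detection-distance and acoustic
propagation, misidentification, within-night temporal autocorrelation
beyond the mixture shape, and between-night weather dependence. Passing
tests therefore demonstrate the correctness of the estimators and the
pipeline on data with the assumed structure, not the field accuracy of
any richness estimate.

## Problem sizes and determinism

Tests and the acceptance script run surveys scaled to desk size: the
recovery study uses 100 single-plot surveys of 14 nights with an
8-species saturating community; the end-to-end run uses two cells at a
tenth of the default sequence rate (~18 000 records). Scale-up only
multiplies Poisson draws and permutation work. All stochastic stages
(simulation, permutation order) take explicit seeds or NumPy generators;
a pipeline run records its seed and config digest in a manifest, and
identical config + seed reproduce outputs byte for byte.

## Known limitations

- Richness extrapolation inherits the Clench model's assumptions; strongly
  non-saturating or multi-phase accumulation will bias `a/b` upward, and
  the recovery guarantees quoted in the tests hold for communities that
  saturate within the sampled effort range.
- Silent sampled nights must be supplied explicitly to be counted as
  effort when reading records from files.
- The cost model treats `T_f` as exogenous and ignores equipment
  depreciation and currency conversion.
- Guild activity assumes every non-order taxonomic level maps to a single
  guild; a genus spanning guilds would need a finer mapping.
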