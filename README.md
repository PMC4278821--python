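# batsurvey

Design and cost evaluation of passive acoustic sampling schemes for
inventorying forest bats.

Passive ultrasound detectors collect enormous numbers of echolocation call
sequences, but how completely they capture a forest's bat community depends
on *where* detectors are placed (forest ground, canopy, forest gap) and
*when* they record (the whole night, the first 4 h after sunset, or a
2 h + 2 h dusk/dawn split). `batsurvey` implements the full evaluation
pipeline for the resulting 21 spatiotemporal sampling schemes (7 nonempty
microhabitat subsets × 3 temporal patterns):

- **Detection records** — a tabular data model for identified call
  sequences (night, minutes-from-21:30 timestamp, cell/plot/site,
  microhabitat, taxon, identification level, echolocation guild), with
  delimited-text I/O, grouping of acoustically inseparable congeners
  (*Plecotus*, *Nyctalus*, *Eptesicus*), and scheme filters.
- **Activity index** — the number of 5-minute intervals per night holding
  at least one detection of a taxon or guild (0–96 for an 8-h night), a
  statistic robust to one bat circling a microphone all night.
- **Species accumulation curves** — richness vs. sampling nights for any
  scheme and sampling unit, by permutation resampling (default 1000 night
  orderings) with an exact closed-form (hypergeometric) oracle:
  `E[S(t)] = Σ_i [1 − C(T−n_i, t)/C(T, t)]`.
- **Clench extrapolation** — nonlinear least-squares fit of
  `S(t) = a·t/(1 + b·t)`, asymptotic richness `a/b`, parameter averaging
  across sampling units, and the closed-form effort to reach a fraction
  *q* of the asymptote, `t_q = q/((1−q)·b)` (so `9/b` nights for the usual
  90 % completeness criterion).
- **Cost model** — total invested time `T_t = T_f + T_a` with analysis
  time `T_a = N_n·N_p·X_s·A` (nights × plots × sequences per plot-night ×
  analysis time per sequence), labor priced at technician/expert rates,
  plus one detector per sampled microhabitat per plot.
- **Synthetic surveys** — a seeded generator producing realistic detection
  records (Poisson counts with species × microhabitat affinities, a
  ~87 %-dominant species, bimodal within-night activity) so every stage is
  testable end to end without field data.

## Worked example

Cost out the two full-night schemes worth deploying at the 1-km² scale
(all three microhabitats, or gap + ground) at 2–4 plots each:

```
$ batsurvey cost --out costs.csv
             scheme  mean_total_cost  sd_total_cost  n_scenarios
GA+GR+CA full_night     36783.333333    1465.506170            3
   GA+GR full_night     33811.666667     632.975776            3
```

Reading `costs.csv`: the three-microhabitat scheme costs about 37 000 €
(± 1466 € sd across plot counts) — e.g. at 2 plots, 11 nights and a mean
of 2069 sequences per plot-night give 252.9 h of sequence analysis,
26 030 € of labor and 9 870 € of detectors (35 900 € total). The
gap + ground scheme saves a detector per plot and lands near 34 000 €
(± 633 €).

The same pipeline on a simulated survey (two 1-km² cells, four plots
each, 10–12 nights):

```python
import batsurvey as bs

com = bs.default_community(base_rate=69.0)          # scaled-down survey
lay = bs.SurveyLayout(n_cells=2, plots_per_cell=4, nights_min=10, nights_max=12)
records = bs.collapse_taxa(bs.simulate_survey(com, lay, seed=1))

scheme = bs.SamplingScheme(
    design={bs.Microhabitat.GAP, bs.Microhabitat.GROUND, bs.Microhabitat.CANOPY},
    pattern=bs.TemporalPattern.FULL_NIGHT)
fits = []
for plot in sorted({r.plot_id for r in records}):
    inc = bs.build_incidence(records, scheme, "plot", plot)
    fits.append(bs.fit_clench(bs.accumulation_permuted(inc, 1000, seed=2)))
avg = bs.average_fits(fits)
print(f"asymptote={avg.asymptote:.2f}")             # asymptote=12.01
print(bs.effort_to_fraction_nights(avg, 0.9))       # 9
```

The averaged Clench fit estimates ~12 taxa at the plot scale and 9 nights
of full-night, three-microhabitat sampling to record 90 % of them under
these simulated conditions.

`batsurvey run --simulate --seed 0 --out outdir` runs every stage
(simulate → summarize → accumulate → fit → effort → cost) and writes
per-stage delimited-text tables plus a manifest that makes the run
reproducible.

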