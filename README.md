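# phenosync

Tools for quantifying **phenological synchrony** between a consumer's food
requirement and a seasonal resource pulse, built around the breeding biology
of insectivorous birds (great tits feeding nestlings on a short caterpillar
peak), and for asking which of two synchrony metrics better explains
demographic outcomes:

* **MD — match in dates.** The difference, in days, between the date of peak
  consumer demand and the date of peak resource availability.  At the brood
  level, `MD_b = (hatch date + 10) − peak date` (nestling energy needs peak
  near day 10 post-hatching); at the population level,
  `MD_p = mean laying date + 33 − peak date` (laying precedes peak demand by
  ~33 days).  Positive values mean the consumer is late.
* **MO — match in overlap.** The relative area under the intersection of the
  food-requirement and food-availability distributions,

  `MO_p = ∫ f_I(t) dt / ∫ f_F(t) dt`,

  where `f_F` is the availability curve, and `f_I = min(f_F, f_R)` its
  intersection with the requirement curve, both scaled to [0, 1] jointly
  across seasons.  The brood-level proxy `MO_b` is the total availability
  over nestling ages 5–15, standardised across broods within a season.

The package covers the full analysis pipeline:

1. **Curves** (`food_curves`) — interpolate sparse frass-net biomass samples
   (g/m²) to a daily availability curve with an exact cubic spline and a
   linear-tail/zero-out boundary rule; stack per-brood daily requirements
   (the age-specific series 2.57 … 4.51 g wet biomass per nestling per day,
   from energy needs ÷ 21.4 kJ/g dry × 5 for wet mass); scale both kinds
   across seasons; peak date, peak height (HCP), skewness and kurtosis.
2. **Metrics** (`synchrony_metrics`) — MD and MO at brood and population
   level, signed MO, and the quadratic MD–MO association (beta regression).
3. **Model comparison** (`model_comparison`) — the two candidate suites
   (4 binomial nestling-recruitment models; 9 Poisson selection-on-laying-
   date models, plus skewness/kurtosis shape variants), fitted as
   random-intercept GLMMs by Laplace-approximation maximum likelihood and
   ranked by AICc (ΔAICc ≤ 2 = competitive), with parametric-bootstrap CIs
   and VIF diagnostics.
4. **Measurement-error simulation** (`mo_uncertainty_sim`) — how MO's
   explanatory power degrades when the availability signal passes through
   two imperfect correlation layers (density → total food → provisioned
   food), across a 4×4 grid of correlation levels {1, 0.75, 0.5, 0.25}².
5. **Synthetic data** (`synthetic_data`) — a study-shaped generator with
   known ground truth (configurable recruitment and selection effects), so
   every stage is testable without field data.

## Worked example

```python
import phenosync as ps

truth = ps.TruthParams(n_years=12, pairs_per_year=40, sampling_noise_cv=0.0,
                       beta_md2=-0.03, random_sd_year=0.0,
                       random_sd_mother=0.0, random_sd_brood=0.0, seed=3)
study = ps.generate_study(truth)
curves = ps.build_season_curves(study.frass, study.breeding, truth.season_window)
sync = ps.compute_synchrony(study.breeding, curves.avail_raw, curves.avail_scaled,
                            curves.req_scaled, curves.peak_dates, curves.stats)
comp = ps.fit_recruitment_suite(study.breeding, sync.brood_metrics)
print(comp.table[["model", "k", "n", "logLik", "AICc", "dAICc"]].to_string(index=False))
```

```
                     model  k    n      logLik        AICc      dAICc
Dens + BCI + MD_b + MD_b^2  8 3498 -710.967043 1437.975359   0.000000
         Dens + BCI + MO_b  7 3498 -728.099130 1470.230352  32.254994
                Dens + BCI  6 3498 -783.012607 1578.049277 140.073918
         Dens + BCI + MD_b  7 3498 -782.966455 1579.965002 141.989643
```

The study was generated with recruitment declining quadratically in the
brood-level date mismatch (`beta_md2 = −0.03` per day² on the logit scale)
and no overlap effect, and the AICc ranking recovers exactly that: the
quadratic-MD candidate wins by ~32 AICc units over the overlap proxy
(which, being a unimodal transform of the same mismatch, picks up part of
the signal), while the linear-MD and base models are far behind.

The same pipeline runs from the shell:

```bash
phenosync --seed 3 --out-dir run simulate-study
phenosync --out-dir run metrics --frass run/frass.csv --breeding run/breeding.csv
phenosync --out-dir run fit-recruitment --breeding run/breeding.csv \
          --brood-metrics run/brood_metrics.csv
phenosync --seed 3 --out-dir run mo-sim --grid --iterations 200
```

Repeated runs with the same seed are byte-identical.

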