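# coucal

Parental care and offspring growth in two sympatric coucal species with
opposite sex roles: the classically polyandrous **black coucal**
(*Centropus grillii*), in which males incubate and provision alone, and the
socially monogamous, biparental **white-browed coucal**
(*C. superciliosus*).  The package implements, as a tested analysis
pipeline over synthetic stand-ins for the field data, the four
quantitative pillars of that comparison:

1. **Incubation off-bout detection** from nest-temperature loggers sampling
   every 3 min in 0.5 °C steps: an absence bout begins with a steady drop of
   ≥ 2 °C and ends when the reading has risen 2 °C above the bout's minimum.
   Daily summaries (interruptions/day, total absence, bout duration by
   morning/noon/afternoon) feed Gaussian mixed models comparing the species.
2. **Hierarchical models of care behaviour**: a binomial GLMM of which sex
   is found incubating (time-of-day covariate, nest random intercept); a
   Poisson GLMM of feeding visits with log watch duration as exposure
   offset, species × sex fixed effects, standardized brood mass and time of
   day, and crossed parent/nest random intercepts; and a duration-weighted
   Gaussian model of the "off-time" proportion (time perched high on
   bushes or grasses).  Non-Gaussian models are fitted by Laplace-
   approximate maximum likelihood; 95% credible intervals come from
   flat-prior posterior simulation, and fit quality is reported as
   marginal/conditional R².
3. **Nestling growth curves**: mass(t) = A / (1 + exp(−K (t − I))) per
   species and sex, with correlated bivariate-normal random effects on the
   asymptote A and inflection point I at the nest and the
   nestling-within-nest level, fitted by alternating linearization
   (Lindstrom–Bates style).  Fledging mass is expressed relative to adult
   body mass.
4. **Prey composition**: conjugate Beta posteriors for the proportion of
   grasshoppers, frogs and mantises delivered to nestlings, and
   region-of-practical-equivalence (ROPE) probabilities that the two
   species' proportions differ by less than ε = 0.05.

Because the original field data are not deposited, a first-class
synthetic-data module (`coucal.synth`) generates all five input streams
with known ground truth — thermal on/off dynamics, Poisson provisioning
with lognormal parent/nest heterogeneity, logistic growth with nested
random effects, binomial incubation checks, multinomial prey tallies — so
every estimator has a parameter-recovery oracle.

## Worked example

```python
from coucal import synth, bouts, growth
from coucal.composition import estimate_proportions, rope_similarity
from coucal.datasets import PREY_COUNTS

# detect off-bouts on a simulated black-coucal logger trace
trace, truth = synth.simulate_temperature_trace(synth.IncubationSchedule(), n_days=4, seed=42)
detected = bouts.detect_absence_bouts(trace)
print(len(truth), len(detected))                     # 16 16

# prey composition from the published tallies
tab = estimate_proportions(PREY_COUNTS["black"]).set_index("category")
print(tab.loc["grasshoppers", "mean_2dp"])           # 0.73
print(rope_similarity(PREY_COUNTS["black"], PREY_COUNTS["white-browed"],
                      "frogs", epsilon=0.05, seed=1))  # 0.00012

# growth at the inflection point is half the asymptote
print(growth.predict_mass(A=77.1, K=0.377, I=6.2, t=6.2))   # 38.55
print(growth.relative_fledging_mass(77.1, 165.9))           # 46.5
```

The first block says the detector found every simulated interruption; the
ROPE value states there is essentially no chance (~0.01%) that the two
species deliver frogs in practically equivalent proportions; the last lines
show that black-coucal females fledge at 46.5% of adult female mass.

Running the numbered drivers reproduces the full analysis narrative:

```bash
python analysis/01_simulate_field_data.py      # five input CSVs + truth
python analysis/02_detect_incubation_bouts.py  # bouts, daily summaries
python analysis/03_incubation_models.py        # binomial GLMM + LMMs
python analysis/04_provisioning_models.py      # feeding + off-time models
python analysis/05_growth_curves.py            # growth tables per group
python analysis/06_prey_composition.py         # Beta posteriors + ROPE
python analysis/07_full_report.py              # everything, orchestrated
```

Outputs land under `results/`.  The same pipeline is available as a CLI
(`coucal simulate`, `coucal detect-bouts`, `coucal fit-feeding`,
`coucal fit-growth`, `coucal prey`, `coucal report`, ...).

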