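# eve2sim

Stochastic modeling of transcriptional bursting at *even-skipped* stripe 2
in the early *Drosophila* embryo.

Live imaging of nascent transcripts shows that *eve* stripe 2 expression is
"bursty" at minute resolution. A long-standing question is whether such
time series can reveal the structure of the underlying regulatory
mechanism — in particular, whether transcription switches between OFF and a
single ON rate (the telegraph model), or whether the minimal stripe element
(MSE) drives **two** distinct ON states: a LOW rate with Bicoid (Bcd) bound
alone, and a HIGH rate with Bcd plus the co-activator Hunchback (Hb).
`eve2sim` implements a complete, seeded pipeline for posing that question
with synthetic data: a mechanistic model of the MSE, its deterministic and
exact-stochastic solutions, the sequential calibration of all rate
constants from data features, and the time-series statistics that
discriminate the mechanisms.

## The model

The MSE carries one effective binding site each for the activators Bcd (B)
and Hb (H) and the repressors Krüppel (K) and Giant (G). The regulatory
state `E[BHKG]` is the bound/unbound pattern of the four sites — 16 states
on the 4-cube, with independent per-site kinetics

```
k_bind_X · [X] :  site X binds   (second order, M⁻¹ s⁻¹)
k_unbind_X     :  site X unbinds (first order, s⁻¹)
```

Transcription initiates only from `E[1000]` (rate `k_1000`, LOW) and
`E[1100]` (rate `k_1100`, HIGH); a bound repressor blocks initiation.
Each initiation adds a nascent transcript; termination is first order with
rate `k_T`, releasing a finished mRNA. At equilibrium each site is bound
with probability `p_X = k_bind_X·[X] / (k_bind_X·[X] + k_unbind_X)` and the
16-state distribution is the product over sites.

TF concentration profiles over 30–55 %EL (percent embryo length) are
generated synthetically: Bcd and Hb high anterior and constant in time; the
Gt domain (centered ~28 %EL) and Kr domain (centered ~53 %EL) flank the
stripe, vanish at its center (42 %EL), and grow ten-fold over the 45-minute
transcription window of nuclear cycle 14, sharpening the stripe.

All rate constants are pinned by features of the experimental time series
(sequential calibration): 55% positive per-minute changes → 55% Bcd-site
occupancy; mean output 230 transcripts, half of it Bcd-only → `k_1000` and
the Hb occupancy; maximum gain +33.5/min → `k_1100 = 0.56 s⁻¹`; a 4.2-min
transit time → `k_T = 3.97e-3 s⁻¹`; and autocorrelation conditions →
`k_unbind = 0.033 s⁻¹` for all TFs.

## Worked example

```python
import eve2sim as e

report = e.run_full_estimation()          # calibration steps 1-8
print(report.render())

profiles = e.make_tf_profiles()
conc = profiles.conc_at(42, time_varying=False)   # stripe center
ode = e.solve_nucleus_ode(conc, report.rates, record_every=2700.0)
print(ode.final)

two = e.run_scenario("stripe_center_two_state", base_seed=1, profiles=profiles)
one = e.run_scenario("one_state_zero_high",    base_seed=1, profiles=profiles)
print(e.compare_mechanisms(two, one).render())
```

The calibration reproduces the rate set (`k_bind_b = 2.6e6`,
`k_bind_h = 1.8e5 M⁻¹s⁻¹`, `k_1000 = 0.0899`, `k_1100 = 0.56`,
`k_T = 0.00397 s⁻¹`, …). The deterministic run prints

```
deterministic 45-min output: 228.2 transcripts (LOW pathway 114.5, HIGH pathway 113.7)
```

— the calibrated 230-transcript mean split evenly between the Bcd-only and
Bcd+Hb pathways (the ~1% deficit is the relaxation from the unbound initial
condition). The mechanism comparison prints

```
Mechanism comparison (pooled per-minute-change histograms)
  chi2 = 40.538, df = 10, p = 0.0000
  replicates with significant change-series ACF: A 2/10, B 1/10
  dwell fractions A (off/low/high): 0.447/0.479/0.073
  dwell fractions B (off/low/high): 0.806/0.194/0.000
```

The two-ON-state mechanism (A) spends ~45% of its time OFF, ~48% at the
LOW rate and ~7% at HIGH, producing a smoothly decreasing distribution of
per-minute gains; the one-ON-state mechanism (B), forced to make the same
mean output from a single HIGH rate, is OFF ~80% of the time and shows a
sharp drop from the 0–1 to the 2–3 additions-per-minute class. The pooled
histograms differ significantly (Pearson χ², classes with counts > 5).

A command-line interface mirrors the library:

```
eve2sim calibrate
eve2sim simulate --position 42 --seed 1
eve2sim scenario stripe_center_two_state --seed 1 --outdir out/
eve2sim compare stripe_center_two_state one_state_zero_high --seed 1
eve2sim pseudo-data --mechanism two_state --seed 1 --out series.csv
```

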