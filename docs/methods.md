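# Methods

## Model

One nucleus carries one (optionally two) copies of the *eve* stripe 2
minimal stripe element (MSE), reduced to one effective binding site per
transcription factor: Bcd and Hb (activators), Kr and Gt (repressors). The
regulatory state `E[BHKG]` ∈ {0,1}⁴ evolves by independent per-site
binding/unbinding; there is no cooperativity and no TF–TF interaction term,
so the state graph is the full 4-cube and the stationary law factorizes
over sites. TF concentrations are external boundary inputs — binding is
pseudo-first-order `k_bind·[TF]` and does not deplete the TF pool.

Initiation is state-dependent: `k_1000` from `E[1000]` (LOW), `k_1100` from
`E[1100]` (HIGH), zero elsewhere; either repressor bound blocks initiation.
Whether repression acts by quenching or competition is not resolved — only
the blocking effect is modeled, and repressor binding does not block
activator binding. Nascent transcripts are individual molecules with
exponential residence: termination is first order (`k_T`), so the nascent
pool is an M/M/∞-type queue driven by the switching initiation rate. A
deterministic elongation delay is deliberately not modeled; the exponential
transit absorbs the variability in elongation times. The ~10-minute lag at
the start of nuclear cycle 14 is not simulated: time 0 is transcription
onset and the horizon is 45 min (2700 s).

Nuclei are independent — no species diffuses between them — so a stripe
(30–55 %EL, one nucleus per 1 %EL) is an array of independent single-nucleus
problems. One nucleus corresponds to a (5 µm)³ ≈ 1.25e-13 L subvolume, so
1 nM ≈ 75 molecules; this conversion is exposed for interpreting the
synthetic profiles but propensities take molar inputs directly.

## Default parameters

| constant | value | units | pinned by |
|---|---|---|---|
| k_bind_b | 2.6e6 | M⁻¹s⁻¹ | 55% Bcd-site occupancy at the stripe-center [B] |
| k_bind_h | 1.8e5 | M⁻¹s⁻¹ | 230-transcript mean output (joint with k_1000) |
| k_bind_k | 9.9e6 | M⁻¹s⁻¹ | spatial accumulated-mRNA profile, 35–47 %EL |
| k_bind_g | 1.98e7 | M⁻¹s⁻¹ | spatial accumulated-mRNA profile, 35–47 %EL |
| k_unbind (all) | 0.033 | s⁻¹ | autocorrelation conditions (a)/(b), see below |
| k_1000 | 0.0899 (≈0.09) | s⁻¹ | 115 transcripts via the Bcd-only pathway |
| k_1100 | 0.56 | s⁻¹ | maximum observed gain +33.5/min |
| k_T | 3.97e-3 | s⁻¹ | 4.2-min mean transit time |

The one-ON-state (simple ON-OFF) comparison mechanism sets `k_bind_h = 0`,
`k_1000 = k_1100 = 0.56 s⁻¹`, and `k_bind_b = 4.75e5 M⁻¹s⁻¹` (18% of the
two-state value) so a single HIGH rate carries full-scale output. Note the
equilibrium mean with those constants is ~276 transcripts, not 230; a
`one_state_zero_high_rebalanced` scenario solves `k_bind_b` for an exact
230 mean, and both variants are provided rather than guessing which
accounting produced the printed constant.

## Calibration

The constants are estimated sequentially from `DataFeatures`, not by
likelihood fitting:

1. The positive-change fraction (default 0.55) is identified with the
   Bcd-bound occupancy `p_B`; with `k_unbind` fixed this gives `k_bind_b`
   for the fixture `[B]`. Only the product `k_bind·[TF]` is identifiable —
   the calibration is exactly invariant under rescaling all concentrations
   with inverse rescaling of binding constants (a seeded simulation is
   bit-identical under that transformation).
2.–4. Steps 2 and 4 are solved **jointly**: the HIGH pathway equation
   `k_1100·p_B·p_H·T = total − low` gives `p_H` (0.1383), then the LOW
   pathway `k_1000·p_B·(1−p_H)·T = low` gives `k_1000` (0.0899 s⁻¹), and
   `p_H` inverts to `k_bind_h`. The purely sequential reading (using `p_B`
   alone for step 2) would give `k_1000 ≈ 0.077 s⁻¹`, inconsistent with the
   115/115 split; only the joint solution reproduces both.
3. `k_1100 = max_gain/60`, reported at 2 significant figures (0.56);
   computation carries the rounded value because later steps are anchored
   to it.
5. `constrain_unbinding` scans a grid of unbinding constants, rescaling
   binding constants to hold occupancies fixed, and simulates stripe-center
   replicates to test (a) significant nascent-count autocorrelation within
   1–3 min lags and (b) no significant autocorrelation of per-minute
   changes, each required in a majority of replicates. The default 0.033 s⁻¹
   is feasible; values ≲1e-3 s⁻¹ fail (frozen, persistent or silent
   trajectories). **Limitation:** condition (a) does not exclude *fast*
   switching — the 4.2-min residence of nascent transcripts sustains
   minute-scale count autocorrelation at any switching speed (the ACF of an
   M/M/∞ queue is `exp(−k_T·t)` regardless of arrival-rate mixing), so the
   upper bound on the switching speed is not recoverable from (a) as
   operationalized here.
6. `k_T = 1/(60·4.2 min)`.
7.–8. Kr/Gt binding constants are fit by least squares of the
   deterministic spatial profile against a target accumulated-mRNA table
   (35–47 %EL at 5/20/45 min of transcription). On a self-consistent
   synthetic target the printed constants are recovered to well within 5%.
   A flat target is reported as non-identifiable rather than fit.

The positive-change-fraction identification in step 1 is a convention, not
an unbiased estimator: simulated two-state series at a true 55% occupancy
show only ~41% positive minutes (the change distribution is skewed — many
small losses, fewer large gains). Round-trip recovery tests therefore read
occupancy as the Bcd-bound dwell fraction, the stochastic interpretation of
the same quantity.

## Numerical solution

**Deterministic.** Because sites are independent, the mean-field equations
close on the four site probabilities plus the expected nascent count and
pathway integrals; they are integrated with fixed-step classical RK4
(default 0.1 s for single-nucleus runs, 0.5–1 s for spatial sweeps — the
fastest rate is 0.56 s⁻¹, and halving the step changes the 45-min output by
<1e-6 relative). The initial condition is all sites unbound; the resulting
~13–26 s occupancy relaxation costs ~2 transcripts of the 230 (−0.8%),
which is why the deterministic output prints 228.2.

**Stochastic.** Exact Gillespie direct method per nucleus (6 reactions:
4 site toggles, initiation, termination). The ten-fold Gt/Kr ramp is
handled by piecewise-constant propensities on a 1 s grid with waiting-time
redraws at slice boundaries — exact for exponential clocks, and the rates
change by <0.1% per slice on the linear ramp. Two-copy nuclei run two
independent model instances with per-copy initiation rates halved, summed
at observation time. Every stream derives from
`SeedSequence((base_seed, position, replicate, copy))`, so ensembles are
bit-reproducible and any nucleus can be regenerated alone.

## Statistics

Series are regularized by averaging samples within each integer minute;
empty minutes are flagged as gaps, and no per-minute change is computed
across a gap. Changes are `Δcount/Δt` in transcripts/min. The ACF uses the
standard biased sample estimator with Bartlett cumulative significance
limits `± t(0.975, df=n)·sqrt((1+2Σ_{j<k} r_j²)/n)` (the display convention
of classical ACF tools); the default maximum lag is `n/4`, and a
Monte-Carlo check confirms each lag's flag fires ≈5% of the time under
white noise. Rate histograms use integer-aligned classes of width 2
(class 0 = "0–1 additions per minute"); pooling sums counts class-wise.
The mechanism comparison is Pearson's χ² of independence on the 2×K table
of classes whose count exceeds 5 in *both* pooled histograms (a symmetric
reading of the count filter), df = K−1, with per-class contributions
reported. `compare_mechanisms` can restrict the test to net-addition
classes (`classes="additions"`), the 8-bar layout in which the strongest
contributions sit at the 2–3, 8–9 and 12–13 classes; the full-range test is
the default and separates the default mechanisms more strongly (p ~ 1e-4)
than the additions-only variant (p ~ 0.03), partly because the one-state
mechanism's printed constants overproduce mRNA (~276 vs 230).

Dwell fractions (OFF / LOW `E[1000]` / HIGH `E[1100]`) are computed two
ways — exact time-in-state from the event log, and per-minute
classification by dominant state — because "fraction of time at a rate"
admits both readings; at the calibrated point they are close (e.g. ~45/48/7%
OFF/LOW/HIGH for the two-state mechanism).

## Synthetic data

`make_tf_profiles` generates what quantitative AP profiles would provide:
an exponential Bcd gradient (length constant 20 %EL), a logistic Hb plateau
edge at 49 %EL, and compact-support parabolic Gt/Kr domains centered at
28/53 %EL that vanish at 42 %EL, the Gt flank shallower than the Kr flank.
Absolute activator levels are anchored so the calibrated occupancies hold
at the stripe center (`[B](42) ≈ 1.55e-8 M`, `[H](42) ≈ 2.94e-8 M`);
repressor amplitudes are sized so expression is half-maximal at 38 %EL and
low posterior of 45 %EL, giving a stripe that peaks at 42 %EL, extends
further anterior than posterior, and sharpens as the repressors ramp
ten-fold. The generator reproduces the *geometry and anchors* of the real
gradients, not their measured molecule counts or embryo-to-embryo
variability; passing tests show the pipeline's internal consistency on
data with the stated structure, not fit quality to any real embryo.
`pseudo_experimental_series` adds the irregular ~1-minute sampling of live
movies (normal gaps, mean 60 s, sd 15 s, floor 20 s — configurable, not
inferred from data).

## Known limitations

- Collapsing each TF to one effective site rolls multi-site effects into
  the state initiation rates; no cooperativity or position dependence.
- No spatial coupling, diffusion, or 3-D geometry; no fluorescence
  calibration from counts to signal.
- The one-state/two-state χ² separation at default parameters is stronger
  than marginal, and is sensitive to which rate classes enter the test
  (see above).
- Change-series autocorrelation is a weak discriminator at these kinetics:
  with ~25 s occupancy correlation times, per-minute changes are nearly
  white for both mechanisms, and detections over 10 replicates sit near
  the familywise false-alarm floor of the multi-lag band (~2/10) for the
  one-state as well as the two-state mechanism.
- The unbinding-rate scan bounds the switching speed only from below
  (see Calibration, step 5).
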