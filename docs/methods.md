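# Methods

`inhibpipe` quantifies GABAergic inhibition onto dentate granule cells from
two kinds of raw data — whole-cell voltage-clamp current sweeps and
two-channel 3D confocal stacks — and validates the whole chain on synthetic
data with known ground truth. This note records the models, the estimators,
the defaults and the reasoning behind the genuinely open design choices.

## Evoked-IPSC quantification

### Waveform model of the synthetic generator

Evoked IPSCs are inward chloride currents at a holding potential of
−80 mV (high-chloride internal solutions put E_Cl near 0 mV), so all
synthetic responses are negative deflections and all reported amplitudes
are magnitudes. Each response is a difference of exponentials

    w(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise),  t ≥ 0,

normalized to unit peak. The generator is parameterized by observables,
not by the raw time constants: the requested 20–80 % rise time is
converted to τ_rise by a bracketed root solve (relative tolerance 1e−9;
the 20–80 % rise of w is monotone in τ_rise), with τ_decay taken directly
from the requested decay constant. A sweep holds two responses separated
by the inter-stimulus interval (200 ms for electrical and PV-type
protocols on 1.5 s sweeps, 500 ms for SOM-type on 2.0 s sweeps; stimulus 1
at 0.2 s, synaptic latency 1 ms), plus a −5 mV membrane-test step in the
final 250 ms of the sweep, plus i.i.d. Gaussian current noise per sweep.

Two generator details matter for parameter recovery:

* the first response is scaled so that its noiseless extremum **on the
  sample grid** equals the configured amplitude, making the planted A1
  exact rather than approximate at 20 kHz;
* the second response is scaled so that the extremum of the *summed*
  trace in the second-response window equals PPR × A1 — the small
  residual decay of the first response at the second peak is compensated
  at generation time, so the planted PPR is exactly what an analyzer
  measuring from the common pre-stimulus baseline should report.

An optional 4-pole low-pass at 8 kHz emulates the acquisition filter; it
is off by default so that analytic expectations hold exactly on the grid.

### Measurement operators

All measurements run on the pointwise mean trace across sweeps.

* **Baseline**: mean over 1,280 samples (64 ms at 20 kHz) ending at the
  first stimulus onset. The window length is fixed; its placement
  (immediately before stimulus 1) is a design choice, and the same
  baseline serves both responses — the ISI is chosen in these protocols
  so the first response has essentially decayed by the second stimulus.
* **Amplitude**: extremum of the stated polarity in a search window of
  stimulus onset + [1, 100] ms (excludes the stimulus artifact, covers
  slow rises), reported as the mean of the 5 consecutive samples centered
  on the extremum. The centered mean was chosen over a sliding-window
  maximum because it is symmetric and suppresses single-sample noise
  without a systematic bias toward larger magnitudes; ties in extremum
  location break to the earliest sample.
* **20–80 % rise**: threshold levels at 20 % and 80 % of A1 relative to
  the baseline, crossing times linearly interpolated between samples on
  the rising phase.
* **Decay**: weighted biexponential fit of the second response from the
  first post-peak sample at or below 95 % of the peak amplitude to
  250 ms after the second stimulus. The fit start is sample-aligned (no
  sub-sample interpolation), which is within one 50 μs sample period of
  the exact crossing.
* **PPR** = A2 / A1, both measured against the common baseline.
* **Detection floor**: A1 below 3× the baseline-window SD is declared a
  no-response; PPR and kinetics are then undefined. This makes the
  no-response decision deterministic on synthetic data.
* **Percent block** = 100 × (1 − A1_drug / A1_control), clipped to
  [0, 100] with a logged flag when negative.

### Biexponential fitting

The model is A_fast·exp(−t/τ_fast) + A_slow·exp(−t/τ_slow) + offset,
fit by Levenberg–Marquardt least squares (lmfit) with τ bounded to
[0.1 ms, 10× the segment length]. The reported constant is the
amplitude-weighted mean τ_w = (|A_fast|τ_fast + |A_slow|τ_slow) /
(|A_fast| + |A_slow|); absolute amplitudes make inward (negative)
currents weight correctly, and τ_w is invariant under exchange of the
component labels (components are reported with τ_fast ≤ τ_slow).

Initialization is deterministic so fits are reproducible: the offset
starts at the mean of the last 10 % of the segment, and two starting
points for the taus are tried — (i) a log-linear monoexponential
estimate of the dominant tau with the fast tau at one fifth of it, and
(ii) taus at 20 % and 80 % of the segment length — with amplitudes from
a linear solve at the fixed starting taus; the lower-RSS solution wins.
Both amplitudes are additionally constrained to the sign of the decay
(peak minus baseline). This matters: an unconstrained biexponential of a
near-monoexponential decay admits a degenerate family of almost-equal
taus with huge opposite-sign amplitudes that fits noisy data marginally
better while rendering the absolute-amplitude-weighted τ_w meaningless
(and, under noise, bimodally biased). A post-peak synaptic or capacitive
decay has same-sign components, so the constraint encodes physiology
rather than convenience. Non-convergent fits are flagged
(`converged=False`), never silently replaced by the initial guess.

On noiseless difference-of-exponentials input the measured τ_w sits
about 1–2 % below the generating τ_decay, because the fit window still
contains a trace of the (opposite-sign) rising exponential which enters
τ_w through its absolute amplitude. This is a property of the estimator
definition, not a defect, and is well inside the acceptance tolerances.

## Passive membrane properties

The membrane test is a single-compartment voltage-clamp circuit: series
resistance R_s into a membrane (R_in ∥ C). For a step ΔV the clamp
current jumps instantaneously by ΔV/R_s and relaxes with
τ = C·(R_s ∥ R_in) to a steady state ΔV/(R_s + R_in). Estimators:

* baseline: mean over 1,800 samples (90 ms) before step onset;
* R_s = |ΔV| / |ΔI_peak| with the transient peak taken as the raw
  extremum (k = 1) — the transient is far too fast for 5-sample
  smoothing, which would bias R_s upward;
* R_in = |ΔV| / |ΔI_ss| − R_s, with ΔI_ss the mean over a 50 ms window
  starting 100 ms after onset. Subtracting R_s makes R_in the membrane
  term; at a ceiling R_s of 20 MΩ this changes values by ≤ 6 % relative
  to the total-resistance reading, and it is the convention that makes
  the synthetic round trip exact;
* τ_break-in: weighted biexponential τ of the transient from 95 % of its
  peak to 20 ms after onset;
* C_p = τ_break-in / R_s. For the ideal circuit this understates the true
  capacitance by the factor R_in/(R_s + R_in) (≈ 3 % at typical values) —
  a known, documented property of this estimator family, matching the
  magnitude relationship between the reported τ, R_s and C_p of mature
  granule cells (≈ 1.5 ms / 12.6 MΩ ≈ 120 pF).

A transient smaller than 5× the baseline noise SD raises an error rather
than returning garbage. With the 8 kHz acquisition filter enabled the
sampled transient peak is attenuated, so R_s is overestimated; the
effect is asserted as monotone in the tests and documented here, not
corrected. Per-sweep R_s tracking reports 100·(max − min)/first as the
stability metric.

## Inclusion QC

Five rules, evaluated deterministically per cell: seal ≥ 1 GΩ, R_s never
above 20 MΩ, R_s change < 30 %, recording ≤ 7 h after slice preparation,
and R_in at or below the maturity cutoff. Boundary semantics follow the
wording of each rule: R_in exactly at the cutoff and R_s exactly at
20 MΩ pass; an R_s change of exactly 30 % fails. Missing metadata makes a
rule not-evaluable and excludes the cell with that reason. The default
cutoff of 550 MΩ ships as a configuration constant because the reference
population it was derived from is not available; `compute_rin_cutoff`
recomputes a cutoff from any new reference sample (n ≥ 20) as the 95th
percentile with the linear-interpolation definition — the phrase
"95-percentile of the cumulative contribution" is read as the ordinary
95th percentile of the R_in distribution.

## Imaging arm

### Synthetic stacks

Two-channel stacks (VGAT plus CB1 or PV) default to 50 × 50 × 7 μm at
0.10 × 0.10 × 0.14 μm voxels — the z-step and stack thickness of the
emulated acquisition; the lateral voxel approximates an AiryScan 40×/63×
acquisition with 2× zoom and is configurable. VGAT puncta are a uniform
Poisson process at the planted density; exactly round(frac_double × N)
of them are duplicated into the second channel with 0.05 μm Gaussian
centroid jitter (co-labeled presynaptic terminals), making the planted
double fraction exact by construction. Each punctum renders as an
anisotropic 3D Gaussian (σ 0.12 μm lateral, 0.35 μm axial — a typical
confocal PSF scale), amplitude 100 over a background of 10, followed by
Poisson photon noise and Gaussian read noise (SD 2): a nominal peak SNR
of about 10. Puncta smaller than half a voxel raise an error.

What the generator does **not** emulate: tissue texture, layer
boundaries, membrane-shaped (non-punctate) staining, bleed-through,
depth-dependent attenuation. Passing recovery tests therefore shows the
detection chain is calibrated for punctate objects at realistic density,
SNR and PSF anisotropy — not that it is robust to every real staining
artifact.

### Detection and colocalization

The workflow mirrors a spot-reconstruction pipeline with every parameter
surfaced: (1) background subtraction on the VGAT channel — a Gaussian
blur at 2 μm (≫ punctum size) is subtracted and the result clipped at
zero; (2) blob detection by negated anisotropic Laplacian-of-Gaussian at
a kernel scale of spot_diameter/4 laterally (default spot diameter
0.35 μm) stretched 2.2× axially, local maxima above quality_threshold
(default 10) times the robust noise scale (1.4826 × MAD) of the
response, with sub-voxel refinement by center of mass of the response in
a 3³ neighborhood; (3) one-to-one colocalization — candidate pairs
within 0.3 μm are sorted by centroid distance and matched greedily so
each punctum on either side is used once. Centroid-distance matching was
chosen over voxel-overlap masking as the more transparent criterion; the
radius is a config parameter for sensitivity analysis. Densities divide
counts by the whole z-stack volume (no tissue masking), and per-animal
unweighted means over the (nominally 12) stacks per animal are the
statistical units.

Defaults were calibrated on the synthetic benchmark: at well-separated
densities recall and precision exceed 0.95; at the crowded planted
density of 0.62 puncta/μm³ merge losses cost ~6 % of the count, which
propagates to the double-positive density but largely cancels in the
double-positive percentage (both channels lose puncta together).

## Statistics

* Unpaired two-tailed t-tests use the classical equal-variance form (no
  Welch correction), with the p = 1 convention for the degenerate
  zero-variance equal-means case.
* One- and two-way ANOVA are OLS-based (type-II sums of squares for the
  two-way design); rank-deficient designs raise an error naming an
  aliased term.
* Repeated-measures input–output curves use a linear mixed model with a
  random intercept per cell, REML fitting, sum-to-zero fixed-effect
  coding, and Wald F tests per term. Denominator degrees of freedom use
  the containment rule (between factor against subjects; within factor
  and interaction against the subject × within stratum), which is exact
  for balanced complete data — where the Wald F matches classical
  repeated-measures ANOVA, verified against an independent
  implementation — and a conservative approximation under missingness.
* Šídák adjustment: p_adj = 1 − (1 − p)^m, clipped at 1; never larger
  than Bonferroni.
* α = 0.05 throughout. Units: cells (electrophysiology), animals
  (imaging).

## Full-study pipeline

`run_full_study` simulates both arms at study-like sample sizes
(10 vs 9 cells × 3 intensities, 20 sweeps per recording, noise SD 20 pA;
4 vs 3 animals), runs every analysis and the statistical battery, and
writes a report comparing recovered parameters to planted truth with
pass/fail at configured tolerances. Group amplitude means, PPR, rise,
decay, densities and fractions default to the respective printed group
values of the study being emulated; per-cell amplitudes vary lognormally
with CV 0.4, matching the reported between-cell SEMs. Default stack
volume (20 × 20 × 5 μm) and stacks per animal (3) are smaller than an
acquisition session so the default study completes in well under a
minute on one CPU; both are configuration fields. Every stochastic step
derives its seed from the single run seed, every output file embeds the
config hash, and a rerun with the same config reproduces the report
exactly.

## Problem sizes used in validation

The test suite and the acceptance script regenerate everything at run
time. Recovery checks use 50-sweep recordings for the ephys quantities;
the acceptance script uses ten 50 × 50 × 7 μm stacks per imaging
condition, while the in-suite imaging recovery test uses 35 × 35 × 7 μm
stacks (still thousands of puncta per condition) to keep the suite
quick. Property suites use 100 seeded noise realizations for the fit
oracle and 2,000 simulated null datasets for type-I calibration.

## Known limitations

* The biexponential τ_w inherits a small (≲ 2 %) downward bias on
  difference-of-exponential inputs, as explained above.
* R_s from the sampled transient peak is exact only when a sample falls
  on the step onset; with the acquisition filter enabled it is biased
  upward and no correction is applied.
* The detection chain is not a reimplementation of any commercial
  spot-analysis tool; its parameters (LoG scale, threshold, radius) are
  transparent substitutes calibrated on the synthetic benchmark.
* The mixed model's containment degrees of freedom are approximate for
  unbalanced data (no Satterthwaite machinery); p-values there are
  conservative rather than exact.
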