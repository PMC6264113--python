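# Methods

`mrcploop` simulates and analyses a closed-loop brain-computer-interface (BCI)
plasticity experiment: a self-paced detector finds movement-related cortical
potentials (MRCPs) in continuous EEG, each detection triggers afferent
feedback, and the resulting change in corticospinal excitability is quantified
by TMS motor evoked potentials (MEPs) and a mixed-model inference chain. This
note records the models, defaults, and numerical choices, and what the
synthetic data do and do not emulate.

## Synthetic study data

**Background EEG.** Gaussian 1/f^α noise (α = 1 by default) generated by
spectral shaping, scaled to a per-channel RMS of 5 µV in the broadband signal.
Channels share a common-mode component: each channel is
`sqrt(rho)·common + sqrt(1−rho)·own` with `rho = 0.9` shared variance. The
common mode stands in for volume conduction and the shared reference; it is
what makes zero-sum spatial filtering profitable, exactly as on real scalp
recordings. With spatially independent noise no zero-sum filter can beat the
raw centre electrode, and a Laplacian would be pointless.

**Planted MRCP.** A smooth half-cosine negative ramp lasting `mrcp_rise`
(2 s) that reaches its most negative value, −`mrcp_amplitude`, at the
movement onset, followed by a 1 s linear return to baseline — the "initial
negativity" morphology that pre-movement potentials show, without rebound
components. Spatial profile: Cz 1.0, C3/C4/Fz/Pz 0.6, remaining electrodes
0.3, FP1 0. The default peak amplitude is 10 µV. Real MRCPs at Cz span
roughly 5–30 µV; 10 µV against 5 µV-RMS noise with 0.9 spatial correlation
was chosen once, as a realistic operating point, so that a calibrated
detector on held-out sessions lands inside the range of detection
performance reported for human participants (TPR roughly 59–96%,
0.2–4.6 false positives/min) rather than at either extreme. These numbers
are calibration choices, not measurements.

**Blinks.** Raised-cosine transients of 0.3 s and 200 µV peak on FP1 with a
5% leak into every other channel. The leak is identical across non-FP1
channels, so a zero-sum spatial filter cancels it exactly; the blink's job is
to exercise the FP1 amplitude gate, not to contaminate the surrogate channel.

**EMG.** 20–1000 Hz band-shaped noise at 0.05 mV RMS baseline with 1 s bursts
of 0.5 mV RMS starting at each movement onset (10:1 burst-to-baseline RMS).
No motor-unit structure is modelled; the bursts exist so onsets are
recoverable by envelope thresholding.

**MEP trial tables.** The generator is the generative mirror of the fitted
model: for subject i in session j at time k,

    log mean_ijk = log(baseline) + effect_jk + b_ij,   b_ij ~ N(0, tau^2)

with each block value the mean of `n_trials_per_block` independent
Gamma(shape ν) draws with that mean. Defaults: baseline 0.12 mV, τ = 0.3,
ν = 5, 15 trials per block. With one trial per block a table row is a single
Gamma(ν) observation — the exact observation model of the Gamma GLMM, used
by the recovery and link-selection simulations. The pre-intervention block is
drawn at the baseline mean *without* the random intercept, so that the
pre-MEP covariate is exogenous with a true slope of zero; if the pre block
shared `b_ij`, the covariate would partially absorb the random effect and no
ground-truth value for its coefficient would exist. BCI performance
covariates (TPR, FP/min, task time, repetitions) are uniform over the
observed participant envelopes and independent of the MEPs unless a log-scale
slope is explicitly planted (slopes are applied to covariates centred at
fixed range midpoints, so the implied regression truth does not depend on the
sample).

**What the synthetic data do not emulate.** Real EEG nonstationarity, alpha
rhythms and movement artifact other than blinks; MRCP habituation and
amplitude variability; EMG motor-unit physiology; any dependence of plasticity
on detection accuracy (effects are planted, not emergent). Passing tests
therefore demonstrate that the pipeline recovers what was planted under its
own assumptions — not that those assumptions hold for any particular
laboratory's recordings.

## Signal chain and detector

Calibration uses the offline chain: 2nd-order zero-phase Butterworth
band-pass 0.05–10 Hz (forward–backward `sosfiltfilt` with edge padding of
3/low-corner seconds, capped by the record length), decimation by the integer
factor to 32 Hz (the 10 Hz low-pass is the anti-alias filter; 2048/32 = 64
exactly), then a zero-sum spatial filter centred on Cz. Onsets within 5 s of
either record edge are excluded from template extraction because the 0.05 Hz
corner settles very slowly.

**Spatial weights.** The weights maximize template-window SNR — power of the
onset-locked epoch average over power of the epoch-to-epoch residual — as a
generalized Rayleigh quotient restricted to the zero-sum, FP1-free subspace,
solved by a symmetric generalized eigenproblem with a small ridge on the
noise covariance. The fixed large-Laplacian (Cz 1, C3/C4/Fz/Pz −0.25) is
returned whenever the eigenproblem is ill-conditioned, the best attainable
SNR does not exceed 1 (no recoverable evoked signal, e.g. white-noise
epochs), or the solution violates the centre-dominance invariant.

**EMG onsets.** Rectify, zero-phase 2nd-order low-pass at 10 Hz, threshold at
baseline mean + 3 SD (baseline = first 5 s), sustained ≥ 50 ms, minimum
separation 6 s. The envelope cutoff is 10 Hz rather than a more conventional
5 Hz because the zero-phase envelope smears the burst edge backwards: at 5 Hz
the measured onset bias on noiseless bursts is −66 ms, at 10 Hz −34 ms, which
keeps recovered onsets within ±50 ms of ground truth.

**Template and matching.** The template is the mean-subtracted epoch average
of the 2 s preceding each onset, at 32 Hz. The detector output is the
Pearson correlation between the template and the signal window ending at the
current sample — normalization makes the threshold scale-free across
subjects, which matters because absolute MRCP amplitude varies several-fold
between people.

**Calibration ROC.** Detections for threshold sweeping are similarity *peaks*
pruned to a minimum separation of one lockout interval (5 s), counted against
the true onsets by one-to-one greedy interval matching (±1 s tolerance).
Counting pruned peaks rather than raw threshold crossings makes both the TPR
and the FP rate non-increasing in the threshold by construction; crossing
counts are not monotone (a single excursion can split into several at a
higher level, and lockout suppression can flip a detection between TP and FP
between adjacent thresholds).

The ROC is computed on the *causally* filtered training trace even though the
template comes from the zero-phase chain, because the threshold must hold
under deployment conditions: the causal band-pass both weakens the signal
match and makes 1/f background noticeably more template-like (measured
noise-peak 90th percentile rises from ≈0.76 to ≈0.85), so thresholds swept on
the zero-phase trace do not transfer. Threshold policy: maximize TPR subject
to ≤ 10 false positives per 10 min; among ties the *lowest* feasible
threshold is returned, leaving the widest margin below the training peaks
for unseen epochs (the training match is self-fitted and therefore
optimistic). If no threshold is feasible the one closest to the ideal corner
(TPR 1, FP 0, FP axis scaled by the ceiling) is used.

**Online pass.** Causal 2nd-order Butterworth (zero-phase filtering is
impossible causally — this train/online filter discrepancy is deliberate and
its cost is absorbed by calibrating the threshold on the causal trace),
decimation, spatial filter, sliding correlation; a detection fires on an
upward threshold crossing, then the detector is disabled for 5 s; no sample
may fire while |FP1| > 125 µV or within a 0.5 s guard window after such an
excursion (blink tails). The gate is evaluated on the raw FP1 trace.
Detections are labelled TP/FP against true onsets one-to-one within ±1 s;
unmatched onsets are misses. ±1 s is the tolerance self-paced MRCP systems
typically accept; the causal filter's group delay (~0.2–0.5 s at MRCP
frequencies) sits comfortably inside it.

**Intervention.** Imagery events arrive at uniform 8–16 s intervals (above
the lockout; yields task times in the observed 7–23 min range at realistic
hit rates). The session stops at the instant of the 50th true positive;
detections and misses after that instant are discarded. Metrics:
TPR = TP/(TP+FN)·100 (the denominator counts confirmed detections plus
reported misses), FP/min = FP/T, repetitions = TP+FN. Whether false positives
during the lockout should be counted is ambiguous; here crossings during
lockout simply cannot fire, so they are not counted.

## MEP quantification

Peak-peak amplitude is max − min in a 20–60 ms post-stimulus window (typical
tibialis anterior MEP latency band); blocks average 15 trials; percent change
is (post − pre)/pre·100. The resting motor threshold scan walks an ascending
stimulator-output grid and returns the first output where ≥ 5 of 10 drawn
MEPs exceed 50 µV. The bundled sigmoid response model has lognormal
trial-to-trial variability with an exceedance probability of exactly 0.5 at
its `p50` output.

## Statistical chain

All designs are treatment-coded with reference cell (ES, post); continuous
covariates enter untransformed.

**Gaussian LMM** (covariate screen, percent-change model). Scalar
random-intercept model fitted by profiled REML over the variance ratio
λ = τ²/σ²: for fixed λ the GLS fixed effects and σ² are closed-form via the
Woodbury identity, leaving a bounded 1-D search on log λ (with an explicit
boundary check at λ = 0; boundary fits are reported as singular with a
warning, not an error). Estimates agree with statsmodels `MixedLM` to ≥ 5
digits in the test suite. Satterthwaite denominator df for a contrast ℓ'β̂:
df = 2f²/(g'Ag) with f = ℓ'C(θ)ℓ, g its numeric gradient over θ = (σ², τ²)
and A the inverse observed information of the REML criterion (numeric
Hessian) — the lmerTest construction. df is clipped to [1, n−p] and falls
back to n−p at boundary fits or numerically degenerate Hessians.

**Covariate screen.** The blinded model (session deliberately withheld)
MEPabs ~ pre-MEP + Time + TPR + FPm + Tt + Mr + (1|Subject). Each performance
covariate's semi-partial R² is the Wald R²β: R² = F/(F + df)·100 with
F = (β̂/se)² and Satterthwaite df; covariates at or above 5% are selected.
This is a deliberate, documented substitute for a Kenward–Roger-based R²:
the estimand is the same, but the small-sample covariance correction is not
implemented, so values near the 5% cutoff may differ by a few points from a
Kenward–Roger implementation. Exactly collinear designs raise an error
naming the offending columns; numerically exact fits (residual variance at
machine zero) short-circuit to R² = 100 for the responsible covariate and 0
for coefficients at machine zero.

**Gamma GLMM** (absolute amplitudes):
MEPabs ~ Session×Time + pre-MEP + Tt + (1|Subject:Session), Gamma
observation model. The scalar random intercept is integrated out by adaptive
Gauss–Hermite quadrature, 15 nodes by default, centred and scaled at the
per-group Laplace mode. With the log link the per-group mode has closed-form
Newton updates (the likelihood depends on the group only through Σy·e^(−η)
and the group size); with the identity link the mode search is damped Newton
with feasibility clipping (means must stay positive) and node contributions
below the positivity floor drop out of the quadrature. Modes are
warm-started across likelihood evaluations. The outer optimizer is bounded
L-BFGS-B over (β, log ν, log τ) with Gamma-GLM starting values (a
least-squares warm start from the log fit's predictions for the identity
link), a Nelder–Mead polish on non-convergence, and a convergence error
carrying the gradient norm if no finite optimum is reached. Standard errors
come from the inverse numeric Hessian of the marginal likelihood. With τ
pinned at 0 the likelihood collapses to the plain Gamma GLM, which is the
oracle-equivalence check in the tests. Wald z statistics are used for
Gamma-model inference; Satterthwaite t for Gaussian models.

**AICc.** −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects, shape
and RE-SD; undefined (an error) for n ≤ k+1. Link selection fits both links
and takes the lower AICc; an identity fit that fails to converge cannot be
selected. At the study's own size (72 rows) the two links are nearly
indistinguishable and the AICc difference is small and seed-dependent; the
link-selection simulations therefore run at 150 subjects, where the log link
wins reliably on log-generated data.

**Marginal effects.** Predicted (session, time) cell means at covariate
sample means, on the response scale (exp of the linear predictor for the log
link, i.e. conditional on a zero random intercept), with delta-method SEs.
Requests outside the observed covariate range warn about extrapolation.

**Tukey-adjusted contrasts.** All pairwise cell contrasts within a family —
the three session contrasts at a fixed time, or the single post/post-30
contrast within a session. Log-link contrasts are exponentiated to
response-scale ratios with delta-method SEs. The family-wise adjustment is
the equicoordinate tail of the contrasts' joint normal/t distribution (what
marginal-means software computes; the classical equal-n studentized range
does not apply to mixed-model contrasts). Contrast families are rank
deficient (3 contrasts of 3 cells span a 2-D space), where library
multivariate-t box probabilities are unreliable, so the tail
P(max|T| ≥ t) is evaluated by scrambled-Sobol quasi-Monte Carlo over the
underlying full-rank Gaussian with a shared chi-distributed denominator
(2^17 points, fixed seed; agreement with the studentized range on the
balanced Gaussian toy is ~4·10⁻⁴). Adjusted p-values are floored at the raw
two-sided p, which both preserves the monotonicity guarantee and absorbs the
QMC integration error. For Gaussian fits the family's multivariate-t df is
the minimum Satterthwaite df across the family.

**Repeated-measures ANOVA.** Subject-blocked one-way decomposition for the
per-session performance metrics: F with (k−1, (k−1)(n−1)) df — (2, 22) for
12 subjects and 3 sessions. Cross-checked against pingouin.

## Problem sizes and reproducibility

Every generator and fit is a pure function of its explicit seed; the
acceptance script derives all seeds from a single `--seed` via
`SeedSequence.spawn`. The simulation studies use the sizes their questions
need: detector checks run on 7–10 min sessions; GLMM recovery and link
selection use 150 subjects (100 and 200 replicates respectively), where
per-coefficient 2-SE coverage and AICc discrimination are meaningful; the
family-wise-error and screen simulations use the study's own 12- and
100-subject scales (200 and 100 replicates). The analysis scripts default to
a handful of subjects for the interactive demo and accept a subject count on
the command line.

## Known limitations

- Kenward–Roger covariance corrections are not implemented (screen values
  near the 5% cutoff are approximation-sensitive); no bootstrap CIs; no
  Bayesian fits.
- The identity-link Gamma mode search is damped rather than provably
  convergent (the log joint need not be concave in the random intercept);
  in practice the quadrature nodes bracket the mode and failures surface as
  convergence errors rather than silent bias.
- The online detector is simulated block-free at the 32 Hz hop; true
  streaming latency (buffering, hardware) is not modelled.
- EDF export is not provided; signals round-trip through long-format CSV.
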