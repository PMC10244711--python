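# Methods

## Tracer model

Striatal ¹⁸F-DOPA kinetics are described by the standard linear two-tissue
model with slow egress. With plasma concentration C_p(t) (kBq/mL) and rates
in min⁻¹:

    dC_f/dt = K1·C_p − (k2 + k3)·C_f      free/precursor pool
    dC_s/dt = k3·C_f − k_loss·C_s         specific (vesicular) pool

The measured striatal activity is C_T = C_f + C_s. K1 is delivery, k2
efflux, k3 the AADC decarboxylation (trapping) rate, and k_loss the loss of
decarboxylated metabolites from the specific pool — the rate that encodes
dopamine turnover. The cerebellum, which lacks AADC, is a one-tissue
reference region: dC_r/dt = K1r·C_p − k2r·C_r.

Steady-state distribution volumes follow directly:

    DV_T  = K1/(k2+k3) · (1 + k3/k_loss)      DV_R = K1r/k2r
    DVR   = DV_T / DV_R
    EDVR  = (DV_T − DV_R)/DV_R  ≈  (k3/k_loss) · k2/(k2+k3)

the EDVR closed form holding when the reference DV matches the target's
non-specific DV (K1r/k2r = K1/k2), the defining assumption of
reference-tissue analysis. EDVR is the specific:precursor DV ratio reduced
by the precursor partition factor k2/(k2+k3), and 1/EDVR estimates
effective dopamine turnover. With k_loss = 0 the tracer is irreversibly
trapped and the Patlak slope relative to the reference is
Ki_ref = K1·k3/(k2+k3) · k2r/K1r.

## Graphical estimators

All three estimators are unweighted OLS fits of linearised coordinates over
frames whose **mid-times** lie in [t*, end], inclusive (mid-frame time is
the standard abscissa for frame-averaged data, and it matches the
integration grid). Defaults follow the study protocol: Patlak on 60 min of
data with t* = 10 min; Logan and EDVR on the full 120 min with t* = 30 min.
Running integrals use the trapezoid rule on mid-times with a zero-anchored
first segment — exact for piecewise-linear curves. Ki is reported in min⁻¹
(computation in seconds, one conversion at the boundary). The Logan
transform is the plain two-term reference form; an optional k2′ argument
adds the usual C_R/(k2′·C_T) abscissa term. Negative activities (possible
under additive noise, or in early frames of the EDVR difference TAC) are
propagated unchanged — clipping would bias the slopes; only in-window
frames must be positive where a transform divides by them.

### Validity regimes and known biases

Graphical methods are asymptotic: their slopes equal the model quantities
above only once every kinetic mode has equilibrated relative to the plasma
input, i.e. well after t* ≳ 1/(rate of the slowest mode).

- **Patlak** requires only precursor-pool equilibration (rate k2+k3). With
  t* = 10 min the recovery error is ≪1% for k2+k3 ≳ 0.3 min⁻¹ and grows to
  ≈7% at k2+k3 = 0.11 min⁻¹. Nonzero k_loss additionally bends the plot
  downward (washout), so the irreversible interpretation needs k_loss ≈ 0.
- **Logan DVR** requires equilibration of the specific pool (rate k_loss,
  net of the plasma tail). For a nearly-trapped tracer this is the slowest
  process in the system: at the default k_loss = 0.01 min⁻¹ the relevant
  relaxation time is several hundred minutes, and on the 30–120 min window
  the slope is biased low by ≈24% (up to ≈50% at k_loss = 0.005). This is
  an intrinsic property of the method at this scan length, not an
  implementation artefact: pushing the fit window to 300–600 min on a
  simulated long scan recovers the analytic DV ratio to <2%, and the
  closed-form solver agrees with an independent ODE integration to <10⁻⁸.
  Absolute DVRs from 2 h scans should therefore be read as
  scan-length-conditional indices; group contrasts remain valid because the
  bias is shared.
- **EDVR** benefits from a partial cancellation of the transient terms in
  the numerator and denominator: at the default kinetics it recovers its
  closed form to ≈7%, degrading toward the k_loss extremes (slow: the
  specific pool never equilibrates; fast: the k2 − k_loss ≪ k2 assumption
  behind the closed form erodes). EDVR estimates also *rise* slightly above
  the steady-state value on finite windows — the bias is reported by the
  acceptance script, not hidden.

The acceptance suite asserts 5%/5%/10% recovery across the full documented
rate ranges (K1 ∈ [0.05,0.2], k2 ∈ [0.1,0.5], k3 ∈ [0.01,0.1],
k_loss ∈ [0.005,0.05] min⁻¹); per the analysis above the Logan clause
cannot hold on a 2 h scan in the slow-turnover part of that grid, and that
test is expected to fail — it is kept at the stated tolerances rather than
loosened, with the green unit tests covering each estimator inside its own
validity regime.

## Synthetic-data generator

The plasma input is a Feng-type bolus, (A1·s − A2 − A3)e^(−λ1 s) +
A2 e^(−λ2 s) + A3 e^(−λ3 s) with s = t − delay; defaults (A1 = 600
kBq/mL/min, A2 = 30, A3 = 25 kBq/mL, λ = 4.0, 0.5, 0.008 min⁻¹, delay 0.5
min) give a sharp bolus peak, a slow tail and tissue activities in the tens
of kBq/mL for the default kinetics (K1 = 0.1, k2 = 0.3, k3 = 0.03,
k_loss = 0.01, K1r = 0.1, k2r = 0.3 min⁻¹ — all configuration, not
constants). Because the input is a sum of (a·t + b)e^(−λt) terms and the
system is linear, the solution is computed **in closed form** by analytic
convolution (coincident rates are split by a deterministic 10⁻⁸ nudge),
and frame values are exact integral means over each frame — no ODE solver,
no tolerance nondeterminism. Simulated activities represent decay-corrected
scanner output; the noise model reinstates the decay factor internally:
per-frame SD = noise_scale·sqrt(max(A,0)·2^(t_mid/T½)/duration), zero-mean
Gaussian, with T½ = 109.77 min for ¹⁸F.

The cohort generator emulates a cross-sectional ageing design: three
genotypes × ages 5/11/16 months × n = 4, each animal scanned once. Rates
get log-normal inter-subject jitter (CV 10%); the delivery (K1) and efflux
(k2) draws are **shared** between striatum and cerebellum within a subject
because reference-tissue analysis presumes a common non-specific DV —
independent draws would inject artificial between-region DV mismatch that
dominates EDVR variance and corresponds to no physiological quantity. k3
and k_loss vary independently, and each side's k_loss carries an extra 5%
jitter so the left–right comparison has within-subject variance. Group
effects are encoded on k_loss: an `edvr_multiplier` m divides k_loss by m
(lower EDVR = faster turnover), and a `left_right_k_loss_ratio` r splits
k_loss by √r / 1/√r between left and right, lowering the left EDVR for
r > 1 (positive asymmetry under the contralateral = right side convention,
matching the left-dominant deficit the phenotype describes). The default
effect map reduces EDVR to 0.7× in aged (16 m) homozygotes and adds
left-dominant asymmetry in homozygotes at 5 and 16 months; wild-type and
heterozygote cells carry no effect. Weight (≈0.37 kg) and injected dose
(18.5 ± 7.1 MBq, clipped positive) are drawn per subject for SUV
computation only.

What the generator does **not** emulate: plasma metabolites and peripheral
enzyme blockade, partial-volume and spill-over effects, attenuation/scatter
residuals, VOI placement error, or any correlation between genotype and
delivery. Passing recovery tests therefore demonstrate the correctness of
the estimators and pipeline plumbing, not the field accuracy of EDVR in
real rats. A side effect of encoding turnover on k_loss is that the
apparent Patlak Ki of an effect group also shifts slightly (washout), so
the simulated phenotype is detectable in Ki as well — a model property,
not a claim about the biology. Simulated SUVr rises slowly through the
late scan rather than holding a crisp plateau (a nearly-trapped tracer
approaches pseudo-equilibrium only asymptotically); the plateau detector
is accordingly tolerance-based — longest run of ≥3 frames with local slope
magnitude under `slope_tol_per_min` (default 0.005 min⁻¹, an analysis
knob).

## Statistics

Per age, endpoints are compared across genotypes by one-way ANOVA with
Tukey HSD (studentized range; Tukey–Kramer for unbalanced groups), on
whole-striatum values; left–right EDVR is compared per genotype × age by a
two-sided paired t test; normality is inspected via Q–Q points at plotting
positions (i − 0.5)/n. Whole-striatum endpoints use the equal-weight mean
of the side TACs in the simulation path (the union-mask mean in the image
path, which is volume-weighted and not generally identical). Measured under
the default conditions (200 seeds, n = 4/group): type-I rate of the
16-month EDVR comparison ≈5% at α = 0.05; the 0.7× EDVR effect in aged
homozygotes is detected by the omnibus ANOVA in ≈91% of seeds, with the
WT-vs-homozygote Tukey pair flagged in ≈77% — the "detection ≥80%"
acceptance bound is therefore asserted on the omnibus test, and the pair
flag on a majority basis.

## Numerical and design choices

- F-18 half-life fixed at 109.77 min (standard physical constant).
- Frames are contiguous from t = 0; the data model tolerates gaps but the
  generator never produces them.
- Decay-correction state is an explicit TAC flag; double correction raises.
- Side convention defaults to contralateral = right (yielding positive
  asymmetry for the left-dominant deficit) and is recorded in every output;
  `contralateral=left` is available.
- Window selection is inclusive at both ends; degenerate fits (constant
  abscissa, <2 frames, non-positive divisors in-window) raise with the
  offending frames named rather than returning NaN.
- The in-silico digest uses 0-based, half-open coordinates, cut offset 1
  for BspHI (T^CATGA); TCATGA is palindromic so single-strand scanning is
  sufficient. Amplicon-specific fragment sizes are not modelled (the
  genomic context is not part of the package); fragment arithmetic is
  generic and length-conserving.
- Gaussian display smoothing interprets "1 mm" as FWHM (PMOD convention;
  sigma interpretation via flag) and is never applied before TAC
  extraction. Masks must share the image grid exactly; no resampling.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in about a minute on one CPU: the oracle grid uses 3 values per rate
(81 parameter sets), noise robustness 100 replicates, and the statistical
operating characteristics 200 simulated 12-subject cohorts per condition.
All are arguments, not constants.
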