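# Methods

This note documents the models, numerical choices and limitations behind
`cordmpm`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Signal models

**FLASH steady state.** The exact model is the ideally spoiled
gradient-echo steady state, extended with a per-TR saturation fraction
`δ` applied to the longitudinal magnetisation before each excitation
(the MT-FLASH experiment):

    S_exact = A·sin(a)·(1−δ)·(1−E1) / (1 − (1−δ)·cos(a)·E1),  E1 = exp(−TR/T1).

The estimation chain inverts the small-angle/short-TR rational
approximation

    S ≈ A·a·TR·R1 / (a²/2 + δ + TR·R1),

which is algebraically invertible from two (PDw, T1w) or three (plus
MTw) contrasts. At the default acquisition settings the two models agree
to < 0.1% at 6° and < 1% at 20° over T1 ∈ [800, 4500] ms (property test).
Inverting exact-model signals with the rational form overestimates T1 by
≈ +1.3% at 1800 ms (1824 ms recovered) and by at most ~1.6% over
[800, 2500] ms; the brute-force numerical inversion of the exact model
(a root find on the PDw/T1w signal ratio) recovers the truth exactly and
anchors this bias measurement.

**Echo decay and TE = 0 correction.** Each contrast is simulated and
fitted as `S(TE) = S(0)·exp(−R2*·TE)`. R2* is fitted by unweighted OLS of
log-signal against TE on the PDw echoes; unweighted because noise
weighting is itself biased at low SNR, and the heteroscedasticity of
log-transformed magnitudes is a known, accepted limitation of the
log-linear approach. Because the three contrasts average different echo
sets (six versus five echoes), their echo averages carry different T2*
weighting. `estimate_all` therefore divides each averaged volume by
`mean_i exp(−R2*·TE_i)` (using the fitted R2*) before inverting the
signal equations. This makes the forward-inverse round trip exact to
floating-point precision on noiseless data and removes a ~3% T1 bias
that differential T2* weighting would otherwise cause. The correction
assumes a common R2* across contrasts, which holds in the phantom and is
a reasonable approximation in vivo.

**AFI.** The transmit map uses the idealised ratio model
`r = (1 + n·cos a)/(n + cos a)`; the estimator is its exact inverse, so
the noiseless round trip is exact by construction. T1 dependence of AFI
is neglected on both sides (simulation and estimation), which is a
modelling choice, not an approximation error — the residual T1
sensitivity of real AFI is out of scope.

**MT saturation and B1.** δ is estimated at the *nominal* MT-contrast
flip angle, without B1 correction. In the simulator the local transmit
factor f scales the excitation angle of every contrast and scales δ as
δ·f² (the saturating effect of the off-resonance pulse grows with the
square of its amplitude, to leading order). Under these two effects the
nominal-angle estimate of δ is exactly compensated in the rational
model: the f²-biased R1 and f-biased A cancel the f-scaled readout and
the f²-scaled saturation. The acceptance script measures MT saturation
deviations at machine precision while MTR shifts by 8–19% over
f ∈ {80, 90, 110, 120}%. Omitting the δ·f² scaling (`mt_b1_scaling=False`)
breaks this compensation and makes MT saturation *more* B1-sensitive
than MTR — the scaling is therefore essential to emulating the method's
central robustness property. T1 and APD, by contrast, are corrected with
the measured B1 map (effective angles f·a) by default.

## The digital phantom

The phantom emulates an axial cervical-cord acquisition: a WM disc
(split into dorsal and two mirror-image lateral columns by angular
sectors), a central GM butterfly, a CSF annulus, and — around the canal —
paraspinal soft tissue and a vertebral column (bodies with curved
endplates alternating with discs along z). The cord radius tapers
linearly along z (0.4%/mm). Default grid 64×64×30 at 1×1×3 mm.

Tissue parameters default to healthy-adult cord values (per-column APD,
T1, MT saturation and R2*); CSF, surround and vertebra values are
literature-plausible configuration defaults. Acquisition defaults: PDw
TR 24.05 ms/6° with six echoes equally spaced over 3.0–18.55 ms; T1w TR
22 ms/20°, five echoes; MTw five echoes with a 4 ms Gaussian MT pulse
(220° nominal, 2 kHz offset) and — since the MT readout is not otherwise
constrained — the PDw excitation settings, configurable; AFI 60°,
TR 50/150 ms.

The surround anatomy and the taper exist for a scientific reason: a cord
floating in empty background leaves axial rotation and through-slice
translation nearly unobservable to any intensity-driven registration
(the cross-section is close to circular and, untapered, identical in
every slice). Measured on the cord-only phantom, axial-rotation errors
reached several degrees; with the surround the worst-case recovery over
±3 mm/±3° motions is ≈ 0.3 mm / 0.1°. In vivo the same role is played by
the vertebrae and neck musculature inside the field of view. Setting
`with_surround=False` restores a six-label cord-only phantom.

**Noise.** σ is defined as (mean noiseless WM signal of the first
echo)/SNR, one unambiguous scalar per scan. Rician noise is
`|S + N(0,σ) + i·N(0,σ)|`; the background mean of σ·√(π/2) is verified by
Monte Carlo. All randomness flows from a single seed; outputs are
bit-reproducible.

**Cohorts.** Inter-subject variation is modelled as one multiplicative
factor per parameter per subject, shared across cord tissues (global
biological variation). Independent per-tissue draws would partially
average out in whole-cord means and could not realise a prescribed
whole-cord CoV. A target MTR CoV is injected by inverting the
approximate MTR relation for δ at fixed T1. Draws that would go
non-physical are truncated (T1 at 100 ms) and logged.

**What the phantom does not emulate.** k-space sampling, partial volume
beyond voxelisation, receive-field inhomogeneity (APD is uncorrected by
design), B0 effects, physiological within-scan motion, slab profiles,
and MT pulse-shape/lineshape physics (the MT effect is a per-tissue δ
with a B1² amplitude scaling). Passing tests therefore demonstrate the
correctness and numerical robustness of the estimation and registration
chain under the stated generative model — not in-vivo accuracy against
these unmodelled effects.

## Registration

6-DOF rigid transforms (translations mm, rotations deg about the volume
centre, applied x→y→z), normalised mutual information
`(H(A)+H(B))/H(A,B)` from a 64-bin joint histogram over each image's
0.5–99.5 percentile range, derivative-free Powell search with a 2-level
multi-resolution pyramid (2× block-mean, then full resolution), bounds
±10 mm/±10°, 1 mm ≙ 1° parameter scaling.

Four numerical choices in the cost, each fixing a failure mode measured
during development:

1. **Off-grid jittered sampling** (frozen uniform jitter, 0.25 voxel
   in-plane, 0.5 voxel through-slice): grid-aligned sampling biases NMI
   optima toward integer-voxel shifts (up to half a slice thickness in
   z); sampling both images at the same off-grid points removes the
   asymmetry between "no interpolation" and "interpolated" states.
2. **Cubic-spline sampling of both images** during the search: linear
   interpolation's offset-dependent blur leaves a ~0.35 mm cross-contrast
   bias in the thick-slice direction; cubic halves it. Final resampling
   of data uses a Hann-windowed sinc kernel with 7-voxel support and
   per-axis weight normalisation (integer shifts are exact).
3. **Overlap-restricted histograms**: zero-filled out-of-field samples
   otherwise pull the optimum toward maximum overlap (tz → 0 for
   slice-sized shifts).
4. **Coarse-level multi-start over axial-rotation offsets** (±3°, ±6°,
   plus tilt seeds): the near-circular cross-section creates shallow
   side basins in the axial rotation.

At full resolution a random half of the sample points is histogrammed
(measured: no accuracy change, half the cost). The search interpolation
is intentionally cheaper than the final sinc resampling; every echo used
for fitting is interpolated exactly once, under the step-4 transform.

The four-step scheme re-registers the MTw average to the step-3 target by
default (`reregister_mtw=False` pins it), and target construction
normalises each volume by its robust mean before averaging.

## Statistics

Sample (n−1) SDs throughout. CoV = 100·SD/mean across subjects.
Odd/even robustness = 100·SD/mean of the two half-data values
(SD of a pair = |a−b|/√2). Paired t-tests are two-sided with n−1 df.
ICC defaults to the one-way random-effects single-measure form
(MSB−MSW)/(MSB+MSW) for k = 2 — the two half-echo analyses are not
distinguishable raters — with the two-way absolute-agreement form
available; both are cross-checked against an independent implementation
in the tests. No multiple-testing correction is applied by default,
matching the uncorrected p < 0.05 convention of the analysis this
package reproduces; a Bonferroni flag is deliberately out of scope of
the default path.

Robustness-versus-noise behaviour is asserted on *cross-subject medians*
(9 simulated subjects per SNR in the tests): a single subject's odd/even
difference is a half-normal draw whose ordering between adjacent SNR
levels inverts with ~30% probability, so a per-subject monotonicity
claim would be statistically meaningless.

## Problem sizes and determinism

Default analyses run on the 64×64×30 phantom; interpolation-heavy unit
tests use a 32×32×12 variant; the acceptance script uses 9 subjects per
SNR level for robustness medians and 13 subjects for cohort statistics —
sizes chosen so the whole validation runs in minutes on one CPU while
keeping every statistical check comfortably powered. Registration
accuracy was validated on the full-size phantom. All stochastic stages
(noise, cohort draws) derive from a single integer seed;
subject-level streams are spawned with `numpy` seed sequences, so any
subset of subjects is reproducible independently.

## Known limitations

* The registration accuracy figures hold for the phantom's contrast and
  geometry; real data with artefacts, intensity non-uniformity or
  different surround anatomy will behave differently.
* The decay correction assumes one R2* per voxel shared by the three
  contrasts.
* The AFI model neglects T1 and slab-profile effects; the B1 map is
  smooth by construction, so the default 8 mm FWHM smoothing is benign in
  simulation but is a tunable assumption for real maps.
* MT saturation values are tied to the specific MT pulse and readout
  settings; they are comparable across subjects scanned with one
  protocol, not across protocols.
* Segmentation is out of scope: cord and column masks are inputs (the
  phantom supplies its truth labels).
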