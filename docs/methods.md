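# Methods

`sirkit` implements a stimulus-information-representation analysis for
Bubbles experiments with simultaneous EEG: it quantifies, with mutual
information (MI), which stimulus pixels drive behaviour, where and when
single-trial EEG represents those pixels, and how much of that neural
representation is behaviourally relevant (co-information redundancy) — and it
ships a synthetic-experiment generator that injects known ground truth so
every stage is testable without any recorded data. This note documents the
models, the estimators, the numerical choices, and what the synthetic tests
do and do not establish.

## The synthetic experiment

The generator emulates a face-versus-noise detection task in two age groups
("young", "older"). Defaults are full study-scale conditions; everything is
configurable through `CohortConfig`.

**Stimuli.** Ten schematic base identities are drawn procedurally (oval face,
eyes, brows, nose, mouth) on a 128×128 grid spanning 9.3° of visual angle
(13.8 px/°), with the face oval at 4.9° × 7.0°. The base set is zero-mean and
amplitude-equalised: every identity's Fourier amplitude spectrum is replaced
by the set mean (zero DC). A unique image per trial mixes the original phase
Φ with random phase Φr by circular interpolation,
Φc = angle(c·e^{iΦ} + (1−c)·e^{iΦr}), at coherence c = 0.7 for faces and
c = 0 for noise textures, so all stimuli share one amplitude spectrum
exactly. One affine map (common to all stimuli from a base set, 10% headroom)
takes textures to [0, 1] around mid-gray; because it is common and the DC is
zero, spectra remain identical after display mapping. The mid-gray surround
of the *displayed* stimulus arises from bubble masking: revealed =
0.5 + mask·(stimulus − 0.5), and aperture centres never leave the face oval.
A hard post-hoc crop would have destroyed the shared-spectrum property, so it
is deliberately not applied to the texture itself.

**Bubble masks.** Each trial reveals the image through 10 Gaussian apertures
(σ = 0.36°), centres uniform inside the face oval. Overlapping apertures
combine by pointwise maximum, keeping mask values interpretable as revelation
in [0, 1] (the alternative, summation, can exceed 1 and changes the marginal
distribution of visibility; either choice is defensible — maximum was fixed
here). Analyses run on the mask stack block-averaged to a configurable
resolution (64×64 default, 32×32 at demo scale) for desk-scale runtimes.

**Behaviour.** Eye regions are circles of radius 0.5° at the canonical eye
coordinates; per-trial eye visibility is the mean mask value inside the
region (mean rather than maximum: smooth in bubble overlap). On face trials
RT = (base − slope·v_left)·exp(ε), ε ~ N(0, σ_rt) — the left eye is the
diagnostic feature; noise-trial RTs are feature-independent, so noise-trial
classification images are null by construction. Multiplicative lognormal
noise keeps RT strictly positive without redraws; configurations whose
base − slope could reach zero are rejected at construction. Face-trial
accuracy increases with eye visibility; noise-trial accuracy is a high
constant (0.95). Group RT bases default to 380/580 ms, the ~200 ms
behavioural delay.

**EEG.** Epochs are white noise (sd 6) plus a deterministic evoked template —
a unit-peak alpha function starting at 70 ms (τ = 60 ms) with a fixed
electrode-gain topography — plus, on the lateral-occipital electrodes only, a
negative Gaussian N170-window component (width 10 ms) centred at the group's
eye-coding latency (170 vs 210 ms: the 40 ms neural ground truth) with
per-trial latency jitter (sd 2 ms) and amplitude base + gain·visibility of
the *contralateral* eye (left eye on RE, right eye on LE) on face trials.
The ipsilateral-hemisphere gain ratio is 0.5, which reproduces a hemispheric
lateralization index near −0.2 (right dominance). Oz carries a weaker
component mixing several features; all remaining electrodes are evoked-only,
so the global ERP_STD onset carries no group information. Sampling is 500 Hz
with epochs −300…1000 ms.

**Chosen signal-to-noise.** Gains (90 young / 65 older; the ratio emulates
the weaker representation observed in older adults), noise sd, jitter and
between-participant latency spread (sd 1.5 ms) were fixed once, at design
time, such that the package's stated recovery property — the injected 40 ms
delay recovered within ±4 ms (two samples) from demo-scale cohorts of six
participants per group — is a property of the default conditions
(per-cohort recovery error sd ≈ 1.9 ms in design measurements). Real
cohorts have far larger inter-individual spread; with 6 participants per
group a ±4 ms tolerance is only attainable when individual differences are
modest, and the defaults encode that regime explicitly.

**What the generator does not emulate.** Photographic stimuli; eye movements
and overt attention; 1/f EEG spectra, alpha rhythms or artifacts (noise is
white); volume conduction and realistic topographies; acquisition filtering
(epochs are generated analysis-ready, so the causal/noncausal filtered
dataset distinction collapses and the onset analysis runs on the only
dataset there is); trial rejection and channel interpolation. Passing tests
therefore establish the correctness and calibration of the *estimators and
pipeline*, not performance claims about recorded EEG.

## Estimators

**Equiprobable binning.** Continuous variables are binned at empirical k/B
quantiles (B = 3 throughout). Values on an edge go to the lower bin —
deterministic, no jitter; when ties make occupancies differ by more than one
the result is flagged degenerate and the affected pixels are zeroed in MI
maps rather than tested.

**Plug-in MI and scaling.** MI in bits from the joint contingency table;
maps report MI_scaled = 2·N·ln 2·MI, the G statistic of a log-likelihood
independence test (null ≈ χ² with (Bx−1)(By−1) = 4 df), which adjusts for
participant-specific trial counts. Classification images bin the response
once and each pixel separately (visibility distributions differ strongly
across pixels); pixels outside the face oval are excluded (bubbles never
reveal them; their tables are degenerate).

**Miller–Madow correction.** MI_mm = MI − (Kx−1)(Ky−1)/(2·N·ln 2) with K the
number of *occupied* categories on each margin (equal to the table dimension
when fully populated). The occupied-category convention makes the group-level
copy-case identity exact: when the two quantised predictors coincide, the
joint variable occupies exactly the cells of either alone and the corrected
terms cancel, so the redundancy fraction is 1 by arithmetic. Negative
corrected values are reported, not clamped — group-redundancy arithmetic
needs unbiased terms.

**Gaussian-copula MI.** Each margin is rank-transformed (ties averaged) to
Φ⁻¹(r/(N+1)) and the Gaussian MI is computed from covariance determinants
via Cholesky factors. The estimator is a lower bound on the true MI and is
invariant to strictly monotone marginal transforms. A relative ridge (1e−9
of the mean diagonal) keeps exact-copy constructions finite, acting as the
regularisation cap on degenerate inputs. The parametric digamma small-sample
correction is implemented (`biascorrect=True`) but off by default: the
closed-form checks are cleaner without it, and all within-participant
comparisons use equal trial counts. Being covariance-based, GCMI is blind to
purely higher-order structure (e.g. XOR); the co-information function
therefore also exposes a discrete plug-in estimator, which is the right tool
for synergy checks on categorical systems.

**Co-information.** FeatRed = MI(a; f) + MI(b; f) − MI([a, b]; f): positive
is redundancy, negative synergy. The within-participant trace uses a
two-dimensional EEG response — voltage plus its temporal derivative
(centred first difference, edge-replicated) — against eye visibility and RT,
at every 2 ms sample in 0–400 ms; its argmax is the feature-redundancy peak
time (FRP), ties to the earliest sample.

**Group redundancy.** FRP and median RT are quantised into tertiles across
all participants (ties broken by stable rank order, so small-sample tertiles
differ by at most one); each MI term with age group is Miller–Madow
corrected; GroupRed = MI(FRP; g) + MI(RT; g) − MI([FRP, RT]; g). Confidence
intervals resample participants with replacement (1,000 draws), recomputing
the quantisation inside every resample.

## Significance and summaries

**TFCE + permutation.** Classification-image significance uses the maximum
statistic of threshold-free cluster enhancement over response permutations.
TFCE(p) = Σ_h dh·extent(h)^E·h^H with E = 0.5, H = 2 (the technique's 2-D
defaults), 8-connected clusters, and dh = observed-map max/100 shared
between observed and null maps so all statistics live on one threshold grid.
The implementation activates pixels in descending value order through an
incremental union-find, which is exactly the discrete threshold sum (tested
against an independent flood-fill oracle to 1e−9). The familywise threshold
is the (1−α) empirical quantile (method "higher") of the null maximum; the
mask is invariant to response-bin relabelling because MI is. α ≥ 1 is treated
as the degenerate "everything positive" request.

**Peaks and onsets.** The N170 is the minimum mean ERP in 110–230 ms
(ties → earliest; minima at a window edge are flagged, not silently
reported). ERP_STD is the across-electrode sample SD (ddof = 1) of the mean
ERP, mean-baseline centred. Onset detection: the first poststimulus local
maximum whose height reaches 5× the largest baseline peak — "peak" in the
baseline taken as the largest *absolute* local extremum, the conservative
reading — then a continuous two-segment piecewise-linear model (intercept
plus two hinge bases, i.e. three basis functions) is fitted from the
baseline start to that peak by exhaustive least squares over knots on the
sample grid, and the best knot is the onset. At this problem size the
exhaustive grid search is the same model class as an adaptive
regression-spline fit, and fully deterministic; refining the grid moves the
onset by less than a grid step. Amplitude scaling leaves the onset unchanged.

**Group statistics.** Medians are Harrell–Davis estimates (Beta-weighted
order statistics); uncertainty is the percentile bootstrap (1,000 resamples,
95%); group differences bootstrap the two groups independently and take
quantiles of the difference; Fig-style time-course summaries use the 20%
trimmed mean. Seeds are explicit everywhere and serialized into outputs.

**Lateralization.** (MI_L − MI_R)/(MI_L + MI_R) from the per-hemisphere MI
maxima (LE vs RE stacks) per participant; the index is scale-invariant, so
per-participant normalisation to [0, 1] does not affect it. Undefined (NaN,
warned) when both maxima are zero.

## Pipeline scales and determinism

`CohortConfig()` defaults to full study-scale conditions (17/18 participants,
2,200 trials, 64×64 maps); `CohortConfig.demo()` is the desk-scale
configuration used by the worked example and the acceptance script —
6 + 6 participants, 400 trials, 32×32 maps, 200 permutations — chosen to
complete end-to-end in minutes on a single CPU. Per-participant seeds are
spawned deterministically from the cohort seed; identical configurations
reproduce every numeric output bit-identically (the run manifest records the
configuration hash, per-stage wall time and the output inventory, and the
pipeline refuses to mix outputs from different configurations without
`--force`).

## Known limitations

- GCMI estimates only the Gaussian-copula component of dependence; genuinely
  synergistic or non-monotone structure needs the discrete estimator path.
- The percentile bootstrap of Miller–Madow-corrected MI is not exactly
  centred for very small cohorts; group-redundancy CIs at n ≈ 12 are
  indicative rather than sharp (the demo scale reports them with n_boot and
  seed attached).
- The onset detector assumes an approximately piecewise-linear rise; heavily
  smoothed or oscillatory onsets bias the knot late.
- Permutation tests shuffle trials, assuming exchangeability within the
  analysed subset; the generator satisfies this by construction.
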