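# Methods

This note documents the models, estimators, numerical choices and
limitations of `megpac`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Generative model of the synthetic cohort

Each subject's data are trials × 6 ROIs × samples (bilateral amygdala AMG,
thalamus THA, orbitofrontal cortex OFC; right-hemisphere regions carry the
signals). Per trial:

* **Background**: Gaussian 1/f^β noise per ROI (β = `noise_exponent`,
  default 1.0), generated by frequency-domain shaping, rescaled to
  `noise_sd` (default 1.0) per trace. The realized log–log spectral slope
  is within ±0.3 of −β (tested).
* **Alpha drivers**: rTHA and rOFC carry
  `alpha_amplitude`·cos(2π f_α t + φ_trial) with f_α = `alpha_freq`
  (default 10 Hz) and a per-trial uniform phase. For non-responders the
  driver amplitude is multiplied by `alpha_power_attenuation` (default 0.5)
  inside 20–50 ms (rTHA) and 110–145 ms (rOFC), emulating the attenuated
  post-stimulus alpha of that group.
* **Gamma carrier**: rAMG carries `gamma_amplitude`·E(t)·cos(2π f_γ t + ψ_trial)
  with f_γ = `gamma_freq` (default 60 Hz). Inside each coupling window the
  envelope is E(t) = 1 + κ·cos(φ_driver(t) − φ₀) — rTHA drives 0–50 ms,
  rOFC drives 100–200 ms — and E = 1 elsewhere. φ₀ defaults to 0.
* **Amplitudes**: `alpha_amplitude` = 1.0, `gamma_amplitude` = 0.5 relative
  to unit noise SD. These put the drivers clearly above the in-band noise
  floor (alpha SNR in the 2 Hz phase band is high, so phase estimates are
  well locked) while keeping the gamma envelope noise-limited, which is the
  regime in which the coupling estimator is actually exercised.
* **Epochs**: 3 s post-stimulus at `fs` = 600 Hz by default (1200 Hz
  available), preceded by a 0.5 s pre-stimulus baseline (`pre_stim_s`).
  The baseline matters: the 0–50 ms coupling window would otherwise sit in
  the filter/Hilbert edge-transient zone, which no real epoched analysis
  would tolerate. 600 Hz keeps a comfortable Nyquist margin for the 100 Hz
  analysis ceiling at a quarter of the computational cost of 1200 Hz.
* **Clinical model**: each subject's modulation depth κ is drawn around the
  group mean (`kappa_by_group`: responders and controls 0.6, non-responders
  0.2) with SD `kappa_sd` = 0.1, clipped to [0, 1]; the within-group spread
  is what gives the coupling-to-outcome correlation its within-group
  component. The HAM-D-6 reduction ratio is `intercept + slope·κ + ε`,
  ε ~ N(0, `noise_sd`²) (defaults 0.1, 1.0, 0.12), truncated at 1, and
  conditioned on the side of the 50% responder boundary matching the
  subject's intended group (bounded resampling). Integer HAM-D-6 baseline
  (~N(12, 2.5), clipped to 6–22) and endpoint are derived from the ratio;
  if integer rounding crosses the 50% boundary the endpoint is nudged one
  point, so the stored ratio, scores and label are exactly consistent and
  configured group sizes are exact.
* **Reproducibility**: per-subject RNG substreams are spawned from the
  master seed by subject index, so a subject's data do not depend on cohort
  size; iteration orders are fixed (never over Python sets) so runs are
  bit-identical across processes and platforms.

What the generator does **not** emulate: evoked transients, artifacts
(blinks, cardiac, muscle), realistic head geometry or field spread,
non-sinusoidal alpha, broadband gamma, inter-trial intervals. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain, not its robustness to real MEG nuisance structure.

## Preprocessing

4th-order Butterworth band-pass (default 1–100 Hz) plus 2nd-order
Butterworth band-stop (±2 Hz around 50 Hz), both applied forward–backward
(`sosfiltfilt`): zero phase, so stimulus-locked latencies are preserved;
effective attenuation at the notch exceeds 40 dB and passband ripple at
band centre is within 5% (both verified on realized responses). Epochs
shorter than three time-constants of the 1 Hz edge raise by default
(configurable to warn, which the pipeline uses for short desk-scale runs).

Trial/channel rejection: log-variance per trial (pooled over channels) and
per channel (pooled over trials); robust z = (x − median)/(1.4826·MAD),
two-sided; the single worst entity with |z| above `z_thresh` (default 3) is
removed and statistics recomputed, until none exceeds. Deterministic,
scale-free, values never modified — only rows/columns dropped.

## Source reconstruction

Scalar LCMV beamformer on a toy lead field (random full-column-rank gain,
explicit ROI→source map): w = (lᵀC_r⁻¹l)⁻¹ lᵀC_r⁻¹ with
C_r = C + reg·mean(diag C)·I, reg default 5% of mean sensor variance;
covariance estimated from the whole epoch, all trials pooled. Unit gain
w·l = 1 holds to 1e-8 by construction. ROI aggregation is a sign-aligned
mean (members flipped to correlate positively with the ROI's first
principal direction — beamformer polarities are arbitrary and unaligned
averaging cancels signal); first-principal-component aggregation is
available by flag. The aggregated series' global sign remains a convention.

Symmetric orthogonalization finds the closest set of mutually uncorrelated
region series (Frobenius norm), by alternating the closest-orthonormal-
matrix step (polar decomposition via SVD of X·D) with per-region rescaling
d = diag(XᵀL), to relative objective change < 1e-9 (max 100 iterations).
Series are demeaned first; because the orthonormal frame lies in the span
of the demeaned data, output zero-lag Pearson correlations vanish to
numerical precision. Rank-deficient input raises, naming the most
collinear region pair. The procedure is idempotent and matches a
general-purpose constrained optimizer on random instances (tested).

## Time-frequency power

Low band (1–30 Hz): sliding window of four cycles per frequency, Hanning
taper, 5 ms steps; **amplitude-squared scaling** ((2/Σw)²·|X|²), so a unit
sine reads the same at its own bin regardless of the adaptive window
length — the natural convention for peak location with length-varying
windows. High band (30–100 Hz, default 2 Hz steps): three Slepian tapers
on a fixed 50 ms window, NW = 2 (K = 2NW − 1), one-sided PSD scaling
(antisymmetric Slepian tapers sum to ~0, so amplitude scaling is
unavailable). **Note the smoothing**: NW/T = ±40 Hz at 50 ms. A pure sine's
multitaper profile is therefore nearly flat across the gamma axis; tests
assert the true bin lies within a few percent of the profile maximum
rather than exactly at it. Bins whose window does not fit inside the epoch
are NaN (missing), never zero, and propagate downstream. No baseline
correction is applied; spectrum normalization (divide by the 1–100 Hz
total) is only for spectrum summaries.

## Phase-amplitude coupling

Phase and envelope are extracted by 4th-order Butterworth band-pass over
the **full epoch** followed by the Hilbert analytic signal, then restricted
to the analysis window (0–50 ms is half an alpha cycle — filtering within
the window would be meaningless). Phase bands are f ± 1 Hz; amplitude bands
f ± max(2, 1.2·max phase frequency) = ±15.6 Hz for the default grids —
the half-width must exceed the phase frequency or the modulation side-bands
at f_a ± f_p are filtered out and coupling is undetectable by construction.

The estimator is the phasor–envelope coherence
|Σ A e^{−iφ}| / sqrt(N·ΣA²) over pooled window samples and trials
(50 ms windows have too few samples for stable per-trial estimates):
bounded in [0, 1] (Cauchy–Schwarz), invariant to envelope rescaling and
global phase rotation, 0 for a zero envelope by convention. For a fully
modulated envelope A = 1 + cos φ with uniform phase the value is
(1/2)/√(3/2) = 1/√6 ≈ 0.408. A mean-vector-length variant
(|⟨A e^{−iφ}⟩|/⟨A⟩) is provided as an independent cross-check.

Directionality note: PAC(P→Q) uses P's phase and Q's envelope; swapping
roles is a different statistic (tested on an asymmetric fixture).

Estimator geometry worth knowing: a band whose edge sits within the filter
transition of the carrier passes carrier-plus-one-side-band mixtures whose
envelope is still modulated, so the comodulogram's elevated region spans
roughly the carrier ± half-width; and in windows much shorter than a phase
cycle the per-trial window-mean phasor does not cancel, adding variance
~1/√(n_trials). Argmax localization is therefore markedly more stable in
the full-cycle 100–200 ms window than in the half-cycle 0–50 ms window;
recovery checks use the former.

## Group statistics

Band-power contrasts: one-way fixed-effects F per time bin across the
three groups, Benjamini–Hochberg FDR at q = 0.05 within each band
(zero-within-group-variance bins flagged and excluded from the family),
pooled-variance two-sample t for post-hoc responder vs non-responder
comparisons. A summary-statistic ANOVA (from mean/SD/n) is provided and is
algebraically identical to the raw-data ANOVA.

Cluster test: per-bin two-sample t; bins with |t| above the two-sided
α = 0.05 critical value form 4-connected clusters separately by sign;
cluster mass = Σt; the null is the maximum |mass| over the map per label
shuffle (default 1000); p = (1 + #{null ≥ |mass|})/(1 + P), so p ≥ 1/(P+1)
and the observed labelling counts itself. Group contrasts are pairwise
(non-responder vs responder, etc.), each with its own null. Defaults —
cluster-forming threshold, connectivity, mass statistic — are the common
choices for 2-D maps and are configurable.

## Response prediction

Reduction ratio (baseline − endpoint)/baseline of HAM-D-6; responder iff
≥ 50% (boundary inclusive). Exclusion-cascade bookkeeping is pure audited
arithmetic. Cluster strengths are correlated with reduction ratios by
Pearson r (two-sided p via the t transform) — over patients only, since
controls have no ratio. The two pathway features are combined by ordinary
least squares on the 0/1 non-response label ("linear regression" taken
literally; for ROC ranking, logistic gives near-identical orderings); the
fitted score feeds the ROC, AUC by trapezoid, operating point by Youden's
J. The AUC is **in-sample**: with two refitted features a null cohort of
n = 65 already shows optimism (~0.59 mean AUC, tested), so reported AUCs
should be read accordingly — no cross-validation machinery is included.
Non-responders are the positive class (the clinical question is flagging
patients unlikely to respond). Demographic tables use one-way ANOVA
(continuous), Pearson chi-square without continuity correction (counts),
and pooled t (patient-only scores).

## Pipeline and problem sizes

`run_all` executes simulate → (optional sensor path: forward projection,
filtering, rejection, LCMV, orthogonalization) → (optional band-power
stage: per-region alpha/gamma time courses, three-group F with BH-FDR,
post-hoc t) → comodulograms (both pathways, shared envelope extraction) →
pairwise cluster test (non-responder vs responder) → feature extraction →
correlation and ROC. At moderate cohort sizes the band-power stage
recovers the injected pattern — significant alpha bins in rTHA and rOFC,
none in rAMG gamma — with one estimator-driven caveat: the ±40 Hz
multitaper smoothing lets attenuated alpha leak into the lowest gamma
bins of the driver regions.
All randomness flows from one master seed; reruns are byte-identical.
Feature masks come from the most significant negative cluster; if no
cluster is significant the most negative cluster is used and the run
report flags the fallback.

Evaluation harnesses (`megpac.evaluation`) use deliberately reduced
conditions chosen so the measured quantity is insensitive to them:

* comodulogram recovery: 20 single-subject replicates at the full study
  conditions (40 trials, 3 s epochs, fs 600), amplitude grid at 2 Hz steps,
  100–200 ms pathway;
* cluster calibration: 200 null replicates, 10 subjects/group, P = 200,
  10 trials, fs 300, 0.5 s epochs, coarse amplitude grid (30–80 Hz, 10 Hz
  steps) — type-I error is a property of the permutation scheme, not of
  the grid density;
* cluster power: 20 replicates, 20 subjects/group at the default κ gap;
* end-to-end: 20 cohorts of 33/32/29 at 40 trials, fs 600, epochs
  truncated to 0.5 s post-stimulus (the analysis windows end at 200 ms),
  amplitude grid 30–80 Hz at 2 Hz steps, P = 500.

## Known limitations

* The toy lead field has no spatial structure; beamformer results validate
  the algebra, not anatomical localization.
* The multitaper gamma axis is smoothed ±40 Hz by the 50 ms / 3-taper
  choice; gamma-band structure narrower than that is not resolvable.
* In-sample AUC is optimistic (see above).
* The 0–50 ms window spans half an alpha cycle; single-subject argmax
  localization there is intrinsically unstable, though group contrasts
  remain well powered.
* Comodulogram values at neighbouring amplitude bins are strongly
  correlated (overlapping bands); per-bin interpretation should respect
  the ±15.6 Hz bandwidth.
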