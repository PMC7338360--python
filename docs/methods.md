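# Methods

`roawake` quantifies astrocytic Ca²⁺ activity across the sleep–wake cycle
from two-photon imaging plus ECoG/EMG/video-motion recordings. This note
describes the algorithms, their assumptions, the tunable parameters, what
the synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Event detection (regions of activity)

A region of activity (ROA) is a connected set of suprathreshold voxels in
x-y-t, treated as one Ca²⁺ event. The chain, applied to a motion-corrected
movie `F_raw(t, y, x)`:

1. **Spatial smoothing.** Per-frame 2-D Gaussian, σ = 2 px → `F`.
2. **Baseline and ΔF/F₀.** `F_LP` = centred temporal moving average of `F`
   (width w = 1.0 s, i.e. L = round(w·f_s) frames); the baseline image
   `F₀(y, x)` is the per-pixel histogram mode of `F_LP` (100 bins spanning
   the pixel's 0.1–99.9 percentile range). `S = (F − F₀)/F₀`. Baseline
   pixels below the 1st percentile of positive `F₀` values are floored
   there (count logged) so the division is bounded.
3. **Noise-calibrated threshold.** `S_LP` = moving average of `S`
   (width w); the residual `S_HP = S − S_LP` estimates the noise of `S`,
   and since an L-point average reduces white-noise SD by √L, the per-pixel
   noise SD of `S_LP` is `σ = SD_t(S_HP)/√L`. Slow fluorescence drift is
   removed by subtracting a 10 s moving average, giving `S_BP`. Voxels
   with `S_BP > k·σ` are active; `k = 5` throughout.
4. **Grouping.** Adjacent active voxels (26-connectivity in x-y-t by
   default; 6 available) form one event. Vessel/artifact pixels are masked
   out before grouping. Per event: start frame, duration, spatial
   footprint (µm², union of active pixels over the event's lifetime, or
   the largest instantaneous area with `extent_mode="max_instant"`),
   volume (µm²·s) and voxel count.

Assumptions: approximately Gaussian, temporally white noise per pixel
(the √L calibration); a unimodal intensity history per pixel (the mode
baseline); and a stationary noise level over the recording (one σ map per
movie). The method performs no spatial deconvolution: simultaneous
overlapping events merge, and at high event densities counts saturate
(see "Known limitations").

Three practical rules harden the chain:

* **Edge margin.** The moving averages shrink their window at the
  recording boundaries, so the first/last `drift_window/2` frames carry
  more noise than the σ map calibrates for; they are excluded from
  thresholding and flagged (`ActivityMask.edge_margin_frames`).
* **Temporal persistence.** A suprathreshold voxel is kept only if the
  same pixel is active in an adjacent frame (`min_persistence_frames = 2`,
  settable to 1). Isolated single-frame voxels are the signature of
  threshold noise: at k = 5 the one-sided Gaussian tail (~3×10⁻⁷/voxel)
  still yields a false-event floor of roughly 0.1 events/100 µm²/min at
  30 Hz sampling, which materially biases frequency estimates in sparse
  states, whereas genuine events span at least two frames (≥ 0.07 s).
* **σ floor.** Pixels whose σ falls below 10⁻⁵ ΔF/F₀ are excluded — such
  values are below the single-precision resolution of the chain, not
  measured noise (they arise only in degenerate synthetic input).

## Summary measures

ROA frequency counts each event once at its start frame, normalised to
events per 100 µm² of sampled area (field minus masks) per minute; the
trace integrates back to the total event count exactly. Active-voxel
percentages and per-episode heatmaps (per-pixel fraction of active
frames) follow directly from the activity mask. Hotspot overlap binarises
two heatmaps at their own top-5% quantile (ties at the cutoff all
included, for determinism) and reports intersection-over-union.

## State specificity (Jaccard + PERMANOVA)

Episode heatmaps are compared with the weighted Jaccard similarity
`J(x,y) = Σᵢ min(xᵢ,yᵢ) / Σᵢ max(xᵢ,yᵢ)`; `d = 1 − J` is the distance.
PERMANOVA on the distance matrix tests whether same-state episodes are
more similar than different-state episodes, with the per-episode mean
activation entered first as a covariate (the state effect is conditional
on overall activation). Partitioning uses the distance-based linear
model: with `G = C(−D²/2)C` Gower-centred and hat matrices of the nested
designs, a term's sum of squares is the increment in `tr(HG)`; pseudo-F is
term MS over residual MS and `R² = SS_state/SS_total`. p-values come from
999 free permutations of the state labels by default
(`p = (1 + #{F* ≥ F})/(1 + n_perm)`); Freedman–Lane permutation of
covariate-adjusted residuals is available (`method="residual"`). Only
fields of view with ≥ 8 episodes are analysed, each state level needs ≥ 2
episodes, and a constant covariate degrades gracefully to the one-factor
test. Zero residual sums of squares (perfectly state-specific geometry)
map to F = +∞ so the permutation p attains its floor `1/(n_perm+1)`.

## Sleep–wake scoring

Six states: locomotion, whisking, quiet wakefulness, NREM, IS
(intermediate) and REM sleep. Scoring runs on 1 s epochs with 3-epoch
majority smoothing; band powers (delta 0.5–4, theta 5–9, sigma 10–16,
total 0.5–30 Hz; Welch per epoch, partial edge bins weighted by overlap)
are averaged over 5 centred epochs before ratios are formed — single-epoch
delta estimates have too few degrees of freedom to classify on.

* Wake: video motion above threshold (median + 10 scaled-MAD of the
  trace) — wheel ⇒ locomotion (which subsumes whisking), snout alone ⇒
  whisking — or epoch EMG RMS above 2.5× its 20th percentile; otherwise
  quiet if EMG is high.
* REM: theta/delta > 0.5 with near-absent sigma (sigma/theta < 0.5).
* IS: sigma elevated against both delta (sigma/delta > 0.15) and theta
  (sigma/theta > 0.5).
* NREM: remaining sleep epochs (delta-dominant by construction).

All thresholds are multiples of per-recording statistics (scale-free) and
live in `ScoringParams`. The sigma band is 10–16 Hz by default; 9–16 Hz
descriptions exist in the literature and the bounds are plain data.
Sleep episodes of ≤ 30 s remain in the hypnogram but are flagged
`excluded` for state summaries. The EMG rule presumes the recording
contains enough sleep for the 20th percentile to sit in the low-tone
regime; recordings that are almost entirely active wakefulness would need
an explicit `emg_threshold`.

Microarousals are above-threshold snout intervals fully inside NREM
episodes with 0.3 s ≤ duration < 3 s. Transitions are hypnogram boundary
events; sleep→wake onsets can be refined by an automated
desynchronisation surrogate: scanning from 5 s before the scored
boundary, the onset is the first time the 2 s-window delta power (theta
for REM endings) stays below 30% of the preceding episode's median for
≥ 1.5 s. The persistence requirement exists because short band-power dips
are ordinary fluctuations. The refinement is approximate (window-length
resolution) and flagged `refined` in the output.

## Sleep spindles

The (NREM-normalised) ECoG is bandpass filtered at 10–16 Hz
(second-order zero-phase Butterworth), the Hilbert envelope taken and
smoothed with a 0.2 s Gaussian. Candidate peaks above threshold become
spindles if their envelope width **at the threshold level** lies in
[0.5, 5] s. The amplitude criterion is not standardised; the default is
median + 2.5 robust SDs (scaled MAD) of the smoothed envelope, computed
within the analysed episodes (IS sleep in the pipeline) — a robust scale
keeps the spindles themselves from inflating their own threshold.
Note the width rule's effective minimum duration depends on burst
amplitude: after the mandated 0.2 s smoothing, a very strong (≳ 6×
background) sub-0.5 s burst can hold the envelope above threshold for
more than 0.5 s and be kept. At moderate amplitudes the rule behaves as a
duration filter.

## Transition-locked dynamics

ROA frequency traces are smoothed with the causal kernel
`k(t) = t·e^(−t/τ)`, τ = 0.25 s, normalised to unit area — it has exactly
zero response before an impulse (first tap is zero, peak lag τ), so it
cannot skew onsets early the way a symmetric Gaussian does. Windows of
−15…+15 s around each transition are z-scored against the −15…−5 s
baseline (rows with zero baseline SD are flagged and excluded). The Ca²⁺
onset is where the trace crossed 2.5 baseline SDs: by default the
crossing that starts the suprathreshold excursion containing the window
peak (`scan="excursion"`). A literal first-crossing forward scan
(`scan="forward"`) is available but false-triggers on baseline noise in
roughly one row in six (2.5 SD threshold against ~15 independent smoothed
baseline samples plus baseline-SD estimation error), which biases mean
onsets early by ~0.4 s. Peaks are window maxima. Astro–neuron coupling
uses the maximum Pearson cross-correlation over ±2 s lags after 0.25 s
Gaussian smoothing of both traces.

## Hand-drawn ROI traces

Mean fluorescence inside circle/polygon ROIs; `F₀` = histogram mode of
the trace; neuronal somata corrected by subtracting the 5 µm annulus
("doughnut") trace before dividing by `F₀`. Events are detected on the
smoothed (σ = 0.25 s astro / 0.1 s neuron), drift-corrected (σ = 120 s
Gaussian subtracted) ΔF/F₀ at 2.5× (astro) or 2× (neuron) the SD of the
noise trace (raw minus smoothed); an event spans the zero-crossings
around the excursion, onset at the threshold crossing, amplitude at the
in-event peak. Auto-placement of 5 µm neuropil circles ≥ 5 µm from soma
rims is provided for synthetic work; manual ROI files are authoritative.

## Synthetic sessions (what the generator emulates)

Movies: 512×512 at 30 Hz by default (0.8 µm/px), baseline 100 a.u.,
i.i.d. Gaussian noise (σ = 5 a.u.; optional Poisson shot noise), slow
sinusoidal drift (amplitude 2 a.u., 60 s period), and a random smooth
vessel mask (5% of the field). Events are isotropic Gaussian blobs
(σ_xy = 1.5 µm, amplitude 0.5 ΔF/F₀ ≈ 10× voxel noise) with a linear
rise over 20% of the duration and exponential decay, durations 0.5–2 s,
placed so the half-max support clears vessels and borders. Counts per
state follow a Poisson law with the configured rate (events per 100 µm²
of vessel-free area per minute); defaults are locomotion 2.0, whisking
1.5, quiet 1.0 and 0.23 for each sleep state — the low-density regime in
which counting events is meaningful for a method without deconvolution.

Physiology: ECoG as a sum of band-limited noises with state-specific RMS
weights chosen so the scoring definitions hold by construction
(delta-dominant NREM; IS with elevated sigma/theta and reduced delta; REM
with theta/delta power ratio ≈ 4; desynchronised wake), sampled at
1 kHz. Sleep spindles are non-overlapping Hann-windowed 12–14 Hz bursts
of 0.5–2 s at a Poisson rate (2/min default) during IS, amplitude 6 a.u.
(~3× the NREM background RMS) — most of the elevated IS sigma power comes
from the bursts, with a moderate continuous sigma background (weight
0.65). EMG is 100–450 Hz noise with state-dependent tone (atonia in
REM); wheel/snout traces are rectified-noise bursts during locomotion
(wheel and snout) and whisking (snout).

The generator does **not** emulate: motion artifacts (input is assumed
motion-corrected), indicator kinetics or bleaching, correlated/structured
optical noise, neuronal-channel movies (only per-trace synthesis), ECoG
electrode artifacts, or ambiguous transitional epochs. Passing recovery
tests therefore demonstrates algorithmic correctness under the stated
noise model, not robustness to every property of in-vivo data.

A separate ensemble generator (`generate_transition_ensemble`) emulates
whole-field ROA-frequency traces around SWS→wake transitions: a Poisson
baseline with a steep rate surge whose start is calibrated so the
noiseless smoothed trace crosses 2.5 baseline SDs exactly at the nominal
onset (−1.5 s) — the ensemble's ground truth is defined by the same rule
the estimator applies.

## Validation experiments and problem sizes

`roawake.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: threshold specificity on 128×128×3000
pure-noise movies (measured at the thresholding stage, comparable to the
analytic tail bound); detection recovery on 64×64×1800 sessions, with
footprint/duration compared against noiseless-reference events (the same
injected signals thresholded at the measured k·σ map — a Gaussian blob's
suprathreshold support is defined by the threshold, not by a unique
"true" area); component labelling against a brute-force flood fill on 100
random 16×16×20 masks; σ-map calibration at 3000 frames; PERMANOVA type-I
error over 200 null datasets × 999 permutations plus the degenerate
perfectly-state-specific geometry; sleep scoring over 20 sessions;
spindle recall/precision over 10 IS sessions with short and out-of-band
probe bursts; onset estimation over 100 calibrated transitions; the
sleep-vs-wake ratio experiment (below); and byte-level determinism of
pipeline reruns. Sizes were chosen so the full suite runs on a laptop in
minutes while keeping Monte-Carlo tolerances meaningful.

The ratio experiment configures a wake:sleep event-rate ratio of 1:0.23
(uniform 2.0 within wake, 0.46 within sleep, compact 1.0 µm events of
0.5–1.5 s on a 96×96 field over an 8.5 min session) and re-estimates the
frequency reduction through the full pipeline (detection + scoring),
averaging four replicate sessions. Rates sit well above the residual
false-event floor and low enough that merging stays in the linear
counting regime; the recovered reduction is expected a few points below
the configured 77% because residual merging affects the denser wake
states slightly more than sleep.

## Known limitations

* No spatial deconvolution: overlapping events merge; event counts
  saturate with density. Frequency comparisons between conditions of very
  different density are biased toward the sparser condition.
* The σ map is estimated once per recording; slow noise nonstationarity
  (e.g. laser power drift) is not tracked.
* The scorer's thresholds are calibrated for recordings containing both
  sleep and wake; edge cases (all-wake recordings, heavy artifact load)
  need explicit thresholds.
* The desynchronisation refinement and the scorer's epoch grid limit
  transition timing to ~0.5–1 s accuracy.
* Very strong sub-0.5 s sigma bursts can pass the spindle width rule
  (see above).
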