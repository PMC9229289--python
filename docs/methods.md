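# Methods

## Wavelet transform

The delineator rests on an undecimated (à-trous) dyadic wavelet transform
with the quadratic-spline pair standard in QRS delineation work: low-pass
`h = [1, 3, 3, 1]/8`, high-pass `g = [2, −2]`. At stage *j* the filters
are dilated by inserting `2^(j−1) − 1` zeros between taps; detail scale
S*j* is the running approximation convolved with the dilated high-pass.
Because `g` is a first-difference, S*j* approximates the derivative of a
smoothed signal: a smooth positive wave produces a positive/negative
modulus-maxima pair whose zero-crossing marks the wave peak, which is the
property every detector here exploits. The exact filter pair is exposed
by name (`register_filter`) because only this modulus-maxima behaviour,
not the specific taps, is essential.

Numerical conventions:

* **Alignment.** Filtering is causal (zero-lag convolution); each scale
  carries a group delay computed as the centroid of the absolute cascade
  impulse response, rounded half-up (1, 3, 7, 15 samples for S1–S4 with
  the default pair). Detector positions found on a scale are mapped to
  the time domain by subtracting this delay.
* **Boundaries.** The full-signal transform mirror-extends the input by
  the deepest cascade length — mirror extension avoids spurious edge
  maxima on a whole recording. The *local windowed* transforms inside the
  P/T detector instead use edge (constant) extension: a window
  deliberately cuts into the QRS slope, and mirroring that slope
  fabricates a phantom peak at the window boundary that then masquerades
  as a wave.
* The transform is linear and shift-equivariant, and the stage-wise
  implementation is tested to agree with direct convolution by the
  equivalent cascade filter to < 1e−9 everywhere, including the boundary
  region.

## Delineation

**R.** Threshold `r_threshold_frac · max|S4|` (default 0.3) gates S4
modulus extrema; adjacent opposite-sign extrema above it bracket a
zero-crossing which, after delay correction, is refined to the raw-signal
absolute-amplitude maximum within ±100 ms. Candidate pairs closer than a
0.2 s refractory period are merged, keeping the larger modulus product.

**Q/S.** On S1, modulus maxima are walked outward from each R; the third
extremum is taken as the Q start (S end). The walk is bounded by
`min(TR/2, 0.12 s)` — TR being the mean R–R — because beyond the QRS the
next strong fine-scale extrema belong to the P/T edges. On smooth
morphologies (including the simulator's Gaussian bumps, and clean filtered
ECG) the fine scale shows only *two* QRS lobes on each side, so when fewer
than three extrema exist in-bound the outermost one found is used; a cycle
with none gets a missing Q (S). This keeps the intended "start of Q"
semantics on data without fine-scale texture instead of discarding every
cycle.

**P/T.** For each cycle a fresh 4-scale transform is computed on the
`w_p = 0.20 s` window ahead of Q (the `w_t = 0.30 s` window behind S) so
the dominant R peak never enters the analysed segment. A wave is present
when the in-window S4 minimum falls below `−0.25 · max|S4_window|` (and
the window has non-trivial energy, ≥ 1% of the global S4 maximum —
guarding against structureless segments). The onset is the **last** local
S4 maximum before the minimum that reaches at least 25% of the minimum's
magnitude — the rising-edge member of the wave's own modulus-maxima pair.
Taking the global maximum instead is wrong in a subtle way: whenever the
window reaches back to the QRS, the S-recovery upstroke wins, and the
onset flips between two states from cycle to cycle. The peak estimate
(delay-corrected minimum) is refined to the raw-signal extremum within
±60 ms after a 40 ms moving average (wideband noise on the flat apex of a
P/T wave otherwise drags a raw argmax by tens of samples); the offset
mirrors the onset about the peak by construction. Windows that find
nothing translate outward in 0.02 s steps until `w_p + a·n > TR/2`
(`w_t + a·n > 2TR/3`).

Cycles violating the ordering
`p_on ≤ p_peak ≤ p_off < q < r < s < t_on ≤ t_peak ≤ t_off` are excluded
(counted and logged), never repaired; incomplete cycles never reach the
feature matrix. Inverted-lead recordings are handled by the `polarity`
switch.

## Features

Intervals are reported in seconds so features pool across sampling rates;
amplitudes are signed differences in the signal's own units (choosing
signed over absolute preserves polarity information; nothing downstream
assumes a sign). R–R uses the next cycle's R; the last cycle reuses the
preceding R–R. No standardisation is applied by default — the classifier
kernel operates on the raw feature vector — which means the second-scale
intervals (R–R foremost) dominate the isotropic kernel distance. That is
a faithful property of the method, not an oversight; see limitations.

## Classifier

The PNN scores class *i* by averaging the kernel
`(2π)^(−1/2) δ^(−d) exp(−‖X − X_ij‖²/δ²)` over that class's exemplars.
Two details are deliberate:

* The normalisation constant and the `δ²` (not `2δ²`) exponent
  denominator are kept in exactly this form; both are class-independent,
  so predictions are unaffected, and `standard_gaussian=True` switches to
  the textbook multivariate kernel for users who expect it.
* Predictions are computed in the log domain (`logsumexp`), so the
  δ → 0 limit is *exactly* 1-nearest-neighbour rather than an underflow
  artefact. The δ → ∞ limit follows the second-order kernel expansion:
  because scores are within-class means, class priors cancel and the
  winner is the class with the smallest mean squared distance — not the
  most populous class.

Ties break toward the earliest label in sorted class order. Test error is
available as the misclassification rate (default) or as the mean squared
difference of integer-encoded labels; the latter penalises label
*distance*, which is meaningless for nominal subject identities, so it is
not the default tuning fitness.

**δ tuning.** A 1-D WOA swarm (population 10, 100 iterations, bounds
[0.01, 10]) minimises validation error of a PNN refit at each candidate
δ. The WOA uses the canonical branch structure — spiral with probability
½, otherwise encircling when |A| < 1 and random search when |A| ≥ 1, with
A and C drawn per dimension, l uniform on [−1, 1], spiral constant b = 1
— with positions clipped to bounds and an elitist best. The convergence
factor decays linearly, a = 2 − 2t/T_max.

**k-cycle decisions.** Majority vote over k consecutive single-cycle
predictions (ties to the earliest-seen label). Voting over predictions
was chosen over concatenating k cycles' features because it leaves the
model input dimension unchanged. Voting helps when errors are isolated;
it can lose to single-cycle accuracy when one subject's errors
concentrate (2 of 3 wrong in one group costs a whole vote).

## MIV screening

Feature *i* is scaled by (1 ± α) (α = 0.10, the customary setting; only
the one column changes, bit-identically elsewhere) and the trained
model's scalar output — the numeric predicted label, subjects numbered
from 0 — is re-evaluated on both copies; I_MIV,i is the mean output
difference. Features with |I_MIV| above the 0.1 cutoff are retained, in
ranking order. Two caveats are documented rather than patched:

* The screening model must be *sensitive*: a Parzen kernel much wider
  than the exemplar spacing barely moves under a 10% perturbation and
  reports impact ≈ 0 for everything. The pipeline therefore gives the
  screening PNN a data-driven width (median nearest-neighbour distance of
  the training rows) unless told otherwise.
* Impact values are in label units, so their magnitude grows with the
  number of classes. An absolute cutoff of 0.1 is far more aggressive on
  a 20-subject cohort than on a 156-subject corpus; retention counts are
  data findings, never hard-coded, and the end-to-end evaluation of the
  classifier stage runs without screening for this reason.

## Synthetic cohorts

Each subject is five Gaussian bumps (P, Q, R, S, T) with amplitudes,
widths and latencies drawn once per subject from physiological ranges
(`simulate.TEMPLATE_RANGES`: e.g. R 0.9–1.6 mV / σ 10–16 ms; P 0.10–0.18
mV / σ 22–28 ms, 160–220 ms before R; T 0.15–0.35 mV / σ 40–50 ms,
250–320 ms after R; heart rate 55–75 bpm with 2% cycle jitter). Gaussian
morphology is deliberate: ground-truth peaks are rendered extrema of the
clean signal and onsets/offsets sit exactly two widths out, so detector
scoring needs no manual annotation. P and T are wider and lower-slope
than Q and S, as in real ECG, which is what makes the fine-scale Q/S walk
well-posed. White noise (by SNR) and sinusoidal baseline wander are added
only after truth is recorded.

What the simulator does *not* emulate — and hence what passing tests do
not show about clinical data: beat-morphology variability within a
subject (ectopy, respiration-modulated amplitudes), non-Gaussian wave
shapes (biphasic P, asymmetric T), muscle-artefact noise spectra, and
electrode-motion transients. Detection rates and identification
accuracies on these cohorts are upper bounds of a kind: they validate the
algorithmic machinery, not field performance.

## Evaluation protocol and problem sizes

The bundled evaluation uses 20 subjects × 10 cycles at 360 Hz (the
per-subject cycle count mirrors the reference protocol of 10 cycles per
subject; 156 subjects × 10 cycles = 1560 cycles is reproduced as a
bookkeeping check). Per subject, the first 7 cycles train and the last 3
test; the WOA tunes δ against the held-out cycles' error, as in the
reference procedure. Database-level accuracies are pooled by
subject-count weighting (90/18/48), reported to 2 decimals. These sizes
keep the full suite and the acceptance script in the tens of seconds on
one CPU.

## Known limitations

* The raw-unit isotropic kernel lets R–R dominate; two subjects with
  near-identical heart rates must be separated by the smaller interval
  features, which contribute little distance. Optional per-feature
  standardisation exists but is off by default to keep the published
  kernel semantics.
* Q/S localisation degrades gracefully but early under noise: at 20 dB
  SNR the fine scale is noise-dominated for low-slope Q/S lobes.
* The rejection-free classifier always answers with some enrolled
  subject; there is no unknown-subject option.
* WFDB support covers text headers with format-16 signals only; other
  formats raise with a clear message.
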