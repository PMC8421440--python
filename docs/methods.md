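# Methods

`heliwork` quantifies the workload a helicopter pilot endures while flying an
autorotation — the unpowered descent and landing that follows an engine
failure — from three synchronized data sources: the aircraft's flight-control
displacements, the pilot's physiological signals, and the pilot's subjective
Handling Qualities Rating (HQR).  The analysis compares these measures across
partitions of the Height-Speed ("Dead Man's Curve") diagram and across
pilot-experience groups.

## Study layout

A campaign consists of pilots in three experience groups (autorotation
instructors, test pilots, operational pilots), each flying repeated simulated
engine failures at catalogued height/speed test points.  Every test point
carries two partition labels:

* **classical** — Outside / Line / Inside the Height-Speed diagram
  (Outside = {C1, C2, D3, E1, E5, F3, G3}, Line = {D2, E2, E4, F2, G2, H2},
  Inside = {D1, E3A, E3B, F1, G1, H1});
* **zone** — the maneuvering technique required: Take-off {B3, C1},
  Knee {D1–D3, H1–H3}, Cruise {G*, F*, E3B, E4, E5}, High-hover {E1, E2, E3A}.

Point A1 is excluded (ground contact within a second).  B3 and H3 have no
published classical label and default to `Unlabeled`; C2 has no zone and
defaults to `Unzoned`.  Both are excluded from the corresponding factor in the
statistics, and the catalog file can be edited to assign them.  The heights
and speeds in the shipped catalog are nominal entry conditions chosen to be
consistent with each zone's semantics (e.g. High-hover at zero airspeed,
Cruise at or above the 55 kt MTE branch point); only the labels enter the
statistics.

Three events segment each maneuver on the 64 Hz flight-test-instrumentation
(FTI) clock:

* **engine failure** — first sample at which the gas-generator speed Ng has
  entered a ±1% band around the 65% idle regime and stays there for ≥0.5 s.
  The timestamp is the band entry (causal), not the confirmation.
* **autorotation entry** — first post-failure sample at which the collective
  moves down at ≤ −5 %/s for ≥3 consecutive samples, searched for 10 s.
* **flare** — first sample after entry with a positive pitch-attitude rate
  while height ≤ 65 ft.

Reaction time is entry minus failure.

## Control-activity metric (CPF)

Pilot control activity is summarized by the Cumulative Power Frequency.  For
each 3-s moving window of one control axis (percent of full travel):

    omega_cum = omega_cutoff * P / 10

where `P` is the total power of the mean-detrended window and `omega_cutoff`
is the median-power frequency — the smallest frequency below which at least
half (configurable) of the spectral mass lies.  The spectrum is
Parseval-normalized, so `P` equals the window's mean-square displacement in
%² and a pure tone of amplitude A at f Hz gives `omega_cum = f·A²/20`.  The
divisor 10 is a fixed scale constant of the metric's definition.  The four
axes (collective, lateral cyclic, longitudinal cyclic, pedals) are computed
identically and summed sample-wise, privileging none.  The statistic entering
the models is the peak of the summed series in the 15 s after the engine
failure; the 5 s before the failure are computed for context only.

Numerical choices: rectangular window (an optional Hann taper changes
absolute power and is therefore opt-in), per-window mean removal only,
centered windows with edges dropped, default stride of one sample
(campaign-scale runs in the bundled scripts use a 4-sample stride, which
changes peak values by well under the windowing uncertainty).

## Physiological features

All physiological channels are recorded at 500 Hz and aligned to the FTI
clock by pairing push-button trigger pulses present in both streams; the
offset is the median difference of paired rising edges.

**Electrodermal activity.**  The raw trace is segmented ±60 s around the
failure and expressed as percent change against the mean of the 5 s before
it.  The first skin-conductance response after the event is scored by a
deterministic replacement for the usual manual delimiting: the signal is
smoothed with a causal 200 ms average, a causal slope on the same timescale
must exceed 0.5 %/s for 150 ms, the onset is backtracked to the foot of the
rise, and the peak is where the slope first returns to zero.  Amplitude is
peak minus onset value.  The response is valid only if the onset lies within
0.5–5 s of the event; exact boundary onsets count as valid, with a 50 ms
tolerance absorbing the detector's sub-smoothing-window lag.  A review hook
is not needed here because the rule is deterministic; the R-peak detector
(below) exposes one.  Amplitudes are analyzed on the normalized (percent)
scale by default; an absolute-µS mode is a flag away.

**Heart rate.**  The EKG is band-passed 1–100 Hz with a 4th-order zero-phase
(forward-backward) filter.  R-peaks are local maxima above an adaptive
threshold (half the 99.5th amplitude percentile) with a 250 ms refractory
period; a `review` callback can accept/reject candidates, mirroring
semi-automatic practice.  Instantaneous rate (60/IBI at beat midpoints) is
resampled to a uniform 4 Hz grid, normalized as percent change against the
5-s pre-failure mean, and integrated (trapezoid) over (0, 40] s — the AUC in
%·s is the modelled feature.

**Respiration.**  The belt signal is band-passed 0.05–0.50 Hz (zero phase)
and transformed with a complex Morlet wavelet (centre frequency 6,
bandwidth 1, 48 log-spaced frequencies spanning the band, computed at a 4 Hz
analysis rate).  The wavelet power is divided by scale so equal-amplitude
tones carry equal power at any frequency.  The "promediated" frequency at
each instant is the power-weighted mean of the in-band frequencies — a convex
combination, hence always inside [0.05, 0.50] Hz and invariant to uniform
power rescaling.  The transform runs on ±100 s around the event but only
±50 s is reported; the outer stretch guards against low-frequency edge
smearing.  Respiratory features are exported but excluded from the
inferential models by default, reflecting their poor event-scale specificity;
a flag re-enables them.

## Performance scoring

Each maneuver is scored against an autorotation Mission Task Element.  With
entry airspeed ≥ 55 kt the pilot must also reach the recommended 65 kt
autorotation speed; in both branches the landing must be completed with
touchdown vertical speed ≤ 2 m/s and overall HQR ≤ 4.5.  Touchdown ground
speed < 30 kt is desirable, < 40 kt adequate (strict inequalities, as the
criteria are printed); any violated criterion is listed as a failure reason.
A maneuver is a success if performance is desirable or adequate and the
instructor did not intervene.  Success rates are reported per group over all
points and over "reasonable" points only (Line ∪ Outside).

Inter-pilot HQR agreement uses the 1-rating-unit rule: per test point, the
sample SD (n−1 denominator, configurable) of the ratings must not exceed
1.0.  The package ships the campaign rating table for this check; on the
test-pilot panel (pilots #1–#7) exactly 20 of the 21 points comply, with G1
the exception — consistent with pilots' inability to perform that Inside
point adequately.

## Statistical modelling

Each feature (CPF peak, EDA amplitude, HR AUC, HQR) is modelled with a
linear mixed-effects model: random intercept per pilot, and one fixed factor
at a time (classical partition, zone partition, or experience group).  The
null model has the intercept and random effect only.  Both models are fitted
by maximum likelihood; the factor is *retained* only if it lowers the AIC
and the likelihood-ratio test (chi-square, levels−1 df) is significant at
α = 0.05.  Residual Gaussianity is checked with Shapiro–Wilk on the
conditional residuals; on rejection the response is log-transformed (it must
be strictly positive) and the fit repeated once.  Reported level means and
contrasts come from a REML refit; all pairwise level differences are Wald
z-tests corrected with Benjamini–Hochberg FDR.  Fits fall back across
optimizers and keep the best-likelihood solution, since the profiled
likelihood is flat near singular random-effect variance; such fits are
flagged degenerate.

Design notes: random slopes are deliberately omitted (the simplest structure
consistent with a random-intercept description; an option exists in the model
call), the ANOVA step is implemented as a likelihood-ratio test between ML
fits, and all pairwise contrasts are reported so the baseline level is
inconsequential.

## Synthetic campaign generator

No flight data are distributable, so the generator produces campaigns with
the statistical structure the extractors assume, as study conditions rather
than tunable dials:

* reaction delay N(1.18 s, 0.31 s) truncated at 0.3 s, applied to a −25 %/s
  collective ramp; Ng steps from 85% to 65% at the failure; pitch attitude
  turns positive below 65 ft on a 25 ft/s descent;
* per-axis control activity: low-pass (2.5 Hz) Gaussian noise at 1.2% rms
  scaled by per-zone and per-classical multipliers (High-hover 2.2×,
  Cruise 1.6×, Knee/Take-off 1×; Inside 1.5×, Line 1.2×, Outside 1×) during
  the 12 s after the failure;
* SCRs as a difference of exponentials (0.75 s rise, 3 s decay), base
  amplitude 0.4 µS on a 5 µS tonic level, onsets drawn in 0.8–3.5 s,
  amplitude multipliers Inside 1.6× / High-hover 1.5×, lognormal jitter 10%;
* a biphasic heart-rate template: raised-cosine bumps at 3 s (6%, 6 s wide)
  and 20 s (4%, 24 s wide) on a 75 bpm baseline, scaled by zone only
  (High-hover 1.8×, Cruise 1.4×) — the generator's HR carries no classical or
  group effect, mirroring the pattern the analysis is meant to resolve;
* respiration as a frequency-modulated sinusoid inside 0.05–0.50 Hz with a
  20% post-failure slowdown;
* group success probabilities 0.95 / 0.80 / 0.55 and HQR means by classical
  label 4.7 / 4.8 / 6.8 with pilot offsets (SD 0.5) and rating noise
  (SD 0.7), rounded to half units.

Where the flight campaign reports no numeric value (SCR amplitudes, HR peak
sizes, activity multipliers), the defaults above are stated assumptions
chosen for physiological plausibility, not transcriptions.  Each maneuver's
random stream is keyed by (seed, pilot index, maneuver index), so any
maneuver regenerates identically in isolation and a fixed seed reproduces
the campaign byte for byte.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: aerodynamic coupling between axes, motion and
speech artifacts in the physiology, EDA ceiling effects, non-stationary
baselines beyond slow drift, heart-rate variability structure, and the
correlation between a pilot's physiology and their actual performance.  The
generator validates the measurement chain and the inferential machinery, not
the physiological claims themselves.

## Problem sizes and tolerances

Default campaigns use 11 pilots (3/4/4) with 12 maneuvers each — the lower
end of the campaign's 12–27 range, chosen to keep replicated analyses cheap.
Ground-truth recovery tolerances: event times within 2 FTI samples, SCR
amplitude within 5% (median) with correlation ≥ 0.95, HR AUC within 5% of
the analytic profile integral, respiratory centroid within 0.01 Hz of a tone.
The retention-rule calibration uses 500 simulated null feature tables; the
end-to-end retention matrix uses 12 replicated campaigns of 60 maneuvers,
where ≥95% of (cell, replicate) decisions must match the constructed
effects.  With the null rate pinned near α = 0.05 and four null cells in the
matrix, demanding that every cell of every replicate match would be
mathematically inconsistent with the calibration requirement, so the match
proportion is the criterion.

## Known limitations

* The ω_cutoff energy fraction (0.5) and the Hz frequency convention are
  assumptions; the metric's source does not pin them down.  Both are config
  knobs.
* The SCR scorer replaces a manual procedure; its 18 ms median onset lag is
  absorbed by the boundary tolerance but is a bias nonetheless.
* Mixed-model p-values use the chi-square LRT approximation; at the default
  campaign size (7 pilots, 12 maneuvers each) the measured type-I rate of
  the retention rule is ≈0.05, drifting liberal only for very small panels.
* The channel dialect is an open stand-in; the original recorder's
  proprietary format is not decoded.
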