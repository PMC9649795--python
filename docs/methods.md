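# Methods

This note documents the model, the synthesis procedures, the parameter
choices that matter, and the limits of what the synthetic corpora can show.

## Auditory front end

The time–frequency representation is a bank of 64 fourth-order gammatone
filters implemented as a cascade of four second-order IIR sections (the
classic Slaney digital design), with equivalent rectangular bandwidths
following Glasberg & Moore, ERB(f) = 24.7·(4.37·f/1000 + 1) Hz. Center
frequencies are spaced uniformly on the ERB-rate scale
E(f) = 21.4·log₁₀(0.00437·f + 1), with both endpoints (50 and 20,000 Hz)
included. This convention places channel 20 at 786 Hz and channel 30 at
1775 Hz — the ~800/1800 Hz landmarks that delimit the boundary scan — and is
validated against those landmarks rather than asserted as unique: the
filter order, the exact spacing rule and the framing parameters are not
dictated by the model definition, and other conventions exist.

Filter outputs are squared and averaged in 20 ms rectangular frames with a
10 ms hop. 20 ms resolves a 50 ms envelope dip with at least two interior
frames while averaging out the carrier's fine structure. Energies are kept
on a linear power scale throughout: Balance sums them and Continuity takes
a ratio, so dB compression would change both statistics' meaning.

The analysis rate is fixed at 44,100 Hz (any input at another rate is
resampled on load), the minimum rate whose Nyquist frequency accommodates
the 20 kHz top channel.

## The two indices

**Balance.** From the mean spectrum S₁..₆₄ (per-channel energy averaged over
frames), Balance(b) = Σ₁..b Sᵢ − Σ_{b+1}..₆₄ Sᵢ, evaluated for every integer
boundary b in 20..30. Within `analyze_stimulus` the mean spectrum is first
rescaled to unit total energy, so the reported Balance is a distribution
statistic in [−1, 1]. The reason is comparability: even after waveform-level
intensity normalization, the summed channel energies retain a residual
(≈0.2%) dependence on where spectral energy sits, because the bank's summed
magnitude response is not perfectly flat across frequency. That residual is
irrelevant for a single stimulus but can mask genuinely small high-side
energy differences when stimuli are compared — exactly what the boundary
contrast measures. Dividing by total energy removes it; the regression
absorbs the change of scale. The raw pathway (cochleagram → mean spectrum →
`balance`) is left un-normalized and scales quadratically with input gain,
which is why normalization happens upstream. Balance is non-decreasing in b
by construction (the increment is 2·S_{b+1} ≥ 0); the implementation
computes it from a sequential cumulative sum so the monotonicity also holds
exactly in floating point.

**Continuity.** From the frame-energy track E₁..T (energy summed over
channels), Continuity = ln(minₜ Eₜ / maxₜ Eₜ), a number in (−∞, 0]. Three
numerical policies apply:

- *Log base*: natural log. Any base rescales the statistic by a positive
  constant that the regression coefficient absorbs; the choice only fixes
  reported magnitudes.
- *Silence floor*: the ratio is clamped at 1e−6, i.e. Continuity ≥
  ln(1e−6) ≈ −13.8. A stimulus with a digitally silent interval would
  otherwise return −∞ and break any downstream regression.
- *Interior minimum*: frames in the first and last 10% of the stimulus are
  excluded from the minimum search (the maximum uses all frames). Onset and
  offset ramps are production artifacts, not interior envelope dips, and
  must not masquerade as them.

Continuity is computed only when the caller marks the stimulus eligible.
Whether a stimulus has the vowel–consonant–vowel-like envelope structure
the index presumes is experiment metadata; it is not reliably detectable
from audio alone.

## Fitting round scores

For one experiment, per-stimulus round scores are regressed by OLS on
Balance(b) — plus Continuity when available — separately at every b in
20..30, and the b\* with maximal r² is selected (ties break toward the
smaller b; the 11-fit exhaustive scan is cheap and deterministic). Scores
are fitted on each study's native scale, with unstandardized predictors;
r² is the squared correlation between observed and fitted scores, and the
reported t and p come from the slope test of the simple regression of
observed on fitted values — the statistic that corresponds to the usual
observed-vs-predicted scatter panel. When the observed or fitted scores are
constant, the null contract r² = 0, t = 0, p = 1 is returned.

## Stimulus synthesis

All generators derive per-stimulus seeds from a single master seed via
`numpy` seed sequences and are bitwise-reproducible.

**Noise bands.** 500 ms of white noise filtered by a second-order resonator
(−3 dB bandwidth fc/10) at fc ∈ {300, 500, 600, 700, 800, 900, 1000, 1200}
Hz, then amplitude-modulated by an envelope that is 1 outside 225–275 ms and
`dip_amp` ∈ {0, 0.1, 0.5, 1} inside it (0 = silent dip, 1 = no dip), with
5 ms onset/offset ramps and 2 ms ramps into the dip to avoid clicks. Two
variance-control choices make the factorial manipulation exact rather than
merely expected:

- The excitation noise has random phase but an exactly flat magnitude
  spectrum, so each band's spectral energy distribution is a deterministic
  function of the filter, not of the noise draw.
- The band's intrinsic narrowband amplitude fluctuation (several dB of slow
  Rayleigh-type fading at the lower center frequencies) is divided out
  before the dip envelope is applied, so the amplitude trajectory is
  exactly the designed one — which is also what the factorial design
  describes (constant amplitude outside the dip).
- The four dip variants of a given fc share one band realization: the dip
  is a manipulation of an existing band, making Continuity monotone in dip
  depth by construction.

With these policies, Balance at any boundary decreases strictly across the
eight center frequencies at every dip level, and Continuity is non-
decreasing in dip amplitude at every fc (strictly increasing in the mean).
At the lowest center frequencies the analysis filters ring through the
silent dip, so the dip-0 Continuity reaches the −13.8 floor only from
fc ≈ 800 Hz upward; below that it saturates around −9 to −12.

**Impact sounds.** Modal synthesis of a struck membrane. The cumulative
mode count is modeled by a two-term counting law N(f) = a·f² − p·f with
a ∝ area and p ∝ perimeter; solving N(f_k) = k gives the mode frequencies,
so at fixed area a larger perimeter raises every mode and the disk
(isoperimetric minimum) is the lower bound. Two synthesis constants realize
the law as audio: the wave-speed constant is calibrated so a unit-area round
drum's fundamental is 220 Hz, and the perimeter correction carries a weight
of 8, amplifying the round/spiky separation beyond the literal membrane
value (where a 1.4–1.8× perimeter shifts modes by only a few percent) so
that a 30-sound corpus reproduces the characteristic band contrast of real
round vs spiky struck objects: every round sound carries more energy below
500 Hz than within 500–2000 Hz, every spiky sound the reverse. Each sound
is a sum of 80 damped sinusoids (amplitudes ∝ 1/k with ±10% jitter, random
phases, uniform damping 18 s⁻¹, duration drawn in 200–220 ms) plus a brief
quiet broadband contact click. The corpus pairs five areas (0.25–0.45) with
perimeter factors 1.4–1.8 (larger factors on larger areas, keeping every
spiky fundamental above 500 Hz), three instances each.

**Rolling sounds.** ≈200 ms noise carriers (smooth: 100–700 Hz band;
sharp: 900–3000 Hz band; wood/plastic presets differ only by a ±3 dB/octave
tilt, mirroring the negligible role of surface material) whose intrinsic
envelope is flattened and replaced by a designed one. Smooth rolls get two
slow (3–8 Hz) log-amplitude sinusoids with total swing ≤ ±0.15 nepers
(≈2.6 dB, comfortably under the 6 dB bound for every >40 ms window); sharp
rolls get four seeded Gaussian contact bursts (σ = 8 ms, ×5 amplitude,
≈14 dB, comfortably over the 8 dB-within-40 ms bound). Envelope constraints
are verified on the extracted envelope with a sliding-window dB-range scan
that trims 10% at each edge (onset/offset ramps are not excursions).

**Envelope extraction and transplantation.** Envelopes are full-wave
rectification followed by a zero-phase 4th-order Butterworth low-pass at
32 Hz, sampled at 1 kHz. 32 Hz keeps the 40 ms-scale fluctuations that
distinguish smooth from sharp trajectories while suppressing the carrier;
the operation is exactly linear in input gain. Transplantation multiplies a
carrier by the (upsampled) envelope and re-normalizes RMS. The shaped-noise
carriers match a target mean spectrum by iterative analysis–resynthesis
(four iterations of per-channel √(target/current) gains interpolated onto
the Fourier grid), which lands within 3 dB per channel on channels holding
appreciable energy. The extraction and spectral-matching procedures are
this package's own stand-ins for the unpublished tooling used with real
recordings.

**Scored sweep corpus.** For boundary-recovery studies, 60 dip-free noise
bands with center frequencies log-spaced over 300–2400 Hz sweep spectral
energy through the scan region; noiseless scores map Balance at b = 25
linearly onto [0, 100] and Gaussian noise with σ = 5 score points (5% of
the range) is added.

## Respondent simulation

A simulated participant chooses "round" with probability
logistic(intercept_p + Σ slope·x), with participant intercepts drawn from a
Gaussian of spread `participant_sd` (log-odds). The estimator is a
fixed-effects logistic regression (maximum likelihood, Wald inference);
participant heterogeneity is deliberately present in the generator but not
estimated — it is a robustness dimension of the tests, not an estimand, and
mixed-model machinery would be a heavy dependency tangential to the
acoustic core. Catch trials are not simulated; they filter human
inattention, which has no simulated analogue. Perfectly separated data are
rejected with an error naming the offending predictor.

## Problem sizes used in the validation suite

The recovery studies run at the scale of the experiments they emulate:
boundary recovery uses 20 independent 60-stimulus experiments; type-I-error
calibration uses 400 replicates of a 30-participant, 32-stimulus null
experiment; effect-sign recovery uses 10 seeds of a 31-participant
experiment on the 32-stimulus factorial.

## What the synthetic corpora do and do not show

The generators realize the *documented acoustic structure* of each stimulus
class — band centers and widths, dip depths and timing, mode-frequency
ordering by area and perimeter, envelope smoothness classes — with
variance-control choices (flat-magnitude excitation, envelope flattening)
that real recordings do not enjoy. Passing tests therefore demonstrate that
the analysis pipeline measures what those manipulations manipulate and that
the fitting machinery recovers known ground truth; they do not demonstrate
model fit to human behavioral data, reproduce any recorded stimulus, or
model contact mechanics (modal amplitudes as a function of excitation
point, nonlinear contact noise) beyond a schematic click. The respondent
simulator likewise recovers generator truth, not human effect sizes: the
published per-trial behavioral estimates depend on data that are not all
public and are out of scope as numeric targets.

## Known limitations

- The gammatone convention (order, spacing, framing) is one reasonable
  realization constrained only by the 800/1800 Hz landmarks.
- Continuity eligibility is caller-supplied metadata.
- The perimeter weight in the impact synthesizer is a perceptual
  exaggeration of the literal membrane correction, chosen once to realize
  the documented band contrast at corpus scale.
- Only fixed-effects logistic estimation is provided; random-slope
  structures cannot be recovered.
- WAV is the only supported audio container (PCM and IEEE float).
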