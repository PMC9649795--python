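# soundshape

Acoustic modeling of the **bouba-kiki effect** — the robust human tendency
to match some sounds to round shapes and others to spiky shapes.

`soundshape` implements a two-parameter phenomenological model of round/spiky
judgments, built for auditory psychophysicists who want to score arbitrary
audio stimuli, synthesize controlled stimulus sets, and close the loop with
simulated forced-choice experiments.

## The model

Each stimulus is passed through a 64-channel gammatone filterbank (center
frequencies 50–20,000 Hz, uniformly spaced on the ERB-rate scale), producing
a cochleagram of frame energies. Two marginal statistics feed the model:

- **Spectral Balance** — from the mean spectrum *S*₁..₆₄ (per-channel energy
  averaged over frames), the low-minus-high contrast around a boundary
  channel *b*:

  Balance(b) = Σᵢ₌₁..b Sᵢ − Σᵢ₌b₊₁..₆₄ Sᵢ

  *b* is scanned over channels 20–30 (≈800–1800 Hz), the mid-spectrum region
  separating low-frequency cues typical of round-judged sounds from the
  high-frequency cues typical of spiky-judged ones.

- **Temporal Continuity** — from the frame-energy track *E*₁..T (energy
  summed over channels), the log ratio of minimum to maximum energy inside
  the stimulus:

  Continuity = ln( minₜ Eₜ / maxₜ Eₜ )

  0 for a flat envelope, strongly negative for a deep interior dip.

Per-stimulus round scores (percentage of round choices, or a rating-derived
equivalent) are then predicted by ordinary least squares from Balance — plus
Continuity when the stimulus set supports it — and the boundary *b\** that
maximizes explained variance *r*² is selected.

The package also synthesizes the three non-speech stimulus classes used to
probe this model, grounded in the physics of sounding objects: amplitude-
modulated noise bands (a Balance × Continuity factorial), struck-membrane
impact sounds whose modes follow a Weyl-type area/perimeter counting law (for
equal area, the round, minimal-perimeter drum rings lower — one can hear the
shape of a drum), and rolling sounds with smooth vs sharp envelopes plus
envelope transplants onto spectrally shaped noise.

## Worked example

Synthesize the 32-stimulus noise-band factorial (8 center frequencies ×
4 dip amplitudes), analyze it, simulate 31 forced-choice participants whose
choices are driven by the acoustic indices, and recover the effects:

```python
import numpy as np
from soundshape import forge, indices, model
from soundshape import respondents as rsp

waves, design = forge.noise_band_corpus(master_seed=1)
results = indices.analyze_corpus(waves)

bal = np.array([r.balance(25) for r in results])
cont = np.array([r.continuity for r in results])
pred = design[["stimulus", "fc", "dip_amp"]].copy()
pred["zbal"] = (bal - bal.mean()) / bal.std()
pred["zcont"] = (cont - cont.mean()) / cont.std()

population = rsp.RespondentModel(slopes={"zbal": 1.0, "zcont": 0.6},
                                 participant_sd=0.5, seed=1)
trials = rsp.simulate_trials(pred, population, n_participants=31)

print(rsp.glm_fit(trials, ["fc", "dip_amp"]).round(4).to_string(index=False))

table = rsp.to_experiment_table(trials)
fit = model.scan_boundary(results, table)
print(f"b* = {fit.b_star}, r2 = {fit.r2:.2f}, t = {fit.t_stat:.2f}")
```

Output:

```
   term  estimate     se       z   p
  const    1.1303 0.2119  5.3351 0.0
     fc   -0.0021 0.0003 -8.0885 0.0
dip_amp    1.2353 0.1759  7.0234 0.0
b* = 25, r2 = 0.85, t = 12.85
```

The logistic fit on the raw trials recovers a negative center-frequency
slope (higher bands → fewer round choices) and a positive dip-amplitude
slope (more continuous envelopes → more round choices). Aggregating the
trials to per-stimulus round scores and scanning the boundary, the
Balance × Continuity model explains 85% of the score variance with the
boundary selected at channel 25 (≈1160 Hz).

The same pipeline is available from the shell:

```bash
soundshape synth noise-band --seed 1 --out corpus/
soundshape analyze --in corpus/ --out indices.csv
soundshape fit --audio corpus/ --scores scores.csv --out fit.json
soundshape report --fit fit.json --scores scores.csv --out report/
```

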