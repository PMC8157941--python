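# mfv — maternal–fetal vital-sign processing

`mfv` is the signal-processing and analytics chain of a wireless
maternal–fetal monitoring system: a chest patch (ECG at 512 Hz, tri-axial
accelerometry at 52 Hz, skin temperature at 0.2 Hz), a finger-worn limb
sensor (dual-wavelength PPG at 256 Hz), and an abdominal patch (Doppler
ultrasound at 504 Hz, two-channel electrohysterography/ECG at 500 Hz), all
on one millisecond-synchronized session clock.  From those raw streams the
package derives, for clinicians and researchers studying labor monitoring:

- **Maternal heart rate** — Pan–Tompkins QRS detection (band-pass 5–15 Hz,
  derivative, squaring, 150 ms moving integration, adaptive dual thresholds
  with search-back), HR = 60000 / mean R–R per window.
- **SpO₂** — ratio of ratios `R = (AC_red/DC_red)/(AC_ir/DC_ir)` mapped
  through the empirical linear curve `SpO₂ = c₀ − c₁·R` (defaults 110, 25).
- **Respiratory rate** — fusion of band-passed (0.1–1 Hz) chest-wall motion
  on the accelerometer x/y axes with ECG-derived respiration (R-amplitude
  modulation), combined by quality-weighted median.
- **Fetal heart rate** — rectified low-pass Doppler envelope; S1/S2
  valve-closure peaks paired with an 80–250 ms gap prior and the beat
  period confirmed by windowed autocorrelation, so one heartbeat is never
  counted twice.
- **Uterine contractions** — electrohysterography band-pass (0.34–1 Hz),
  60 s RMS envelope, two-channel max fusion, baseline-adaptive threshold,
  optional affine mapping to mmHg against a reference tocodynamometer.
- **Fetal ECG** — maternal-template subtraction on the abdominal
  biopotential (median beat, per-beat least-squares scale + derivative
  alignment term), then QRS detection retuned to fetal rates on the
  residual.
- **Continuous blood pressure** — pulse arrival time (R peak → PPG pulse
  peak) with the linear surrogate model `BP = a·PAT + b·HR + c` calibrated
  against a continuous monitor or sparse cuff readings.
- **Body posture** — an 8-component Gaussian mixture over gravity-frame
  accelerometry, clusters merged into supine / lateral / hands–knees /
  high Fowler's by nearest canonical gravity direction.
- **Analytics** — Bland–Altman limits of agreement, pooled time-to-vital
  heat maps with 4-hour window normalization, per-posture vital summaries,
  and Markdown session reports.

A scenario simulator (`mfv.simulate`) generates every stream at the native
rates with exact ground truth (beat, pulse, and breath times; contraction
schedules; posture labels; per-beat PAT and BP), which is how the entire
chain is validated.

## Worked example

```python
import numpy as np
from mfv.simulate import ScenarioConfig, simulate_session
from mfv.maternal import detect_r_peaks, hr_from_beats
from mfv.abdominal import doppler_envelope, detect_fhr

cfg = ScenarioConfig(duration_s=60.0, maternal_hr_bpm=94.0,
                     fetal_hr_bpm=140.0, seed=1)
session, truth = simulate_session(cfg)

beats = detect_r_peaks(session.get("chest", "ecg"))
hr = hr_from_beats(beats)
print("maternal beats:", beats.n, "truth:", truth.maternal_beat_ms.size)
print("maternal HR:", round(float(np.nanmean(hr.values)), 1), "bpm")

env = doppler_envelope(session.get("abdominal", "doppler"))
fetal_beats, fhr = detect_fhr(env)
print("fetal HR:", round(float(np.nanmean(fhr.values)), 1), "bpm")
```

prints

```
maternal beats: 94 truth: 94
maternal HR: 94.0 bpm
fetal HR: 140.0 bpm
```

every maternal QRS found (94 beats in 60 s at a 638 ms R–R interval), the
windowed heart rate at the simulated 94 bpm, and the fetal rate read as
140 bpm — not the 280 peaks/min the S1+S2 pair train would suggest without
pairing.

## Command line

`mfv` exposes the same pipeline as subcommands operating on EDF or
long-format CSV sessions:

```
mfv simulate --duration 600 --seed 1 --out session.edf --truth truth.json
mfv info     --in session.edf
mfv vitals   --in session.edf --out vitals.csv --window 10
mfv fhr      --in session.edf --out fhr.csv --audio doppler.wav
mfv toco     --in session.edf --out contractions.csv
mfv fecg     --in session.edf --out fetal_beats.csv
mfv bp       --in session.edf --calib cuffs.csv --out bp.csv
mfv posture  fit --in session.edf --model posture.json
mfv posture  apply --in session.edf --model posture.json --out posture.csv
mfv agree    --device vitals.csv --reference ref.csv --vital hr_bpm
mfv heatmap  --in vitals.csv --vital hr_bpm --out heatmap.csv
mfv report   --in session.edf --out report.md
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a freshly simulated labor
session — QRS/pulse detection, SpO₂, respiration, temperature, fetal heart
rate, contraction detection, fetal ECG isolation, cuff-calibrated blood
pressure, posture classification, and the agreement/heat-map analytics —
prints each derived quantity, and writes the JSON manifest to `--out`.

## Documentation

`docs/methods.md` describes the models, their assumptions, every tunable
parameter with units and defaults, what the simulator does and does not
emulate, and known limitations.
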