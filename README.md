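# piva

Windowed-FFT analysis of venous pressure waveforms recorded during CPR.

During chest compressions, pressure oscillations at the compression frequency
appear in peripheral and central venous lines. This package extracts their
amplitude per FFT window — the PIVA (Peripheral Intravenous Analysis) value —
tracks its rise-peak-fall trajectory at multiple venous sites, detects the
end-tidal CO2 doubling event, summarizes hemodynamics over CPR quarters, and
compares event timings relative to ROSC (return of spontaneous circulation)
across subjects. A seeded synthetic-recording generator with known ground
truth makes the whole pipeline testable end to end.

## What's inside

- `piva.synthetic_data` — multi-channel CPR-epoch recording generator
  (three venous sites with configurable amplitude envelopes, an arterial
  pressure ramp, a capnography trace with a pre-ROSC surge) plus the ground
  truth the parameters imply.
- `piva.io` — CSV sample matrix + JSON sidecar interchange, results
  serialization, and a tolerant reader for tab-delimited chart exports.
- `piva.spectral` — non-overlapping 8192-sample window segmentation,
  single-sided amplitude spectra (a pure sinusoid of amplitude A reads A at
  its bin), dominant-frequency search in a band around the nominal
  compression rate (200/min → 3.33 Hz), PIVA series extraction.
- `piva.events` — PIVA peak detection, the >100%-of-first-minimum etCO2
  rule (three variants of the ambiguous "first lowest value"), coronary
  perfusion pressure, per-cycle amplitudes and arterial metrics,
  equal-duration quarter summaries.
- `piva.stats` — timing tables (seconds before ROSC), mean ± SE
  descriptives, Shapiro–Wilk normality (Royston AS R94, implemented here),
  uncorrected pairwise Fisher's LSD with an optional repeated-measures
  error term.
- `piva.cli` — the `piva` command.

## Command-line pipeline

```sh
# 1. generate a synthetic recording with ground truth
piva simulate --seed 1 --out-dir sim --noise-sd 0.2

# 2. analyze a recording: PIVA series, events, quarter summary
piva analyze sim/recording.csv sim/recording.json --out-dir analysis \
    --window-samples 8192 --band-hz 1.0 --taper rect

# 3. aggregate several subjects' events into timing statistics
piva report analysis_a/events.json analysis_b/events.json \
    --out-dir report --alpha 0.05
```

`analyze` writes `events.json` (with a provenance block recording every
parameter and input checksum), `piva_<channel>.csv` per venous channel, and
`quarters.csv` (metrics × quarters). `report` writes `timing_table.csv`
(subjects × event types, seconds before ROSC) and `comparisons.json`
(descriptives, Shapiro–Wilk screens, pairwise LSD p-values). All commands
accept `--config config.yaml` with per-subcommand sections; flags override.
Exit codes: 0 success, 1 user error, 2 internal error.

## Conventions

- Time is seconds from the first sample; annotations (CPR start, ROSC,
  nominal compression rate) live in the JSON sidecar in seconds.
- All pressures and partial pressures are mmHg.
- Window timestamps are window centres; the default hop equals the window
  length (no overlap) and is configurable.
- Amplitude spectra subtract the window mean and use a rectangular taper by
  default (`--taper hann` compensates the coherent gain).
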