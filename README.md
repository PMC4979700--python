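# dawnchorus

Soundscape phenology from dawn-chorus recordings: detect the spring arrival
of migratory songbirds in long-running acoustic monitoring data, without
listening to any of it.

Passive acoustic recorders are cheap to deploy at remote sites, but the
resulting months of audio are far too large to review by ear. `dawnchorus`
implements the standard reduction chain used in ecoacoustic monitoring and
the statistics that turn it into phenology:

1. **Calibrated band levels** — waveforms are reduced to 1-second
   1/3-octave-band sound pressure levels (SPL, dB), 12.5–6300 Hz, with
   broadband A-weighted hourly medians (L50) to locate the dawn chorus.
2. **Dawn windowing** — analysis is restricted to 0.5 h before to 2.5 h
   after local sunrise, computed offline with NOAA solar-position
   equations.
3. **Quality screening** — seconds obscured by wind/rain/anthropogenic
   noise are flagged by a low-frequency energy proxy; days with
   strictly more than 25 % obscured seconds are excluded, and index
   analysis keeps only the eight 1/3-octave bands between 1250 and
   6300 Hz where songbird energy concentrates.
4. **Acoustic Complexity Index (ACI)** — per band *f* with per-second
   levels SPL₁…SPLₙ over the 3-h window,

   ACI_f = Σₜ |SPLₜ − SPLₜ₊₁| / Σₜ SPLₜ,   ACI_tot = Σ_f ACI_f,

   high for intermittent biotic sound, low for steady noise. A
   fine-resolution STFT variant (0.01-s frames, ≈86.1 Hz bins) is included
   for sensitivity comparison.
5. **Bayesian change-point analysis** — the daily ACI series is fit with a
   Barry–Hartigan normal product-partition model by Gibbs sampling
   (10,000 iterations after 5,000 burn-in); the first posterior-probability
   peak above 0.5 dates the spring transition, reported with the ACI
   fold-change over the preceding days. An exact enumeration over all
   2ⁿ⁻¹ partitions is provided as the small-n calibration oracle.
6. **Species detection and community metrics** — band-limited
   (time–frequency) energy detectors with false-negative-rate count
   correction, Shannon/Gini–Simpson/richness diversity of vocalization
   tables, and OLS association of ACI with call counts and weather.

Because real monitoring archives are rarely shareable, the package ships a
seeded synthetic-scene generator (`dawnchorus.scenes`) producing
dawn-chorus audio and/or band-SPL matrices with exhaustive ground truth:
2–4 species templates (tonal whistle 2500–5850 Hz, complex FM song
3–9 kHz, intermediate phrase), a Poisson song process whose daily rate
steps up on a configurable arrival day, ambient noise, and broadband
weather bursts. All tests and the acceptance script run on these scenes.

## Worked example

A 60-day synthetic spring season with three species arriving on
2012-04-16 and two storm days (config in `examples/season.yaml`):

```sh
$ dawnchorus sunrise --lat 58.45625 --lon -135.86603 --date 2012-04-16 --utc-offset -8
2012-04-16T05:46:46-08:00

$ dawnchorus run-all --config examples/season.yaml --out run1
run complete: 7 outputs in run1
transition 2012-04-16 prob=1.00 fold=2.20
```

The run directory contains the daily ACI table, the screening report (the
two storm days are excluded), the per-day change-point posterior, the
diversity and association tables, and a `manifest.json` with the config
hash and seed; reruns are byte-identical. The transition line says: the
earliest day whose posterior change probability exceeds 0.5 is
2012-04-16 — the configured arrival day — where the daily ACI is 2.20×
the mean of the preceding retained days. The association table from the
same run shows ACI tracking vocal activity (OLS of daily ACI on true call
counts: slope 3.7 × 10⁻⁴ per song, R² ≈ 0.999) and temperature
(R² ≈ 0.60), and no relationship with wind (R² ≈ 0.002).

The same steps are available as library calls (`synthesize_day_band_spl`,
`restrict_bands`, `aci_total`, `bcp_fit`, `detect_transition`, …) for use
on real band-SPL matrices or WAV audio.

## Documentation

`docs/methods.md` describes the model, the synthetic-scene design and its
limits, numerical choices, and known limitations.
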