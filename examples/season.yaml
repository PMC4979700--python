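# A 60-day spring season at Bartlett Cove-like coordinates, with three
# synthetic species arriving on 2012-04-16 and two storm days.
site: {name: BARTLETT, lat: 58.45625, lon: -135.86603, utc_offset: -8}
season: {start: 2012-03-17, end: 2012-05-15, arrival_day: 2012-04-16}
scene:
  mode: band            # "band" = 1-s 1/3-octave SPL substrate; "audio" = WAV
  pre_arrival_rate: 2.0   # songs/h per species before arrival
  post_arrival_rate: 40.0 # songs/h per species on/after arrival
  band_ambient_db: 30.0
  noise_jitter_db: 0.3
weather_events:
  - {date: 2012-03-24, start_s: 1200, duration_s: 4000, level: 22}
  - {date: 2012-04-29, start_s: 300, duration_s: 5000, level: 25}
screen: {low_band_ceiling: 800, threshold_db: 10}
aci: {min_freq: 1250, max_freq: 6300}
changepoint: {iterations: 10000, burn_in: 5000, threshold: 0.5}
seed: 1
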