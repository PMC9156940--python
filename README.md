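# nremlink

Analysis pipeline linking neural population activity during NREM sleep to
next-day exploratory behavior, exercised end to end on a synthetic
multimodal data generator. The package provides:

- **`nremlink.synthetic_data`** — multi-mouse, multi-day dataset generator:
  semi-Markov hypnograms (NREM-majority, REM-sparse, configurable REM
  latency), state-dependent EEG/EMG (delta-dominant NREM, theta-dominant REM
  with atonia), photometry traces with Poisson calcium-like transients, and
  maze/object-arena trajectories whose slow-vs-fast port-visit mixture is
  coupled (with a controllable coefficient) to the preceding simulated NREM
  activity. Ground truth (hypnogram, event times, motif labels, coupling) is
  returned for every recording.
- **`nremlink.sleep_scoring`** — rule-based vigilance-state classification in
  5 s epochs from EEG band power (delta 1–4 Hz, theta 4–10 Hz) and EMG RMS,
  plus bout tables, state occupancy, relative-power spectral profiles and
  per-state EMG tone.
- **`nremlink.photometry`** — dF/F = (F_r − F_m)/F_m with median baselines,
  polynomial detrending, automatic "quiet period" search in NREM, transient
  detection (prominence > 3 × quiet SD, half-width ≥ 1.5 s), per-state
  counts/rates/cumulative integrals, cross-animal standardization, and
  event-aligned averaging.
- **`nremlink.maze_behavior`** — port-zone visit detection (50–58 cm annulus,
  ±6° wedges), port-visit speed (−0.5 to +2.5 s around entry), BIC-selected
  Gaussian-mixture bimodality of visit speeds, correct-pod visits
  with/without entry, trial distance/velocity metrics, novelty preference
  and occupancy maps.
- **`nremlink.behavior_clustering`** — temporally regularized VAE + SOM
  clustering of 10 s trajectory windows (100 steps × 7 features) into 36
  behavioral clusters with per-trial occupancy vectors. Implemented in
  numpy with hand-written backpropagation (deterministic given a seed,
  CPU-friendly).
- **`nremlink.stats_linking`** — sleep→next-day behavior link tables,
  per-cluster Pearson correlations with Bonferroni control, quartile-based
  Mann–Whitney comparison of visit speeds, generic group comparisons and
  coupling-recovery regression.
- **`nremlink.cli`** — `nremlink` command with `simulate`, `score-sleep`,
  `photometry`, `maze`, `object`, `cluster train|assign`, `link`, `run`
  (full pipeline) and `report` subcommands, a YAML run config and a
  reproducibility manifest.

## CLI quick start

```sh
# generate a synthetic experiment as plain-text files
nremlink simulate --seed 1 --out data/

# score one rest recording
nremlink score-sleep --eeg data/mouse00/day00/eeg.csv \
    --emg data/mouse00/day00/emg.csv --fs 100 --out scored/

# full synthetic pipeline (simulate -> score -> photometry -> maze ->
# cluster -> link -> report) with one config file
nremlink run --seed 1 --out run/
cat run/report.json
```

Run configs are YAML files with per-module sections (`sim`, `cluster`,
`geometry`, `photometry`, `link`); `nremlink run --config cfg.yaml` fills
defaults for anything omitted.

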