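# walknet

Analysis pipeline for arm–leg coordination during treadmill walking, from
multichannel gait EMG and kinematics to muscle synergies, bias-corrected
intermuscular coherence, and multiplex muscle networks — exercised entirely
on a synthetic-study generator with planted ground truth.

## What it does

- **`walknet.synthgen`** — generates study-like datasets: 26-channel EMG
  (2 kHz) whose envelopes mix a small number of planted synergies,
  band-limited common inputs shared by muscle subsets (planting coherence in
  chosen bands), ground-reaction-force traces with recorded heel-strike
  onsets, and arm/leg kinematics locked at 2:1 or 1:1 (or drifting between
  them). Deterministic given a seed.
- **`walknet.gaitkin`** — heel-strike detection (8%-of-mean GRF threshold)
  and coordination-mode classification (2:1 / transition / 1:1) from
  spectral overlap after frequency-axis rescaling and the circular variance
  of the generalized relative phase.
- **`walknet.emgprep`** — ICA-based heartbeat suppression, 30 Hz
  bidirectional high-pass + analytic-signal rectification, 10 Hz envelopes,
  stride time-normalization (N = 200), amplitude normalization to the
  fastest speed, and assembly of the concatenated envelope matrix X.
- **`walknet.synergy`** — multiplicative-update NMF with best-of-restarts,
  the dual-cutoff rank rule (λ ≥ 80%, Δλ ≥ 1.5%), per-synergy contributions
  λ_s, and peak-timing ordering.
- **`walknet.imc`** — Welch squared coherence (200 ms Hamming taper, ~50%
  overlap, 1 Hz padded grid) for all 325 muscle pairs, phase-randomization
  surrogate bias correction with χ²(2) significance masking, the f × (SC·325)
  coherence-set matrix, NMF frequency components (λ ≥ 55%, Δλ ≥ 4%), and a
  low-frequency variant (5 s taper, 0.6–4 Hz).
- **`walknet.musclenet`** — synergy networks (outer products weighted by
  waveform integrals), coherence networks per frequency component ×
  condition, minimally-connected multiplex thresholding with equal edge
  counts, Louvain community structure, weighted global efficiency /
  transitivity / average strength, and partition comparison (Rand, adjusted
  Rand, permutation p-value).
- **`walknet.waveformstats`** — 1-D paired waveform comparison via sign-flip
  permutation cluster inference (Bonferroni-corrected α, e.g. 0.05/(3·5) =
  1/300) and repeated-measures ANOVA on network metrics with paired
  post-hoc tests.
- **`walknet.pipeline`** — orchestrates everything into one JSON report and
  scores the run against the planted ground truth.

## CLI

One entry point with subcommands:

```sh
walknet generate --out study/ --subjects 2 --speeds 1.0,2.0,4.0 --seed 0
walknet classify --trial study/trial_s01_v1.0.tsv
walknet synergy-fit --envelopes X.tsv --seed 0
walknet imc-run --trials study/ --band 4:60 --surrogates 100 --seed 0 --out coh.tsv
walknet net analyze --layers layers.json
walknet run --config run.yaml --out report/ --seed 0
walknet validate --report report/report.json --truth study/ground_truth.json
```

`walknet run` uses defaults mirroring the study's printed parameters
(cutoffs, tapers, alphas) with generator sizes scaled for a single CPU;
any value can be overridden in the YAML config.

## Data formats

Trials are long-format TSV (`time_s, channel, value`) with a JSON
ground-truth sidecar; envelope matrices are TSV; networks are edge lists /
JSON; reports are JSON. Everything is plain text and reproducible from a
seed.
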