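# ecgrbp

Human identity verification from raw single-lead ECG using reduced binary
patterns (RBP). The signal is symbolised by the sign of (optionally strided
and amplitude-thresholded) sample-pair differences, the resulting bits are
grouped into overlapping m-bit words, and the word histogram's rank/frequency
profile is the biometric feature. No QRS detection, de-noising or baseline
correction is performed anywhere — raw samples go straight in.

Components:

- `ecgrbp.core` — signal → bits → words → rank profile (`reduce_binary`,
  `words_from_bits`, `count_and_rank`, `profile_signal`). The basic variant
  is stride `alpha=1`, threshold `beta=0`; the advanced variant exposes both.
- `ecgrbp.similarity` — rank-weighted segment distance in [0, 1] and the
  mean group distance over two segment sets (`segment_distance`,
  `group_distance`, `pairwise_matrix`).
- `ecgrbp.evolving` — per-subject models whose frequencies are blended with
  each new recording at weight `gamma`, plus the daily-update long-term
  protocol (`record_profile`, `update_model`, `run_longterm_protocol`).
- `ecgrbp.evaluation` — subject-pair success rate and FA/FR at a threshold
  tuned to minimise (FA + FR)/2.
- `ecgrbp.io` — record loading (WFDB header/signal pairs in formats 212/16,
  one-column CSV, synthetic specs) and fixed-duration segmentation.
- `ecgrbp.synthetic` — seeded multi-subject generator (five Gaussian bumps
  per beat, rate variability, noise, optional per-session drift) so the full
  pipeline is testable without any downloads.
- `ecgrbp.experiments` — drivers tying these together for database-wide
  evaluations.

## CLI

```sh
# rank profile of a record as JSON
ecgrbp profile rec.csv --fs 360 --m 8 --out profile.json

# distance between two records (whole-record profiles by default;
# pass --segment-seconds to average over fixed windows)
ecgrbp distance a.csv b.csv --fs 360
ecgrbp distance 1:80:360 2:80:360 --format synthetic

# multi-subject verification; --alpha takes a comma list to sweep the stride
ecgrbp evaluate --synthetic 10 --seed 1 --alpha 1,5,15 --beta 1 --out report.json
ecgrbp evaluate --database-dir data/mitdb --format wfdb --matrix-out dist.csv

# long-term protocol with daily model updates
ecgrbp evolve --synthetic-seed 3 --sessions 5 --drift-rate 0.05 \
    --alpha 13 --beta 1 --gamma 0.5

# write synthetic fixture records (CSV or WFDB) plus a manifest
ecgrbp synth --subjects 10 --duration 80 --fs 360 --seed 1 --out-dir fixtures/
```

A YAML config can supply defaults for any flag (`ecgrbp --config cfg.yaml
evaluate ...`); explicit flags win.

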