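# create-lab

A tested, reproducible implementation of a multi-modal cognitive-training
analysis pipeline. It covers four measurement modalities and the
statistical machinery used to validate them, plus a synthetic-cohort
generator with planted ground truth so every stage can be exercised
end to end without any external data.

## Modules

| Module | What it does |
| --- | --- |
| `create_lab.synthetic_cohort` | Gaussian-copula latent traits (WM, emotion regulation, sleep, dopaminergic tone) mapped monotonically to trial logs, questionnaire responses, narrative texts, and eye-opening signals with planted blink events; emits `truth.json` alongside the data |
| `create_lab.wm_game` | Adaptive sequence-recall task engine (level/display-duration schedule re-evaluated every 10 trials) and the eight session metrics (correct counts, max/median/mean running score, threshold counts, longest streak) |
| `create_lab.psychometrics` | PSQI scoring (7 components, global 0–21, Good/Poor split at global > 5) and ERQ scoring (reappraisal items 1,3,5,7,8,10; suppression 2,4,6,9) |
| `create_lab.sentiment_text` | Six narrative features per comment — polarity, subjectivity, average word length, token count, unique tokens, type–token ratio — from a packaged, auditable affect lexicon with a one-token negation rule |
| `create_lab.blink_sebr` | Blink detection from eye-opening-ratio series (threshold + hysteresis state machine, minimum-duration filter, refractory merge) and pre/post/diff summaries |
| `create_lab.affect_space` | Valence–arousal quadrant classification (midpoint 5.5, boundary = low) and the per-participant HVHA arousal-deviation predictor |
| `create_lab.stats_validation` | ±2 SD listwise outlier filter, Spearman correlation matrix with 2000-permutation empirical p-values, exact/approximate Mann–Whitney U, and single-predictor OLS with the full diagnostic report (R², F, AIC/BIC, Durbin–Watson, omnibus, Jarque–Bera, condition number) |
| `create_lab.pipeline` / `create_lab.cli` | Orchestration: simulate → score → analyze → report with deterministic, byte-stable outputs |

## CLI

```bash
# generate a synthetic 27-participant dataset
create-lab simulate --out data/ --seed 1

# individual scoring stages
create-lab score-wm --in data/wm_trials.csv --out wm_scores.csv
create-lab score-questionnaires --in data/questionnaires.csv --out q_scores.csv
create-lab text-features --in data/art_ratings.csv --out features.csv
create-lab detect-blinks --signals data/eye_signals.csv \
    --sessions data/eye_sessions.csv --out blinks.csv

# full statistical pipeline (outlier filter, permutation correlations,
# sleep-group comparisons, HVHA regression)
create-lab analyze --data data/ --out analysis/ --seed 1
create-lab report --analysis analysis/
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. All randomness is
seed-controlled; re-running any command with the same inputs and seed
produces byte-identical outputs.

## Data formats

All files are UTF-8 CSV with a header row and ISO-8601 timestamps:

- `wm_trials.csv`: participant_id, trial_index, level, display_duration_ms, correct (0/1), running_score, timestamp
- `art_ratings.csv`: participant_id, stimulus_id, presentation_index, arousal, valence, familiarity (1–10), comment, timestamp
- `questionnaires.csv`: participant_id, instrument (PSQI|ERQ), item_id, response
- `eye_signals.csv` + `eye_sessions.csv`: sampled eye-opening ratio per frame plus per-recording fps metadata
- `truth.json`: planted latent traits, sleep groups, blink counts/onsets, and narrative targets for the synthetic cohort

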