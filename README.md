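# oxyreg

Closed-system respirometry analysis for hypoxia response curves (HRCs) in
corals, plus in-situ dissolved-oxygen logger summarization.

A sealed chamber containing one coral fragment is logged (% air saturation,
60 s cadence) while the fragment draws oxygen down from ~100% saturation to
anoxia. `oxyreg` turns such traces into oxygen-consumption-vs-ambient-O2
curves, fits a constrained model family, and extracts oxyregulation
statistics from the regulation function

```
rho(x) = f(x)/x - f'(x)
```

which is zero under strict oxyconformity (respiration proportional to
ambient O2) and positive wherever respiration is held above the conformity
line. Extracted statistics:

- **T_pos** — integral of the positive part of rho over the evaluated pO2
  window (total positive regulation, relative units);
- **P_cmax / P_cmin** — pO2 (% air saturation) at which rho is maximal /
  minimal, i.e. where regulation effort peaks / vanishes.

## Modules

| module | role |
|---|---|
| `oxyreg.respirometry` | trace reading, O2 solubility (Benson–Krause), windowed blank/volume-corrected VO2, drawdown durations, curve normalization |
| `oxyreg.hrc_models` | model family (origin-constrained linear, polynomials of degree 2–12, Michaelis–Menten), Gaussian AIC, ranking |
| `oxyreg.regulation_profile` | rho evaluation, T_pos/P_cmax/P_cmin extraction, replicate summaries |
| `oxyreg.field_oxygen` | in-situ DO logger series: threshold statistics, time-at-DO histograms, interior/exterior deltas, tide/diel alignment |
| `oxyreg.stats_compare` | pooled/Welch/paired t-tests, Pearson correlation, Shapiro–Wilk/Levene checks |
| `oxyreg.synthetic_data` | drawdown and field-series generators with known ground truth (RK4 chamber integration) |
| `oxyreg.pipeline` | end-to-end orchestration from a sample sheet or YAML config |

## CLI

```sh
# simulate a Michaelis-Menten drawdown and its seawater blank
oxyreg simulate drawdown --model mm --K 0.15 --seed 7 --out trace.csv

# windowed VO2 rates for all chambers in a sample sheet
oxyreg vo2 --traces traces/ --sheet samples.csv --window 600 --step 300 --out rates.csv

# fit the model family to a normalized curve (columns x,y) and rank by AIC
oxyreg fit --curve curve.csv --models linear,mm,poly:2..12 --out fits.json

# regulation statistics from the best fit
oxyreg profile --fits fits.json --floor 0.02 --grid 1000 --out profile.csv

# group comparisons on a results table
oxyreg compare --table profile.csv --group position --stat t_pos,p_cmax,p_cmin --out compare.json

# field logger pair: summaries, histograms, deltas
oxyreg field --int int.csv --ext ext.csv --out summary.json

# full study from a YAML config
oxyreg run --config study.yaml
```

`oxyreg run` writes `fragments.csv`, `groups.csv`, `comparisons.json` and
(when field series are configured) `field.json` into the configured output
directory.

Column dictionary for `fragments.csv`: `chamber_id`; `group` (comparison
label); `flag` (non-empty = excluded with reason); `duration_h` (+
`duration_censored`) — 100%→0% drawdown time; `selected_model`, `rss`,
`aic` for the AIC-best fit (`aic_<model>`/`rss_<model>` for all ranked
candidates); `t_pos`, `t_neg`, `p_cmax`, `p_cmin`; `x_lo`, `x_hi` —
evaluation window. `groups.csv` holds per-group `n` and `<stat>_mean` /
`<stat>_se` for each statistic.

### Study config (YAML)

```yaml
sample_sheet: samples.csv   # chamber_id, group, chamber_volume,
                            # displacement_volume, blank_id, ...
trace_dir: traces           # one <chamber_id>.csv per chamber
blanks:                     # blank_id -> trace CSV
  site-blank: blanks/site-blank.csv
models: [linear, mm, "poly:2..12"]
window: 600                 # rate window (s)
step: 300                   # window step (s)
salinity: 35                # air-sat -> mg/L conversion for incubations
floor: 0.02                 # low-pO2 floor of the rho evaluation window
tpos_mode: integral         # or range_mean
out_dir: results
```

The paper-style zero-salinity conversion (100% air sat = 7.67 mg/L at
29.12 °C, 1013 mbar) is an explicit override: `salinity: 0`.

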