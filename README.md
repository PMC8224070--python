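# orchardphen

Temperature-driven phenology forecasting for integrated pest management in
apple orchards: predicts the spring emergence of first- and
second-generation *Aphelinus mali* parasitoid adults and the onset of
woolly apple aphid (*Eriosoma lanigerum*) crawler migration from orchard
temperature records.

The package covers the full pipeline:

- **`rate_models`** — temperature → development-rate curves (saturated
  polynomials and linear degree-day models) with lower-threshold and
  upper-cutoff clamping; ships the two published polynomial models and the
  degree-day constants (5.2 °C / 267.6 DD for the aphid, 8.3 °C / 254.8 DD
  for the parasitoid).
- **`rate_fitting`** — nonlinear least-squares fitting of rate curves to
  development-time-at-constant-temperature data, AIC model comparison and
  residual diagnostics.
- **`phenology_engine`** — cumulative development over hourly or daily
  weather series starting 1 January with overwintering head starts
  (parasitoid: half a generation, from the 1:4:5 egg:larva:pupa stage
  ratio; aphid: first instars, no head start), first-crossing event
  extraction, and stochastic cohort simulation (50 individuals,
  rate sd 0.015 by default).
- **`validation_stats`** — observed-vs-predicted accuracy: day indices
  after 31 March, trap-bracket midpoint observation dates, OLS of observed
  on predicted (R², slope, p), MAE/RMSE/signed error, plus the
  parasitism-degree and leaf-wall-area field formulas.
- **`synthetic_data`** — seasonal + diurnal + AR(1) synthetic weather and
  interval-censored trap observations for end-to-end testing without
  external data.
- **`datasets`** — packaged fixtures: the 2010–2020 validation tables,
  degree-day constants and model configuration files.
- **`cli`** — the `orchardphen` command.

## CLI

```sh
# fit polynomial rate models to a development-time table and keep the best by AIC
orchardphen fit devtimes.csv -d 5 -d 6 --lower-threshold 8.3 -o model.yaml

# predict event dates (and a spray-avoidance advisory window) from weather
orchardphen predict weather.csv -m src/orchardphen/data/amali_polynomial.yaml \
    -m src/orchardphen/data/elanigerum_polynomial.yaml -o events.csv

# score predicted vs observed dates per event
orchardphen validate src/orchardphen/data/elanigerum_observations.csv -o report.csv

# end-to-end synthetic monitoring campaign
orchardphen simulate --years 11 --seed 1 -o synthetic_report.csv
```

Weather files are delimited text with `timestamp` (ISO-8601) and
`temperature_c` columns; observation files carry `year`, `event`,
`predicted` and either `observed` or `last_negative`/`first_positive`
bracket columns. Model configurations are human-editable YAML (see
`src/orchardphen/data/*.yaml`).

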