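# savphen

Savannah leaf-phenology modelling toolkit: estimates NDVI from lagged soil
moisture (optionally scaled by mean annual precipitation, MAP) and day
length, selected by exhaustive BIC search over all lag/transform
combinations, with relative-importance decomposition, site-holdout
cross-validation, and start-of-season / amplitude phenometrics. A
synthetic-site generator (pulsed bucket soil moisture, solar-geometry day
length, lagged log-linear NDVI response with composite-style sampling)
makes the whole pipeline testable without any external data.

## Layout

| module | purpose |
| --- | --- |
| `savphen.synthetic` | site ensembles: rainfall/bucket soil moisture, latent NDVI, 16-day-composite sampling |
| `savphen.preprocess` | day length, NDVI gap-fill + 8-day resampling, adaptive Savitzky–Golay smoothing, 8-day climate aggregation, variable screening |
| `savphen.lagged_model` | candidate enumeration (275 models at max lag 10), pooled OLS, BIC, selection |
| `savphen.importance` | grouped average-over-orderings R² decomposition (soil moisture vs day length, lags bundled), exact per-regressor LMG for small designs |
| `savphen.evaluation` | holdout CV (RMSE / r² / VIF), site-count sensitivity, SOS & amplitude phenometrics, correlation analyses |
| `savphen.io` / `savphen.pipeline` / `savphen.cli` | CSV/JSON/YAML I/O, orchestration, command line |

## Command line

```sh
# synthesize an ensemble, then run each stage explicitly
savphen simulate --out sites/ --seed 1
savphen preprocess --in sites/ --out aligned/
savphen select --in aligned/ --meta sites/metadata.csv --out model.json
savphen predict --model model.json --in aligned/ --meta sites/metadata.csv --out pred/
savphen importance --in aligned/ --out importance.csv
savphen evaluate --in aligned/ --meta sites/metadata.csv --model model.json \
    --reps 1000 --seed 42 --out eval/

# or everything at once on synthetic input
savphen run --simulate --out out/ --seed 1
```

`run` writes `out/model.json` (selected terms, coefficients, full BIC
ranking), `out/importance.csv`, `out/eval/` (per-repetition holdout rows,
site-count sensitivity curve, per-site RMSE / SOS error / amplitude
error), `out/summary.json`, and a stage-by-stage `run.log`. A YAML config
(`--config`) can override any knob; defaults are window 7, small window
3, jump threshold 0.08, max lag 10, 1000 repetitions, 3 held-out sites.

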