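# snowcross

Snow-track crossing-site analysis for road ecology: quantify a highway's
barrier effect from winter track surveys, select among four count-data
models with multi-scale landscape predictors, and compose per-group
abundance predictions into a community crossing-site preference map.

The pipeline stages:

1. **`snowcross.synthetic`** — generate landscape predictor tables (12
   digitized habitat proportions + 11 remote-sensed variables at 200 m /
   500 m / 1 km = 45 candidates), survey-point counts under Poisson / NB /
   ZIP / ZINB truths, and raw track records with a planted highway
   permeability, so every downstream stage is testable with known ground
   truth.
2. **`snowcross.survey`** — repeat-track deduplication (300 m rule), 12-hour
   effort standardization, crossings per km, permeability
   (highway rate / transect rate; 1 = no barrier), and track-accumulation
   curves with flat-segment (candidate barrier) detection.
3. **`snowcross.count_models`** — mean-0/sd-1 predictor standardization and
   maximum-likelihood fitting of Poisson, negative binomial (variance
   mu + mu²/θ), ZIP and ZINB (log link for counts, logit link for the
   structural-zero probability), with AIC/AICc and predicted-zero summaries.
4. **`snowcross.selection`** — likelihood-ratio tests, the Vuong non-nested
   test, distribution choice, a branching ΔAICc ≤ 2 beam search over
   predictor pools (plus exhaustive enumeration for small pools), the
   p ≤ 0.15 / >50-magnitude candidate filters, Akaike-weight model
   averaging, and cross-approach comparison with summed importance scores.
5. **`snowcross.mapping`** — 30 m prediction grids along a route corridor
   (15 m crossing buffer, 1 km approach buffer), averaged-model abundance
   surfaces, decile scores, the multiplicative community score
   (∏ deciles / 10^(g−1), max 10), and crossing-vs-approach overlap
   classification.
6. **`snowcross.cli`** — YAML-configured, seeded orchestration.

## CLI

```sh
snowcross full-run --seed 1 --out-dir out/
```

runs simulate → permeability → compare-distributions → search → average →
community-map with the shipped defaults (study-design constants, reduced
problem size) and writes delimited-text tables, a JSONL search trace,
GeoJSON cell maps and per-stage provenance manifests into `out/`.
Individual stages are available as subcommands (`simulate`, `permeability`,
`compare-distributions`, `search`, `average`, `predict`, `community-map`);
each reads the data artifacts in `--out-dir` and recomputes what it needs
deterministically. `--config my.yaml` overrides any default block
(landscape size, truth coefficients, filters, searched families/approaches,
buffers).

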