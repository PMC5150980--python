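# oxylume

Flow-injection chemiluminescence quantification of superoxide at biological
surfaces, as a tested, fully synthetic-data-driven pipeline:

- **`oxylume.simulate`** — kinetic trace simulator: piecewise-constant
  superoxide production with pseudo-first-order decay (`dC/dt = P(t) − k·C`,
  solved piecewise-analytically), linear instrument response, reagent-blank
  baseline, transit delay through the sampling tubing (pure `exp(−kτ)` loss),
  SOD-quench events, decaying standard injections, and blank replicate series.
- **`oxylume.traces`** — trace CSV I/O, plateau detection by a rolling
  coefficient-of-variation rule (<4 % CV), SOD-quench verification, and the
  tiered blank-correction scheme (coral − seawater, raw − reagent blank).
- **`oxylume.calibration`** — KO₂ primary-standard quantification from
  ΔA₂₄₀ (Beer–Lambert, ε = 2,183 L mol⁻¹ cm⁻¹), log-linear first-order decay
  fits, back-extrapolation of standard luminescence to the quantification
  time, and calibration curves with sensitivity (pM per count), 3σ detection
  limit, and matrix half-life.
- **`oxylume.quantify`** — corrected signal → concentration conversion,
  seawater normalization with quadrature s.d., and net production rates
  (steady-state concentration × flow rate, normalized per organism, reported
  in amol or fmol per organism per hour).
- **`oxylume.stats`** — full-factorial two-way ANOVA (Type-II SS) with Tukey
  HSD and two-sample t-tests (statsmodels/scipy-backed), plus Bray–Curtis
  dissimilarity and ANOSIM with permutation p-values implemented from their
  definitions (exact enumeration available for small n).

## CLI

The `oxylume` entry point exposes the pipeline stages:

```sh
# 1. simulate a field session from a YAML config (SimulationConfig fields,
#    plus an optional `phases:` list for a multi-segment session)
oxylume simulate --config session.yaml --seed 3 --out trace.csv

# 2. plateau detection + blank correction per annotated segment
oxylume process --trace trace.csv --annotations trace.annotations.csv \
    --cv-threshold 0.04 --window 30 --out segments.csv

# 3. calibration curve from standards + blanks, stored as YAML
oxylume calibrate --standards standards.csv --blanks blanks.csv \
    --matrix-k 0.0231 --out curve.yaml

# 4. concentrations and per-organism production rates
oxylume quantify --signals signals.csv --curve curve.yaml \
    --organisms 1000 --flow-rate 2.0 --out measurements.csv

# 5. statistics
oxylume stats anova  --table measurements.tsv --out anova.tsv
oxylume stats tukey  --table measurements.tsv --factor species --out tukey.tsv
oxylume stats ttest  --table pairs.tsv --variant unequal_variance
oxylume stats anosim --matrix counts.tsv --groups groups.tsv \
    --permutations 999 --seed 1
```

Trace CSVs carry a `#key=value` metadata header (`flow_rate_ml_min`,
`matrix`, `temperature_c`, `sampling_rate_hz`) followed by
`time_s,luminescence_counts` rows; annotations are a sidecar CSV with
`label,start_s,end_s`.

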