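# concord

Cross-community congruence analysis for multi-taxon surveys along an
environmental gradient — built for prairie-pothole-style wetland data where
birds, aquatic macroinvertebrates and vascular plants are sampled at the
same sites and the sites span a hydroperiod gradient from temporary to
permanently ponded.

**Who it is for.**  Community ecologists asking whether the agreement
between taxon groups' relative-abundance patterns (cross-community
congruence) can be explained by a shared response to the dominant
environmental gradient, or instead points to direct biological
interactions — and whether that agreement is stationary across the
gradient.

**What it computes.**  For Hellinger-transformed site × taxon matrices X, Y
(zero-padded to a common width, centered, unit-scaled), the symmetric
Procrustes correlation

    r = Σ σᵢ(Y*ᵀX*),    m² = 1 − r²,

with significance from the PROTEST row-permutation test,
p = (1 + #{r_perm ≥ r_obs})/(B + 1).  Around that statistic the pipeline
provides

- a **rarefaction sweep** (n = 3…40, resampled B times per n) locating the
  sample size where congruence estimates stabilize;
- a **stratified balanced bootstrap** that repeatedly subsamples each
  hydroperiod group to the size of the smallest one (proportional
  allocation by permanence class, largest-remainder rounding) before any
  group contrast;
- the **elevation summary** — how much cross-community congruence exceeds
  each community's congruence with four hydroperiod indicators (days
  ponded, maximum depth, amplitude ratio, evaporative index) — with an
  interactions-dominant / environment-consistent classification;
- a **stationarity contrast** (long- minus short-hydroperiod congruence per
  matrix pair, CI-overlap verdict); and
- a **synthetic-data generator** producing gradient-structured communities
  with a tunable cross-community coupling κ, so every stage can be
  exercised and validated without field data.

See `docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

Run the full analysis on a synthetic landscape (96 sites, three
communities, coupling κ = 0.6):

```python
import concord as c

cfg = c.PipelineConfig(
    scenario=c.SyntheticScenario(coupling=0.6),
    rarefaction=c.RarefactionSettings(n_min=3, n_max=40, iterations=30),
    bootstrap=c.BootstrapSettings(iterations=200, permutations=99, sig_iterations=20),
    seed=1,
)
report = c.run_pipeline(cfg)
print(report.table.to_frame().head(6).to_string(index=False))
print(report.elevation.to_dict())
```

which prints (group "all", balanced to the long-group size):

```
group                      pair   mean_r   ci_low  ci_high  median_p  significant
  all       birds~invertebrates 0.903951 0.894564 0.912108      0.01         True
  all              birds~plants 0.907771 0.898721 0.916798      0.01         True
  all      invertebrates~plants 0.989823 0.988793 0.990794      0.01         True
  all         birds~hydroperiod 0.735607 0.719252 0.750783      0.01         True
  all hydroperiod~invertebrates 0.756691 0.733384 0.781385      0.01         True
  all        hydroperiod~plants 0.760626 0.738644 0.781812      0.01         True
```

Every pair is significantly congruent (median permutation p = 0.01, the
floor at 99 permutations).  Cross-community congruence (≈0.90–0.99) clearly
exceeds community–hydroperiod congruence (≈0.74–0.76); the per-community
elevations are 23.1% (birds), 25.1% (invertebrates) and 24.7% (plants),
mean 24.3% ± SE 0.6%, and since every cross-pair interval lies above the
corresponding hydroperiod congruence the run is classified
`interactions-dominant` — the coupled world the scenario was built to
represent.  With `coupling=0.0` the same pipeline classifies the outcome
`environment-consistent`.

The same analysis runs from the shell on CSV inputs (site IDs in the first
column, taxon codes as header; metadata with permanence class and the four
indicators):

```sh
concord simulate --out demo/ --seed 3          # or bring your own CSVs
concord protest demo/birds.csv demo/plants.csv --permutations 999 --seed 1
concord run --config cfg.yaml                  # full pipeline from YAML
```

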