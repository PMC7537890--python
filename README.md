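# esvnet

Surrogate modelling and disassembly of the socioeconomic drivers of
ecosystem service value (ESV) on gridded city data.

Urban planners and landscape ecologists often know *that* ESV — the
monetized benefit flow from a region's ecosystems, assessed per land-area
unit with class-specific value coefficients (the equivalent-factor
method) — correlates with socioeconomic conditions, but not *how*: which
factors matter, in which direction, and where the optima sit. `esvnet`
re-implements a deep-learning answer to that question as a tested,
seed-reproducible pipeline:

1. **Spatial fusion.** City-level statistical totals (industry outputs,
   electricity/water consumption) are spread over the grid dasymetrically,
   `Af_i = As_i · wf_i / ws_i`, using ancillary weighting rasters
   (cultivated / industrial / residential / construction land, nighttime
   light, population). All 1 km layers are aggregated to 2×2 km analysis
   units, land-use areas become percentages, and every column is z-scored.
   The result is a table of n grid units × 23 coded factors (A1–A8 growth
   quality, B1–B7 ecological protection, C1–C8 resource utilization) plus
   the ESV response.
2. **Surrogate model.** A multilayer perceptron
   (128 linear → 256 tanh → 16 ReLU → 1 linear, dropout 0.3 after each
   hidden layer) is trained with Adam on MSE, 70/30 split, 200 epochs.
   Fit quality is scored with the Nash–Sutcliffe efficiency
   `NSE = 1 − Σ(o−p)²/Σ(o−ō)²` and the RMSE-to-SD ratio
   `RSR = RMSE/σ_o` (so `NSE = 1 − RSR²` exactly); `NSE > 0.5` with
   `RSR ≤ 0.70` grades as *satisfactory*.
3. **Model disassembly.** Each factor is swept over its sampling domain
   with all others at their means; the width of the traced response
   domain classifies its influence intensity (ES ≥ 0.2 > S ≥ 0.1 > NS)
   and the curve's trend is named (monotone, U-shaped, inverted-U,
   fluctuating), with U-type optima reported back in original units.
   Factor pairs are probed the same way on 2-D coupling surfaces. Finally,
   because the output layer is linear, predictions decompose exactly as
   `y = Σ_j w_j h_j + b` over the 16 penultimate ReLU units; each unit is
   extracted as a "synergistic feature" with per-factor weighted ranges
   and compared against a plain PCA.

Because the original municipal rasters are not redistributable, a seeded
synthetic-city generator (`esvnet.synth`) produces inputs with the same
statistical structure — spatially autocorrelated land-use mosaics, totals
to allocate, an ESV surface built from the land-use coefficients — plus an
*oracle mode* that plants closed-form single-factor effects so recovery of
shapes, rankings and optima can be tested against known truth.

## Worked example

```python
import esvnet

rasters, totals = esvnet.generate_landscape(esvnet.SynthConfig(seed=42))
table = esvnet.build_sample_table(rasters, totals)
model, metrics = esvnet.train(table, esvnet.ModelConfig(seed=42))
print(f"test NSE={metrics.nse:.3f}  RSR={metrics.rsr:.3f}  grade={metrics.grade}")

report = esvnet.response_report(model, table)
print(report.head(3)[["factor", "response_range", "intensity", "shape"]])
```

prints

```
test NSE=0.985  RSR=0.122  grade=satisfactory
factor  response_range intensity               shape
    B7        1.734237        ES monotone_decreasing
    B5        1.675730        ES monotone_increasing
    C6        0.723037        ES monotone_decreasing
```

Read: on this synthetic city the surrogate explains 98.5% of the held-out
ESV variance, and the two dominant drivers it recovers are the land-use
structure factors — water area (B5) raising ESV monotonically, unused
land share (B7) lowering it — exactly the kind of ranking the planted
value coefficients imply. Response ranges are on the standardized ESV
scale, so 1.68 means the B5 sweep moves predicted ESV by 1.68 response
standard deviations.

The same run from a shell:

```sh
esvnet run --seed 42 --outdir city_run
```

writes rasters, the fused table, model weights and history, the
influence-intensity report, per-factor curves, coupling surfaces, the
feature/PCA comparison, and a manifest with a content hash per artifact.
Stages can be rerun individually (`esvnet generate|fuse|train|
analyze-single|analyze-pairs|extract-features|pca-compare|report`).

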