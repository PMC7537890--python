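# Methods

## The model

The analysis treats ecosystem service value (ESV) per grid unit as an
unknown function of 23 socioeconomic factors and approximates it with a
multilayer perceptron trained on fused spatial data. Everything
downstream — influence intensities, response shapes, optima, coupling
surfaces, synergistic features — is read off the *trained surrogate*, not
off the data directly. The method therefore assumes (a) the surrogate
fits well enough that its sweeps reflect the underlying relationship, and
(b) inference is deterministic, so a sweep is a well-defined 1-D function.
Both assumptions are enforced: fit quality is scored on held-out units
(NSE/RSR) and dropout is disabled at inference.

## Spatial fusion

City totals lack spatial structure, so each statistical indicator is
allocated dasymetrically over an ancillary weighting raster:
`Af_i = As_i · wf_i / ws_i`. The thirteen indicator→weighting pairings
(industry outputs to the land class hosting the activity, tourism to
nighttime light, total electricity/water to population) are fixed as the
package default and verified by test. Allocation conserves mass exactly;
block aggregation to the 2×2 km analysis grid sums extensive variables
(areas, ESV, allocated totals) and averages intensive ones (NDVI, light
index). Partial edge blocks keep their partial sums rather than being
renormalized or dropped — this conserves city totals and mirrors the
irregular boundary units a real administrative extent produces.

Land-use factors enter as area percentages (0–100) of the unit. The
default then z-scores them like every other column; because percentage
sweeps are sometimes easier to read on their natural scale, a
`standardize_percent=False` switch leaves them on 0–100 (with identity
scaling parameters so destandardization stays exact). Zero-variance
columns abort with an explicit error: a constant factor cannot enter a
sweep analysis, and silently dropping it would corrupt the 23-column
data model.

Coordinates are raster row/column, 0-based, origin top-left, units
indexed row-major. Rasters are exchanged as single-band float32 TIFF with
a JSON sidecar (resolution, nodata = −9999, CRS tag); only identical
grids may be fused — reprojection is out of scope.

## Surrogate

Architecture: dense 128 (linear) → dropout 0.3 → dense 256 (tanh) →
dropout 0.3 → dense 16 (ReLU) → dropout 0.3 → dense 1 (linear). The
first layer's linear activation is honored as specified rather than
upgraded to a nonlinearity, and the scalar linear output is a hard
requirement — the feature analysis depends on the exact decomposition
`y = Σ w_j h_j + b`.

Training: Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, batch 32 — standard framework
defaults, recorded in `ModelConfig`), MSE loss, 200 epochs, 70/30
shuffle split, no early stopping. Initialization is seeded
Glorot-uniform. One `numpy` generator seeded from the config drives the
split, the initialization and every dropout mask, so identical
(table, config) pairs reproduce weights, per-epoch history and metrics
bit-for-bit. Divergence (non-finite loss) raises rather than returning a
broken model.

Evaluation uses population (1/n) normalization in both RMSE and SD so the
identity NSE = 1 − RSR² is exact; the "satisfactory" grade requires
NSE > 0.5 and RSR ≤ 0.70 (with a 1e-9 boundary tolerance, since
0.70 computed as √0.49 can land one ulp high). Reported metrics are
test-set values.

## Response analysis

A factor's sampling domain defaults to its observed [min, max] on the
model scale; wider report-style domains can be passed per factor, since
nothing constrains how far beyond the data a sweep may extrapolate — by
default we do not extrapolate at all. Sweeps use 201 points (pair
surfaces 51×51); the grid-refinement tests show ranges and contributions
move by well under 2% when the density is increased tenfold, so these
defaults are resolution-converged at negligible cost.

Intensity classes threshold the response-domain range at 0.2 (ES) and
0.1 (S), inclusive upward, so a range exactly at a threshold takes the
stronger class; the classification is total and monotone in the range.

Shape naming smooths the curve with a centered 5-point moving average,
cuts it at its turning points into monotone runs, and merges away runs
whose net change is below `flat_tol` (2%) of the curve amplitude. One
surviving run → monotone; fall-then-rise → U-shaped; rise-then-fall →
inverted U; more → increasing/decreasing with fluctuation by net change.
The tolerance is applied to a run's *net* movement, not to single-point
differences — per-step differences of a smooth 201-point sweep are of
order amplitude/200 and would otherwise always be "flat". All-flat
curves return monotone-increasing with a zero-range flag rather than
failing. "Inflection point" in the reports means the curve's extremum
(U-type arg-min/arg-max), located on the smoothed curve and
destandardized to original factor and ESV units; monotone curves return
the better endpoint with an explicit non-interior flag.

## Synergistic features

Each of the 16 penultimate ReLU units is a candidate feature. Its weight
is |w_j| (the output-layer coefficient magnitude) and its per-factor
contribution is |w_j| × (max − min of h_j under that factor's sweep) —
the weighted range of the response attributable to unit j through that
factor. This is the simplest construction consistent with the linear
output decomposition. Factors with contribution ≥ 3e-4 form the
contained set (the threshold sits at about a tenth of a typical retained
feature weight and is configurable); units with zero output weight or
empty contained sets are dropped, the rest ranked by weight. Feature
labels ("city-scale factor" etc.) are human annotations — the package
stores a free-text slot and never auto-names. The comparison reduction
is scikit-learn PCA on the factor matrix with contained factors at
|loading| ≥ 0.1; loadings are orthonormal and variance shares
non-increasing by construction, both asserted in tests.

## Synthetic city and oracle tables

The landscape generator emulates the data model the pipeline consumes,
not any particular city. Smoothed Gaussian white noise (kernel width =
correlation length, default 6 km) is pushed through a softmax to give
per-cell land-use fractions that sum to one; a second smoothed field
splits construction into industrial/residential (both needed as
weighting layers); population, light and NDVI surfaces are correlated
transforms of the built-up and vegetated patterns; ESV is the exact
coefficient expansion Σ area × value-density plus Gaussian noise scaled
to a fraction (default 0.1) of the signal SD. The default 64×64 km grid
at 1 km yields 1024 analysis units after 2 km aggregation — the same
order as a real mid-size city's unit count. Synthetic value coefficients
rank water > woodland > grassland > cultivated > unused > construction,
mirroring the sign structure such analyses recover; the magnitudes are
arbitrary and configurable, and no attempt is made to match any real
city's composition or ESV level. What passing tests show is therefore
that the *machinery* recovers planted structure under realistic spatial
autocorrelation and noise — not that any substantive finding transfers
to real data, where unmeasured confounders, non-additive effects and
measurement error all enter.

Oracle tables draw (optionally equicorrelated) standard-normal factors
and build `Y = Σ f_i(X_i) + ε` from a closed-form shape family (linear
for monotone, quadratic with stated vertex for U-types). Recovery tests
plant amplitudes at ≥ 3× the noise SD; under those conditions the
trained surrogate ranks the two strongest factors top-2 by response
range, labels their shapes correctly, and locates a planted inverted-U
vertex within 10% of the domain width, in at least 8 of 10 seeded
replicates (10/10 in the runs the acceptance script performs).

## Pipeline

One global seed fans out to per-stage seeds (stage name hashed into the
multiplier chain, all below 2³¹) so any stage can be rerun alone and
reproduce its part of a full run. Every stage writes its artifacts plus
a manifest entry with a SHA-256 per file; two runs with one config are
bit-identical, which the test suite asserts at the hash level. Stage
failures abort with the failing stage named and earlier artifacts
retained. Exit codes: 0 ok, 1 configuration error, 2 stage failure.

## Known limitations

- The surrogate's response curves are conditional-mean probes along axes
  through the mean point; with strongly correlated factors they can visit
  factor combinations unsupported by data (the usual partial-dependence
  caveat).
- Feature extraction is architecture-specific (last hidden layer +
  linear output) and not identifiable across retrainings: different
  seeds give different but similar decompositions.
- The allocation step is plain proportional (dasymetric) spreading; no
  refinement against auxiliary constraints is attempted.
- No CRS handling beyond asserting identical grids; no uncertainty
  quantification on curves or metrics.
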