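# Methods

## Problem and model

A hurricane converts standing live mass (AGB) to standing dead mass
(AGN) and downed wood (WD). Field plots measure that conversion
directly but cover a few hundred square meters; paired airborne lidar
surveys see the whole forest but only its canopy. The package links the
two: the fractional change in canopy fractional cover (F-Cover) between
epochs predicts plot-level AGN through a linear calibration,

    AGN = a1 + a2 * dPFc,      dPFc = (F_after − F_before) / F_before,

fitted by ordinary least squares and cross-validated leave-one-out. The
covariate is dimensionless and enters as a fraction: a 36% cover loss
is −0.36. This matters because the bundled calibration constants
(a1 ≈ −34, a2 ≈ −304 Mg/ha) only reproduce the published per-plot
predictions under that convention, even though cover values are printed
as percents.

Key assumptions: damage is expressed through first-return interception
above the 1.37 m breast-height threshold; the AGN–cover-change relation
is linear over the observed range (cover losses of ~13–36%); plots are
independent calibration points; and the calibration transfers across
the mapped region (it does not transfer across forests with different
structure — applying the bundled Everglades constants to a structurally
different forest, including the package's own synthetic worlds, gives
biased maps, which is why the end-to-end pipeline always recalibrates
in-world).

## Lidar processing

Returns are stratified by height above ground: exactly 0 → ground,
(0, 1.37] → shrub, > 1.37 m → tree; the tie at exactly 1.37 m is shrub
because the tree stratum is defined as *above* breast height. "First
returns" means return_number 1, with no height gate. Per 13 m cell:
F-Cover = tree-stratum first returns / all first returns; Tree/Shrub
Mean are stratum mean heights over all returns; Pulse Density = first
returns per m²; CHM = maximum tree-stratum height (0 where treeless).
Cells with no first returns are no-data for F-Cover and Pulse Density.

Ground models: (A) a bilinear surface through vendor-classified ground
returns, the default when classification is present; (B) a bilinear
surface through per-cell minimum z on a configurable grid (default
5 m), for unclassified clouds. Mode B's accuracy depends on that grid
resolution relative to terrain slope — on a 5° plane a ~1 m grid is
needed to recover heights to 0.1 m. Negative normalized heights are
clamped to 0 (sensor/interpolation noise).

Grid geometry: origin snapped to the lower-left of the extent; cells
half-open [edge, edge + cell) with the outermost row/column closed so
every return lands in exactly one cell. The 3×3 moving-average filter
ignores no-data and shrinks (truncates) at raster edges rather than
padding, so plot extractions near swath edges stay defined. Plot-scale
metric values average the 3×3 cell neighborhood (39×39 m) around the
plot center, compensating ~3 m hand-held GPS error in plot positions.

Pulse-count change reports all returns by default with a
first-returns-only switch, since plot "total returns" could be read
either way.

## Field masses

Stem mass is total aboveground mass minus the leaf component, each
log10-linear in DBH; the per-species constants (red, white, black
mangroves) are fixed package data and each species satisfies a > c, so
mass is positive and strictly increasing for DBH ≥ 5 cm. Dead stems use
the same allometry as live ones — no decay-class deduction. Species
outside the three with constants are rejected rather than approximated.
Per 10×10 m plot, kg of summed stem mass converts to Mg/ha by ×0.1, and
AGTM = AGB + AGN holds exactly by construction.

Woody debris uses the line-intercept estimator: per transect and size
class, volume/area = π²·Σ(dᵢ in m)²/(8·L). Coarse (≥ 7.5 cm) and fine
pieces are computed separately and summed; the size class is always
recomputed from the diameter. The five replicate transects per plot are
averaged after per-transect conversion. Mass conversion needs a wood
specific gravity, which the field protocol leaves open; the defaults
(0.8 coarse / 0.6 fine g/cm³) are configurable package choices, not
literature constants.

## Calibration, uncertainty, and validation

The OLS fit goes through statsmodels; the reported p-value is the
two-sided t-test on the slope (a single model, so no multiplicity
correction). Points lacking a field AGN value are dropped with a logged
note, never imputed; two plots sharing one lidar cell may share a dPFc
value. Cover change is always recomputed from the before/after cover
columns rather than trusted from any pre-computed percent column — the
bundled cover table carries one published percent cell that contradicts
its own before/after values (plot WSC-9-100, printed −287.7% where the
columns give −27.7%), preserved as-printed alongside a corrected
column.

LOOCV is an explicit refit loop (n = 13, cost irrelevant), tested
against the hat-matrix identity e_i/(1 − h_ii) to 1e−9. Validation
reports the Pearson correlation between field and modeled AGN; because
the prediction is affine in dPFc, that correlation equals
|corr(AGN, dPFc)| exactly. On the bundled tables the recomputation
gives a1 = −34.23, a2 = −304.48, LOOCV RMSE = 25.7 Mg/ha, r = 0.70.
The source analysis quotes a fit R² of 0.81 for this regression, which
is not recoverable from the published plot tables (they yield
r² ≈ 0.49, matching the separately quoted 0.70 correlation and 0.67
validation R²); the package reports what the data reproduce and leaves
the discrepancy documented here rather than guessing an alternative R²
definition.

## Upscaling

Each epoch's F-Cover raster is smoothed first, then differenced —
smoothing after differencing would mix cover levels across the change
boundary. Predicted AGN is clamped at 0 for mapping (negative
predictions arise wherever cover increased), while an unclamped
diagnostic layer preserves residual structure for audit. Regional
summaries: total (Mg) = Σ value × pixel area (0.0169 ha for 13 m
cells); mean over all masked non-missing pixels (not only
positive-AGN pixels — a flagged alternative some analyses prefer);
histogram bins half-open with the last bin closed, default width
10 Mg/ha. AGTM from canopy height uses B = 10.0·H applied to the
13 m CHM pixel value. Mean necromass fractions over plot sets are
arithmetic means of per-plot AGN/AGTM ratios, not ratios of means.
Mask inputs are thresholded at ≥ 50% cell coverage.

## Synthetic worlds

The generator's defaults emulate the study system: tall riverine
mangrove stands (log-normal DBH, median ~12 cm, heights
H = 2.5·DBH^0.63 with 10% log-normal noise giving 12–18 m canopies),
1500 stems/ha, a 60/20/20 red/white/black mix, and crowns
(cones, radius 1.0 + 0.12·DBH m) wide enough to close the canopy
(pre-storm F-Cover ≳ 0.9). The sensor default of 24 pulses/m² yields
several thousand returns per 10×10 m plot, matching real plot
extraction magnitudes. Disturbance defaults: 29% stem mortality (the
mean plot-level mass-loss fraction of the study region), 90% canopy-
return loss per killed tree, 30% height breakage. Randomness is one
seed with named substreams (stand / disturbance / sensor), so changing
the sensor seed never alters the stand, and clouds are byte-for-byte
reproducible.

What the simulator does *not* emulate: occlusion and multiple canopy
returns per pulse, waveform and radiometric effects, spatially
autocorrelated mortality (mortality is uniform random), damage to
surviving trees, terrain relief (ground is flat at z = 0 plus sensor
noise), and co-registration error between epochs. Passing full-chain
tests therefore demonstrate internal consistency of the estimation
chain under known truth — not sensor realism or transferability to
real surveys.

The full-chain acceptance check fits the calibration on simulated
plots and requires the LOOCV RMSE to stay within twice the in-sample
residual RMSE of the same fit; the simulator injects noise through
sampling and crown geometry rather than one additive sigma, so the
in-sample residual scale is the operative noise scale of that world.
The default end-to-end problem sizes (13 plots on 65 m stands, a 130 m
region, 24 pulses/m²; the test suite uses 8 plots on 39 m stands at
8 pulses/m²) were chosen to exercise every stage at realistic densities
while keeping a run in seconds.

## Scope and I/O choices

Point clouds are read from a plain-text xyz-table dialect
(x y z return_number n_returns [class], class 2 = ground); rasters are
ESRI ASCII grids (text, explicit no-data, north-up on disk). Binary
LAS/LAZ and GeoTIFF are out of scope for this package; both text
formats convert losslessly to and from the binary ones with standard
GIS tooling. All inputs are assumed to share one projected CRS in
meters; no reprojection is performed. The regional totals of the
original surveys (tens of thousands of Mg per river swath) require the
archived flight-line rasters and are intentionally not bundled; the
operations that would compute them are the same ones exercised on
synthetic regions. No WD model is shipped: no lidar metric change
correlates with downed wood at the plot scale (all candidate
regressions fall in −0.3 < R² < 0.3), so the package exposes the
fitting machinery but deliberately provides no WD calibration.
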