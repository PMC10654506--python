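# Methods

`retinotile` quantifies the single-cell precision of a topographic
projection — concretely, the mouse retinocollicular pathway — by comparing
the spatial arrangement of labeled points in two spaces: positions of
retinal ganglion cell (RGC) axon terminals (or superior colliculus (SC)
somata) on the SC surface, in μm, and the centers of the matching receptive
fields (RFs) in visual space, in degrees. This note describes the statistic,
the generative model used to invert it, the synthetic-data generators, and
the numerical choices behind them.

## The tiling-pattern match

Given two patterns paired by cell id, the Delaunay triangulation is computed
independently in each space (Euclidean metric, `scipy.spatial.Delaunay`).
Each triangulation's edges are recorded as unordered id pairs, and the match
is

    match = 100 · |E_a ∩ E_b| / mean(|E_a|, |E_b|)   [%]

Edges are identified purely by cell labels, never by geometry, so the
statistic measures preservation of *neighborhood relations* and is exactly
invariant under any similarity transform of either pattern (Delaunay
triangulations are preserved by similarity maps; general affine maps can
flip triangulation diagonals, which is why the invariance tests use
similarity transforms).

Cocircular degeneracies (e.g. four points on a square) make the
triangulation non-unique. Before triangulating, every point is displaced by
a deterministic index-keyed perturbation of ~1e-9 of the pattern extent
(golden-angle directions, magnitude growing with index), far below any
measurement precision in this domain, so tie-breaks are reproducible across
runs and platforms.

Cells dropped in one space (off-screen RF, failed fit) must be removed from
both patterns before triangulating — the statistic is only defined on the
common id set; `TilingPattern.subset` and the pipeline handle this.

**Chance level.** The null hypothesis is "no correspondence": the id
assignment of one pattern is randomly permuted (a full permutation, without
replacement) and the match recomputed; 10,000 permutations give the null
distribution and the chance level is its empirical 95th percentile
(one-sided p = 0.05). Because only labels change, both triangulations are
computed once and the null is evaluated on integer edge codes, making 10⁴
repetitions essentially free. The chance level falls with pattern size
(expected null match ≈ 2|E|/(n(n−1)) · 100%): ≈28–30% at n = 25, ≈16% at
n = 49, ≈10% at n = 81.

**Affine-optimal deviation Δ.** The 6-parameter affine transform mapping one
pattern onto the other is fit by least squares (normal equations via
`numpy.linalg.lstsq` on the [x, y, 1] design); Δᵢ is the Euclidean residual
of point i in destination units, summarized as median ± MAD (the package's
default summary statistic throughout). Because the fit absorbs 3 of n
degrees of freedom per axis, i.i.d. Gaussian displacement of SD σ per axis
yields an expected median Δ of σ·√(1−3/n)·√(2 ln 2), the oracle used in the
tests.

## Generative model of the projection

Four steps, each with its own named RNG substream of a single root seed:

1. **RGC RF lattice.** RF centers (equivalently, RGC soma positions) sit on
   a triangular ("hexagonal-packing") lattice of spacing `l_rf` = 7.2°, each
   node displaced by i.i.d. per-axis Gaussian jitter of SD 10% of the
   spacing — the dense, semi-regular mosaic of retinal cell bodies. The
   jitter is applied per axis (the radial-vs-per-axis convention is an open
   choice; per-axis is used throughout and matters little at 10%).
2. **Axonal projection.** The RF pattern is scaled isotropically by
   `l_axon / l_rf` μm/deg (`l_axon` = 100 μm, the measured neighbor spacing
   of axonal patches) and each point displaced by i.i.d. Gaussian noise of
   SD σ — the axonal projection jitter, the first inferred parameter. σ = 0
   is a pure similarity transform: 100% match by construction.
3. **SC soma lattice.** An independent jittered triangular lattice with
   spacing `l_soma` = 56 μm (measured neighbor spacing of SC somata).
4. **Convergence.** Each SC neuron draws its input count k from a
   zero-truncated Poisson with mean parameter λ (zeros are resampled: a
   neuron with no retinal input has no RF and no counterpart in recordings),
   connects to its k nearest axon centers, and weights each input by the
   overlap area of its dendritic field (disk, radius 200 μm) with the
   axon's terminal field (disk, diameter 135 μm) at their distance,
   renormalized to 1. The neuron's RF center is the weighted mean of its
   inputs' RF centers. If every selected overlap is zero (possible only in
   pathological configurations), weights fall back to uniform.

The disk-overlap weight uses the exact two-circle lens formula, with the
closed-form limits (disjoint, contained) handled explicitly. "135 μm" is
the axonal *field size*, i.e. a diameter; the radius 67.5 μm enters the
formula.

**Lattice extent and boundary.** The default grid is 9×9 with a 1-node
margin excluded from match evaluation (49 interior nodes) — the order of
one experimental field of view. Delaunay adjacency at the convex hull is
unstable (hull edges flip under tiny perturbations and would bias the match
down), so both triangulations are computed on all 81 nodes but only edges
with both endpoints interior are compared. Grid and margin are configurable
(`SimConfig`).

## Inference of σ and λ

The model is swept one parameter at a time — σ from 0 to 50 μm in 1 μm
steps (steps 1–2 per repetition), then λ from 1 to 10 in 0.25 steps with σ
fixed at its estimate (steps 1–4 per repetition) — with many independent
repetitions per grid value (1000 by default; 500 in the bundled acceptance
runs, which changes medians by well under one percentage point). Each grid
value records the median match and the 2.5/97.5 percentiles over
repetitions.

The median curve is monotone in expectation (decreasing in σ, increasing in
λ) but finite repetitions leave small wiggles, so it is projected onto the
monotone cone by isotonic regression before inversion; the point estimate
is the linear-interpolation crossing with the observed match (midpoint if a
flat segment ties), and the 95% CI is the parameter interval whose
isotonic-smoothed percentile band covers the observed value. Isotonic
projection is order-preserving, so the band still brackets the median and
the CI always contains the point estimate. An observed match outside the
median curve's range raises an error for the point estimate; the band CI is
also available alone (`ci_from_band`) for pseudo-experiments whose
single-repetition match lands in a tail.

This CI reflects the spread of a *single-repetition* match, so its width
scales like 1/√(interior edge count): with the default 49 interior nodes it
is ≈±6 μm for σ at an observed 84% and ≈±2.7 for λ at 77%. Larger simulated
fields narrow it. Coverage is calibrated by construction: pseudo-experiments
simulated at known σ* ∈ {15, 27, 40} μm are covered by the CI in ≥90% of
trials (tested).

At the defaults, the inversion of 84% gives σ̂ ≈ 28 μm and the subsequent
inversion of 77% gives λ̂ ≈ 5.6 — a low input convergence: SC retinotopy
inherits its precision from the axonal projection rather than from
selective wiring.

## Receptive-field estimation

**Stimulus.** Binary checkerboard: rectangular fields 3.7° × 2.9°, each
modulated independently by white noise at 4 Hz, tiling a screen of ±36.5°
azimuth × ±22° elevation (19 × 15 fields with the default geometry,
centered; the outermost partial fields are not simulated).

**Reverse correlation.** The spatio-temporal RF is the response-weighted
average of the mean-subtracted stimulus over a 0.5 s window before each
activity sample, in 30 bins of 16.7 ms (a 60 Hz presentation grid; the 4 Hz
checkerboard is held piecewise-constant on it, and each lag bin samples at
its center to avoid frame-boundary ties). Weights are the deconvolved
event counts. Per-lag totals normalize the average, so samples earlier than
one window into the recording do not bias it. The peak latency is the lag
whose spatial frame has the largest summed squared deviation.

**Significance.** A cell's peak energy is z-scored against a null of 100
circular shifts of its trace (which preserve the event statistics and break
the stimulus alignment); z < 3 marks the cell unresponsive. A constant
trace gives a degenerate null (every shift identical); z is defined as 0
there. The z = 3 cutoff is this package's inclusion rule — the original
experimental criterion beyond on-screen centers is not documented.

**Gaussian fit.** The peak-latency frame is fit with a signed elliptical 2D
Gaussian (amplitude, center, axis SDs, orientation, offset) by bounded
nonlinear least squares. Initialization is the weak point of such fits at
low SNR, so the fitter seeds from up to five local extrema of the
3×3-smoothed frame (a genuine RF spans several fields and survives the
smoothing; single noise pixels do not), runs each with two initial widths
and the center bounded to a ±2-field window, and keeps the lowest-cost
solution. Axis SDs are bounded below at half a stimulus field — the
checkerboard cannot resolve finer structure, so smaller SDs are artifacts —
and a fit whose SD exceeds the screen extent, or that fails to converge, is
flagged (`fit_ok=False`) and excluded downstream. At per-pixel noise of 20%
of the amplitude, a spurious noise ridge attains lower squared error than
the true blob in ~2% of frames; no least-squares fitter recovers those, and
the tests assert ≥95/100 recovery at that noise level. RF size is
`sd_long + sd_short` (the mean of the two 1-SD diameters); RF overlap is
intersection-over-union of the 1-SD ellipses on a 0.2° raster (<1% error at
these scales).

**Inclusion rules.** Cells whose center falls in the outermost ring of
stimulus fields ("on the border") or off screen are dropped; a recording
with fewer than 10 surviving cells is excluded from tiling analysis.

**Patch geometry.** Axonal-patch masks (binary, 1.3 μm/pixel) yield area,
equivalent-circle radius √(area/π), and the binary centroid. The RF-size vs
patch-size Pearson correlation drops pairs outside either variable's central
95% interval first; note that on bivariate normal data this trim attenuates
a true ρ = 0.19 to ≈0.14 (range restriction) — on real, heavier-tailed data
it removes genuine outliers instead.

## Synthetic recordings

The LNP generator exists to exercise the RF pipeline end to end: each ROI
filters the mean-subtracted stimulus with its ground-truth Gaussian RF
(unit L2 norm) at its latency, passes the drive through
softplus(baseline + gain·drive), and emits Poisson event counts per imaging
frame (default 30 Hz). Defaults (gain 8, baseline −1.5) give ≈1 Hz mean
event rates — realistic for deconvolved calcium activity. What it does
*not* emulate: deconvolution artifacts, correlated noise across ROIs,
eye/body movement, RF surrounds and temporal dynamics, or overlapping
source crosstalk. Passing recovery tests therefore validate the estimator's
correctness and statistical efficiency on clean LNP data, not robustness to
every artifact of real two-photon recordings.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams
(`substream(seed, name)`, CRC32-keyed `SeedSequence` spawn keys), so any
pipeline stage reruns identically in isolation; rerunning a stage with the
same seed is byte-identical. The bundled acceptance computation uses the
full experimental sweep grids at 500 repetitions and the default 9×9
lattice (≈80 s on one core); the demo pipeline configuration uses a 5-min
recording, 300 repetitions and a coarser λ grid (a few minutes end to end).

## Known limitations

- The simulated lattice extent, boundary handling and the treatment of
  zero draws from the Poisson convergence are not constrained by
  measurements; the defaults above are this package's choices, exposed in
  `SimConfig`.
- The CI construction (band crossing) is one defensible reading of a "95%
  confidence interval" on an inverted curve; its width depends on the
  simulated field size (see above).
- The bootstrap null permutes correspondences; resampling cells with
  replacement or regenerating positions are alternatives the API does not
  currently implement.
- No RGC cell-type structure, no development/plasticity, no SC RF
  sizes/shapes — only RF center locations are modeled.
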