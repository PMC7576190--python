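# Methods

## The measurement problem

Optical coherence tomography angiography (OCTA) produces en-face maps of
retinal capillary flow in the superficial and deep capillary plexus (SCP,
DCP). In retinal vein occlusion (RVO), capillary dropout and altered
transmural pressure change the geometry of the capillary bed; `octamorph`
quantifies that geometry from a single en-face angiogram per layer:

1. **Binarization.** The grayscale angiogram becomes a binary vessel mask —
   either via a scribble-trained pixel classifier (a bagged-decision-tree
   rule over a multiscale feature stack: raw intensity, Gaussian-smoothed
   intensity, gradient magnitude, and the two Hessian eigenvalues per
   smoothing scale) or via Otsu / fixed thresholds. All convolutions use
   reflective padding; one classifier is trained per layer and applied to
   every image of that layer. No morphological cleaning is applied by
   default (an optional small-object filter exists, off by default).
2. **Regions.** The central 3×3 mm square is cropped out of the 6×6 mm
   scan (side in pixels = round(crop·1000/scale); an odd remainder drops
   the extra row/column at the bottom/right) and split into a superior and
   inferior half (rows `[0, H//2)` / `[H//2, H)` with superior at the top
   by default, configurable). In branch RVO the occluded half is labeled
   *affected* and the other *nonaffected*; fellow eyes mirror the occluded
   eye's assignment onto the same hemifield; control and central-RVO eyes
   keep anatomical labels.
3. **Skeleton graph.** The mask is thinned to 1-px centerlines
   (Zhang–Suen, 8-connectivity) and decomposed: pixels with one neighbor
   are endpoints, with two are slab pixels, with three or more are
   junction pixels; adjacent junction pixels merge into one junction node;
   maximal slab runs between nodes are branches. Per branch, the branch
   length BL sums the pixel steps (1 orthogonal, √2 diagonal) times the
   µm/px scale, and the Euclidean length EL is the chord between the
   branch's own terminal pixels.
4. **Metrics.** Per region: branch number; ΣBL and ΣEL (mm); mean BL and
   mean EL (µm, arithmetic means over branches); vessel tortuosity
   VT = ΣBL / ΣEL (≥ 1; 1 = perfectly straight); vessel density
   VD = vessel pixels / region pixels. A branch belongs to the hemifield
   containing its path's midpoint pixel.
5. **Statistics.** Per-eye records join a clinical table. Group contrasts
   use Student's t against control and paired t between occluded and
   fellow eyes; demographics use ANOVA / chi-square / Mann–Whitney.
   "Univariate, age- and sex-adjusted" regressions are three-predictor
   ordinary least squares of a logMAR acuity outcome on the rescaled
   metric plus age and sex, reporting the metric's coefficient and its
   two-sided p. Predictor rescalings: length sums mm→cm, branch number
   →hundreds, mean lengths →tens of µm; VT and VD unscaled. Acuity change
   is defined as 1-year minus baseline logMAR (negative = improvement);
   the opposite convention is available in the configuration. No multiple
   testing correction by default (Benjamini–Hochberg behind a flag).

## Conventions chosen where the procedure was open

* **Junction bookkeeping.** Branch paths terminate at — and include — the
  first junction-cluster pixel reached; EL runs between terminal pixels,
  not cluster centroids. This keeps BL ≥ EL provable per branch, hence
  VT ≥ 1 per region.
* **Closed loops** (no junction) are one cyclic branch: BL includes the
  closing step, EL is defined as 0, and loops are excluded from the VT
  sums (a zero chord would distort the ratio) but counted in branch number
  and ΣBL. **Isolated single pixels** are treated as segmentation noise
  and excluded everywhere.
* **Irreducible 2×2 junction cores.** Thinning leaves a 2×2 block of
  mutually adjacent junction pixels where two vessels cross; no pixel of
  such a core can be removed without detaching an arm. The graph stage
  accepts exactly these blocks (they merge into one junction cluster) and
  rejects any 2×2 block that still contains a removable pixel.
* **No spur pruning** by default; a minimum-BL filter exists in the
  configuration.

## The synthetic plexus generator

Clinical OCTA angiograms for RVO cohorts are generally not
redistributable, so the package ships a generator whose images have an
exactly known branch graph. Vessel centerlines are edges of a Delaunay
triangulation over a jittered lattice; a weighted subsample of edges is
kept such that

* no lattice vertex has degree exactly 2 (a bend would be merged by the
  measurement stage, breaking the one-to-one branch correspondence),
* junction valence is capped at 3 (the dominant valence of capillary
  junctions), and
* edges sharing a vertex subtend at least 30° (near-tangent tubes thin
  into spurious short branches).

Each centerline is perturbed by a perpendicular sinusoid with an integer
number of half-periods (endpoints exact), rasterized to an 8-connected
near-minimal pixel chain, and dilated to the vessel radius. Ground truth
records, per branch, the continuous arc length of the polyline
(quadrature-checkable) and the chain-code BL/EL of the rasterized
centerline. Pipeline-fidelity comparisons use the chain-code truth: the
chain-code metric overestimates continuous arc length by several percent
for oblique curves, and the measurement stage shares exactly that metric,
so chain-level comparison isolates tracing errors from digitization bias.
Published tortuosity values carry the same digitization bias, as the
standard skeleton-analysis tooling uses the identical step metric.

**Lesions** remove a stated fraction of branches, uniformly or with
probability proportional to the rank of 1/BL (shortest first), optionally
restricted to one hemifield. Dropout is spatially coherent: a junction
left with only two surviving segments is a bend, not a junction, so one of
its in-lesion neighbors is dropped too (cascades run to completion, which
may slightly overshoot the nominal fraction). This models contiguous
nonperfusion and keeps the surviving network measurable branch-by-branch.

**Cohorts** draw per-eye lesion severity per group (hemifield-restricted,
short-branch-preferential dropout for BRVO-like eyes; diffuse uniform
dropout for CRVO-like eyes; none for controls and fellows) and plant a
linear acuity model on the true metrics (in the regression's rescaled
units) plus age, sex, and Gaussian noise, emitting the same CSV schemas
the real pipeline consumes.

### Default parameters and calibration

| Parameter | DCP preset | SCP preset | Why |
|---|---|---|---|
| grid / scale | 1024 px / 2.93 µm/px | same | 3 mm crop; fine enough that the sinusoid curvature survives thinning |
| branch count | 445 | 294 | published control means per layer |
| median branch length | 100 µm | 130 µm | near published control mean BL (80 / 114 µm), excluding the noise spurs real skeletons contain |
| sinusoid amplitude / wavelength | 12.5 / 100 µm | 11.5 / 130 µm | calibrated so the *measured* VT of control-style images lands in the published control windows (1.203 ± 0.024 and 1.142 ± 0.013) |
| vessel radius | 1 px | 1 px | skeleton fidelity degrades with tube width |

The amplitude calibration was done once against the published windows and
frozen. At these defaults the full measurement recovers generator truth to
within ~3 % in branch number and ~0.011 in VT (20 seeds), and VD is exact
by construction (same mask). Synthetic vessel density (~0.03–0.04) is
deliberately far below the published ~0.2: at a resolution where the
skeleton is faithful, matching VD would require ~9-px-wide vessels, which
destroys branch-level fidelity. VD-dependent claims are therefore tested
as within-simulation contrasts, never as absolute levels.

### What the generator does not emulate

Speckle and decorrelation noise textures, projection artifacts, vessel
caliber variation, curvature beyond a single sinusoidal mode, noise spurs
on the skeleton (real mean BL is pulled down by them), and any coupling
between the two plexus layers. Passing tests therefore demonstrate that
the measurement pipeline is correct on networks whose truth is known, and
that the described dropout mechanisms have the claimed signatures — not
that clinical images would yield identical values.

## Problem sizes used by the test and acceptance runs

Formula checks use 1,000 randomly constructed branch collections;
branch-tracer equivalence is checked exhaustively on all 4×4 grids up to
12 pixels plus seeded 8×8 sparse masks and 50 random thin skeletons;
ground-truth recovery and the dropout mechanisms use 20 seeds at the full
DCP preset; the amplitude-monotonicity sweep uses 5 amplitudes × 20 seeds
at a reduced 512-px grid with 120 branches; statistical recovery uses a
noiseless 25-eye and a noisy 200-eye single-group cohort on a reduced
320-px grid (150 branches), and the t-test calibration uses 1,000 null
replicates of two 15-sample groups.

## Numerical notes and limitations

* Determinism: every stochastic step flows from one integer seed through
  `numpy.random.default_rng`; identical inputs and seeds give
  byte-identical metric CSVs and bit-identical rasters.
* Otsu on a constant image returns an empty mask rather than an error.
* A degenerate regression outcome (zero variance) reports beta 0 with a
  flagged fit instead of a spurious p-value; constant predictors and
  rank-deficient designs raise.
* The classifier is a stand-in for interactive pixel-classification
  training; no claim is made that its decision boundary matches any
  specific interactive tool, and segmentation-level agreement with
  published cohorts is untestable without their images — only downstream
  behavior on known ground truth is validated.
* 2D only; no projection-artifact handling; no vessel diameter, fractal
  dimension, or foveal avascular zone metrics.
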