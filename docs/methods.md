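# Methods

This note documents the models and procedures implemented in `lidarvol`,
the assumptions behind the synthetic-forest simulator, the numerical
choices, and the known limitations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Planted stands of straight-stemmed species (a dense-crowned conifer such as
dawn redwood, and a broadleaf such as poplar) are surveyed with two
near-field LiDAR systems. The above-canopy scan (ULS, ~84 pts/m²) resolves
treetops and crown surfaces but few stem returns; the under-canopy backpack
scan (BLS) resolves stems densely but, with a single horizontally scanning
head, reaches only ~9 m up. Neither cloud alone supports taper modeling;
together they yield, per tree, total height H (ULS), DBH D and upper-stem
diameters d(h) at h = 1.3…8.3 m (BLS). A taper equation fitted to those
samples is integrated into a two-way standard volume model, tabulated over
DBH/height classes, and expanded to stand volume.

## Preprocessing

* **Outlier removal** — statistical k-NN filtering: a point is dropped when
  its mean distance to its k = 8 nearest neighbors exceeds the global mean
  of that statistic by 3 SD. The global threshold assumes broadly
  comparable local densities; on clouds mixing very dense structure with
  very sparse returns it will sacrifice the sparse component (see
  Limitations).
* **Ground filtering** — progressive TIN densification. Seeds are the
  lowest point per 5-m block, vetted by an iterated robust plane fit
  (residual ≤ median + max(3·1.4826·MAD, 1 m)) so blocks containing only
  crown overhang cannot contribute canopy seeds. The TIN is densified
  iteratively: a point joins the ground when its perpendicular distance to
  the containing facet is ≤ 0.5 m and the largest point-to-vertex angle is
  ≤ 8°. Facets steeper than 30° never accept points — without that guard,
  chains of near-vertical micro-facets climb dense stems. Four virtual
  corner vertices on the seeds' least-squares plane keep every point inside
  the triangulation (this also makes collinear seed sets non-degenerate).
* **DEM** — per-cell mean ground elevation on a 1-m raster; empty cells are
  IDW-filled (power 2, 12 nearest populated cells); a populated cell more
  than 3 neighborhood SDs above its neighbors is treated as contaminated
  and re-filled the same way. Heights are normalized by subtracting the
  cell elevation; negative normalized heights are preserved.

## Tree detection

* **ULS** — top-down distance-judgement clustering. Points are processed in
  strictly descending normalized height (ties by point index, for
  determinism). The highest unassigned point above h_min = 2 m seeds a tree
  (its treetop); later points join the nearest tree when the 2D distance to
  that tree's assigned points is ≤ T1, and may seed a new tree only beyond
  T2 of every existing apex. Defaults T1 = 2 m (below the 3–8 m planting
  spacing) and T2 = 2.5 m (an average crown radius); trees with < 30 points
  dissolve. Tree height is the apex height; crown radius is the mean
  horizontal apex-to-point distance.
* **BLS** — the normalized cloud is sliced at 1.3 ± 0.05 m (half-open
  interval) and clustered by DBSCAN in the 2D projection (Eps = 0.2 m,
  MinPts = 15, neighborhood counts inclusive of the point itself). Each
  cluster's **gravity-center circle** gives DBH: center = point mean,
  radius = mean distance to the center, D = 200·radius (the single m→cm
  conversion in the codebase). Upper-stem diameters repeat the slice and
  circle fit at 1-m steps, keeping points within 2·Eps of the stem center
  tracked upward (a jump > 0.5 m marks the slice unmatched; unmatched
  slices are omitted, never guessed). The gravity-center radius has a
  small finite-sample bias (≈ −0.3 ± 0.3 cm at 80 points per slice, from
  the centroid chasing angular sampling fluctuations); it is measured by a
  Monte-Carlo test and accepted as part of the estimator.

## Co-registration

Both clouds are height-normalized first, so only a 2D rigid transform
(rotation + translation; optional constant z offset) is estimated. Coarse
alignment solves the 2-D Kabsch problem over ≥ 2 surveyed control poles.
Fine alignment alternates (a) optimal one-to-one assignment (Hungarian
algorithm) of BLS trunk positions to ULS treetop positions among pairs
within 2 m under the current transform and (b) re-estimation of the
transform from the matched pairs, until the update moves matched points by
< 1e-9 m. The 2-m pairing radius sits below the minimum planting spacing to
prevent cross-row locking; the initial transform must place true pairs
within that radius, which the control-pole stage guarantees. Registration
quality is reported as the mean treetop–trunk horizontal distance (cm);
note this conflates registration error with true apex lean, exactly as a
field comparison of apex and stem positions does.

## Taper and volume

Five taper forms give d² = f(D, H, h):

| id | form | free coefficients |
|----|------|-------------------|
| M1 | D^b₀ · (H/(H−h))^(c₀+c₁·D/H) | b₀, c₀, c₁ |
| M2 | a₀·D^a₁·(H−h)^a₂ / H^a₃ (modified Schumacher) | 4 |
| M3 | a₀·D·((H−h)/(H−1.3))^a₁ | 2 |
| M4 | D²·((H−h)/(H−1.3))^a₀ (anchored: d(1.3)=D) | 1 |
| M5 | D²·(a₀ + a₁·(H−h)/h) | 2 |

M1's source form is ambiguous; the DBH exponent is collapsed to one
identifiable parameter b₀ and the entry is swappable in the registry.
Fitting minimizes residuals on d (cm, so RMSE/MAE are in centimeters) by
Levenberg–Marquardt (`scipy.optimize.least_squares`, method "lm", 3-point
finite-difference Jacobian, tolerances 1e-10); negative d² under candidate
coefficients is clipped to zero, which steers the iteration back into the
valid region. Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹ with s² = SSE/(n−k); intervals are Student-t at 95%. A Monte-Carlo
experiment (800 replicates, n = 500, σ = 1 cm, covariates drawn as the
field workflow produces them: D∈[24,38], H∈[23,33], h on the 1.3…8.3 grid)
measures empirical coverage at 94–96% per coefficient. Model selection is
minimal RMSE, ties broken by higher R², then fewer parameters.

Volume is V = K ∫₀ᴴ d² dh with K = π/40000, the constant that converts d in
cm and h in m to m³ (a circle of diameter d cm has area π d²/40000 m²).
M2 integrates in closed form, V = K a₀ D^a₁ H^(a₂+1−a₃)/(a₂+1); all forms
integrate by adaptive quadrature (relative tolerance 1e-8), and the two
routes agree to ≤ 1e-6 relative on a (D, H) grid. Volume tables default to
2-cm DBH and 1-m height classes spanning the fitted data, rounded to 4
decimals; monotonicity along both axes is asserted. Stand volume selects
standard trees within ±5% of the quadratic mean DBH Dg = √(mean D²) (the
standard reading of the D_g notation) and of the mean height, and expands
by basal area; a plot volume M on A m² scales to M/(A/10⁴) m³/ha. The
pipeline will not integrate a selected form whose d² diverges at the tip;
it falls back to the next-best integrable fit.

## The synthetic forest

The simulator defines the conditions every end-to-end claim is tested
under; its defaults are the study conditions, not tuning knobs.

* **Stand** — a 30 × 30 m plot, regular planting on a 3–8 m grid (default
  5 × 5 m), ~0.1 m position jitter, 10% random thinning (the medium-density
  configuration uses 10/36 so a 6×6 grid carries 26 trees in expectation).
  DBH and height are truncated normals per plot-level statistics (the
  medium-density conifer stand: D = 31.57 ± 3.95 cm, H = 27.30 ± 1.71 m).
  Ground is a plane with a 0.04% slope. Crown radius ~2.5 ± 0.4 m; the apex
  may lean horizontally up to 0.3 m (0.6 m for the broadleaf
  configuration) — lean is what limits how well a treetop predicts its
  trunk position.
* **Stems** — straight vertical cylinders whose radius at height h follows
  the configured taper **shape normalized so the diameter at 1.3 m equals
  the tree's DBH exactly**. The anchoring is deliberate: DBH is defined as
  what a tape or breast-height circle fit measures, so the simulated stem
  must actually have that diameter at 1.3 m. (The raw modified-Schumacher
  form with the default coefficients evaluates to d(1.3) ≈ 0.79·D and
  would make every measured DBH disagree with the stand statistics.)
* **ULS scan** — total points = density × area (default 84 pts/m²), split
  between crown surfaces (cones for the conifer-like species, upper
  half-ellipsoids for the broadleaf-like) proportionally to projected
  crown area, remainder on the ground. Each tree's exact apex point is
  always included, so with zero noise the per-tree maximum height is exact.
  Isotropic Gaussian noise, default σ = 3 cm.
* **BLS scan** — stem rings at ~80 points per 10-cm slice, ground at
  50 pts/m², clumped understory shrubs below 1.5 m (locally dense, so they
  survive statistical denoising and genuinely exercise DBSCAN's noise
  rejection), height cap 9 m, σ = 1 cm, the whole cloud pushed through a
  known rigid transform (default 3°, (5, −3) m, +0.5 m z). Ground density
  matters: a backpack scan sees the ground densely, and simulating it
  sparsely makes the global k-NN denoiser delete it wholesale.
* Every point carries its source tree id (−1 for ground/clutter), so
  segmentation is scored exactly; identical seeds give byte-identical
  clouds.

What the simulator does **not** emulate: occlusion and shadowing, multiple
returns and intensity, trajectory drift (the BLS offset is a single rigid
transform), stem lean and sweep, branches, and bark roughness. Passing
end-to-end tests therefore demonstrates the correctness and calibration of
the algorithms under clean geometry, not field-grade robustness.

## Identifiability of the modified Schumacher scale

One structural property deserves emphasis. Within a single tree the M2 form
factorizes as d² = [a₀D^a₁/H^a₃] · (H−h)^a₂: the bracket is a per-tree
scalar. When DBH is itself measured from the stem at 1.3 m — as this
workflow and any purely LiDAR-derived dataset must — the bracket is pinned
to D²/(H−1.3)^a₂, and every (a₀, a₁, a₃) consistent with that constraint
fits the data identically. The shape exponent a₂ is well identified (the
anchored one-parameter refit recovers it within ~4% end-to-end); the scale
coefficients sit on a flat likelihood ridge and land wherever the
iteration's starting point and the noise put them. The wide published
uncertainty on such scale coefficients (relative standard errors above 20%)
is consistent with this ridge. Practical consequence: compare taper
*curves* and *volumes*, which are gauge-invariant, rather than individual
scale coefficients; the end-to-end test that asserts all four coefficients
is expected to flag a₀.

## Problem sizes

Default test and acceptance runs use one 30 × 30 m plot (~27 trees), a
75,600-point ULS cloud and a ~230,000-point BLS cloud; the CI-calibration
experiment runs 800 replicates of 500 samples. A full pipeline run takes
~12 s and the whole suite under a minute on one CPU — sizes chosen so the
package's claims can be re-verified routinely, while the algorithms
themselves are vectorized and handle proportionally larger clouds.

## Known limitations

* The gravity-center circle fit is biased low by ~1% at 80 points per
  slice and is not robust to partially occluded (arc-only) stems; a
  least-squares or RANSAC circle would be the upgrade path.
* The global-threshold k-NN denoiser assumes comparable local densities.
* The ULS segmenter's "barred from seeding near an existing apex" rule can
  merge a genuinely shorter tree standing within T2 of a taller neighbor.
* M5 diverges at h → 0 for a₁ ≠ 0 and M1 can diverge at the tip; volumes
  for such fits are rejected rather than silently truncated.
* Registration assumes both clouds are height-normalized; vertical
  alignment is delegated entirely to the DEMs.
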