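# Methods

Conventions, model formulations and numerical choices used throughout the
package.  All lengths are cm, ages days, angles degrees at API
boundaries (radians internally where noted).

## Frames and the digitizer dialect

The soil frame is right-handed with `z = 0` at the soil surface and
`z < 0` below ground.  Digitizer files store points in the device frame,
whose x axis reads positive-down; the map to the soil frame is
`(x, y, z) → (y, z, −x)` (orthogonal, determinant −1), followed by a
translation that puts the soil-reference stem point at the origin.  All
derived quantities are therefore invariant to where the digitizer's
transmitter stood.

Each line of a digitizer file is `<ID> <organ> <x> <y> <z>`, where the
organ is `stem` or `root` and the ID encodes topology:

- stem points carry plain integer IDs in order along the stem (point 0 the
  grafting point, point 1 the soil horizon by default, 2+ down the
  cutting);
- a root point's ID is its axis prefix plus a 1-based point index; the
  axis prefix is the *full ID of the parent branch point* (axis `2.1.3`
  branches at point 3 of axis `2.1`);
- each lateral's first point re-digitizes the parent branch point (the
  "double point").  The pair's deviation is recorded as an operator-error
  observation and the node is snapped onto the parent coordinate, so
  point *i* of a non-stem axis sits at node *i − 1* of its polyline and
  `nodes[0]` always coincides with the parent attachment node.

Because shared branch nodes are recorded twice, the number of records in
a file equals the sum of node counts over all axes.

Root types follow hierarchy depth: 0 stem, 1 woody adventitious, 2
first-order laterals, 3 (or deeper) fine laterals.

## Traits

Per-type length, count, mean length and diameter, surface area
(`2πa·l`) and volume (`πa²·l`) from the per-axis radius; rooting height
(vertical extent of root nodes below the surface) and width (maximum
pairwise distance of horizontal projections, computed on 2-D convex-hull
vertices); 3-D convex-hull volume and planar hull areas (SciPy Qhull,
with a degeneracy flag for collinear systems); and a root-length depth
profile.  Depth binning apportions each segment linearly to the
half-open layers `[kh, (k+1)h)` it spans, so mass is conserved exactly
and refining `h` never changes aggregate totals.

## Growth model

Axis elongation follows the negative-exponential law
`l(t) = lmax·(1 − e^(−r·t/lmax))`, with closed-form inverse used for node
ages.  Lateral positions on a parent follow the basal-zone/spacing/
apical-zone schedule: `s₁ = lb`, `s_{k+1} = s_k + ln_k`, truncated at
`lmax − la`; the lateral at position `s` activates when the parent first
reaches length `s + la`.  Per-axis parameters (`lb`, `la`, `ln` draws,
insertion angle `θ`, radius `a`) are sampled from positive-truncated
normals; `θ` is additionally truncated at 180°.

A growing root extends in fixed steps `dx` (default 0.5 cm).  Heading
updates are probabilistic tropism: `N` candidate headings are drawn, each
the old heading deflected by `|N(0, σ√dx)|` radians about a uniformly
random azimuth, and the candidate minimizing the objective is kept —
`z` for gravitropism, `|z|` for plagiotropism.  Type-2 roots draw the
objective gravitropic with probability `p_gravi`; per-segment by default,
or once per root (`tropism_mode: per_root`).  Type-3 roots are purely
gravitropic with `N = 1`.  The first segment of every lateral follows the
sampled insertion heading; tropism steers from the second segment onward,
which keeps the insertion-angle parameter identifiable from the final
geometry.  Parent polylines receive an exact node at every lateral
position (segments are split at schedule positions), so branching
parameters are recoverable without interpolation error.  Static axes
(types 0 and 1) are persistent and never modified.

## Hydraulics

Theoretical axial conductivity of a cross-section sums Hagen–Poiseuille
flow over elliptical vessels: `Kh = π/(64η) · Σ aᵢ³bᵢ³/(aᵢ²+bᵢ²)` with
`η = 1.002·10⁻⁹ MPa s` (water, 20 °C); for circular vessels this reduces
to `π d⁴/(128η)`.  Conversion from `m⁴ s⁻¹ MPa⁻¹` to head-based
`cm³ d⁻¹` per unit gradient multiplies by
`9.80665·10⁻³ · 86400 · 10⁶ ≈ 8.47·10⁸`.  Axial conductance per segment
uses a power-law fit `kx(d) = α·d^β`; radial conductivity comes from a
type-and-age class table (the shipped defaults are literature
order-of-magnitude placeholders: young unsuberized ≈ 10⁻⁷, suberized ≈
10⁻⁸, woody ≈ 2·10⁻⁹ m s⁻¹ MPa⁻¹; stem zero).

Water flow is solved on the segment network with one unknown potential
per node: axial conductance `kx/ℓ` between segment ends, radial
conductance `kr·2πaℓ` split half/half onto both end nodes (trapezoidal
lumping, second-order accurate — the numeric whole-system conductance of
a uniform single root converges to the closed form
`Krs = √(kx·kr·2πa)·tanh(L·√(kr·2πa/kx))` at 10⁻⁶ relative error with
2000 segments).  The collar is held at a fixed potential and the soil at
uniform total potential; by linearity the standard uptake fractions
(SUF, each segment's share of total inflow, summing to 1) and `Krs`
(total inflow per unit potential difference) are independent of the two
boundary values.  SUF can be aggregated per depth layer and per soil
horizon with the same conservative binning as the depth profile.

## Accuracy metrics

Calibration digitizations of an object with known segment lengths give
`RMSE = √(mean (x−y)²)`, `bias = mean(x−y)` (a difference-of-mean-squares
variant is available behind `squared_form=True`), and per-length accuracy
`1 − RMSE_L/L`, optionally stratified by transmitter-distance bands
(< 100, 100–150, > 150 cm).  Double-point deviations (branch points
digitized twice) summarize operator error, with an OLS trend of deviation
on transmitter distance.

## Synthetic data

No field dataset ships with the package; `synthetic_fixtures` closes the
loop for testing.  It simulates a root system from a genotype parameter
set, down-samples each polyline to digitization-like vertex density
(keeping endpoints, all branch nodes, and vertices where the heading has
turned > 10°), and emits the digitizer dialect with a noise model:
per-coordinate Gaussian jitter, a double-point offset whose *expected
magnitude* is the configured parameter (uniform direction, half-normal
magnitude), and optional fine-root length loss emulating excavation.
Zero noise makes parse → build reproduce the down-sampled truth exactly.
Generators for calibration-object records and xylem vessel tables
complete the set.

## Estimators

From a reconstructed system: `lb` (arc length to the first branch), `la`
(length beyond the last branch), `ln` (successive branch spacings) per
parent type; insertion angles between the parent's central-difference
local direction and the child's first segment; `lmax` as the observed
maximum (or a quantile) and `r` by solving
`mean(l) = lmax·(1 − e^(−r·age/lmax))` with Brent's method; and a
tropism-probability heuristic, the fraction of long type-2 roots
(> 40 cm) with tips shallower than 50 cm.  Note the heuristic carries a
small systematic leakage (deep-planted gravitropic roots that have not
yet crossed the depth threshold count as shallow), so it ranks genotypes
reliably but recovers the probability only approximately.
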