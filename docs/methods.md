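# Methods

## Plant geometry (canopy3d)

The generator emulates a two-year-old, vase-shaped greenhouse mango. Leaf
blade dimensions are drawn uniformly from configured ranges (defaults
L ∈ [18, 26] cm, W ∈ [4.5, 6.5] cm) and converted to one-sided area by the
'Irwin' allometry `LA = −14.623 + 8.074·W + 0.085·L² + 0.452·W²`; dimensions
whose allometric area is non-positive are rejected, never clamped, because a
clamped area would silently corrupt every area-weighted integral downstream.
With the default 52 leaves and the reference target of 4194.84 cm², per-leaf
areas are rescaled multiplicatively (geometry by √factor) so the total
matches the target exactly while per-leaf area fractions are preserved to
machine precision. `LeafRecord.allometric_area` is then the scaled area, not
the allometry re-evaluated at the scaled dimensions — the two differ by the
rescale factor's nonlinearity, and the scaled area is the one the mesh and
the integration use.

Blade outline: the source morphology gives no blade shape, so a flat
lanceolate outline is used (two mirrored quadratic arcs, maximum width at
40 % of blade length), triangulated into 10 triangles whose summed area
equals the allometric area *exactly* (the width scale is solved against the
triangulated area, which is linear in it). Leaf inclination is not reported
anywhere for the study plant; the default is uniform in [−30°, +45°] from
horizontal and is a config knob.

Architecture: a main stem (0.5 m, ⌀25 mm) on a 0.40 m pot splits into two
branches per level ("Y-shape") for `branch_levels` levels (default 2;
0.35 m, ⌀15 mm, tilts 25°/35° from vertical). Leaves are distributed along
the terminal branches; each branch carries a phyllotactic spiral whose
azimuth advances by the configured divergence sequence — either the explicit
list (cycled) or draws from (mean, sd), defaulting to the measured mean
137.6° with sd 0. All stochastic draws flow from one seeded generator, so a
build is bit-reproducible.

Coordinates: metres, z up, +y north, plant base at the origin; every module
shares this frame.

## Illumination (lightenv)

Everything is band-integrated PPFD; there is no spectral resolution. Solar
zenith/azimuth come from the standard NOAA low-precision series
(fractional-year Fourier declination + equation of time), accurate to a few
hundredths of a degree — ample against the 0.5° contract, verified against
symmetry cases and the midsummer noon value at the study site (37.45° N,
126.98° E; the source's printed longitude has an impossible arc-minute field
and is read as decimal degrees). Natural light splits a horizontal PPFD
forcing into a collimated beam, `(1−f)·GHI/cos z` beam-normal, plus a
uniform-radiance diffuse dome `f·GHI`; f defaults to 0.3 (clear sky) and is
forced to 1 below the horizon. The artificial source is a Lambertian disc
lamp (default radius 0.15 m) mounted 1.5 m above the canopy top.

The diffuse dome is discretized into equal-solid-angle patches (default 145)
for the flux ledger; in transport, a uniform-radiance sky is sampled exactly
by a horizontal emitting disc above the scene with cosine-weighted downward
directions. That equivalence is exact for horizontal receivers under the
disc and approximate at grazing incidence on the enclosure walls, which is
why the disc radius carries a margin proportional to scene height.

The study's chamber geometry is internally inconsistent (2 m chamber, 0.4 m
pot, lamp 1.5 m above the canopy *inside* the chamber); the lamp clearance
is treated as the binding dimension and the artificial-light ceiling is
raised just above the lamp plane.

## Transport (raytracer)

Forward Monte Carlo with constant-weight photon packets. Each surface hit
adds the packet weight to that element's *incident* tally — both faces
count, matching a quantum sensor laminated to the leaf ("intercepted light"
is pre-scattering flux per one-sided area). The packet then reflects
(probability ρ, cosine-weighted about the incident-side normal), transmits
(τ; cosine-weighted for leaves, direction-preserving for glazing-like
materials flagged `diffuse_transmission=False`), or is absorbed; paths
terminate after `max_impacts` (default 10). Because survival is sampled and
weights never change, the ledger emitted = absorbed + escaped + truncated
closes exactly on packet counts.

Default leaf optics are ρ = 0.10, τ = 0.05 (typical PAR values for thick
evergreen leaves; the study measured but did not print its values). Default
ray budget is 10⁶ per trace with per-leaf standard errors reported —
desk-scale in place of the study's 10⁹-ray runs; SE is estimated from
per-packet leaf contributions, so within-packet multi-hit correlation is
accounted for. Intersection uses Möller–Trumbore through a median-split BVH
whose per-triangle arithmetic is identical to the exhaustive loop (ties
broken toward the lower triangle index), so accelerated and brute-force
results agree bitwise. Ray restarts are offset 10⁻⁹ m to avoid
self-intersection; detector grids per leaf use a local UV frame at 5 mm
pitch and are diagnostics — whole-leaf means drive the photosynthesis model
(per-patch evaluation would expose the Jensen gap of the nonlinear light
response; leaf means are the study's convention).

Lamp calibration exploits transport linearity: one trace at nominal flux,
then a scalar rescale so the top sensor reads its target (833.1 by default).

Virtual sensors are 3 cm black quads in a five-sensor vertical stack (two
top above the canopy, two middle in-canopy, one bottom below it, 15 cm
spacing). The stack's (x, y) is chosen by a deterministic lamp-visibility
scan: the bottom sensor must see at most 5 % of the lamp disc and the middle
pair about half — the arrangement that reproduces the study's strong
top–middle–bottom gradient, which is how the physical sensors were mounted
relative to the foliage. On the default plant this yields a gradient with
top/bottom ≳ 30.

## Leaf model and integration (photosynthesis)

The two-variable model P(I, C) = 12.928·(1−e^(−0.014·I))·(1−e^(−0.001·C)) −
0.889 is evaluated per leaf at its mean PPFD; whole-plant rate is total flux
divided by total one-sided leaf area — the same normalization the chamber
measurement produces. The model is separable in I and C, so a single traced
light field yields the whole CO₂ response. Temperature, humidity and
stomatal conductance are outside the model by design. Parameter recovery
uses trust-region nonlinear least squares with the analytic Jacobian,
positive bounds and a seeded 5-start multi-start; identifiability failures
(constant response, single-axis designs) return an explicit failure status.
Note that at the synthetic-recovery design (108-point grid, Gaussian noise
sd 0.2) the sampling error of the respiration offset is itself ~3–5 %, so
recovery-within-5 % holds for typical but not all noise draws.

## Chamber (chamber)

Air amount n = pV/RT (ideal gas; humidity ignored, a ≤ 2 % effect at 32 °C
and 60–70 % RH). Rates come from the least-squares slope of CO₂ over a
centred 180 s window (robust to 1 Hz sensor noise), scaled by n and leaf
area; drawdown ⇒ positive rate, rising CO₂ ⇒ negative (dark respiration).
The leak correction adds k·(ambient − C)·n/A, the sign required for a
plant-free leaky chamber to analyze to zero; leakage defaults to zero and
the leak workflow (exponential decay fit from a 48 h plant-free trace) is
exercised on synthetic traces only. Forward simulation integrates
dC/dt = (−F(C,t) + k·(amb−C)·n)/n with classic RK4 at fixed step; the
analyzer recovers generating rates within 1 % and mass balance closes to
integrator tolerance.

## What the synthetic data do and do not show

The generator reproduces the study's *conditions* — leaf area and
allometry, phyllotaxis, chamber geometry, the calibrated 833.1 top-sensor
PPFD, 12 h drawdowns from 1000 μmol mol⁻¹ — but not the physical plant's
actual leaf placement, the unreported leaf optics, or the real weather, so
the study's exact figures (e.g. its validation R² = 0.790, RMSE = 0.263, or
the measured diurnal 0.2 → 7.3 → −1.0 course) are reproduced as *patterns*
(gradient ordering and ratios within a factor of 2, CO₂-response
monotonicity and separability, unimodal diurnal course with negative dark
values), not as point values. Likewise the study's printed artificial-light
CO₂ response "2.0 → 2.9" over C 600 → 1000 is not reproducible even in
principle under the separable model, which maps 2.0 at C = 600 to ≈ 3.2 at
C = 1000 for any fixed light field.

Problem sizes used in tests: 10⁶-ray traces for the analytic oracles,
2×10⁶ for the calibrated artificial scene, 10⁵ per hour for the diurnal
course, 16 × 2×10⁵ for the Beer–Lambert ensemble (a single 500-leaf random
field has ~0.01–0.02 configuration scatter in its realized gap fraction, so
the e⁻¹ check averages over configurations).

## Other numerical choices

- Ray/triangle ε = 10⁻⁹ m; determinant cutoff 10⁻¹⁴ rejects
  parallel/coplanar rays.
- Beam source discs are tight bounding discs of the scene's projection
  (+1 % margin); packet weight = source flux / rays of that source; rays are
  allocated to sources proportional to flux.
- Zero-flux illumination short-circuits to an all-zero map; a missing
  material for any element kind present in the mesh is an error.
- The drawdown analyzer's sliding window uses prefix sums (O(n) for 1 Hz ×
  12 h traces); negative simulated concentrations clip to zero with a
  warning.
- Mesh I/O: OBJ carries full element identity (one named object per
  element, kind in the material name) and round-trips; PLY export (via
  trimesh) is geometry-only.
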