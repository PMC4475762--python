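# Methods

## Plan geometry

The reference plan lives in a 200 mm cubic water phantom. Five cubic target
voxels of 5 mm side form a row along the beam axis with the proximal target
face 50 mm from the near phantom face (target center shifted 37.5 mm
upstream of the phantom center); one normal-tissue voxel flanks the target
on each side (indices 1 and 7, target indices 2–6). Each field holds ten
monoenergetic Gaussian pencil beams (σ = 3 mm) whose Bragg peaks tile the
25 mm target with 2.5 mm spacing, from proximal face + 1.25 mm to distal
face − 1.25 mm; two peaks land in every target voxel. Opposed fields place
the same peak depths approached from the far phantom face, so peak placement
is mirror-symmetric about the target center while the water path to the
target differs between fields (50 mm vs. 125 mm), as it should for an
off-center target.

The package works directly in range (peak-depth) space and never converts to
beam energy; an energy–range calibration would only re-parametrize the same
geometry while dragging in transport physics the optimization does not need.
The 3 mm lateral width is carried as metadata only: descriptors are scored
on the beam axis inside 5×5 mm slabs, where lateral falloff does not enter.
Each voxel holds three scoring positions (proximal/central/distal, at 1/6,
1/2 and 5/6 of the voxel depth); descriptors are averaged over the three.

## Synthetic track generator

The generator replaces step-by-step track-structure transport with an
explicit clustered point process inside a cylindrical scoring region
(500 nm diameter × 500 nm height):

* a chord is chosen axis-parallel with its entry point uniform over the
  region face (SOBP fields are quasi-parallel at the nanometer scale);
* primary-ionization sites follow a Poisson process of linear density
  λ (`lambda_primary`, nm⁻¹) along the chord;
* each site spawns 1 + Poisson(`cluster_mean`) ionizations, displaced
  isotropically with exponential radial distance (mean `radial_scale`, nm);
* points falling outside the region are clipped;
* only `round(n_primaries × fluence_factor)` primaries generate points; the
  rest are kept as empty tracks so the absolute ICSD reflects attenuated
  fluence.

Depth dependence is a four-parameter toy Bragg model per particle class:
λ and the cluster mean rise from plateau to peak values as
`(depth/range)^rise_power`, stay at peak across a distal falloff of width
`falloff_mm` (stopping particles dominate there, which is what drives the
high conditional cluster sizes just beyond the deepest peaks), and return to
plateau-like quality only in the optional fragment tail. The fluence factor
decays exponentially (`attenuation_per_mm`), drops linearly to zero across
the falloff, and beyond that keeps the small `fragment_tail` fraction
(carbon only).

Preset parameters (chosen once as desk-scale stand-ins that preserve the
orderings that matter — carbon denser than proton everywhere, a steeper
distal rise for carbon, quality hardening with depth):

| parameter | proton_like | carbon_like |
|---|---|---|
| λ plateau → peak (nm⁻¹) | 0.05 → 0.35 | 0.12 → 0.8 |
| rise power | 8 | 12 |
| cluster mean plateau → peak | 0.5 → 1.8 | 0.8 → 2.5 |
| radial scale (nm) | 8 | 5 |
| falloff width (mm) | 4.5 | 2.0 |
| attenuation (mm⁻¹) | 0.0008 | 0.0015 |
| fragment tail | 0 | 0.06 |

Densities are set high enough that the rare-cluster (ν ≥ 4) descriptor
matrices are statistically resolved at the desk-scale history counts below;
much thinner tracks would leave the single-vs-opposed feasibility contrast
to sampling noise rather than to the depth structure of the field.

What the generator does **not** emulate: real interaction cross sections,
delta-ray transport and angular straggling, energy-dependent W-values,
nuclear fragmentation spectra, and any chemistry stage. Cluster-size
magnitudes are therefore not comparable to measured nanodosimetry; passing
tests demonstrate the correctness of the sampling, distribution and
optimization machinery and the qualitative depth/arrangement behavior, not
absolute radiobiological yields. Real track-structure output can be
substituted through the event-table import, which is the intended production
path.

## Sensitive-volume sampling

SVs are cylinders of 2 nm diameter × 16 nm length placed with orientation
uniform on the sphere and center uniform over the admissible sub-volume in
which the whole SV fits inside the scoring region (no boundary clipping —
truncated SVs would bias cluster sizes low). Admissibility uses the exact
z-extent of a tilted cylinder and a conservative radial extent
(length/2·sin θ + diameter/2); orientations that cannot fit are redrawn.
Containment uses closed inequalities (a measure-zero convention fixed for
determinism) with a 10⁻¹² slack on the squared radial test to absorb
floating-point noise.

Every (SV, primary) pair is one cluster-size realization; with 10⁴ SVs and
n primaries the absolute-ICSD denominator is 10⁴·n. Pairing each SV with
every primary is the only convention that uses all SVs under a
per-primary cluster definition; different primaries never merge into one
cluster. One SV set is drawn per scoring location and shared by all beams,
since the scoring cylinder belongs to the location, not to the beam.

Counting uses a uniform spatial grid over the SV centers with cell size
equal to the SV circumscribing-sphere radius (≈ 8.06 nm): each ionization
point checks the SVs in its 3×3×3 neighborhood against the exact cylinder
predicate (a numba kernel; ≈ 2 s for 1.9×10⁷ points × 10⁴ SVs). An
exhaustive double-loop oracle with no spatial index verifies exact
equality of the sparse count tables on randomized fixtures.

## ICSDs and descriptors

Distributions are stored on ν = 0..30 with overflow pooled into the top bin;
no descriptor reads ν > 10, so pooling only truncates the (already tiny)
extreme tail of M1/M1*. Absolute ICSDs are normalized over all primaries;
conditional ICSDs divide out 1 − P(0). All operations renormalize exactly,
holding the Σp = 1 invariant to 10⁻¹².

The composite conditional mean M1\* is exposed in two modes: the literal
unweighted sum of per-beam conditional ICSDs, and a "physical" mode that
weights each conditional by w_i·(1 − P_i(0)) — i.e., the conditional of the
fluence-mixed absolute distribution. The two coincide when every beam has
the same zero-cluster probability; the physical mode is the default in plan
evaluation because it respects both the optimized fluences and each beam's
ionization probability. M1_bio requires mass in the ν ∈ [2, 10] window and
is reported as undefined otherwise (e.g., a voxel reached by no beam).

Dose conversion uses D = M1·W/m with W = 30 eV by default (overridable; a
representative mean energy per ion pair in water) and m the mass of the
2 nm × 16 nm water cylinder (5.0265×10⁻²³ kg).

## Optimization

Composite M1, Y_SC and Y_LC are exactly linear in the fluences (mixture
linearity of absolute ICSDs), so both strategies reduce to bounded linear
least squares over the target voxels only — normal-tissue voxels are
evaluated but unconstrained. The default w ∈ [0, ∞) problem is solved with
the Lawson–Hanson active-set method (deterministic); finite upper bounds use
a trust-region bounded solver. Prescription levels default to "auto": the
target-voxel mean of the unit-fluence composite descriptor, which makes
optimization a pure re-balancing and needs no absolute calibration. The
two-yield objective scales each row block by its mean unit-fluence composite
yield so neither cluster class dominates the residual by sheer magnitude
(Y_SC is typically 10–20× Y_LC here).

Convergence is declared when the achieved percent spread
100·(max − min)/min over target voxels is below the uniformity tolerance
(default 2%) for every objective descriptor; failure is a reported outcome,
not an exception. Opposed-field problems are underdetermined (20 beams,
≤ 10 target constraints), so the exact fit is not unique; the strategy
functions add a tiny Tikhonov term (10⁻⁶ relative) that deterministically
selects the minimum-norm non-negative solution. This spreads fluence
symmetrically over both fields — which is also what lets the uniform-yield
solution deliver an (unconstrained) uniform M1 — instead of the arbitrary
sparse vertex an active-set solver would return. The residual perturbation
is quadratic in the ridge and far below every tolerance used.

## Problem sizes and statistical precision

Defaults are 10⁴ primaries per (beam, voxel, depth) cell and 10⁴ SVs per
scoring cylinder. The package's own test runs use 3–5×10³ of each for the
four end-to-end reference plans, which keeps a full four-plan regression
under three minutes on one CPU while leaving the qualitative outcomes
(opposed-field convergence at <2% spread, single-field failure at >5%,
flat-M1/rising-yield profiles) far from their decision thresholds.

The statistical-precision study samples a densely ionizing quality
(λ = 0.3 nm⁻¹, cluster mean 1.5, radial scale 5 nm) with 5×10⁴ primaries
through three scoring cylinders × 10⁴ SVs and measures the across-seed
relative standard error of each descriptor. At this budget M1, Y_SC and M1\*
resolve to ≈ 0.3%, ≈ 0.5% and ≈ 0.1% respectively. Y_LC is the rare-event
descriptor: only ~2×10³ clusters with ν ∈ [4, 10] occur per measurement at
these densities, which floors its relative standard error near
1/√2000 ≈ 2–3%. Reaching the sub-1% precision of the other descriptors
would take roughly five times more ν ≥ 4 events (denser tracks or more
histories) at proportionally higher runtime; the precision study reports
the honest maximum across all four descriptors.

## Known limitations

* The generator's absolute cluster-size scale is a desk-scale stand-in;
  composite conditional means stay well below the values real carbon
  tracks produce. Orderings, not magnitudes, are meaningful.
* Inter-track pile-up is ignored by construction (clusters are per-primary),
  consistent with the cluster-size definition but not with very high dose
  rates.
* The admissible-center radial margin is conservative by up to diameter/2
  ·(1 − |axis_z|), slightly under-filling a ≤ 1 nm shell at the region wall.
* Opposed-field plans assume perfectly mirrored geometry; no range
  uncertainty or setup error is modeled.
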