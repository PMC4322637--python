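# Methods

`stimdense` couples three physical models — a quasi-static extracellular
field, streamline tractography, and myelinated-axon cable dynamics — and
reduces their joint prediction to countable, comparable maps. This note
records the models, the numerical choices behind them, and what the bundled
synthetic phantom does and does not establish.

## Extracellular field

The tissue potential under monopolar cathodic stimulation is the solution of
the quasi-static Poisson problem ∇·(σ∇V) = 0 with an anisotropic conductivity
tensor σ per voxel. Conductivity is derived from a diffusion-tensor volume by
the linear transform σ = k·D with k = 0.844 S·s/mm² by default (the
literature scaling for white matter; exposed as `tuch_scale` because the
appropriate constant depends on the acquisition). Eigenvectors are preserved
by construction, so fiber-aligned anisotropy carries over to conduction.

The electrode is a quadripolar cylindrical lead (four 1.5 mm contacts, 0.5 mm
gaps, 1.27 mm diameter; contact lateral area π·d·h ≈ 5.98 mm²). The
electrode–tissue interface is treated quasi-statically: a fixed fraction
(default 42%) of the programmed amplitude is dropped across the interface and
encapsulation, so a −1.5 V pulse drives the contact at −0.87 V. An
RC-filtered waveform mode (τ = impedance × interface capacitance =
1000 Ω × 3.3 μF = 3.3 ms) is available for sensitivity checks; it is computed
as the periodic steady-state response of an ideal RC high-pass, which makes
the per-period charge balance exact. The square-pulse mode with amplitude
scaling is the default because the activation criterion is per-pulse and the
cited usage of the drop figure is amplitude attenuation, not waveform
shaping.

Discretization is a conservative finite-difference scheme on the conductivity
grid: diagonal tensor entries enter a 7-point stencil with harmonic face
averaging (so a zero-conductivity voxel blocks flux exactly); off-diagonal
entries add central-difference cross terms when present. Boundary conditions:
Dirichlet v_eff on voxels intersecting the active contact, Dirichlet 0 on the
outer box (monopolar return far away), an insulating shaft (σ ≈ 0 in
non-contact lead voxels), and an encapsulation shell (default 0.128 S/m,
0.5 mm) around the lead. The linear system is solved directly (sparse LU) up
to ~1.2 × 10⁵ unknowns and by Jacobi-preconditioned conjugate gradients
above; the solve is rejected if the residual exceeds 10⁻¹⁰ of the source
norm.

Verification exploits the isotropic homogeneous limit: with the contact
shrunk toward one voxel the solution must follow the monopole closed form
V = I/(4πσr). Two discretization artifacts matter at desk scale and shape
how the check is done. First, the grounded box truncates the 1/r tail — with
the boundary ≈60 mm from the source the far field behaves like a grounded
sphere of that radius, a ≤7% effect over 3–10 mm once the source current is
calibrated at a mid-range reference radius (6 mm). Second, the 7-point
lattice Green's function carries an anisotropic O(h²/r²) error term whose
angular average over the sphere vanishes; potentials are therefore averaged
over a 14-direction Lebedev rule (6 axes, weight 1/15; 8 body diagonals,
weight 3/40) before comparison. Under these conditions the solver agrees
with the closed form to within ~6.5% over r ∈ [3, 10] mm on a 1 mm, 121³
grid.

## Probabilistic tracking

Seeding follows the comparative-study design: an 11×11×11 cube of 2 mm
voxels (1331 seeds, 22 mm edge) centered on the active contact, 100
streamlines per seed — 133,100 attempted trajectories per placement at full
scale. Tracking is Euler integration at a fixed 0.5 mm step through a
per-voxel orientation field holding up to two fiber populations with volume
fractions and an angular dispersion. At each step the population is drawn
categorically by fraction, the direction is sign-aligned with the incoming
direction (fiber orientations are axial, not polar), and jittered by a
Gaussian polar angle of the voxel's dispersion about a uniform azimuth.
Tracking terminates on a ±80° curvature violation, entry into the
termination mask (CSF), leaving the field, a 2000-step cap, or loop
detection. Tracking is bidirectional from the seed and the halves are
concatenated, following probtrackX convention.

Numerical choices: orientation lookup is nearest-voxel (no directional
interpolation), matching the 2 mm resolution regime and keeping the analytic
arc oracle exact; loop detection counts voxel *entries* (several sub-voxel
steps inside one voxel are one visit) and terminates on the third entry into
any voxel. "N samples per seed" is implemented literally as N independent
draws; post-hoc likelihood ranking of a larger sample pool would require a
per-streamline likelihood model the orientation field does not define.

## Axon activation

Each tracked fiber long enough to carry at least 21 nodes of Ranvier
(≥10 mm) becomes a cable model with nodes every 0.5 mm placed by exact
arc-length resampling. The membrane model is an MRG-style reduction for the
5.7 μm fiber class, with four compartments per 0.5 mm section: an active
node (1 μm × 1.9 μm; fast Na⁺ 3.0 S/cm², persistent Na⁺ 0.01 S/cm², slow K⁺
0.08 S/cm², leak 0.007 S/cm², 2 μF/cm², 36 °C kinetics), two merged
paranodes (38 μm × 3.4 μm), and one lumped internode (423 μm × 3.4 μm),
the myelinated compartments passive with capacitance and conductance
attenuated by 80 lamellae in series (6.25 × 10⁻⁴ μF/cm², 5.9 × 10⁻⁶ S/cm²).
Axial resistivity is 70 Ω·cm. All values live in a named, versioned
parameter table (`data/mrg_5p7um_v1.yaml`), not in code.

The fitted node kinetics admit several steady states; the model rests at the
most hyperpolarized stable zero of the steady-state ionic current (≈ −88.6 mV
for this table), found by a scanned bracketing root search. The passive
reversal is pinned to that value so the uniform resting state is exactly
stationary — resting drift is then pure integrator error (< 10⁻¹¹ mV over
3 ms at dt = 2 μs).

Extracellular coupling samples the solved voltage volume trilinearly at each
compartment center and modulates it by the stimulus waveform; compartments
outside the volume see 0 V with the consequence that truncated fields can
only under-predict activation. Integration is backward Euler on the cable
system (axial currents computed from Vi = Vm + Ve) with Rush–Larsen
exponential gate updates and ionic conductances frozen per step — an
unconditionally stable scheme whose threshold predictions move < 0.5% under
dt halving on the straight-fiber fixture. A numerical-blow-up guard trips
when |Vm| exceeds 500 mV plus 1.2× the peak extracellular drive; the margin
above the drive matters because volt-scale fields legitimately polarize
near-electrode compartments by hundreds of millivolts.

A fiber is **active** when the membrane potential crosses 0 mV upward at
*both* terminal nodes within the simulation window (default 3 ms after
onset of a single pulse) — a local response at one end does not count. A
single pulse decides activation; the 130 Hz rate only sets the waveform
period. Threshold searches ladder up from small amplitudes before bisecting,
because very strong fields block conduction (hyperpolarizing surround), so
the active amplitude set is an interval and the lowest activating amplitude
is the threshold of interest. An activating-function screen (second spatial
difference of Ve at the nodes) is provided for pre-ranking but never
replaces the simulation.

## Density maps, contrasts, regions

The activation density heat map overlays a 1 mm³ Cartesian grid (bounding
box of all fiber nodes, padded 2 mm, origin snapped to integer mm so maps
from different runs align) and counts, per cell, the number of *distinct*
active fibers with at least one node of Ranvier in the cell. The counting
unit is deliberately the node, not the swept path: a fiber clipping a cell
corner between nodes contributes nothing there. Display thresholding (on a
percentile of the nonzero-count distribution) exists for visualization only
and feeds no quantitative output.

Contrast maps are the elementwise (Hadamard) product of one placement pair's
maps minus the product of another pair's: positive cells mark pathways
characteristic of the first pair, negative of the second, and swapping pairs
negates the map exactly. Because unequal total fiber counts inflate raw
products, an optional per-map max-normalization flag exists; it is off by
default to keep the raw-count semantics.

Region quantification resamples a label atlas onto the map grid by nearest
neighbor (labels are categorical; value interpolation is meaningless) and
counts each active fiber once per region it reaches — "reach" meaning a node
in a cell carrying the region's label, mirroring the heat-map counting unit.
Percentages default to the region-reaching denominator: fibers reaching no
labeled region are excluded and reported. The all-active denominator is kept
switchable because either convention is defensible for summary shares.

## Synthetic phantom

The phantom is a 60 mm cube (2 mm orientation/tensor grid, 1 mm label grid)
holding straight or arc-shaped bundle tubes: in-tube voxels carry the bundle
tangent and a prolate tensor (λ∥ = 1.7 × 10⁻³, λ⊥ = 0.3 × 10⁻³ mm²/s;
white-matter-like), the background is isotropic 0.7 × 10⁻³ mm²/s, and CSF
slabs get 3.0 × 10⁻³ mm²/s and terminate tracking. Region slabs stand in
for the cortical atlas. The two-placement scenario puts one electrode 4 mm
from bundle A's centerline and a second, shifted 4 mm laterally, near
bundle B — so contrast maps and region rankings have a construction-known
answer.

What the phantom establishes: every counting rule, the field/tracking/cable
coupling, determinism, and end-to-end discrimination between placements.
What it does not: realism of human anatomy, bedpostX-style posterior
uncertainty, registration error, or the absolute activation counts of any
clinical configuration — phantom activation counts are properties of the
phantom geometry, not predictions.

## Problem sizes and determinism

Full-scale runs (1331 seeds × 100 samples) are supported but the shipped
tests and the acceptance script run a scaled-down study — a 5³ seed cube at
2 samples per seed with a 200-step cap on the 60 mm phantom — which
exercises every stage in minutes on one core. All stochastic stages consume
a single integer seed (tracking draws per placement use seed + placement
index); repeated runs with one configuration reproduce bit-identical stage
outputs, which the pipeline manifest verifies by checksum.

## Known limitations

- Axis-aligned grids only; oblique acquisitions must be resampled upstream.
- Single-contact monopolar stimulation; no bipolar or current-controlled
  modes.
- The reduced 4-compartments-per-section cable reproduces the qualitative
  physiology (propagation, strength–duration with positive chronaxie,
  distance-dependent thresholds, high-amplitude block) but its absolute
  thresholds are not calibrated against the full double-cable model.
- The interface drop is a static scaling; a full equivalent-circuit
  transient would slightly reshape near-threshold behavior at short pulse
  widths.
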