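# Methods

`hearts` reproduces, at desk scale, a sensitivity analysis of the QRS complex
of the ECG to the number and anatomical location of Purkinje–myocardial
junction (PMJ) stimuli.  This note documents the model, its assumptions, the
calibrations behind the defaults, and what the synthetic anatomy does and
does not capture.

## Electrophysiological model

Tissue electrophysiology follows the monodomain reaction–diffusion equation

    Cm dVm/dt = (1/beta) div(D grad Vm) − I_ion + I_stim,

with `Cm` the membrane capacitance (1 µF/cm²), `beta` the surface-to-volume
ratio (140 /mm), `D` the anisotropic conductivity tensor built from the fiber
field as `sigma_t I + (sigma_l − sigma_t) f fᵀ`, and `I_ion` the ten
Tusscher–Panfilov 2006 human ventricular ionic model (19 state variables;
epicardial parameter set everywhere by default, with endo/M variants
available).  Currents are expressed per unit capacitance (µA/µF ≡ pA/pF), so
`Cm` cancels in the reaction update; a positive stimulus current depolarizes.

Space is discretized on a Cartesian voxel grid: finite-volume face fluxes
for the divergence (harmonic-mean face conductivity for the normal
component, averaged central differences for the anisotropic cross terms)
with zero-flux boundaries at every tissue/background and tissue/cavity face.
Time integration is forward Euler for the membrane potential and ionic
concentrations.  The twelve gating variables use the exponential
(Rush–Larsen) update of the published model code: the fast sodium activation
gate has a time constant near 0.001 ms at rest, so a plain forward-Euler
gate update would require a ~0.001 ms step; the hybrid scheme is stable at
the 0.02 ms default.  A pure forward-Euler mode exists for verification with
its own, much smaller, step bound.  A stability guard computes the explicit
diffusion bound from the spacing and conductivities and rejects unstable
settings rather than silently subsampling.

Activation times are recorded as the first upward crossing of 0 mV with
sub-step linear interpolation.  Simulations stop 50 ms after the last voxel
activates (configurable), which truncates nothing of the QRS.

## Conduction-velocity calibration

Image-based models of this kind run at ~0.1 mm; this package runs at millimetre
spacings, where the numerical conduction velocity (CV) of the scheme departs
substantially from the continuum value and the departure depends on both the
spacing and the propagation speed.  The conductivities are therefore
calibrated per spacing on a uniform-fiber slab so that a planar wave runs at
0.07 cm/ms along fiber and 0.035 cm/ms across fiber (human ventricular
norms; anisotropy ratio 2).  Calibrated values (mS/mm):

| spacing (mm) | sigma_l | sigma_t |
|---:|---:|---:|
| 0.25 | 0.210 | 0.0660 |
| 0.5  | 0.2675 | 0.1031 |
| 1.0  | 0.4173 | 0.1952 |
| 2.0  | 0.7774 | 0.4146 |
| 2.5  | 0.9762 | 0.5443 |

Intermediate spacings interpolate linearly.  Because the coarse-grid CV
penalty is speed-dependent, the effective tensor ratio varies with spacing
even though the physical anisotropy it realizes does not.  A fixed tensor
ratio (e.g. 4:1) leaves the transverse wave at ~0.12 mm/ms on the 2.5 mm
grid — slow enough to erase the timing differences the analysis measures —
which is why both eigenspeeds are calibrated independently.

## Idealized anatomy

The heart is a pair of truncated half-ellipsoid shells on the package's
shared frame (x right→left, y posterior→anterior, z apex→base): a
thick-walled LV (cavity radius 22 mm, wall 12 mm, apex-to-base 85 mm) and a
5 mm RV crescent wrapped onto its septal side.  The septum is the part of
the LV wall within one wall-thickness of the RV cavity.  The RV basal
boundary slopes down from the septal junction toward the lateral free wall
(6% of the long axis), emulating the atrioventricular groove sitting below
the outflow region; the cavity is cut one wall thickness deeper than the
wall so every axial slice keeps both cavities enclosed by tissue.

Fibers follow a rule-based transmural helix: the helix angle varies linearly
with normalized transmural depth from +60° at the endocardium to −60° at the
epicardium (common rule-based defaults), with vectors tangent to the wall.
Transmural depth comes from the ratio of distance-to-endocardium to total
wall crossing (for the septum, LV-side to RV-side distance).

The four initial-activation regions are subendocardial patches (within 3 mm
of the endocardium) around seeds placed per the classic isolated-heart
mapping description: left midseptum (S), anterior superior LV wall near the
base (LASW), posterior inferior paraseptal LV wall one third of the
apex-base distance (LPIW), and the anterior RV free wall at mid height,
where the anterior papillary muscle inserts (RAIW).  Wall regions use a
13 mm radius and the septal region 24 mm — large enough to contain their own
stimulus patterns once those are snapped onto the curved wall (a 10 mm
radius cannot contain the 7 mm-spaced pattern corners after snapping at
coarse grids).  RAIW centrality on the free wall matters: it is what lets
the healthy beat finish the RV quickly while a transseptally activated RV
(bundle-branch block) stays slow — the contrast the analysis measures.

Electrodes LA/RA/LL sit on an Einthoven triangle in the frontal plane of the
heart centroid, LA/RA symmetric about the sagittal midline, 250 mm torso
scale.  The heart orientation relative to this triangle is a calibration,
not a physical claim: it was chosen so the default healthy beat shows a
dominant positive R wave in lead I.

## Stimulus protocol

Each PMJ is an 8 mm³ box injecting 72 µA/µF for 1 ms (period 1000 ms); boxes
in the RV wall fire 5 ms late.  Seed configurations add one box per IAR in
the order S, S/LASW, S/LASW/LPIW, S/LASW/LPIW/RAIW.  Dense levels layer
regional boxes around every seed — apico-basally (levels 2–4), laterally
(5–7), then one transmural layer (8) — with totals 4, 12, 20, 28, 84, 140,
196, 384 and per-IAR counts 1, 3, 5, 7, 21, 35, 49, 96.  Sparse variants
keep each level's seed plus peripheral extremes (line ends, or the 3×3
corner/edge-midpoint subsample), preserving the topographical extent with
totals 12 (lines) or 36 (grids).  Peripheral spacing is 7 mm in the wall
IARs and 16 mm apico-basally in the septum; the septal anterior–posterior
spacing is not specified anywhere and is set to 8 mm so the patterns stay on
the septum.  Dense spacing is one third of sparse, so sparse extremes
coincide with dense extremes.

Box positions are generated in the seed's local wall frame (apico-basal
tangent, lateral tangent, transmural normal) and snapped to the nearest
admissible wall voxel, which makes the patterns follow the curved wall; a
nominal position farther than 8 mm from any admissible voxel is a placement
error.  The transmural layer keeps the 47 copies (of 49) closest to the
seed among those that remain in tissue, which reproduces the 384 total on
the default geometry deterministically.

On grids coarser than the box itself, a single stimulated voxel cannot
ignite propagation: the spacing-calibrated diffusivity makes the
source–sink mismatch insurmountable.  Each box therefore excites all voxel
centers within max(box half-diagonal, one spacing) of its center, and
overlapping boxes saturate rather than sum (a voxel carries one PMJ's
current density).  This widened footprint is purely a discretization of the
suprathreshold volume; box objects keep their 8 mm³ identity.

Bundle-branch-block configurations derive from the 12-stimulus sparse
protocol: RBBB removes the RV boxes and LBBB the LV ones; in both, a single
septal stimulus repositioned one sparse step toward the base emulates the
physiological delay distal to the blocked bundle (RBBB keeps 7 boxes; LBBB
keeps the 3 RV boxes plus the basal septal one — the LBBB count is a package
choice, as no count is specified for it).

## Pseudo-ECG and QRS features

Surface potentials use the infinite-homogeneous-conductor pseudo-ECG,
`phi_e ∝ −Σ (D grad Vm)·grad(1/r) h³`, which corresponds to a torso of
homogeneous material; heterogeneous torso conduction is out of scope.
Leads are Einthoven differences I = LA−RA, III = LL−LA, and II = I + III
(the identity holds exactly by construction).  A single global gain of 0.5,
calibrated once so the healthy 12-stimulus beat has a ~1 mV R wave on the
default 2.5 mm anatomy, scales the leads; amplitudes are meaningful
relatively, never as patient-scale absolutes.

QRS features follow the study conventions: Q and R amplitudes and QRS
duration from lead I, S amplitude from lead II, all amplitudes as
magnitudes.  The Pan-Tompkins construction — the squared lead-I derivative
integrated over a 30 ms moving window — both locates the beat (rejecting
multi-beat traces) and defines the QRS window: onset/offset are the
earliest/latest sustained (5 ms) crossings of this energy envelope above
0.01% of its beat maximum.  The threshold is deliberately tiny because the
simulated signals are noise-free while the terminal activity of prolonged
beats is low-amplitude; a raw-derivative threshold truncates such tails
inconsistently (28 ms offset scatter across configurations, against a known
reference — the full-depolarization time of each beat — versus 8 ms for the
envelope).  The envelope widens every measured duration by a nearly
constant ~30 ms; differences and ranges across configurations, which are
what the sensitivity statistics consume, are unaffected, but absolute
durations read long by that amount.  The S-wave duration in lead I runs
from the last downward zero crossing after the R peak to the QRS offset.  Physiological ranges ship as
an editable table (textbook values: QRS 60–110 ms, lead-I Q ≤ 0.3 mV, lead-I
R 0.3–2.0 mV, lead-II S ≤ 0.9 mV); the bundle-branch-block cutoffs (QRS
> 120 ms, lead-I S wave > 40 ms) are named constants.

## Sensitivity statistics

For each feature, the metric series over total stimulus count
N ∈ {1,2,3,4,12,20,28,84,140,196,384} yields

* DF = range(metric, 1 ≤ N ≤ 4) / range(metric, 4 ≤ N ≤ 384), the
  desensitization factor (N = 4 belongs to both categories; range =
  max − min).  DF is undefined when the regional range is zero (an
  undetectable feature), mirrored by an explicit flag.
* ASPS(M) = mean(|Δmetric_N| : N ≤ M) / M for
  M ∈ {4,12,20,28,84,140,196,384}, where Δmetric_N is the change from the
  configuration with the next smallest N.  N = 1 has no predecessor and
  contributes no Δ by default; a flag switches to counting it as zero.

## Problem sizes and determinism

The package's study-scale runs use the 2.5 mm grid (~10⁴ tissue voxels,
dt = 0.02 ms), where one beat takes well under a minute on one core and the
full eleven-configuration sweep runs in minutes; spacing is a configuration
knob and everything recalibrates through the conductivity table.  All
computations are deterministic: no random number generator is used anywhere
in the pipeline, and identical configurations produce identical outputs.

## What the synthetic anatomy does and does not show

The idealized geometry preserves what the analysis needs — two enclosed
cavities, a septum, apex-base axis, realistic wall thicknesses and path
lengths, four anatomically placed IARs — but it is not an image-based heart:
absolute wave amplitudes, the detailed QRS shape, and amplitude-dependent
classifications transfer only qualitatively.  Timing-based conclusions
(activation sequences, QRS and S-wave durations, the seed-vs-regional
sensitivity ordering) are the quantities the desk-scale model is designed to
reproduce.  There is no torso heterogeneity, no Purkinje network, no
repolarization (the simulation covers ventricular depolarization only), and
no beat-to-beat dynamics (a single beat per configuration).

## Known limitations

* The coarse grid requires the stimulus-footprint widening and per-spacing
  CV calibration described above; both are desk-scale artifacts with no
  analog in a fine-grid model.
* Measured QRS durations carry the ~30 ms envelope-window overhang, so the
  healthy beat reads above the textbook 110 ms bound even though its
  activation completes in ~110 ms; classifications of absolute durations
  should be interpreted with that bias in mind.
* The epicardial cell variant is used everywhere by default; transmural
  heterogeneity is available but unexercised by the default protocol.
* The flat truncated base makes late basal activation unusually coherent,
  which deepens the terminal S deflections (and the lead-II S amplitude)
  beyond what real hearts show; the positive R wave still dominates the
  onset phase of the healthy beat, which is how the orientation calibration
  is stated.
* DF separates features unevenly at desk scale: R and S amplitudes give
  DF ≈ 4.2 and 2.0 (seed-dominated, as expected), but the QRS-duration DF
  sits at ~0.9 — the idealized anatomy leaves ~50 mm paths from the four
  seeds to the basal laggards, so the protocol's 7–16 mm pattern extensions
  shorten total activation almost as much as adding seeds does — and the Q
  amplitude's seed range is degenerate (~0.1 mV), making its DF
  uninformative.
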