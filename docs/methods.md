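# Methods

`morphotrack` implements the computational pipeline of a single-molecule
morphogen-dispersal study: an agent-based simulator of hindered diffusion in
extracellular tissue geometry, and the analysis chain for single-particle
tracks — linking, jump-distance mixture fits, angle anisotropy, MSD fits,
photobleaching-corrected dissociation-rate spectra and localization-density
ratios. All stages are validated by parameter recovery on synthetic data
with known ground truth; no experimental data ships with the package.

## Tissue geometry

Geometries are binary rasters (1 = extracellular) at 10 nm pixel pitch for
simulation-grade masks, plus labeled region polygons in µm. Two region
classes matter: *interfaces* (narrow films where two cells are aligned) and
*cavities* (larger voids where more than two cells meet). The extracellular
fraction is η = 100 × extracellular pixels / total pixels.

`synthesize_tissue` emulates an embryonic blastoderm: cell centers are a
blue-noise point set; the extracellular network is the generalized Voronoi
channel (pixels whose two nearest seeds are nearly equidistant) with its
half-width bisected to the target η; cavities are disks grown around a
subset of the triple junctions. Defaults are blastoderm-like — cells of
~15 µm (`cell_area_um2 = 100` for generic use; the simulation studies below
use 225), cavity radii of 1.5–2.5 µm (`cavity_fraction = 0.4–0.45` of the
extracellular area on `cavity_site_fraction ≈ 0.25` of the junctions), and
interfaces of 0.2–0.5 µm at η = 8–16%. The cavity size relative to the
~1 µm free jump length is *not* a free dial: centimeter-accurate but
micron-scale-wrong cavities qualitatively change where molecules accumulate
(see below). What the generator does not emulate: irregular cell shapes,
image-border cell truncation, segmentation noise, 3D structure.

`morph_extracellular_width` erodes/dilates one pixel per side per iteration
(20 nm of width at simulation pitch) until η crosses the target, erroring if
erosion disconnects the network. `classify_regions` estimates local width
as twice the Euclidean distance to the nearest cell and paints the
free-space disk of every >2-cell junction as cavity; the default 1 µm width
threshold is a reproducible stand-in for what was a manual classification
in the experimental workflow. On synthetic tissue it agrees with the
generator's own labels on ≥ 98% of extracellular pixels.

Receptors are placed by arc-length resampling of the marching-squares
boundary contours at spacing 1/σ (σ = receptors per µm of membrane), with
one receptor per boundary pixel (and a warning) if 1/σ falls below the
pixel pitch.

## Agent-based simulator

Morphogens are agents on the extracellular lattice. Per 10 ms step an agent
draws a jump distance r from the discretized 2D Brownian step-length law
f(r) = r/(2 D dt) · exp(−r²/(4 D dt)) for its state (D_free = 30,
D_bound = 0.5 µm²/s) and moves to a uniformly chosen admissible pixel on
the annulus at distance r; if none exists the distance is redrawn (8
tries), then the agent stays put — reflective behaviour at boundaries. A
free agent landing within 20 nm of a receptor binds for
t_b = τ · log10(1/v), v ~ U(0,1) (mean residence 0.434 τ); the timer is
decremented each step and not renewed. Simulations start with
BF_I = τS / (50 log10(10/σ)) of the agents bound (clamped to [0, 1]) so
that binding equilibrium is reached quickly.

Two deliberate choices:

* **Jump-law support.** The jump grid runs in 10 nm steps to the larger of
  2 µm and the distance containing all but 10⁻⁴ of the step-length
  distribution. A hard 2 µm cap would clip 3.6% of the D_free = 30 µm²/s
  distribution and depress the walk's effective diffusion coefficient by
  ~12%; with the adaptive support the MSD of an unconfined walk recovers
  D_free within 1–2%.
* **Bound motion is membrane-tethered.** A bound morphogen is attached to
  a membrane receptor, and bound molecules in the underlying experiments
  move slowly *along the membrane*. Bound jumps are therefore restricted
  to extracellular pixels within the binding radius of a membrane
  (`bound_on_membrane = True`; set False for an unconstrained slow walk).
  This matters: with unconstrained bound motion the bound population
  spreads √(4 D_bound t_b) ≈ 4 µm from its capture site and the
  interface-retention regime below disappears.

Two robust regimes emerge on tissue-like geometry, matching the study's
phenomenology. Without binding (τ = 0), molecules accumulate in cavities:
the stationary density of the annulus-resampling walk weights positions by
the availability of extracellular space around them, which is largest
inside voids wider than the jump length — pure geometry, no binding
(ρc/ρi ≈ 2–3.5 at η = 8%). With strong binding (σ = 5 µm⁻¹, τ = 16 s) the
bound, membrane-tethered population dominates and localizes molecules to
the narrow interfaces (ρc/ρi ≈ 0.3–0.5). The parameter screen covers
σ ∈ {0.05, 0.5, 5}, τ ∈ {0, 1, 6, 11, 16} s, η ∈ {8, 10, 12, 14, 16}% (75
runs). Simulation studies in the test suite use 2,000 steps and the
acceptance scale of 10 seeds; full-length runs are 10,000 steps.

## Track linking and region assignment

Per-frame localizations are linked frame-to-frame by greedy global-nearest
assignment within a tracking radius (default 1.66 µm, i.e. 10 camera pixels
of 166 nm); candidate pairs are sorted by distance and accepted greedily so
the closest pairs win conflicts. One missing frame may be bridged when the
molecule was already detected in ≥ 2 consecutive frames; the same radius
applies across the gap (a documented alternative would scale it by √gap).
Bound-molecule tracking presets pin radius and minimum track length per
frame cycle time (257/340/485/601 nm and 5/3/3/3 frames for 11.7/58/199/
1006 ms). `predict_tracking_radius` gives the closed-form radius at which a
free jump escapes with a stated probability, r = √(−4 D t ln p); the preset
radii additionally folded in photobleaching upstream, so they are constants
here, not recomputed values. Tracks are assigned to a region class only if
every localization lies inside a single polygon; border-crossers are
discarded; TALM maps bin localization counts (default 2 × 2 camera pixels).

## Jump-distance mixture analysis

The cumulative distribution of consecutive-frame jump distances (≤ 10 jumps
per track, none across gap frames) is fitted on a 1 nm grid up to the
tracking radius with a K-component Brownian mixture; only the fastest
component carries the tracking-radius cut-off normalization
1 − exp(−r_tr²/(4 D_K τ)), matching how the plotted density is defined.
Diffusion coefficients are optimized in log space and fractions through a
softmax, from 10 multi-starts. K is chosen by
ΔAIC = (2k₂ + n ln RSS₂) − (2k₃ + n ln RSS₃) (positive favours three
components; k counts D and A parameters, i.e. 2K). Errors come from 500
refits of random 50% subsamples. The empirical CDF is evaluated at bin
centers. Localization noise ε (default 20 nm per coordinate in the
generators) adds ~ε²/τ ≈ 0.03 µm²/s to the apparent slow component; the
recovery tests compare against the effective (noise-inclusive) truth.
Known biases of real data (2D projection of 3D motion, defocus loss) are
deliberately not corrected — the 2D generators produce none.

## Angles and MSD

Jump angles use three consecutive localizations with both segments ≥ 166 nm;
θ = 0° is forward, 180° a reversal, measured signed in [0, 360)°. The fold
anisotropy f180/0 is the probability ratio of the 180° ± 30° and 0° ± 30°
wedges; 1 for free diffusion, > 1 under confinement. The angle between a
jump and a region border takes the polygon vertex closest to the jump
midpoint (lowest index on ties) and averages the two adjacent edge
directions as undirected lines — accurate for densely sampled ROI outlines,
coarse at sharp corners. MSD fits use tracks ≥ 20 frames, the time-averaged
MSD at lags 1–10 with all overlapping pairs, and OLS on MSD = 4Dτ + c
(c absorbs localization error); fits with D > 0.5 µm²/s are flagged as too
fast for a bound molecule.

## Dissociation-rate spectra

Binding durations collected at frame cycle times 11.7/58/199/1006 ms are
integer frame counts; photobleaching removes the molecule with a fixed
probability per illuminated frame, so its apparent rate is −ln(1−p)/Δt and
differs across conditions while true unbinding does not — fitting all
conditions jointly separates the two. The model is a superposition of 40
exponentials with rates fixed on a log grid 10⁻²–10² s⁻¹.

The default inversion maximizes the exact likelihood of the discretized
durations: per condition a truncated geometric mixture with per-cycle
survival factor q_j = exp(−k_j Δt − κ), conditioned on reaching the minimum
track length, with acquisition-spanning events kept as right-censored
observations and the tail beyond the 1% survival probability re-censored
at that point rather than trusted event-by-event. Amplitudes are fitted by
SQUAREM-accelerated EM (plain EM sharpens this near-collinear mixture only
logarithmically); the bleach number κ is profiled on a grid and refined.
Because a dense grid smears each rate population over neighbouring grid
points — and the 1/k weighting of the state spectrum then biases cluster
residence times upward — the grid solution is sharpened by a per-cluster
continuous-rate maximum-likelihood refinement with BIC-guided split/drop
moves, and projected back onto the fixed grid so that both event mass and
state mass (amplitude/rate) are conserved; cluster summaries of the
projected spectrum equal the continuous estimates exactly. A survival-curve
NNLS route with Tikhonov regularization and L-curve weight selection is
retained (`method="nnls"`) as a cross-check; it is substantially noisier at
desk-scale event counts because the survival tail carries almost no
least-squares weight.

The event spectrum (how often events of each rate occur) is converted to
the state spectrum (probability a bound molecule occupies each rate) by
dividing amplitudes by their rates and renormalizing. Clusters are either
summarized over explicit rate boundaries (default long-bound boundary
0.15 s⁻¹) on the sharpened spectrum, or detected automatically as
contiguous above-threshold runs of the *dense grid-stage* spectrum — the
automated analog of assigning boundaries by eye on a plotted spectrum.
Runs confined to the outermost grid bins are treated as out-of-grid
artifacts (truncation-amplified mass from rates beyond the resolvable
band), not clusters. A cluster's residence time is the inverse of its
state-weighted mean rate. Errors come from 500 re-inversions of random 80%
subsamples (reduced counts in tests).

Resolution limits, measured on synthetic data: with four time-lapse
conditions, 10% bleaching per frame and 10⁴ events, the information floor
for a 16 s residence time is ~25% per experiment (an oracle two-component
parametric fit scatters that much), so recovery checks aggregate the median
over replicate experiments; and a component's detectability requires its
likelihood contribution to exceed the BIC bar, which for components less
than a decade apart needs of order 10⁵ events at moderate (3%) bleaching.
The observable rate band is bounded below by the acquisition span
(~1/23 s⁻¹) and above by the minimum track length (~15 s⁻¹); spectra
synthesized for resolution demonstrations stay inside it.

## Density ratios

Per movie, the spot density of a region class is the detection count inside
its polygons divided by the class area in rasterized pixels at the mask
pitch; the per-movie ratio is ρc/ρi. Movies with only one region class or
zero detections in a class are invalid; ratios above 10 are display-flagged
but retained. Cohorts are summarized by median and quartiles; hypothesis
testing is out of scope.

## Synthetic data

Generators produce every input the pipeline consumes, with truth records:
jump distances (component choice by fraction, Rayleigh step, Gaussian
endpoint noise of ε per coordinate so E[r²] = 4Dτ + 4ε², tracking-radius
rejection); binding durations (state fractions converted to event fractions
by multiplying with the rates — the exact inverse of the state conversion —
exponential durations, frame discretization, geometric bleaching on
illuminated frames, acquisition-end censoring, minimum-track-length
selection, with 5 frames minimum for the continuous condition and 3 for
time-lapse); and movies (simulator positions sampled per frame with a
detection efficiency, plus localization noise, carrying hidden agent
identities for link-accuracy scoring). All generators are deterministic
under a seed. Passing recovery tests on these generators demonstrates the
estimators under the model's own assumptions; real data add biases the
generators deliberately omit (3D projection, defocus, segmentation error,
drift).

## Reproduction script

`scripts/acceptance.py` regenerates the two morphogen-like ground truths
(slow clusters of 16.2 s at 50.0% and 11.0 s at 28.9% of bound states, fast
companion at 1 s⁻¹), observes 10⁴ events through the four time-lapse
conditions with 10% per-frame bleaching, inverts and summarizes the slow
cluster, and reports the median over 11 replicate experiments (the
single-experiment noise floor above is why a median is reported). Runtime
is a few minutes on one CPU.
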