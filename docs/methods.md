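# Methods

`atriasim` simulates electrical activity of AF-remodeled human atrial
tissue, maps the frequency and phase structure of fibrillatory episodes,
and evaluates virtual ablation of the dominant-frequency (DF) areas under
controlled conduction-velocity (CV) conditions.  This note records the
model, the numerical choices, and the limits of what the desk-scale test
suite demonstrates.

## Membrane model

The ionic model is the Courtemanche–Ramirez–Nattel human atrial myocyte
model: 21 states (membrane potential, 15 gates, 5 ion concentrations),
12 membrane currents and a two-pool sarcoplasmic-reticulum calcium
subsystem.  Currents are densities in pA/pF, so `dV/dt = -(I_ion +
I_stim)` in mV/ms; the whole-cell capacitance (100 pF) enters only the
concentration balance equations.  Implementation checks: the published
resting state is a fixed point to |dV/dt| < 1e-3 mV/ms; the maximal
upstroke velocity of a paced action potential is ~219 mV/ms and APD90 at
1000 ms cycle length is ~298 ms, both matching the published model; the
trace of the optimised integrator agrees with an independently coded
forward-Euler transcription of the same equations to < 1 mV.

Chronic-AF electrical remodeling multiplies four maximal conductances:
I_to x0.2, I_Kur x0.5, I_CaL x0.6, I_K1 x1.5.  Remodeled cells are the
default everywhere (including CV calibration); the remodeled action
potential is strongly abbreviated, which is what sustains fibrillatory
rates near 6 Hz.

## Tissue model and numerics

The monodomain equation `dV/dt = div(D grad V) - I_ion - I_stim` is
discretised with linear finite elements on triangles.  Structured 2D
sheets are triangulated with a uniform diagonal split: interior lumped
masses are then exactly h^2 and an axis-aligned diffusion tensor
reproduces the classical 5-point stencil (the alternating split, by
contrast, makes the pointwise operator inconsistent by up to 50%).
Closed surface meshes use the same assembly (cotangent weights arise
naturally).  Anisotropy is specified as a longitudinal:transverse CV
ratio; since planar CV scales with sqrt(D), a conduction ratio 2 means a
diffusion-eigenvalue ratio 4.  Fibers are given as an in-plane angle
field (2D sheets only); surfaces are isotropic.

Time stepping is operator-split per outer step: an ionic reaction update
(Rush–Larsen exponential integration for the 12 voltage-dependent gates
with tabulated steady states and decay factors on a 0.05 mV grid;
forward Euler for V, concentrations and the calcium-release gates),
followed by an explicit diffusion update.  The step switches between
`dt_min` and `dt_max` (defaults 0.01/0.1 ms) on a global |dV/dt|
threshold (default 10 mV/ms), on an integer microsecond clock so that
recording (1 ms cadence) and stimulus onsets stay exactly aligned.
Planar-sheet production runs use a fixed 0.1 ms step, the configuration
of the reference 2D experiment.  Explicit stability is checked at setup
against a power-iteration estimate of the diffusion spectral radius, and
`stable_settings` halves `dt_max` when a large D demands it.  Nernst
potentials are refreshed every 2 ms rather than every step
(concentrations drift on a seconds scale; the approximation is below
1 uV per step).  Blow-up is detected by a vectorised finiteness/range
check every step and reported with the offending node and time.

### Mass lumping and conduction velocity

At ~300 um spacing the depolarisation upstroke is marginally resolved,
and the discrete CV depends on the mass-matrix treatment: lumped mass
(the fast production path) underestimates planar CV, while the
consistent P1 mass matrix — the textbook finite-element formulation —
propagates faster and reproduces the literature reference value for the
AF-remodeled tissue (0.72 m/s at D = 0.00154 cm^2/ms, 500 ms pacing)
within the acceptance tolerance.  The benchmark path
(`SolverSettings(consistent_mass=True)`, used by `scripts/acceptance.py`)
therefore solves the diffusion update with a prefactorised consistent
mass matrix at dt <= 0.025 ms.  Production sheet runs keep mass lumping
for speed; their D values are *calibrated* (see below) with the same
lumped solver that runs the experiments, so their realised CVs are
internally consistent.

### CV measurement and calibration

CV is measured from threshold-crossing activation times (−40 mV on the
upstroke, linearly interpolated between 1 ms samples) at the two ends of
a node path, using the last beat on which both endpoints activate in
order.  `calibrate_diffusion` adjusts D on a homogeneous strip paced at
500 ms cycle length until the measured planar CV is within 2% of the
target, using sqrt-law proposals with a log-bisection bracket; on coarse
grids there is a conduction threshold in D below which discrete
propagation fails, and the routine brackets above it.  At 0.5 mm spacing
CV targets below ~0.25 m/s are not reachable without phase-wave
artefacts, so all desk-scale sheets use the reference 0.25 mm spacing.

## Protocols

The AF-induction ramp is 24 stimuli, eight each at cycle lengths
200/190/180 ms (total footprint 4,560 ms), delivered at the high-septum
analogue landmark.  The dynamic restitution ramp descends from 500 to
196 ms (default 2 ms decrement, 10 beats per level) and feeds APD90- and
CV-restitution curves; levels at or below the detected 1:1
capture-failure cycle length are excluded.  Stimuli are 2 ms rectangular
current pulses; defaults are −20 pA/pF for an isolated cell (about twice
the measured capture threshold) and −40 pA/pF over a ~0.6 mm-deep node
set in tissue, where electrotonic load raises the threshold.

## DF and PS analysis

DF is the argmax of the power spectrum of the mean-removed
membrane-potential signal over a 6-s window (rectangular window by
default, Hann optional) within a 1–20 Hz band; a 6-s window gives 1/6 Hz
resolution.  Quiescent nodes (no band power) carry an undefined DF.  The
highest-k% DF area is the ceil(k% N) nodes with the largest DF, ties
broken by peak power then node index, which makes the k = 10/15/20 sets
nested.  Regional proportions are fractions (not percentages) of the
selected set per anatomical segment; the spatial (across 10 segments,
then averaged over windows) and temporal (across windows, then averaged
over segments) mean variances use the sample variance (ddof = 1).

Phase is computed by time-delay embedding,
`theta = atan2(V(t+tau) - V_mean, V(t) - V_mean)`, with `V_mean` the
per-node average over the analysis window itself and `tau` defaulting to
a quarter of the dominant period (rounded to the 1 ms sampling grid).
Phase singularities are detected by topological charge: the sum of
wrapped phase differences around every grid plaquette or mesh triangle;
loops summing to +-2 pi yield a detection with that charge.  Detections
are counted per 1-ms frame and linked into trajectories by greedy
same-charge nearest-neighbour assignment with a step bound (default
0.2 cm/frame) and zero gap tolerance; a trajectory's life-span is last
minus first frame time.

## Virtual ablation and outcome classification

Lesions are the highest-k% DF node sets (k = 10, 15, 20), applied by
setting D = 0 and dropping every element touching a lesion node, so no
flux crosses the lesion boundary; lesioned membrane states are frozen
(equivalent to removal, and reproducible).  Each branch restarts from
the checkpoint states of its analysis window, making branches across k
directly comparable.

The post-ablation label over a 30-s observation is:

* `terminated` — no probe activation over a terminal interval >= 1 s;
* `AT` — sustained but organised activity: probe cycle-length
  coefficient of variation < 10% and mean PS count per ms <= 1;
* `AF_maintained` — otherwise.

"Defragmentation" = terminated or AT.  The thresholds are declared
defaults recorded in every label's evidence; the source definitions are
qualitative, so the exact numbers are a package choice.

## Episodes and desk scale

An episode calibrates D for its CV target, induces activity, observes up
to a cap (default 300 s) with 6-s analysis windows every 30 s of
maintained AF (T1–T9), checkpoints each window for ablation branches,
and classifies the rhythm on rolling windows.  Induction success means
AF maintained > 20 s after pacing; AF maintenance ends at termination or
at the first window classified AT; AF/AT maintenance ends at
termination.  Ensemble variability on homogeneous geometry comes from
±1 ms stimulus jitter and 0.1 mV initial-voltage noise (ramp mode) or
from the seeded-core position (spiral mode, below).

**Ramp induction does not scale down.**  The reference 2D configuration
is a 15 cm sheet (600 x 600 at 0.25 mm).  On desk-scale sheets (3–5 cm)
the ramp cannot induce AF at any tested CV: below its 1:1 capture limit
(~200–210 ms) the homogeneous tissue responds 2:1 globally, the
effective wavelength exceeds the domain, and every episode terminates at
pacing end.  This is a property of the physics at reduced scale, not of
the implementation; a single full-scale pacing run costs tens of CPU
minutes and is outside the test budget.  Desk-scale episodes therefore
use `induction="spiral_seed"`: nodes are initialised from a paced
single-cell limit cycle at a phase equal to their azimuth about a core
(the classical cross-field initial condition), which starts a rotor that
then evolves freely.  The full-scale preset keeps the ramp protocol
unchanged.  Consequences for interpretation: desk-scale tests
demonstrate the CV dependence of *rotor maintenance, frequency, phase
structure and ablation response*, on seeded reentry; they do not
demonstrate ramp inducibility, nor reproduce patient-geometry statistics
(which depend on anatomy that the homogeneous sheet lacks).

Desk-scale problem sizes used by the test suite (package choices): the
CV-dependence ensemble seeds one rotor per episode on a 160 x 160 sheet
(4 cm at 0.25 mm, conduction ratio 2) for three seeds per CV condition,
observes up to 2 s with early stop at quiescence, counts PS over a
fixed 2-s window, takes DF from a 1-s spectral window (1 Hz bins) when
the episode outlives it, and branches a top-10%-DF ablation at 1 s for
the CV strata the ablation comparison uses.  On this configuration the
low-CV rotor outlives the high-CV one, ablation defragments the
high-CV strata at least as often as the 0.4 m/s stratum, and PS counts
are lower at 0.6 than at 0.4 m/s.  Two desk-scale limits are
documented rather than worked around: the CV 0.3 rotor annihilates on
its first lap (a boundary resonance of the 4 cm domain, absent at full
scale), and episode lifetimes at CV 0.3/0.6 are shorter than any
usable spectral window, so the full-scale non-monotonic DF-vs-CV
pattern is not reproducible at desk scale (a single rotor's frequency
is set by its circuit, monotone in CV).

## Synthetic geometry

`make_sheet` builds the anisotropic fiber sheet (10 labelled segments:
3 x 3 blocks with the centre split, named after the atrial segments);
`make_strip` the calibration strip; `make_la_surrogate` a closed
icosphere-based left-atrium stand-in (four pulmonary-vein ostia and a
mitral-annulus hole, ten angular-sector segments, high-septum and
appendage-tip landmarks, ~300 um mean edge at the default radius).  The
surrogate replaces unavailable patient CT meshes: its topology, labels
and landmarks are faithful in *structure*, its shape and segment
boundaries are declared arbitrary, so regional statistics computed on it
are comparable in form, never in value, with patient results.  Analytic
movies (pulse trains, planar waves, spirals, dual spirals) provide
machine-precision ground truth for the DF and PS oracles.  All
generators are deterministic given their arguments.

## Known limitations

* Homogeneous membrane properties; no fibrosis, wall thickness or
  regional APD gradients — rotor meander is therefore boundary-dominated
  on small domains.
* Monolayer only; no bidomain, no transmural structure.
* The consistent-mass path is a benchmark tool (direct solver); large
  sheets run mass-lumped.
* Desk-scale ensembles use seeded reentry (above); ramp-induction
  statistics exist only at full scale.
* The AT/termination thresholds are declared conventions; labels near
  the organisation boundary are sensitive to them.
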