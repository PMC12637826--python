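# Methods

`vtwin` is a desk-scale digital-twin pipeline for reentrant ventricular
tachycardia (VT): it builds a fibrotic right-ventricular substrate from an
LGE-style intensity image, populates it with genotype-specific membrane
kinetics, induces VT by programmed electrical stimulation, plans a minimal
set of virtual ablation lesions that renders the substrate non-inducible,
and scores the predicted lesions against a reference lesion set. This note
records the models, the parameter choices that matter, and what the
synthetic test bed does and does not establish.

## Membrane model

The baseline myocyte is the ten Tusscher–Panfilov 2006 (TT2) epicardial
human ventricular model with an added late sodium current (O'Hara-style
`mL`/`hL` gating, `G_NaL = 0.011 nS/pF` at baseline). Gates advance by
Rush–Larsen, everything else by forward Euler, at `dt = 0.02 ms` (single
cell) or `dt = 0.05 ms` (tissue). Voltage-dependent rate expressions are
tabulated on a 0.02-mV grid and read by nearest bin inside a compiled
kernel; action-potential features agree with the untabulated formulation
to well under the feature tolerances used in tests.

Two deliberate calibrations sit on top of the published constants:

* **Repolarization reserve.** `I_Kr` and `I_Ks` are scaled ×3.2 / ×3.0 so
  that the baseline APD90 at a 600-ms drive train is ≈185 ms, in the human
  epicardial range. The published TT2 epicardial cell has an APD90 near
  280 ms at that rate, which would put the entire clinical extrastimulus
  coupling range (250 ms downward) inside the refractory period and make
  programmed stimulation vacuous. The scaling is a package constant, not a
  patient-derived value.
* **Phenotype remodeling.** Three phenotypes are expressed as conductance
  multipliers on this baseline. `GE` (gene-elusive) is the baseline
  itself. `PKP2` models plakophilin-2 loss of function: `g_Na ×0.35`
  (slower upstroke, lower peak), `g_K1 ×0.40` (≈ +1.2 mV resting
  potential), `g_CaL ×0.70` (flattened APD restitution). `FIB` models
  diffuse-fibrosis remodeling: `g_Na ×0.40`, `g_CaL ×0.65`, `g_Kr ×0.45`,
  `g_Ks ×0.40`, `g_to ×0.70`, giving a longer action potential (≈245 ms
  at CL 600) and slow conduction. The magnitudes are package defaults
  chosen to reproduce the established qualitative contrasts between these
  phenotypes; they are configurable per run.

## Tissue model

Propagation is monodomain on a structured grid (`h = 0.25 mm` default),
with an anisotropic 9-point in-plane stencil built from per-node fiber
angles and longitudinal/transverse diffusivities `σ_L, σ_T` (mm²/ms).
Weights are face-averaged and rows sum to zero, which yields no-flux
boundaries and exact mirror symmetry; contributions across non-conducting
faces are dropped. Dense scar and ablation lesions carry no conductivity,
are excluded from the state update entirely, and can never activate.
Stability is guarded by a Gershgorin bound (`dt·‖W‖∞ ≤ 2`). Activation is
the upward crossing of −40 mV, re-armed below −50 mV.

Fiber rules: uniform in-plane angle for sheets; linear endo-to-epi
rotation (default +60° → −60°) across slab layers.

### Conduction-velocity calibration

Conductivities are derived from CV targets by the logarithmic-fit
procedure: plane-wave CV is measured on a 40-mm strand (probes at the
25%/75% stations of the conducting extent) over a coarse conductivity
ladder, the target is bracketed, and `CV = a·ln σ + b` is fitted over five
probes concentrated around the bracket (globally CV grows like √σ, so the
logarithmic law is applied locally; the local fit reaches R² ≥ 0.99 and
closes the loop within ~3%). Default targets (mm/ms): GE 0.60/0.25
(longitudinal/transverse), PKP2 0.24/0.13 (the 60%/48% genotype-specific
reductions), diffuse fibrosis 0.07 isotropic. A transverse fibrosis target
of 0.05 mm/ms is below the propagation limit of the 0.25-mm grid
(conduction fails below σ ≈ 0.006 mm²/ms, CV ≈ 0.06 mm/ms), which is why
the fibrosis default sits at 0.07. The pre-calibrated σ values shipped as
config defaults are reproducible with `calibrate_conductivity`.

## Programmed stimulation

Each pacing site receives six S1 at 600 ms, then premature extrastimuli:
S2 starts 250 ms after the last S1 and is decremented in 10-ms steps to a
180-ms floor; if no arrhythmia results, S3–S5 are added in turn, each
scanned the same way with earlier stimuli fixed at their shortest captured
coupling. Stimuli cover 1 mm³ (1 mm² on a sheet) at twice diastolic
threshold for 2 ms. The scan reuses state snapshots so the drive train is
simulated once per site. Tissue may be initialized at each phenotype's
600-ms single-cell limit cycle; with that initialization the drive train
is entrained after two beats, and time-constrained tests use `n_s1 = 2`
(the default remains six).

A sustained episode requires re-excitation of a substantial tissue
fraction (≥5% of conducting nodes re-crossing threshold) lasting at least
two cycles at the same critical site. The cycle length is the median
inter-crossing interval; per cycle, the core is located as a
phase-singularity proxy — the lattice point at which the local activation
phases cancel (minimum normalized resultant of `e^{iφ}` within 4 mm) —
tracked across cycles by preferring the minimum within 4 mm of the
previous core (a figure-of-eight has two mirror singularities; tracking
follows one). "Same critical site" means core displacement ≤5 mm per
cycle. Median intervals below 100 ms are rejected as electrotonic flutter
at block sites rather than reentry. Nine pacing sites are chosen
automatically, one per AHA-style segment (3×3 partition of the sheet),
each the conducting node nearest its segment centroid.

## Circuit analysis

One full cycle of the detected episode is decomposed into eight uniform
isochrones. The analysis window is phase-aligned so that the diastolic
interval — the stretch of the cycle with the fewest activations, i.e. the
slow corridor crawl — is centered on bins 4–5. With this convention the
critical isthmus occupies the mid-cycle bins, the entrance falls in bins
2–3 and the exit in bins 6–7, matching the clinical coloring convention
for VT activation maps. Isthmus candidates are conducting mid-cycle nodes
walled by non-conducting tissue on two opposing sides within a 4-mm
corridor halfwidth (ray test against scar/lesion/boundary); the isthmus is
the largest connected candidate component near the core trajectory, and
its center is the component medoid.

## Ablation planning

Lesions are 3,500-µm-radius insulating spots (balls/discs) or line
capsules joining two spot centers. The planner loops: run the nine-site
protocol; if any site induces, ablate the first episode's isthmus center
(falling back to the core-trajectory medoid if no corridor is found); if
an episode's core path passes between two lesions closer than 10 mm, join
them with a line lesion; repeat until no site induces or 20 rounds elapse.
Pacing sites swallowed by a lesion are relocated to the nearest conducting
node. A leave-one-out audit reports which spot lesions are individually
necessary. Greedy targeting with this audit approximates—but does not
prove—minimality.

## Evaluation

Predicted and reference lesion point sets are compared after rigid
fiducial registration (Kabsch/SVD on matched landmarks; optional
similarity mode) and nearest-node projection onto the endocardial surface.
Each point contributes a hemisphere of 3,500 µm radius extending inward
along the surface normal; masks are unioned on a 0.5-mm evaluation grid
(voxel centers offset half a voxel from the surface plane so the midpoint
rule is unbiased), and Dice, sensitivity, specificity and false-detection
rate are counted over myocardial voxels with the reference as ground
truth. The average point-cloud distance is the symmetric mean
nearest-neighbor distance. Cohort statistics use Pearson correlation on
pooled per-segment proportions and the Wilcoxon signed-rank test on paired
volumes (zero differences dropped; exact null for n ≤ 25 without ties,
exact sign-flip enumeration for tied small samples, normal approximation
otherwise).

## Synthetic study conditions

Because real patient MRI/EAM data are private, every experiment runs on
seeded synthetic patients. A bundle contains: an intensity image
(0.35 mm isotropic) whose class bands respect the ≥2 SD / ≥4 SD
segmentation thresholds up to boundary noise; ground-truth labels; six
fiducial landmarks duplicated in a "clinical" frame through a random
rigid transform plus 0.2-mm noise; and a mock catheter-lesion cloud
sampling the true channel center lines with 1-mm jitter plus 30%
off-target points.

The default substrate is a 17.75-mm square sheet (a stand-in for an RV
free-wall patch) with a dense-scar block pierced by one vertical
slow-conduction channel (halfwidth 0.75 mm, fibrosis kinetics and
σ = 0.0089 mm²/ms), surrounded by ~6% patchy diffuse fibrosis kept 1.5 mm
clear of the scar. Seeds jitter the channel position (±1.5 mm), the scar
extent, the fibrosis patches, the intensity noise and the landmark
transform.

The geometry encodes the condition for desk-scale inducibility, found
empirically during development: a premature wave that enters a slow
channel in the same direction as the preceding drive-train wave chases
that wave's refractory tail and blocks, so reentry must start by entry
from the channel's far end against the drive's activation gradient. With
a corner pacing site, the S2 blocks decrementally at the near mouth,
conducts around the scar, enters the recovered far mouth and returns
through the channel — a figure-of-eight with cycle length ≈320 ms. This
requires the slow bulk conduction of the PKP2 phenotype; a GE-speed sheet
of this size conducts around the scar too quickly for the far mouth to
recover, so the bundled inducible fixtures are PKP2 patients. All ten
default seeds induce at the first S2 coupling and localize the isthmus
within 0.3 mm of the true channel midline.

What the synthetic bed does *not* capture: real ventricular geometry and
transmural fiber rotation, MRI artifacts and partial-volume effects,
multi-channel substrates at organ scale, epicardial/endocardial
distinctions, and clinical mapping noise beyond simple jitter/extras.
Passing tests demonstrate internal correctness and the stated physics at
desk scale, not clinical accuracy.

## Problem sizes and numerical choices

Defaults used by the test suite and the reproduction script (chosen as the
package's desk-scale study conditions): 72×72 simulation grid at 0.25 mm;
`dt = 0.05 ms` in tissue; observation window 1200 ms per extrastimulus
with early exit on quiescence (max Vm < −70 mV and no pending stimulus);
ten seeded fixtures for isthmus localization (reduced two-beat drive from
the limit cycle); the end-to-end ablation loop runs the full six-beat,
S2–S5, nine-site protocol. Degenerate inputs are handled explicitly:
all-equal intensity defeats Otsu (all-normal labels with a warning), empty
AHA segments are skipped with a warning, lesions smaller than a voxel
claim the nearest node, and couplings that fail to capture are skipped
rather than treated as errors.

## Known limitations

* Exact PKP2/fibrosis channel-remodeling magnitudes and the absolute
  CV/conductivity table of the source protocol are not public; package
  defaults satisfy the qualitative contrasts only.
* The planner is greedy; the leave-one-out audit can certify individual
  necessity but not global minimality.
* The two-cycle sustained criterion with a 5-mm same-site radius is an
  operationalization; meandering rotors that drift faster are classified
  as non-sustained.
* 2-D sheets cannot express transmural reentry; the slab mode exists but
  the shipped fixtures are sheets.
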