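# Methods

This note documents the models, numerical procedures and design choices of
`ktrepro` at the level of detail a user needs to interpret (and distrust)
its outputs.

## Synthetic B1+ maps

The transmit field of an 8-channel pTx body array is modelled with
point-like coil elements: four on an anterior plate, four on a posterior
plate, placed just outside an ellipsoidal torso. Channel `c`'s complex
sensitivity at position `r` is

```
b1_c(r) = exp(−μ · depth(r)) / (d_c + d0) · exp(i [φ_c + (2π/λ) d_c]),
```

with `d_c = |r − p_c|` the distance to the element centre, `d0 = 60 mm` a
near-field softening length, `λ = 140 mm` an effective in-tissue RF
wavelength at 7 T, `φ_c` fixed per-channel cabling offsets, and
`depth(r) = max(0, 1 − ρ(r))` the normalized depth below the torso surface
(`ρ` is the ellipsoidal radius; `μ ≈ 1.2`). This is the cheapest model that
produces the two phenomena the analysis depends on: constructive/destructive
channel interference at the scale of the heart, and flip-angle dropouts
under a mis-set static shim. It is not an electromagnetic solver: no eddy
or displacement currents, no conservative-field component, no SAR.

Maps are normalized per session so that the ROI mean of `Σ_c |b1_c|` is 1,
which removes the arbitrary absolute scale; every design and evaluation
step operates on normalized maps.

Grids default to 32×40×40 voxels at 8 mm isotropic — a desk-scale stand-in
for a clinical chest field of view. The torso extends beyond the grid along
the head–foot axis by construction (a chest FOV never contains the body),
so grid-containment is enforced transversally only.

## Longitudinal structure

A *subject* is a draw of torso/heart ellipsoid geometry and attenuation. A
*session* adds three effects, each a pure function of recorded seeds:

1. **Coil placement** — rigid translation and rotation about z of the
   element array: a systematic per-operator bias (up to ≈ 25 mm between
   operators; operators follow the same instructions but differ in habit)
   plus per-session jitter of (7, 7, 12) mm / 2.5° (1 SD).
2. **Anatomy drift** — the torso/heart geometry moves along a fixed
   direction (population-systematic component: chest growth, heart
   settling posterior–caudal; plus a per-subject random component) by an
   amount proportional to the elapsed time since the baseline scan, with a
   per-subject susceptibility factor in [0.5, 1.4] at 0.10/year. Sessions
   acquired on the same date share the anatomy state exactly. The default
   calendar is (0, 1, 2, 2) years — baseline, one-year rescan, and two
   same-day scans two years in.
3. **Loading screens** — small per-channel smooth complex fields
   (magnitude ±2–8 %, phase up to ≈ ±0.25 rad) emulating residual
   coil-loading/electronics differences between sessions.

The operator assignment for a 4-session study is A, B, A, C, so the
session pairs (3, 4) isolate a same-day operator change, (1, 3) a two-year
interval under the same operator, and (1, 2, 4) the full three-operator,
two-year span.

These amplitudes were calibrated once, while building the package, so that
the static shim's CV lands in the tens of percent and the cross-session
degradation of tailored pulses is clearly expressed, then frozen. No
in-vivo dataset quantifies these magnitudes; they are study conditions, not
claims about any scanner.

What the generator deliberately does **not** emulate: respiratory and
cardiac motion, B0 off-resonance, realistic dielectric wave effects,
receive (B1−) profiles, and measurement noise in the maps. Passing tests
therefore demonstrate the *logic* of the reproducibility analysis — that
the pipeline's statistics respond to placement/anatomy variability the way
the in-vivo study observed — not that the synthetic effect sizes match any
particular scanner or cohort.

## Pulse design

All three strategies minimize the small-tip-angle magnitude cost

```
cost(w) = mean_r (|A_r w| − θ)² + λ‖w‖²,   A_{r,(c,k)} = c0 b1_c(r) e^{i k_k·r}
```

with θ = 10° and `c0` chosen so that unit drive at a voxel with unit
sum-of-magnitudes sensitivity flips θ. The data term is the per-voxel
*mean* so λ has the same meaning regardless of ROI or library size;
λ = 5·10⁻³ by default, shared by all methods. At this level the penalty
matters: solutions are predominantly constructive (moderate RF power), so
that decoherence between sessions *lowers* the achieved flip angle — with a
numerically inert penalty the optimizer exploits delicate cancellations and
misapplied pulses can pile up excess FA instead, which is not what happens
in practice.

**Variable exchange.** The magnitude target is handled by alternating the
optimal target phase `z = Aw/|Aw|` with the regularized least-squares
solve `w = (AᴴA/n + λI)⁻¹ Aᴴ(θz)/n` (Cholesky, with a relative 1e−12
factorization floor so duplicate kT-point columns at λ = 0 stay solvable).
Both half-steps minimize the shared surrogate, so the recorded cost trace
is non-increasing — a tested contract. Convergence: relative cost change
< 1e−6 or 200 iterations.

**kT-point placement.** Candidates live on a ±2 cycles/FOV grid with
1 cycle/FOV steps (125 candidates), scanned in order of (‖k‖, kz, ky, kx).
Each greedy stage scores every candidate by a truncated (10-iteration)
variable exchange *from one shared initialization* — scoring must rank
candidates, not the luck of per-candidate starts; for K = 1 the cost is
k-invariant, so the shared start also makes the k = 0 tie-break exact —
then re-solves the weights over all selected locations to full tolerance.
Stage initialization from the previous weights (new point at zero)
guarantees cost(K) ≤ cost(K−1). Ties keep the earlier (smaller-norm)
candidate, with an absolute 1e−12 floor.

**Design rows.** The design matrix uses a deterministic, evenly strided
subsample of ROI voxels (256 per map for tailored/default design, 512 per
library member for the universal design, whose dilated regions are larger).
Evaluation metrics always use the full ROI.

**Tailored pulse (TP).** Greedy selection plus final variable exchange on
one subject/session, then a global scale so the mean design-ROI FA equals
the target (the power penalty biases the raw solution slightly low; CV is
scale-invariant, so homogeneity is untouched).

**Universal pulse (UP).** Same machinery over the stacked library systems
(equal member weighting), with two universal-specific choices: the design
region is each library heart *dilated by 3 voxels (24 mm)* — the uniform
region must extend beyond the heart so displaced or changed anatomies stay
inside it, which is also what in-vivo universal pulses are observed to do —
and the absolute scale is calibrated once on a fixed 16-subject validation
cohort (seed 424242, at its latest-date sessions, i.e. under full expected
anatomy change), the analogue of validating a precomputed pulse's nominal
output on a held-out population. No per-subject adjustment exists anywhere
in the universal path.

**Default shim.** Phase-only MLS (equal channel magnitudes, alternating
phase projection) on one designated library member, scaled to the target
mean FA on that reference, then frozen for the entire study. The true
vendor phases are proprietary; this stand-in captures the operative
property — a static setting not adapted to the subject at hand.

**Gradient blips.** Each inter-point displacement Δk is realized per axis
as a triangular lobe of shared duration (the smallest 10 µs raster multiple
respecting a 40 mT/m amplitude and 170 T/m/s slew limit on every axis),
with per-axis peak `2·Δk/(γT)` so the k-space area is exact. Subpulses are
100 µs; timing is metadata and enters only the Bloch simulator.

## Flip-angle simulation

The STA prediction is the closed form `FA(r) = c0 |Σ_k Σ_c b1_c(r) w_{c,k}
e^{i k_k·r}|` on the full grid. The Bloch simulator applies each subpulse
as an exact axis-angle rotation (axis in the transverse plane at phase
`angle(b_k) + k_k·r`, angle `c0|b_k|`), composed per voxel with
quaternions — exact for piecewise-constant fields, no relaxation, no
off-resonance. The two agree to < 1 % relative FA at the 10° target (a
tested contract); at large angles the linear STA overestimates.

## Evaluation statistics

CV is the population (ddof = 0) standard deviation over mean of the FA
inside the ROI, in percent; at ROI sizes of several hundred voxels the
sample/population distinction is negligible. FA distributions are
summarized by order statistics (median with the midpoint rule, quartiles
with linear interpolation). RF metrics: peak |w|, mean |w|² and per-channel
mean |w|² — subpulse durations are equal, so duty weighting reduces to
plain means.

Cluster statistics operate on a subjects × scan-groups CV table: inertia
(reported on its natural squared-percent scale, with a root-inertia
convenience field), centroid norm, and the perpendicular distance from the
centroid to the identity line, which equals the norm of the centroid's
residual after orthogonal projection onto span{1} (tested against that
projection oracle). Paired comparisons use the Wilcoxon signed-rank test:
zero differences dropped, exact two-sided p by full 2ⁿ enumeration of sign
assignments for n ≤ 12 (tie-averaged ranks enumerate cleanly), normal
approximation with tie correction above, two-sided p = 2·min(P≤, P≥)
capped at 1. Bonferroni families are all method pairs within one study
grouping; the family size is recorded in the output rather than assumed.

## Study pipeline

One run designs a tailored pulse per (subject, session), one universal
pulse from the library, and one frozen default shim; evaluates every
configuration on every session of every subject (a tailored pulse's
configuration index equals the session it was designed on; a cell is *TSG*
when configuration and session match); regroups cells into the three
sub-studies; and computes cluster summaries and pairwise test matrices per
grouping. The cluster comparison family holds default, UP and the
per-configuration TP clusters; the configuration-matched TP table is
reported separately for the headline orderings. Everything — cohort,
library, designs, tables — is a deterministic function of the master seed,
and repeated runs produce byte-identical CSVs.

Problem sizes used throughout (6×4 cohort, 22-member library, 16-member
calibration cohort, 32×40×40 grid, 256/512 design rows) keep a full study
around half a minute on one core, which makes the multi-seed robustness
checks in the test suite practical.

## Known limitations

* The coil model is geometric, not electromagnetic; absolute CV levels and
  RF-power ratios depend on its parameters and should not be read as
  scanner predictions.
* Anatomy change is a smooth geometric drift; organ motion, breath-hold
  state and through-plane deformation are absent.
* With six subjects, mean-based cluster statistics (especially d⊥) carry
  substantial sampling noise; occasional seeds exist where the default
  shim's session means cancel by chance to a smaller d⊥ than the universal
  pulse's. The multi-seed acceptance check quantifies exactly this.
* The default-shim stand-in is itself an optimized phase-only shim on a
  reference anatomy; a true vendor shim could behave better or worse.
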