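# Methods

## Model

Tumor burden visible on daily in-room imaging is modelled as three
compartments per unit initial volume: cancer stem-like cells (CSCs, `u`),
non-stem tumor cells (TCs, `v`) and dead cells not yet cleared from the
imaged volume (`w`). The governing system is linear with
piecewise-constant coefficients (one set per calendar day):

```
du/dt = (δ·m_u − γ_u)·u                        = A·u
dv/dt = (1−δ)·m_u·u + (m_v − m_a − γ_v)·v      = B·u + C·v
dw/dt = γ_u·u + (m_a + γ_v)·v − γ_w·w
```

Assumptions baked into this form:

- CSCs divide at a constant rate `m_u = ln2/T_u`; a division is symmetric
  with probability `δ` (adding one CSC) and asymmetric otherwise (adding one
  TC). CSCs do not die except by radiation.
- TCs divide at `m_v = ln2/T_v` and undergo programmed death at
  `m_a = ln2/T_a`; during fitting the three growth times share one value (a
  doubling time with death exactly offsetting division for the TC pool, so
  that untreated tumor burden growth is driven by the CSC compartment).
- A 2 Gy fraction acts as a continuous kill rate over its day
  (`γ_u = −ln SF_u`, `γ_v = −ln SF_v` on treated days, zero otherwise), not
  as an instantaneous pulse; killed cells move to the dead compartment and
  leave the imaged volume at `γ_w = ln2/T_h`.
- Tumor volume is proportional to total cell number `G = u + v + w`, so all
  trajectories are normalized to the first fraction day and absolute scale
  never enters.

Out of scope by design: dose-response (LQ) modelling — dose enters only
through the fixed per-2 Gy surviving fractions; transitional progenitor
states; quiescence, hypoxia, immune and microenvironment effects;
stochastic birth-death formulations.

## Exact daily update

Being lower-triangular, the system integrates in closed form. With
`φ(x,t) = (e^{xt}−1)/x` the one-day propagator has entries

```
P_uu = e^{At}
P_vu = B·e^{Ct}·φ(A−C, t)          P_vv = e^{Ct}
P_wu = e^{−γ_w t}[γ_u·φ(A+γ_w, t) + D·B·(φ(A+γ_w,t) − φ(C+γ_w,t))/(A−C)]
P_wv = D·e^{−γ_w t}·φ(C+γ_w, t)    P_ww = e^{−γ_w t}
```

where `D = m_a + γ_v` is the TC death inflow. Resonant denominators
(`A−C`, `A+γ_w`, `C+γ_w`, and their pairwise differences) are handled by
switching `φ` and the second-difference term to truncated power series below
a threshold of 1e−9/day (1e−4 for the cancellation-prone second
difference), so degenerate parameter sets (e.g. `δ=0` on untreated days,
or `T_v = T_a`) evaluate exactly rather than blowing up. The propagator is
validated against `scipy.linalg.expm` over random parameter sets at 1e−10
relative tolerance, and against a forward-Euler integration of the
differential system at its first-order accuracy.

A convention note: one published algebraic form of the coefficient `C`
(`m_v + m_a + ln SF_v`) and of the dead-cell inflow (`m_v + γ_v`) is
inconsistent with the differential system above; this package implements
the ODE-consistent `C = m_v − m_a − γ_v` and `D = m_a + γ_v` (identical
when `T_a = T_v`, the fitting configuration). The alternative algebra is
available behind `convention="printed"` for comparison but is not used
anywhere by default.

## Treatment calendars

A course is the contiguous block of calendar days from first to last
fraction. Fractions (2 Gy each) fall on consecutive weekdays; weekends are
rest days; an optional interruption pauses treatment for a configurable
number of calendar days after a configurable fraction count. The standard
33-fraction course from a Monday spans 45 days; midweek starts span up to
47. The benchmark's interrupted patient uses a Wednesday start with an
8-day pause after fraction 5, which stretches the course to a 55-day span.
Imaging is flagged on every fraction day (daily CBCT); the file reader also
accepts measurements on untreated days.

The model state at day index `i` is the burden at the start of day `i` —
i.e. at imaging time, before that day's fraction — so the measured and
modelled series align without any half-day offset.

## Parameter estimation

The objective is `R = sqrt(mean_i |M_i/M_0 − G_i/G_0|)` over measurement
days after the first (whose term is identically zero; `n` counts the
included days, so a single post-baseline deviation of 0.04 gives R = 0.2).
`R` is non-smooth at its minimum, so the search is derivative-free:
bounded Nelder-Mead from a coarse 36-point multi-start grid over
`(δ, p, SF_u, T_h)`, followed by a tighter polish from the best start. A
conventional RMS variant (squared deviations) exists behind
`FitConfig(rms_objective=True)` and is non-default.

Free-parameter bounds: `δ ∈ [0.001, 0.2]` and `SF_u ∈ [0.001, 1]` (the
documented scan ranges), `p ∈ [0.001, 0.995]`, `T_h ∈ [0.1, 20]` days
(generously bracketing reported fits of 0.5–8.1 d). `SF_v` is never free:
each candidate must satisfy `SF_v = (SF_T − p·SF_u)/(1−p) ∈ (0, 1]`, and
infeasible candidates receive a graded penalty that steers the simplex back
into the feasible region. Histology constants: squamous `SF_T = 0.90`,
`T_pot = 6.2 d`, `T_div = 2.5 d`, `T_vol = 115.2 d`; adenocarcinoma
`SF_T = 0.62`, `T_pot = 7.1 d`, `T_div = 0.92 d` (22 h), `T_vol = 221.6 d`.

Percent fit errors are `100·|M_i/M_0 − G_i/G_0|` per post-baseline imaging
day, reported as mean ± sample SD (n−1 convention).

Stability scans evaluate `R` along one parameter with all others frozen at
the fitted values; scanning `p` or `SF_u` deliberately does *not* re-tie
`SF_v`, so each scan is a pure one-dimensional slice. On noiseless
synthetic data the `p` and `SF_u` slices show a single sharp grid minimum
at the generating value, and the `δ` slice rises steeply and monotonically
away from it. The doubling-time comparison refits with `T_pot`, `T_div`
and `T_vol` in turn; with `T_div`-scale growth the modelled burden snaps
upward over every untreated weekend (a zigzag no parameter choice can
flatten), and the generating time always achieves the smallest residue on
matched synthetic data.

## Numerical validator

The Euler integrator discretises the differential system directly with
`m` substeps per day (default 1000; 10 000 in equivalence tests, giving
per-compartment agreement with the closed form below 1e−3 relative on full
33-fraction courses). It exists purely as an independent check and is
excluded from the fitting path by module boundary — only the closed-form
propagator produces fitted parameters.

## Synthetic data

The generator stands in for patient imaging series that cannot be shipped.
It emulates: 33 weekday fractions with daily imaging (one volume per
fraction day), baseline volumes at the reported cohort values
(77.6–177.1 cm³), trajectories from the exact forward model, and
multiplicative lognormal measurement noise
(`volume = baseline · G_i/G_0 · e^ε`, `ε ~ N(0, sd²)`), defaulting to
sd = 0.03 — contouring-level uncertainty of a few percent. Lognormal noise
is chosen because volumes are positive and contouring error scales with
size; its mean bias `e^{sd²/2}` (< 0.05 % at the default) is documented and
asserted in tests. The five-patient benchmark uses the published estimates
as ground truth with `SF_v` re-derived from the histology `SF_T` so every
truth is exactly feasible.

What the generator does *not* emulate: day-to-day contouring
autocorrelation, observer changes, image-quality drift, anatomical
deformation, or any model misspecification — synthetic recovery results
therefore demonstrate estimator correctness and identifiability under the
model's own assumptions, not robustness of the model on real images.

## Cell-count assay

Growth curves `N(t) = N0·e^{kt}` are fitted to per-day mean counts; the
default objective is least squares on `log N` (equal relative weight per
day, the convention consistent with day-0 extrapolation practice on these
data), with a count-scale nonlinear variant behind `objective="counts"` —
both recover exact-exponential data to machine precision, and the seed
count (1.6 million plated at day 0) is included by default. SF₂ is the
ratio of extrapolated day-0 counts (irradiated/control), removing the
repopulation confound that drives the raw count ratios downward (0.78 →
0.56 → 0.44 across the packaged table); division time is `ln2/k` of the
control arm. Reported values round to 2 decimals (fractions) and 1 decimal
(hours).

## Problem sizes and determinism

Default test and validation sizes: 33-fraction courses (45–55 day spans),
10⁴ Euler substeps/day for equivalence checks, 81-point stability grids,
20 seeded replicates for the noisy recovery study, 36-start fits (16 starts
inside the replicate loop). Every stochastic step — synthetic noise,
benchmark seeds — flows from explicit integer seeds; fits are deterministic
given data and configuration. All computation is single-threaded
double-precision numpy/scipy.

## Known limitations

- With noisy data `δ` and `T_h` are the weakest-identified parameters
  (flat objective directions); `p` and the surviving fractions are robust.
- The mixing-relation tie makes estimates conditional on the assumed
  histology `SF_T`; an error there propagates into `SF_v` directly.
- The model cannot describe regrowth driven by anything other than CSC
  kinetics (no quiescence reactivation, no immune effects).
- Calendar handling assumes weekday fractions; holiday patterns other than
  explicit interruptions are not modelled.
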