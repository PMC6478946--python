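# Methods

This note documents the model behind `dsbrepair`, its assumptions, the
default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that affect
results.

## State machine and waiting-time law

Each DSB end is a triple (phase, occupancy, lock).  Phases are: inhibited
(a brief end-cleaning stage immediately after break creation, before
proteins can load), free, unstable synaptic complex, stable synaptic
complex, repaired-NHEJ, repaired-HR.  Occupancy is a flag set over Ku70/80,
DNA-PKcs, MRN, RNF138 and CtIP-resected; the lock is none/NHEJ/HR.  The two
repaired phases are absorbing.  Invariants maintained by construction:
DNA-PKcs loads Ku-dependently; a resected end is HR-locked; ends in a
synaptic complex reference their partner.

Transitions are declarative `TransitionRule` objects (guard → mutation)
with a mean waiting time τ.  The waiting-time *distribution* is exponential
with mean τ — the standard memoryless choice for kinetic Monte Carlo; the
sampler is pluggable (`SimulationConfig.waiting_time_sampler`) so heavier-
tailed laws can be substituted without touching the engine.  Among eligible
rules the earliest clock fires, giving selection probabilities
(1/τᵢ)/Σ(1/τⱼ).  Because clocks are redrawn after every state change, the
process is Markovian; redrawing is statistically equivalent to clock
persistence for exponential laws.

Lock-in points: HR locks at CtIP resection in every scenario (canonical
NHEJ cannot process a resected end).  NHEJ locks at synaptic-complex
stabilisation — the last NHEJ step that can still be undone by
dissociation — except in Scenario B, where the initial Ku attachment
already locks.  Scenario A additionally locks the HR route at synapsis
dissociation (failure enforces resection-mediated repair, with no second
NHEJ attempt).

## Whole-break HR semantics

NHEJ repairs a *pair* of ends (ligation of a synaptic complex).  The
post-resection HR branch is deliberately lumped into one time constant
τ_RR (Rad51 filament formation, homology search, repair synthesis,
resolution are not modelled individually).  When that lumped step
completes, the model treats the *break* as resolved: the cognate partner
end is marked repaired at the same event time, and if that partner sat in a
synaptic complex with a third end, the complex dissolves and the third end
falls back according to the scenario's dissociation semantics.  The
alternative — requiring both ends to resect independently — would square
the (small) per-end resection probability and make HR contributions
negligible in every deficient system, which contradicts the observed slow
repair component in NHEJ-deficient cells.

## Scenario D mechanism placement

The three entwined-pathway mechanisms are toggles on the Scenario C rule
set (all three off reproduces C rule-for-rule):

* `mrn_colocalisation` — MRN attaches to ends in free *and* synaptic
  phases (co-localisation with Ku, DNA-PK and the synaptic complex) and
  persists once loaded; MRN unloading kinetics are not modelled.  The
  toggle also enables Ku/DNA-PKcs release from co-localised free ends,
  which fall back to an MRN-attached end.
* `rnf138_removal` — RNF138 attaches MRN-dependently wherever MRN sits.
  Once attached it prohibits Ku (re-)attachment, and on free ends it strips
  Ku and DNA-PKcs, leaving an MRN/RNF138-marked end whose only forward
  route is CtIP resection.  RNF138 remains on the end after stripping;
  restricting its recruitment to free phases would render the mechanism
  kinetically dead, since free-phase windows last only seconds between NHEJ
  attempts.
* `mrn_independent_resection` — naked free ends may resect without MRN
  (with the toggle off and co-localisation on, resection requires MRN).

Stripping inside an assembled synaptic complex is not modelled; an RNF138-
marked end commits to resection only after the complex dissociates.

## Default time constants

The recruitment hierarchy is constrained by two reported ratios —
τ_RNF138 ≈ 80 × τ_Ku and τ_RNF138 ≈ 3 × τ_MRN — and by the ordering
Ku/DNA-PKcs fast, MRN slower, RNF138 slowest.  Within those constraints the
shipped defaults are package choices on the scales seen in live-cell
recruitment and γ-H2AX kinetics, meant to be refined by calibration:

| rule | τ (s) | rationale |
| --- | --- | --- |
| end_cleaning | 10 | brief; placed before first protein loading |
| ku_attach, pkcs_attach | 15 | recruitment within seconds–minutes |
| mrn_attach | 400 | slower than Ku; fixes the 3× RNF138 ratio |
| rnf138_attach | 1200 | 80 × τ_Ku = 3 × τ_MRN |
| rnf138_strip | 120 | fast once RNF138 is engaged |
| ku_release, pkcs_release | 2400 | slow spontaneous release from co-localised ends |
| synapsis_stabilise | 1800 | hour-scale fast repair component |
| synapsis_dissociate | 3600 | ⇒ P(stabilise) = 2/3 per attempt |
| synapsis_ligate | 3600 | NHEJ completion ≈ 1.5 h mean |
| ctip_resect | 2000 | Ku outraces CtIP ~130:1 on naked ends |
| hr_repair (τ_RR) | 14400 | slow component half-life of several hours; the free, scanned parameter |

`enforce_ratio_constraints` warns when a calibrated table leaves a ±2×
band around the two printed ratios.

Deficiencies delete exactly one rule each: XLF → `synapsis_stabilise`,
Lig4 → `synapsis_ligate`.  Partial depletion is out of scope.

## Spatial model

Positions are Cartesian micrometres, nucleus centred at the origin
(default: 5 µm sphere; ellipsoids supported).  Free, unsynapsed ends
diffuse with Gaussian steps of per-axis variance 2·D·Δt, reflected at the
envelope (radial mirror in semi-axis-scaled coordinates).  Defaults
D = 1 × 10⁻⁵ µm²/s and capture radius 0.25 µm sit at the chromatin-locus
mobility scale (≈1.3 µm RMS displacement over 8 h) and are free parameters
of this implementation — the hypotheses under study specify no diffusion
law.  They must satisfy √(2·D·Δt) ≲ capture radius, else cognate ends
out-diffuse capture within one sub-step and strand as isolated ends; the
shipped values respect this by an order of magnitude.

Pairing is evaluated on a fixed sub-step (default = the 30 s recording
interval, configurable via `pairing_dt`): eligible ends (free,
Ku+DNA-PKcs-loaded, unsynapsed) within the capture radius are matched
greedily by distance, ties broken by lower end id
(`pairing_mode="any_eligible"`), which permits mispaired geometry and
isolated ends; `original_partner_only` restricts to cognate pairs for
analytic tests.  The hybrid coupling error is bounded by one sub-step of
pairing latency.  On formation both ends snap to their midpoint; on
dissociation both ends are released at the same event time.  Ends with no
eligible rule are flagged stalled and persist as unrepaired — this, not an
explicit timeout, is the default fate of isolated DNA-PK-loaded ends (an
optional deterministic `synapsis_search_timeout` can release them instead;
it is off by default because synapsis dissociation is the only named
failure route).

## Recording and observables

State counts are recorded on a fixed grid — default 8 h horizon every 30 s,
961 points including t = 0 — via O(1) counters, so grid resolution does not
affect runtime.  Conservation (Σ phase counts = 2 × DSBs) and monotone
repaired counts are invariants checked in the test suite.

Recruitment curves count ends bearing a protein under the state machine's
persistence rules (Ku/DNA-PKcs persist until stabilisation or RNF138
stripping; occupancy clears on repair) and are self-normalised to the mean
curve's maximum; Mre11 is an alias for the MRN occupancy.  The residual
damage curve counts DSBs whose ends are not both repaired — the γ-H2AX
proxy; focus-resolution optics are not modelled.  For goodness of fit both
curves are renormalised to their earliest matched point (the
"self-normalised" convention; max-normalisation is selectable), each
experimental time is matched to the nearest 30 s grid point (interpolation
is immaterial at hour-scale spacing but fixed for determinism), and reduced
chi-square divides by n points with no parameter correction since all
parameters are frozen before evaluation.  DTW is the classic unconstrained
form: absolute-difference cost, steps {(1,0),(0,1),(1,1)}, no window, no
normalisation.

## Calibration

`fit_time_constant` minimises SEM-weighted χ² (RMSE selectable) over a
bounded interval with scipy's bounded Brent method; the 95 % CI is profiled
(Δχ² = 3.84) on a log-spaced global grid plus a fine local grid around the
optimum.  An optimum at a bound raises a warning.  Stochastic objectives
should use common random numbers; `scan_tau_RR` fixes one master seed for
every grid point so the goodness-of-fit profile is smooth in τ_RR.  The
two-stage protocol (fit recruitment, freeze, scan τ_RR, freeze everything
for scenario comparison) is explicit in the API: scans take a frozen
`ScenarioConfig` and vary only `hr_repair`.

## Synthetic data: what it does and does not emulate

`generate_damage` draws DSB counts from Poisson(dose × yield) with
positions i.i.d. uniform in the nucleus.  The default yield, 35 DSB/Gy, is
a literature-typical mammalian value (the order is tens per Gy); dose and
yield are exposed in every interface.  Uniform positions emulate the
low-LET limit only: real particle tracks correlate damage along their
paths, and chromatin density (euchromatin/heterochromatin) biases both
damage and pathway choice — neither is modelled, and the generator is the
designated extension point.  Consequently, passing tests demonstrate
correct repair-choice *kinetics* for spatially homogeneous damage, not
LET-dependent clustering effects.

`generate_benchmark_curve` produces experimental-style (time, value, SEM)
curves from closed forms — saturating exponential recruitment and
bi-phasic exponential decay — with Gaussian noise of sd noise_sd/√n_rep.
These are synthetic stand-ins for digitised literature curves; none of the
published experimental data ship with the package, so absolute
goodness-of-fit numbers computed against them characterise the synthetic
shapes, while scenario *orderings* (competition-only worst, entwined best
or tied with NHEJ-first) are the meaningful output.

## Reproducibility and problem sizes

All randomness flows through numpy Generators seeded from a single master
seed; ensemble repeats use `SeedSequence.spawn`, giving independent,
bit-reproducible streams, and a run manifest snapshots config + seed +
package version.  Event ordering is made deterministic by a monotone
sequence number breaking heap ties.

The test suite and `scripts/acceptance.py` run scaled-down problem sizes
chosen as the smallest that leave the checked statistics' Monte Carlo error
well inside their tolerances: 10-repeat repair ensembles and 20-repeat
recruitment ensembles at 2 Gy × 35 DSB/Gy (the full-size analogues are 50
and 250 repeats), 10³–10⁴ ends for analytic-oracle checks, and 500–1000
single-DSB cells for the branching plateau.  Statistical assertions use
3–4 × the Monte Carlo SEM plus a discreteness floor of one count.

## Known limitations

* Alt-NHEJ and single-strand annealing are absent; any resection-dependent
  repair is classified as HR.
* Post-resection HR is a single lumped exponential; stalling mechanisms
  that shape late XLF-deficient kinetics are not represented.
* Misrepair fidelity is not scored: ligation of non-cognate ends counts as
  repair, and whole-break HR can silently dissolve a mispaired complex.
* Breaks are structureless points — no complexity classes, no SSB/base
  damage, no resection-length tracking.
* The inhibited (end-cleaning) stage has no literature-constrained τ; it
  defaults to 10 s and is toggleable.
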