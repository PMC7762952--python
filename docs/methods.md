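# Methods

## Kinetic models and trace simulation

Three mass-action mechanisms are implemented, with A the labelled
(Trp-carrying) domain:

* two-state: A + B ⇌ AB (k_on, k_off), K_d = k_off/k_on;
* induced fit: A + B ⇌ AB ⇌ AB\* (k₁, k₋₁, k₂, k₋₂), a conformational
  change after the initial encounter;
* displacement: A + B ⇌ AB and A + C ⇌ AC, where C is an unlabelled
  competitor; the competitor's rates occupy the k₁/k₋₁ slots.

Units are fixed throughout: µM for concentrations, s for time,
µM⁻¹s⁻¹ for second-order and s⁻¹ for first-order rate constants, and
kcal/mol for free energies at R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 277.15 K (4 °C) by default.

Trajectories come from `scipy.solve_ivp` with the stiff-aware LSODA
integrator at rtol 1e-8, atol 1e-10 µM (rate constants span ~2.7 to
>200 s⁻¹ and sub-ms pseudo-first-order transients); Radau is tried as
a fallback when LSODA reports failure, and values within integrator
tolerance below zero are clipped to zero. Observed fluorescence is
linear in concentrations: signal = scale·(baseline + Σ c_s·[s]), with
per-trace scaling factors expected near 1 (a warning fires outside
[0.8, 1.2]).

Instrument timeline: the recorded time zero of the stopped-flow
instrument trails the true mixing time by 1.25 ms. Preprocessing first
shifts recorded times onto the true reaction timeline (t → t + 1.25 ms)
and then removes points earlier than 2 ms, where mixing artifacts
dominate. The order matters: the cutoff is applied on the corrected
timeline.

The pseudo-first-order relaxation rates are analytic: k_obs =
k_on·[B] + k_off for two-state; for induced fit, the two eigenvalues of
the linearized 2×2 relaxation matrix, i.e. the roots of
λ² − (k₁B + k₋₁ + k₂ + k₋₂)λ + k₁B(k₂ + k₋₂) + k₋₁k₋₂ = 0. These are
used for diagnostics only; all fitting integrates the full nonlinear
ODEs, because the experimental ligand excess (1–10 µM over 1–2 µM) is
not deep. Ligand depletion biases the single-exponential fit of an
integrated two-state trace below k_on·B + k_off by roughly the bound
fraction over the excess ratio: measured ≈2.8% at 10-fold excess,
<1% from 50-fold on. This is a property of the pseudo-first-order
approximation, not of the integrator.

Exponential fitting (1 or 2 phases) uses `lmfit` least squares with
the time origin at the first observed point. Two-phase fits are
multi-started over several fast/slow rate splits, because widely
separated phases otherwise trap the optimizer. A phase is flagged
unidentifiable when its realized signal change over the observed
window is within 3× the point-to-point noise — the realized change,
not the raw amplitude, because a near-zero rate makes any amplitude
degenerate with the baseline.

Displacement experiments estimate k_off as the single-exponential
k_obs of the trace with (the smallest) ≥20-fold excess of competitor
over labelled complex, following the experimental protocol for
complexes with k_off below ~30 s⁻¹.

## Global fitting and identifiability

A trace set is fitted simultaneously: rate constants shared across
traces, a shared baseline and fluorescence coefficient per fluorescent
species, and (optionally) per-trace scaling factors with the first
trace pinned to 1. Rates are optimized as log₁₀ values — positivity for
free, roughly scale-free steps across decades — inside `scipy`
bounded trust-region least squares, with default bounds 1e-6..1e6 in
native units to keep the integrator out of pathological regimes and a
large flat residual penalty if integration still fails at a trial
point. Five seeded multi-start restarts (rates perturbed up to
~3-fold) guard against local minima.

Standard errors come from the Gauss–Newton curvature at the optimum,
scaled by χ²/(n−p) and transformed back from log coordinates. When the
normal-equation matrix is near singular (condition > 1e10) or two rate
estimates are >0.999 correlated, errors are reported unavailable and
the result flagged — the classic failure being a single
pseudo-first-order trace, which determines only k_on·B + k_off.
Because thousand-point traces make curvature errors unrealistically
small, an optional post-hoc policy replaces the k_on error with the
empirical 10% batch-to-batch figure established by replicate
measurements of the reference complex.

Residuals are unweighted (uniform σ per point): no per-point
uncertainty model is available for the source data.

Confidence contours scan a parameter pair on a log-spaced grid,
re-optimizing all remaining parameters at every node (profile χ²), and
report the ratio χ²_min/χ² ∈ (0, 1] — 1 at the global minimum, with
0.8 as the conventional acceptability boundary. The source analysis
describes the same plot as "χ²/χ²_min with a cutoff of 0.8", which is
only coherent for the inverted ratio; this package standardizes on
χ²_min/χ² and documents the discrepancy here. A parameter is "poorly
determined" when acceptable nodes persist across essentially the whole
scanned range of that axis, which is how the induced-fit k₂ behaves
when k₂ ≪ k₋₂ (the bound-state isomer barely populated).

Mechanism comparison fits both candidate schemes on identical
preprocessed traces, reports χ², and separately diagnoses the phase
structure: a double-exponential slow phase whose rate is constant
across the concentration series (CV < 20%) is the induced-fit
signature; an extra-parameter scheme that improves χ² by <1% over a
simpler one is flagged overparameterized.

## ϕ-value thermodynamics

Sign convention: ΔΔG_TS = RT·ln(k_on^wt/k_on^mut) and ΔΔG_EQ =
RT·ln(K_d^mut/K_d^wt), so destabilizing mutations are positive on both
Brønsted axes and ϕ = ΔΔG_TS/ΔΔG_EQ is unchanged from the ratio of the
published equations. K_d is always recomputed from the unrounded
k_off/k_on of a record, never read from a rounded K_d column — this is
what reproduces the published ϕ-values to ±0.01–0.02.

Error propagation: the default model propagates ΔΔG_TS and ΔΔG_EQ as
if independent, se(ϕ) = |ϕ|·√[(se_TS/ΔΔG_TS)² + (se_EQ/ΔΔG_EQ)²].
This is the convention behind the published ϕ errors and reproduces
them essentially exactly (e.g. 0.136 vs 0.13, 0.061 vs 0.06, 0.181 vs
0.18). A full delta-method variant that accounts for the shared-k_on
correlation is available (`error_model="correlated"`); it is the more
rigorous estimator but gives markedly smaller errors near ϕ = 1, where
the k_on contributions to numerator and denominator cancel, and
therefore does not match the published error bars.

A ϕ-value is flagged unreliable when |ΔΔG_EQ| < 0.14 kcal/mol
(≈0.25·RT, user-configurable): below that the ratio amplifies rate
uncertainty beyond use. The threshold sits between the published
practice of leaving ϕ blank at |ΔΔG_EQ| ≈ 0.10 and reporting it at
0.42. Categories: ϕ < 0 negative, [0, 0.3) low, [0.3, 0.9]
intermediate, > 0.9 high.

Brønsted fits are ordinary least squares of ΔΔG_TS on ΔΔG_EQ with free
intercept (the published procedure does not state weighting; weighted
and through-origin variants are exposed and change the rounded slope
of the helix-1 set by nothing). Fits over an x-span narrower than
0.1 kcal/mol are flagged degenerate. The double-mutant-cycle coupling
energy is RT·ln[(K_d^wt·K_d^double)/(K_d^A·K_d^B)], symmetric in the
two single mutants and zero for additive mutations.

Known recomputation discrepancies in the transcribed tables: S1054G
recomputes to 0.20 vs printed 0.24, M1062G is inconsistent (ΔΔG_EQ ≈ 0
yet a printed ϕ of 0.31), and the human R1069G recomputes to −0.02 vs
printed 0.02 — presumably computed from unrounded source-dataset
values. These records are excluded from exact assertions.

## Ensemble analytics

A native contact between two residues that are not nearest neighbours
(|i−j| ≤ 1 within a chain; inter-chain pairs are never excluded) is a
pair of heavy side-chain atoms within 0.6 nm in at least 50% of the
frames of the native-state reference ensemble. The registry stores the
qualifying atom pairs per residue pair; glycine, with no side-chain
heavy atoms, contributes none. The ϕ-value of a residue in a
conformation is the fraction of its registered pairs currently within
the cutoff (hard counting for all reporting; a rational switching
function centred on the cutoff is available where differentiability
matters). Contact-probability maps use the same atom scope and cutoff:
a residue pair is in contact in a model when any qualifying atom pair
is, and probabilities are weighted model fractions, making them
invariant under model duplication.

Helicity is assigned by a backbone-dihedral surrogate rather than
hydrogen-bond patterns: a residue is helical in a model when its
(φ, ψ) fall in φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°] and it belongs to a
run of ≥4 consecutive in-window residues of one chain. The surrogate
needs no hydrogens and matches hydrogen-bond assignment on regular
helices; it is more permissive at fraying ends, and is labelled a
surrogate wherever reported. Rg is mass-weighted over heavy atoms;
pairwise RMSD uses Kabsch superposition on a configurable selection
(all heavy atoms by default), making it exactly invariant under
rigid-body motion.

Coordinates are nm in memory; PDB I/O (via biotite) converts Å at the
boundary and preserves author residue numbering (NCBD 2058–2116, CID
1018–1088 frames for the real complexes).

## The Gō-model transition-state sampler

The ϕ-restrained simulated-annealing procedure is realized at desk
scale with a structure-based model: one bead per residue at the heavy
side-chain centroid (Cα fallback), harmonic virtual bonds and angles
at native values along each chain, a Gaussian attractive well of depth
ε = 1 (reduced units, k_B = 1) and width σ = 0.05 nm at the native
distance for every contacting residue pair, and a soft r⁻¹²
excluded-volume term (ε_rep = 0.1, σ_rep = 0.35 nm) for the remaining
pairs. With these terms the native conformation is the unrestrained
energy minimum. The per-pair ϕ cutoff equals the reporting cutoff
(0.6 nm) whenever the native bead distance lies within it, so
bead-level ϕ agrees exactly with the ensemble-module definition on the
bead-native systems used in the tests.

Restraint pseudo-energy: E = w·Σ_r (ϕ_r(conformation) − ϕ_r^target)²,
with targets restricted to the open interval (0, 1) — a residue whose
contacts are entirely formed or entirely absent carries no usable
restraint. Two deviations from the reference restrained-MD protocol
are deliberate: the ϕ in the restraint is the instantaneous
(single-trajectory) value rather than a multi-replica ensemble
average, and it is hard-counted with the same cutoff used for
reporting, so the restrained quantity and the measured one coincide.
A consequence of instantaneous hard counting is that ϕ takes discrete
values set by the contact count; the test dimer is built so its
residues have even contact counts and a target of 0.5 is exactly
realizable.

Sampling is Metropolis Monte Carlo with three moves: single-bead
Gaussian displacement (0.04 nm), crankshaft rotation of an interior
bead about its neighbour axis (±0.5 rad), and rigid-body
rotation+translation of a whole chain. Amplitudes are auto-tuned
toward 30–50% acceptance during the first tenth of the run, clamped
within 4× of their configured values. The annealing schedule mirrors
the reference protocol's shape: each cycle cools from 378 K to 278 K
and holds the final 40% of its steps at the 278 K reference
temperature; collection keeps reference-temperature states from the
last 75% of cycles. Setting T_high = T_low gives a constant-temperature
(native-state) run. Laboratory temperatures map linearly onto reduced
temperatures, 278 K → 0.12 and 378 K → 1.2 in units of ε, placing the
model's folding midpoint between the endpoints: contacts are stable at
the reference temperature and melt near the top of each cycle. Seeded
runs are bit-reproducible.

A finding worth knowing when designing restraint sets: on a regular
ladder-like dimer, uniform ϕ = 0.5 restraints admit a *compact*
solution in which one chain shifts register by one rung — every
residue keeps exactly half its native contacts without any chain
separation. Partial unfolding (a right-shifted Rg distribution)
appears robustly when restraints are placed on a subset of residues,
e.g. one chain end, forcing local fraying instead.

## Synthetic data

Generators are pure functions of a specification plus seed. Trace
generation integrates the chosen scheme on the true timeline, stamps
recorded times (shifted by the dead-time convention), and adds i.i.d.
Gaussian noise; defaults mirror the experimental regime — labelled
species at 1 µM, ligand 1–10 µM, 1000 points per trace. The source
data give no noise magnitude, so σ is an explicit parameter with no
claimed realistic default; real photomultiplier noise (shot noise,
drift, bleaching) is not modelled, so passing recovery tests bound
algorithmic error, not instrument robustness. Mutant tables are built
by inverting the ϕ definition (k_on^mut = k_on^wt·e^(−ϕΔΔG_EQ/RT),
K_d^mut = K_d^wt·e^(ΔΔG_EQ/RT)), so the designed ϕ is recovered
exactly; a `too_unstable` row exercises exclusion logic. Toy
structural ensembles build ideal-geometry backbones (NeRF construction
with standard bond lengths/angles; helical φ/ψ −57°/−47°, extended
−139°/135°) with one CB pseudo-atom per residue, dock two chains at a
target closest approach of 0.45 nm, and break designated contacts in
an exact count of models so contact probabilities are known by
construction (a pair broken in 3 of 10 models has probability 0.70,
exactly). Only pairs whose B-side atom is unique among native pairs
are breakable, so one displacement cannot disturb another designated
contact.

## Problem sizes in the test suite

The suite favours sizes that keep each stage honest but quick: trace
fitting uses 4–6 traces of 150–500 points; contour grids are 5×5 with
bounded per-node optimization; sampler checks use a 12-residue dimer
with 40–200 annealing cycles of 100–150 steps (restraint satisfaction
was verified unchanged when doubling the cycle count). Oracle
comparisons (brute-force double loops over residues, atom pairs and
models) run on ensembles of ≤10 residues × ≤20 models where exact
equality is asserted.

## Limitations

* The kinetic layer models only mass-action chemistry plus Gaussian
  noise and dead time — no photophysics, no temperature dependence.
* The Gō sampler is a mechanism-level analog, not a replacement for
  all-atom restrained MD: no solvent, sequence specificity, or
  absolute energy scale; its ensembles support method-level claims
  (restraint satisfaction, collection bookkeeping, qualitative
  compaction trends), not structural predictions for real complexes.
* The dihedral helicity criterion diverges from hydrogen-bond-based
  assignment at helix termini and in distorted helices.
* Brønsted and ϕ reliability conventions (thresholds, categories) are
  configurable defaults, not physical constants.
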