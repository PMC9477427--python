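# Methods

## The model

`h3k27sim` simulates the kinetics of lysine-27 modifications of histone H3
in a 20-kbp region around a transcription start site (TSS), the regime
relevant to Polycomb-target genes in mouse embryonic stem cells.  The
region's 100 nucleosomes are modeled as 200 independent H3 tails (two per
nucleosome, ~100 bp each).  Each tail is in one of five states — unmodified
(u), acetylated (ac), or mono-/di-/tri-methylated (me1/me2/me3) — with the
ladder u ↔ me1 ↔ me2 ↔ me3 moving one methyl group at a time and
acetylation reachable only from u.

Transitions are driven by the local occupancy densities of three enzymes,
supplied as per-site tracks ψ_SUZ12 (PRC2), ψ_p300 and ψ_UTX:

* methylation me_{x−1} → me_x at site i:
  `k_mex ψ_SUZ12(i) + ε_mex Σ_{j≠i} P(i,j) ψ_SUZ12(j) 1[j = me3]`.
  The first term is on-site nucleation by bound PRC2.  The second is
  long-range spreading: PRC2 bound at a trimethylated site j is
  allosterically activated (via its EED reader subunit) and can methylate
  any site i it contacts in 3D, with contact probability
  `P(i,j) = |i−j|^(−λ)`, λ = 1 (the average polymer scaling seen in Hi-C).
  The spreading-to-nucleation ratio `R = ε_mex / k_mex` is the same for all
  three steps, since both activities belong to the same enzyme;
* demethylation me_x → me_{x−1}: `γ_me ψ_UTX(i)`, independent of x;
* acetylation u → ac: `k_ac ψ_p300(i)`; deacetylation ac → u: `γ_ac`
  (uniform HDAC activity);
* histone turnover X → u at `γ_turn` for any modified X.

DNA replication is a scheduled event every `T` hours: each site
independently keeps its state or is reset to u with probability ½
(symmetric redistribution of mother histones between sister chromatids).

Default parameters (the wild-type mESC fit): `k_me3 = 0.81 h⁻¹`,
`k_me1 = k_me2 = 3 k_me3` (ratios r13 = r23 = 3), `R = 0.85`,
`γ_me = 1.5 h⁻¹`, `k_ac = 1.03 h⁻¹`, `γ_ac = 0.6 h⁻¹`, `γ_turn = 0.03 h⁻¹`,
`T = 13.5 h`, `λ = 1`.  The geometry module relates R to the allosteric
fold-change F through `R = F·(6/π)(a/d0)³` with capture distance a = 10 nm
and distance prefactor d0 = 22 nm; evaluating this literally gives
`F ≈ 5.6 R` (≈ 4.7 at R = 0.85).

The model deliberately omits transcription feedback, PRC1/H2AK119ub, and
H3K4/H3K36 crosstalk; enzyme occupancies are inputs, not dynamical
variables.

## Simulation engine

Trajectories are exact continuous-time samples (Gillespie algorithm) with
the clock truncated at scheduled events (replications, protocol changes),
after which propensities are re-drawn.  The spreading field
`S(i) = Σ_j P(i,j) ψ_SUZ12(j) 1[j=me3]` is cached and updated only when a
site enters or leaves me3; per-site total rates are maintained
incrementally with a periodic full refresh (every 4096 events) to cancel
floating-point drift.  Statistical exactness is verified against a
brute-force 25-state master-equation solution on a two-site system and
against the closed-form single-site periodic solution when spreading is
off.

Runs start from a fully unmodified lattice and discard a burn-in of
`burn_in_cycles` cell cycles (default 25) before recording.  Unsynchronized
populations draw a uniform replication phase per trajectory; synchronized
populations share phase 0.  Reproducibility: one master seed yields
per-trajectory sub-seeds via `numpy.random.SeedSequence.generate_state`,
and per-segment kernel seeds from the trajectory's own generator, so
ensembles are bit-reproducible regardless of execution order.

Recording happens on a regular grid (default 0.5 h) plus immediately
before and after every replication and protocol event; a grid sample that
coincides with a replication instant holds the pre-replication state.
Ensemble summaries use the grid samples, which are time-aligned across
trajectories.

### Single-site periodic oracle

With R = 0 the spreading term vanishes and the sites decouple exactly.
Each site then follows a 5-state master equation `dp/dt = Q p` punctuated
by the replication map `p ↦ p/2 + e_u/2` every T.  The unique periodic
fixed point solves `(I − E_T/2) p0 = e_u/2` with `E_T = exp(QT)`; phase
profiles and phase averages follow by propagation.  This oracle is both a
test reference for the stochastic engine and the production path for the
no-spreading inference step (below) — it is the same model solved exactly,
not an approximation.

The closed-form acetylation probability used in fitting treats replication
as an effective first-order dilution `ln 2 / T`:
`P_ac = k_ac ψ / (k_ac ψ + γ_ac + γ_turn + ln2/T)`.  Against the exact
periodic solution this approximation is accurate to better than 0.02
absolute over the full occupancy range at default rates (asserted in
tests); the simulator itself always uses true periodic halving.

## Enzyme profiles and presets

Profiles are Gaussian-plus-background peaks
`ψ(x) = ψ_m exp(−(x−i0)²/2σ0²) + ψ_b` on the TSS-distance axis (kbp).  The
p300 peak carries the published wild-type fit (ψ_b = 0.1196, peak height
0.1666 at the wild-type PcG activator scale, i0 = −0.5438 kbp,
σ0 = 5.1875 kbp).  Recruitment scales (α, β) multiply peak heights only —
α the PRC2/SUZ12 peak relative to its PcG-target amplitude, β jointly the
p300 and UTX peaks relative to their active-gene amplitudes; backgrounds
are never scaled.  Named presets: `pcg_target` (1, 0.3), `active` (0, 1),
`bivalent` (0.4, 0.5).

The SUZ12 and UTX peak constants are packaged values calibrated once
(`scripts/calibrate_presets.py`, seeded) and frozen: SUZ12
(ψ_b = 0.02, ψ_m = 0.28 at α = 1, σ0 = 1.8 kbp), UTX (ψ_b = 0.075,
ψ_m = 0.25 at β = 1, σ0 = 2.5 kbp).  The calibration requires, under the
default rates: a PcG-like valency with the me2/me3 crossover a few kbp from
the TSS at (1, 0.3); an active-like valency at (0, 1); the
no-spreading (EZH2-knockout-like) promoter ordering me2 > me3 > me1; an
intermediate label at (0.4, 0.5); and an inhibitor-washout me3 recovery
time within one to three cell cycles.  Within the Gaussian family these
requirements pin the constants tightly: larger SUZ12 amplitudes make
near-TSS re-trimethylation nucleation-dominated and too fast, while weaker
UTX backgrounds push the crossover beyond the window.  The calibrated
family recovers 90% of the wild-type region-mean me3 about 1.1 cell cycles
after spreading is restored — at the fast end of the accepted range;
because the demethylation-plus-dilution rate near the crossover is bounded
below by `γ_turn + ln2/T`, substantially slower recoveries are not
reachable without breaking the valency constraints.

Track utilities mirror standard quantitative ChIP practice: per-bin signals
are normalized by the maximum over bins inside the (0.1%, 99.9%) quantile
range (outlier-robust), optionally clipped at 1, and smoothed with a
centered 300-bp moving average; bedGraph (0-based half-open) and
two-column text tracks are resampled onto the lattice by overlap-weighted
averaging.  Negative inputs are clipped to zero with a warning.

## Observables

* **Mean profiles**: P_x(i) averaged over trajectories and recorded times
  at steady state (an unsynchronized population average).
* **Valency**: window means (±2.5 kbp default) classified as
  PcG-like (me2 > me1 and me3 > 1.5 me2), active-like (me1 > me2 and
  me2 > 1.5 me3), else intermediate; the rules partition the input space.
* **Crossover distance**: scanning outward from the TSS on each side, the
  smallest distance at which P_me2 > P_me3 holds for ≥ 3 consecutive sites
  (persistence suppresses single-bin flips), averaged over the two sides;
  NaN when no side crosses.
* **Correlation maps**: Pearson correlations between state indicator
  variables at (site, state) pairs, pooled over trajectories and times.
  Degenerate indicators (occupancy 0 or 1) yield NaN, not 0 — the
  correlation is undefined there.
* **Phase diagram**: one steady-state ensemble per (α, β) cell
  (defaults α ∈ 0:1.4:0.2, β ∈ 0:2:0.2), each labeled by its valency.

## Dynamics protocols

* **Cell-cycle average**: synchronized ensembles folded by time since the
  last replication; averages over trajectories and cycles.
* **Histone pools**: from a labeling epoch t0, sites lost to turnover or
  replication join the "new" pool (a site-level label — a replication loss
  relabels the site even if it was already unmodified).  Pool mark
  proportions and sizes are reported per sample; the old-pool fraction is
  independent of the mark kinetics and follows the closed form
  `exp(−γ_turn t) · 2^(−k) (1 − frac/2)` with k = ⌊t/T⌋, frac = t/T − k
  for uniform phases.
* **Effective decay time** t_e: least-squares fit of `exp(−t/t_e)` to the
  old-pool fraction, by default unweighted on the linear scale over the
  recorded window (0–100 h), which weights early times and yields
  t_e ≈ 12.7 h at default rates, slightly above the asymptotic log-slope
  value `1/(γ_turn + ln2/T) ≈ 12.3 h`; a `log_scale` flag exposes the
  asymptotic fit.  The fitting window and loss are package choices — the
  linear-scale default is what reproduces the reported wild-type value.
* **Washout / profile-switch protocols**: evolve to steady state under one
  parameter set or enzyme profile, switch at t = 0, track mark dynamics in
  all histones and in the post-switch new pool.

## Parameter inference

The free parameters are fixed sequentially from four perturbation
conditions, then iterated:

1. **Acetylation** (methyltransferase double knockout): the model reduces
   to u ↔ ac, and `(k_ac, α_bg)` minimize the unweighted squared distance
   between the closed-form P_ac and the observed profile, where α_bg ≤ 1
   scales the p300 background (occupancy differs between wild type and the
   knockout).  Grid-seeded L-BFGS-B; deterministic.
2. **Demethylation** (EZH2 knockout, R = 0): the exact decoupled oracle
   predicts per-site methylation marginals over a γ_me grid; values whose
   promoter-window ordering matches the observed one (me2 > me3 > me1) are
   admissible, and among them the best scale-invariant least-squares fit of
   the predicted profiles to the observed relative profiles is returned
   (one common scale factor, closed form).  The admissible interval is
   reported alongside.
3. **Spreading ratio** (wild type): Gillespie ensembles over an R grid with
   common sub-seeds; admissible R give a PcG-like window valency and a
   me2/me3 crossover within ±0.5 kbp of the target distance (taken from the
   observed wild-type profiles unless fixed).  Among admissible values the
   best scale-invariant fit to the relative wild-type profiles is returned,
   with half- and quarter-step refinement around the optimum; when no grid
   point is admissible the search refines around the closest near-miss
   first, since the admissible interval can be narrower than the grid step.
4. **Nucleation rate** (UTX knockdown, γ_me = 0, acetylation off): the
   absolute, calibrated me3 profile is fit by chi-squared over a k_me3
   grid with two refinement rounds.

Returning the best-fitting admissible value (rather than an interval
midpoint) matters: the midpoint is biased by the asymmetric shape of the
admissible sets (≈ −17% for γ_me, −18% for R at the default conditions)
and would break the scheme's self-consistency on simulated data.

Steps 2–4 loop until all three parameters change by < 5% (relative) or a
previously visited parameter set recurs — the discrete grid search can
enter a short limit cycle, in which case the best-scoring visited state is
returned.  Because the staggered updates leave γ_me fit against the
previous k_me3, a final consistency pass re-fits γ_me at the converged
k_me3 (deterministic and cheap).  All chi-squared comparisons use
300-bp-smoothed profiles on both sides, which suppresses Monte-Carlo and
measurement noise without biasing the fit.  The pair score combines the
absolute UTX-knockdown chi-squared with the wild-type shape chi-squared, so
a wrong ratio pair cannot hide behind a compensated k_me3.

The ratio grid scan repeats the loop over integer pairs r13 ≥ r23 ≥ 1
(default 1–9) from several k_me3 initializations, reporting convergence
status and score per pair.

**Synthetic targets** (`make_synthetic_targets`) emulate the four
conditions from known ground truth: closed-form acetylation for the
no-methylation condition, the exact oracle for the no-spreading condition,
and Gillespie ensembles (64 trajectories, 15 burn-in cycles by default) for
the wild-type and no-demethylation conditions, each perturbed by
independent multiplicative Gaussian noise (5% coefficient of variation,
truncated at zero).  The noise model is a package choice; real ChIP noise
is spatially correlated and sequence-biased, so recovery on these targets
demonstrates the scheme's self-consistency, not its robustness to real
data artifacts.

## Problem sizes

Default study conditions follow the wild-type setup: 32 trajectories ×
25 burn-in cycles for steady-state profiles; 500 trajectories × 100 h for
unsynchronized dynamics; 200 trajectories for protocol timing estimates.
The test suite and the inference harness run reduced configurations
(12–24 trajectories, 8–15 burn-in cycles, coarse step-0.2 search grids with
local refinement) chosen so that recovery accuracy stays well inside the
~10% tolerances of the inference scheme; the reduced settings are exposed
as `InferenceConfig.coarse()` and documented where used.

## Known limitations

* Enzyme occupancies are static inputs; no feedback from marks to binding,
  no explicit PRC2 binding/unbinding, no transcription coupling.  The
  model is monostable by construction — repression reflects stable enzyme
  recruitment, not self-sustaining epigenetic memory.
* The Gaussian presets emulate average profiles; real loci have asymmetric,
  multi-peaked enzyme landscapes (arbitrary tracks can be supplied).
* The default contact kernel is the average power law; locus-specific
  contact matrices can be passed but none are shipped.
* The washout recovery time under the packaged presets sits at the fast end
  (~1.1 T) of the accepted 1–3 cycle range (see the calibration note
  above).
* Replication is symmetric; no leading/lagging-strand asymmetry.
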