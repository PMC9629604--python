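# Methods

This note documents the model, the numerical methods, the synthetic-data
generator and the design decisions behind `jakstat`, in the package's own
terms. Nothing stated here goes beyond what the test suite and the
`scripts/acceptance.py` pipeline actually compute.

## The model

The package implements a stochastic mass-action model of type-I interferon
(IFN-alpha) signal transduction through the JAK-STAT pathway in a single
hepatoma-like cell: 42 species in two compartments (cytoplasm 86.5% of cell
volume, nucleus 13.5%) coupled by 62 reactions. The layers are

1. **Receptor module.** Extracellular IFN binds a receptor subunit (R1) to
   form an intermediate IR, which reversibly dissociates or captures the
   second subunit (R2) to form the ligand-receptor complex RC; RC converts
   to the active receptor AR (the pJAK1-bearing species). SOCS protein
   degrades the active complex — the ligand is consumed, the subunits
   return to the inactive pool (the model has no receptor synthesis, so
   receptor capacity is conserved while IFN is depleted). A slow
   constitutive decay of AR acts in parallel.
2. **STAT activation.** AR catalyzes phosphorylation of cytoplasmic STAT1
   and STAT2. pSTAT1 and pSTAT2 heterodimerize (dimerSTAT); free pSTAT1 and
   pSTAT2 are dephosphorylated back. dimerSTAT binds cytoplasmic IRF9 to
   form ISGF3, which shuttles into the nucleus, and is disassembled there
   (dephosphorylation), releasing nuclear STAT1, STAT2 and IRF9.
3. **Basal expression.** STAT2 and IRF9 constitutively form the STAT2-IRF9
   heterodimer, which shuttles between compartments and turns over
   (degrading the IRF9 moiety, recycling STAT2). Nuclear STAT2-IRF9 drives
   the basal occupancy of the ISG promoters.
4. **Gene expression.** Each of the four ISGs (irf9, socs, mxa, ifit1) is a
   single gene copy in one of three exclusive microstates: free (`I_g`),
   ISGF3-bound (`g`) or STAT2-IRF9-bound (`g*`). The two transcription
   factors compete with identical association constants; the STAT2-IRF9
   dissociation rates are far higher, so before stimulation the promoters
   carry a small STAT2-IRF9 occupancy (basal expression), and after
   stimulation the long-lived ISGF3 occupancy takes over. Both bound
   states transcribe at the gene's rate into nuclear mRNA, which is
   exported, translated in the cytoplasm and degraded; the IRF9 protein
   closes the positive feedback (more ISGF3), the SOCS protein the negative
   one (receptor deactivation). MxA and IFIT1 are the measured reporters.

Rate constants, initial copy numbers and compartment fractions are carried
verbatim in `model.py` (52 named constants; promoter-state initial values
are occupancy probabilities of the single gene copy). The IFN dose converts
linearly at 20 molecules per IU/mL (500 IU/mL = 10,000 molecules).

### Volume convention

Second-order rate constants are referenced to the whole-cell volume.
Propensities of bimolecular reactions are rescaled by the volume fraction of
the compartment where the reaction occurs (1/0.135 in the nucleus, 1/0.865
in the cytoplasm). This convention is strongly supported by the data the
model carries: with it, the stationary promoter occupancies implied by the
rate constants reproduce the tabulated unstimulated occupancies nearly
exactly (irf9* 0.60 vs 0.62, socs* 0.022 vs 0.02, mxa* 0.0605 vs 0.06,
ifit1* 0.137 vs 0.11), while the unscaled form misses all four by a
consistent factor of ~7.

### Reaction wiring

The published material fixes the species list, the constants and the
topology narrative but not the complete reaction-by-reaction assignment of
rate-constant indices; `model.py` therefore keeps the reaction table as
explicit, editable data. The adopted assignment was identified from
internal evidence, in order of weight:

* the unstimulated state must be (approximately) stationary at the
  tabulated initial conditions — this pins the gene order of the
  transcription/degradation/translation quadruplets (irf9, socs, mxa,
  ifit1: it reproduces basal mIRF9_c ~ 14, mIFIT1_c ~ 0.2, mSOCS_c ~ 0.05,
  and basal protein levels near the tabulated MxA/IFIT1 values with k_38 /
  k_39 as their decay constants) and the STAT2 shuttling pair
  (k_45/k_36 gives a nuclear:cytoplasmic ratio of 0.0170 vs the tabulated
  150/9325 = 0.0161);
* the reported phenotypes: a dose-graded, sustained 32-h induction
  (receptor-complex completion is the slow step, so signaling tracks the
  remaining IFN), a transient pJAK1 peak within the first three hours
  (SOCS feedback), an MxA fold-change of ~5.6 at 250 IU/mL, IFIT1
  equilibrating faster than MxA, a receptor complex RC that stays below one
  copy on average yet carries the highest intrinsic variability, and
  conservation of the response under extrinsic noise;
* scale compatibility of each bimolecular constant with its reactants'
  copy numbers.

Two unimolecular constants serve two reactions each (k_37: STAT2-IRF9
turnover in both compartments; k_43: nuclear export of IRF9 and of
STAT2-IRF9), mirroring the sharing that the source tables themselves state
for the promoter association constants. Known limitations of the
reconstruction: nuclear STAT1 is a terminal pool (no export reaction), and
pSTAT2 dephosphorylation is fast (k_9), standing in for the dissociation of
the STAT heterodimer, which is not modeled separately.

## Stochastic simulation

`engine.py` provides an exact Gillespie direct-method SSA and an adaptive
explicit tau-leaping engine with numba-compiled kernels. The tau-leap
partitions reactions per step: any reaction that net-consumes a species
below `N_CRITICAL = 10` copies is critical and fires one at a time with
exponential waiting times (promoter state changes are therefore always
exact); the rest advance by Poisson leaps with the standard mean/variance
step bound at `eps = 0.03` (species bound: max(eps*x/2, 1); only species
that are reactants of a leapable reaction, or scarce net products of one,
constrain the step). Leaps producing a negative count are rejected and
redrawn with a halved step; when a leap would cover fewer than ten expected
events the engine falls back to 100 exact SSA steps. When the total leap
intensity is small the per-channel Poisson draws are replaced by one draw of
the total count plus propensity-proportional attribution (an exact
superposition identity). States are recorded on a fixed grid; grid points
falling inside a step record the pre-step state, which is consistent with
the piecewise-constant interpretation and keeps the recording error within
the leap tolerance. Correctness is defined by the tests, not by constants:
marginals must match exact SSA on analytically solvable toys (KS < 0.05 at
2000 repetitions) and on the full model at desk scale (within the
finite-sample floor). Implicit leaping is not implemented; the explicit
scheme with exact critical handling passes the equivalence tests at the
fitted rates.

Reproducibility: each trajectory of an ensemble draws its initial state and
kernel seed from an independent substream spawned from the master seed, so
an ensemble is a pure function of (model, parameters, seed, engine
settings), byte-for-byte after serialization.

## Intrinsic and extrinsic noise

Intrinsic noise is the trajectory-to-trajectory variability at fixed initial
conditions. Extrinsic noise is modeled by randomizing initial molecule
counts: each in-scope species (ligand, proteins, complexes and mRNAs with
nonzero mean; promoter microstates are always resampled from their occupancy
probabilities) draws from Normal(mu, (sigma*mu)^2), truncated at zero and
rounded. The spread is relative because a single sigma must be meaningful
for species spanning five orders of magnitude. Whether the study rounded or
truncated its draws is not recorded; the truncated-rounded scheme is this
package's documented choice (its mean bias is < 0.1% for mu >= 10 at
sigma = 0.3, verified in the tests).

Variability is summarized by the modified coefficient of variation
cv = sd/(mean + 0.1), computed with the population SD across trajectories;
the offset damps the blow-up for sub-unity pools (RC and the ISG mRNAs) and
is negligible for means above one. The heatmap orders species by the
time-averaged cv of the sigma = 0.3 ensemble and clamps the color scale at
4; promoter microstate indicators are excluded (they are occupancy flags of
a single gene copy, not molecular abundances). Response conservation is the
per-time-point Kolmogorov distance between the readout marginals of an
extrinsic ensemble and the intrinsic-only ensemble, evaluated by default at
the experimental panel times (8, 12, 16, 20, 32 h).

## Distribution metrics

ECDFs are multiplicity-weighted right-continuous step functions; the
two-sample Kolmogorov distance is the exact supremum over the merged sample
points (no grid, no p-values — it is used purely as a distance).
`metrics.py` also carries a Hartigan-style dip statistic (distance of the
ECDF to the closest unimodal CDF, with the candidate mode restricted to 50
sample quantiles) whose null is calibrated by Monte Carlo against the
uniform distribution with the same statistic; it backs the generator's
graded-vs-bimodal checks.

## Observation model and fitting

Observables are affine maps a * (sum of mapped species) + b. The population
(immunoblot-style) readouts are composites reported relative to their own
maximum: pJAK1 tracks AR; pSTAT1 counts pSTAT1 + dimerSTAT + ISGF3 in both
compartments; nuclear IRF9 counts IRF9_n + ISGF3_n + STAT2-IRF9_n. The
snapshot (flow-cytometry-style) readouts map the MxA / IFIT1 protein counts
to arbitrary units.

Two objectives: a sum-of-squares distance between mapped mean-field means
and population time courses, and the snapshot objective — simulate an
ensemble under a candidate parameter vector, map it, and aggregate the
per-time-point Kolmogorov distances to the measured single-cell
distributions (mean over time points; the maximum is reported alongside;
the aggregation rule is this package's choice).

Simulated-measurement protocol: unstimulated cells are samples from the
*stationary law* of basal bursty ISG expression, not copies of its mean
(one mxa mRNA translates into ~640 MxA proteins over its lifetime, so the
basal MxA distribution has a CV near 0.7). Both the generator and the
snapshot objective therefore start every cell from the endpoint of its own
stochastic basal burn-in (4320 min, about three MxA protein half-lives,
capturing ~95% of the stationary variance) before the IFN dose is applied.

Estimation is two-tier (`fit_snapshots`). A first-moment stage runs the
real-coded genetic algorithm (tournament selection of size 3, BLX-0.3 blend
crossover with probability 0.8, Gaussian mutation, elitism 2) on the
mean-field deviation from the stimulated panel's mean time course — the
same quantity the moment pre-screen thresholds, and cheap enough for
thousands of candidates per minute. The means, however, are nearly blind
along burst-parameter compensations (e.g. transcription rate against mRNA
lifetime at fixed mean level), which were measured to form a flat manifold
reaching the data-noise floor. The distribution *width* resolves them: the
second stage re-runs the GA, seeded with the stage-one survivors, on a
Kolmogorov-distance objective against the unstimulated panels — where the
stationary width is governed directly by the burst size and simulation is
cheapest — while candidates straying off the moment manifold fall back to a
cheap ``1 + deviation`` penalty (any KS is at most 1, so penalized
candidates always rank below stochastically scored ones while keeping a
slope toward feasibility). The best vector's per-time-point KS against the
stimulated panel is then evaluated once and reported. Defaults for
desk-scale fits: bounds one decade around nominal values, 50 simulated
repetitions per stochastic score. No posterior uncertainty is attempted;
the robustness assay below substitutes.

## Parameter robustness

Every rate constant is individually halved and doubled. Each condition is
scored against a shared reference ensemble with a paired master seed (a
factor of 1.0 therefore reproduces the reference exactly and scores zero)
by the Kolmogorov distance of the MxA and IFIT1 copy-number marginals at
the evaluation time (default 32 h — the single-time-point choice is this
package's; the source does not state one) and by the relative change of the
mean counts. The headline comparison contrasts gene-expression/degradation
constants with receptor/signal-transduction constants; the packaged
grouping is in `robustness.py`. Default 600 repetitions per condition,
overridable for desk-scale runs.

## Synthetic data generator

The generator stands in for the study's measurements. Snapshot panels:
for each dose (0, 10, 50, 250, 1250 IU/mL) and time (0, 8, 12, 16, 20,
32 h), cells are independent trajectories; the reporter protein count is
mapped to fluorescence and multiplied by unit-mean log-normal measurement
noise (CV 0.25 by default — flow-cytometry convention; the effective
measurement-noise model of the instrument is not recorded, so this is a
generator choice, co-estimable during fitting). Panels start from per-cell
stochastic basal burn-ins (cells in culture are at basal equilibrium when
IFN is added), which makes the dose-0 panels stationary by construction;
the tabulated initial conditions are close to, but not exactly on, the
model's basal fixed point, and remain the initial state for the
noise/robustness analyses, which follow the stated simulation protocol
rather than the measurement protocol. Scales are calibrated so the
unstimulated mean fluorescence sits near the reported ranges (~8e3 a.u. for
MxA, ~2e4 a.u. for IFIT1). Default 5000 cells per time point, scaled down
to a few hundred in the tests. Immunoblot-style curves are ensemble means
of the composite readouts over 0..180 min at 500 IU/mL with 18%
multiplicative Gaussian error, normalized per readout.

What the generator does not emulate: FACS gating artifacts, doublets,
spectral spillover, autofluorescence baselines, instrument drift, or
cell-cycle-correlated extrinsic structure (extrinsic noise enters only
through independent initial-condition draws). Passing recovery tests on
this generator therefore demonstrates pipeline correctness and
identifiability under the stated noise model, not performance on raw
cytometer files.

## Problem sizes used in the packaged runs

Chosen as the package's own desk-scale defaults: response-conservation
ensembles use 600 repetitions at sigma 0 and 0.3 and 250 at 0.6 (the
two-sample KS floor 1.36*sqrt(2/n) is ~0.079 at n = 600, safely below the
effect sizes measured); basal averages use 48 repetitions of a 48-h run
averaged over the second day; the robustness ordering test uses three
representative constants per group at 60 repetitions, evaluated at 16 h;
the recovery test fits three MxA-axis constants (k_22 transcription, k_30
mRNA decay, k_38 protein decay — the transcription/translation pair is an
exact level compensation and unidentifiable from snapshots) on a 150-cell
panel with a 16-member, 25-generation moment GA followed by an 8-member,
5-generation shape GA. The acceptance script regenerates its ensembles
from scratch at 600 repetitions.

## Known limitations

* The reaction wiring is a reconstruction constrained by the published
  tables and phenotypes, not a transcription of the original deposit; the
  table in `model.py` is deliberately editable data.
* The mean-field ODE is a first-moment closure; it is exact only for the
  linear sub-networks (verified against SSA on a linear cascade) and is
  used only for pre-screening and generator equilibration.
* Explicit tau-leaping with exact critical handling is accurate but not
  optimal for stiff regimes; the fitted rates avoid fast reversible pairs,
  and the equivalence tests are the binding contract.
* SBML export and FCS ingestion are not included; the model serializes to a
  human-editable text format and datasets to CSV.
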