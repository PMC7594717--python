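# Methods

## Scope and model

`chemoflux` implements isotopically stationary ¹³C metabolic flux analysis
(¹³C-MFA) for *Corynebacterium glutamicum* growing in a glucose-limited
chemostat, together with the chemostat kinetics needed to supply the
extracellular rates. The carbon-mapped network bundled as
`data/cglutamicum.yaml` reconstructs the classic central-metabolism model
used for flux fitting in this organism: glycolysis, the pentose phosphate
pathway (PPP), the TCA cycle, the full anaplerotic node (pyruvate
carboxylase *pyc*, PEP carboxylase *ppc*, PEP carboxykinase *pck*, malic
enzyme *mez*), protocatechuate (PCA) co-utilization through the
β-ketoadipate pathway, amino acid synthesis for all measured amino acids,
and a lumped biomass equation. Its dimensions are 87 reactions
(22 bidirectional, 65 unidirectional), 45 balanced intracellular pools and
4 non-balanced extracellular pools (glucose, PCA, CO₂, biomass sink), with
27 free fluxes: 7 net and 20 exchange.

Assumptions inherited from stationary MFA:

* metabolic and isotopic steady state (the chemostat guarantees the former;
  sampling several residence times after the tracer switch the latter);
* well-mixed pools — intramolecular label correlations are broken whenever
  molecules are cleaved into separate pools;
* fluxes in the net/exchange convention, `fwd = max(net,0) + exch`,
  `bwd = max(−net,0) + exch`; exchange fluxes affect labeling only.

Units are µmol gCDW⁻¹ h⁻¹ throughout; the growth rate µ is h⁻¹.

### Biomass and free fluxes

Biomass formation is a set of 36 unidirectional drain reactions from
precursor pools whose rates are tied to µ by fixed composition coefficients
(µmol gCDW⁻¹; `biomass_demand` in the model file, overridable). The bundled
composition drains ≈39,400 µmol carbon gCDW⁻¹ (0.47 g C gCDW⁻¹), consistent
with the observed biomass yields. Because the drains are tied to a single
growth-rate coordinate, the free net fluxes of the bundled model are the
three scale fluxes (glucose uptake `pts`, PCA uptake `pca_upt`, growth rate
`__mu__`) plus four branch-point fluxes (`zwf` — the PPP split, `pyc`,
`pck`, `mez`). The basis construction is deterministic: candidate free
fluxes are taken along a documented preference list (uptakes and growth
first, then textbook branch points) and accepted greedily when they
increase the rank of the null-space projection.

Two of the 22 bidirectional reactions — CO₂ transport and the glycine
cleavage system — carry fixed (zero) exchange fluxes: gas export and the
GCS operate far from isotopic equilibrium, and pinning them leaves the 20
free exchange fluxes the model is specified with. Exchange fluxes are
exposed to the optimizer through the bounded transform `t = x/(s + x)`
with scale `s = 1000 µmol gCDW⁻¹ h⁻¹` (configurable), so optimizer
variables live in [0, 1).

Reactions touching C-symmetric metabolites (succinate, fumarate,
meso-diaminopimelate) are expanded into equally weighted orientation
variants before simulation ("scrambling"); stoichiometry is untouched.

## EMU simulation and its oracle

MIDs are simulated with the elementary-metabolite-unit decomposition: the
minimal closure of the measured fragments is built by following atom maps
backwards, and one linear system per EMU size is solved by dense LU
factorization (the largest level of the bundled model has well under a
hundred EMUs, so sparse solvers are unnecessary). Convolution terms from
condensation reactions enter the right-hand side; every solved MID is
checked to be normalized to 1 ± 10⁻⁶ and renormalized, and a singular level
matrix raises an error naming the pool without influx — zero-influx pools
are treated as modeling errors, not pruned.

`isotopomer_oracle` solves the full positional-isotopomer balance (2ⁿ
states per pool) by damped fixed-point iteration for verification on small
networks. Each pool is projected back onto the probability simplex after
every sweep — condensation cycles otherwise admit spurious sub-stochastic
fixed points — and the unnormalized balance residual is verified at the
solution. The equivalence EMU ≡ oracle is enforced to 10⁻⁹ over ≥100
randomized cases (four toy topologies covering cleavage, condensation,
bidirectional exchange, symmetric pools and cycles, with random feasible
fluxes and random tracer mixtures).

## Tracer inputs and natural-abundance correction

The labeling experiment's mixture (67% U-¹³C + 33% 1-¹³C glucose) ships as
a named preset; arbitrary mixtures of binary 6-carbon patterns are
supported, and input MIDs for any glucose EMU are obtained by
marginalization. PCA and CO₂ inputs default to unlabeled material — at
natural ¹³C abundance when simulating raw data, at pure ¹²C when simulating
the corrected-data scale.

The correction matrix for a detected ion combines (i) the mass-shift
distributions of all non-backbone atoms of the ion formula (IUPAC
abundances, configurable) and (ii) a column-dependent binomial for natural
¹³C in the `n − j` backbone carbons not yet labeled at mass shift `j`. Part
(ii) makes the correction the exact inverse of natural-abundance forward
simulation for pure ¹³C tracers (verified to 10⁻⁶ on the full panel);
correcting only non-backbone atoms is available via `correct_backbone=False`.
Corrected MIDs with entries below −10⁻³ raise; smaller negatives are
clipped and the vector renormalized.

## Measurements

The bundled panel holds the 28 measured metabolites (full carbon backbones,
HILIC-QTOF intact ions), which yields 164 MID values; the flat measurement
SD is 2.5 mol% with per-entry overrides. Each metabolite forms one
measurement group with a multiplicative scale factor ω that is profiled
out in closed form (variable projection,
ω = Σsm/σ² / Σs²/σ²) at every objective evaluation. The scale factors
still count as parameters for the χ² test, giving the model's 55 parameters
(7 + 20 free fluxes + 28 scales).

A carbon-atom model cannot simulate O₂ uptake, so the default synthetic
dataset carries the four simulable extracellular rates (µ, glucose uptake,
CO₂ evolution, PCA uptake) with the study's reported SDs — 168 measurements
rather than the study's 170 (which included O₂ rates).

## Flux fitting

The objective is the variance-weighted SSR over scale-projected MIDs and
rates. Direction feasibility (net ≥ 0 for unidirectional reactions) is
maintained by rejection sampling of starts and smooth penalty residuals.

The multi-start heuristic is: (1) random feasible starts — free fluxes that
are directly measured as rates are drawn around their measured values
(±3 SD), the rest uniformly in documented physiological boxes, exchanges
uniformly on the bounded transform; (2) a cheap trust-region screen of
every start; (3) a tight 3-point-Jacobian polish of the best few; (4) a
deterministic sequence of seeded perturbation restarts ("kicks") around the
incumbent, accepting improvements. Stage (4) is what makes the 20-start
default reliably find the global optimum of the 27-parameter bundled
problem; an optional gradient-free (Powell) warm-up per start is available
but off by default, since the trust-region screen proved strictly more
effective per function evaluation. All stages consume one seeded generator,
so fits are reproducible.

Goodness of fit uses the upper-α χ² quantile at dof = measurements −
parameters. For the study configuration (170/55) this is ≈141 at α = 0.05;
the study's printed acceptance threshold of 114 corresponds to a different
dof convention (≈91) that the original software did not document, so both
numbers are reported rather than reverse-engineered.

Confidence intervals default to simultaneous profile intervals: each free
net flux is walked away from the optimum with all other parameters
re-optimized until the SSR exceeds SSR* + χ²₁₋α(n_params); reaching the
physiological box first flags the flux as non-identifiable (the bundled
model's *mez* flux behaves this way at realistic noise, as expected from
its near-redundant labeling role). A linearized mode from local curvature
is available and falls back to profiling when the curvature is singular.

## NADPH and carbon accounting

NADPH production is 2×gnd + icd + mez as percent of glucose uptake (the
oxidative PPP contributes two NADPH per G6P; reactions carry cofactor
annotations so the closed form is cross-checked by enumeration). The
requirement is the growth NADPH coefficient (14,849 µmol gCDW⁻¹) × µ,
normalized to the glucose uptake rate. Carbon balance splits uptaken carbon
(glucose + PCA) into biomass drains and CO₂ export; mol CO₂ per mol glucose
is the CO₂ export flux over the glucose uptake flux.

## Chemostat kinetics and bioprocess model

Steady-state balances: µ = D, q_GLC = D·c_feed/c_X (residual glucose below
detection), Y = c_X/c_feed. Respiratory rates come from gas-phase molar
balances with inert-gas correction of the outlet flow, and the CO₂ rate is
augmented by the dissolved-inorganic-carbon carry-out D·TIC/c_X. Maintenance
parameters come from ordinary least squares of q_GLC (mmol gCDW⁻¹ h⁻¹,
M_glucose = 180.16 g mol⁻¹) on µ.

The bioprocess ODE model is dX/dt = (µ−D)X, dS/dt = D(S_f−S) − q_S·X with
Monod growth µ = µ_max·S/(K_S+S) and Pirt uptake. The maintenance term
saturates with its own much smaller constant (K_m = 0.5 mg L⁻¹): it is flat
over chemostat operating points yet vanishes with the substrate, which
keeps S non-negative in batch and — unlike tying maintenance to µ — keeps
the growth-coupled and maintenance coefficients separately identifiable.
Integration is piecewise between dilution-rate switches. Parameter SDs are
parametric-bootstrap Monte-Carlo: noise is resampled at the stated SDs and
each replicate is refit from randomly perturbed initial parameter values
(the "random initial parameter values" of a multi-start reading are thus
honored within each bootstrap replicate).

## Tracer design

Fisher information J = Sᵀ Σ⁻¹ S with sensitivities S of the simulated
measurement vector by central finite differences. Mixtures are scored by
D-optimality on the identifiable subspace (pseudo-log-determinant; the
criterion of the original design study is not published, so this is the
package's choice, with A-optimality as an alternative) and searched on a
deterministic simplex grid over at most three active candidates with
lexicographic tie-break. The six bundled candidates are U-¹²C, U-¹³C,
1-¹³C, 1,2-¹³C, 6-¹³C and 5,6-¹³C glucose.

## Synthetic data

The generator emulates the study's measurement configuration: MIDs of the
28-metabolite panel simulated at a ground-truth flux state, independent
Gaussian noise (default SD 2.5 mol%) truncated to [0,1] and renormalized,
plus rate measurements with the reported SDs. The `paper_flux_map` preset
pins the free fluxes to the study state at D = 0.4 h⁻¹ (uptake
4,086 µmol gCDW⁻¹ h⁻¹, µ = 0.41 h⁻¹, PPP split 31.6%); its normalized map
reproduces the reported branch percentages and the 65.6/34.4% carbon split.

What the generator does not emulate: correlated residuals across mass
shifts, metabolite-specific error structure, chromatographic artifacts,
isotopically nonstationary dynamics, and O₂ exchange. Passing the closure,
calibration and coverage tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to real-data error
structure.

## Problem sizes used by tests and the acceptance script

EMU-vs-oracle: 100 randomized cases over four toy topologies. Simulate-
then-fit closure: the full 87-reaction network, noise-free, 20 starts. SSR
calibration: 50 noisy replicates at the truth (expected value is below the
fit dof because scale projection absorbs 28 degrees of freedom). Interval
coverage: 100 replicates × 5 starts on the three-free-flux split network
(the acceptance script uses 60 replicates). Bioprocess Monte-Carlo examples
run 12–25 bootstrap replicates.

## Known limitations

* The bundled network is a reconstruction from the published pathway
  inventory and dimension counts; the original reaction list is not public.
  Atom maps follow standard central-metabolism transition tables; lumped
  aromatic and PCA steps use plausible assignments.
* The measured-rate panel omits O₂ (not representable in a carbon model).
* Profile intervals use a bounded walk; fluxes whose interval reaches the
  physiological box are reported non-identifiable rather than unbounded.
* The isotopomer oracle is exponential in carbons per pool and guarded to
  ~2·10⁶ states; it is a verification tool, not a production solver.
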