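# Methods

## Model

`bc1dimer` computes steady-state turnover and superoxide production of
ubiquinol cytochrome c oxidoreductase (the bc1 complex, respiratory
Complex III) treated as a functional dimer. The model tracks the number of
electrons resident on the complex, not their microscopic trajectories:

* **Redox centers.** Each monomer carries four one-electron centers — a
  Q_p-site semiquinone (SQp), heme bL, heme bH and a Q_n-site semiquinone
  (SQn) — eight centers in the dimer, so the theoretical electron capacity
  is eight. Electrons equilibrate across both monomers through the bL–bL
  "bus bar" at the dimer interface.
* **Electronic states.** The state variable is the electron count k. State
  E_k is the Boltzmann-weighted ensemble of all C(8, k) configurations of
  k electrons over the eight centers. Only E0..E5 are retained: a
  six-state truncation justified below.
* **Configuration energies.** G(c) = Σ_occupied (−F·Em_r + F·δ_r·Δψ)
  plus Coulombic repulsion terms: ΔG_bHbL for every monomer whose bL and
  bH are both occupied, and ΔG_bLbL when both bL hemes are occupied.
  Energies are referenced to the empty complex at zero; only differences
  matter. δ_r is the electrical depth of center r in the membrane
  dielectric measured from the p side (SQp 0, bL 0, bH 0.5, SQn 1.0), so
  the b-heme → Q_n leg is electrogenic. The ensemble free energy
  G_ens(k) = −RT ln Σ_c exp(−G(c)/RT) is the thermodynamic potential of a
  Boltzmann-equilibrated state and is what state-transition energetics
  are built from.
* **Semiquinone couples.** The SQp center potential is derived from the
  two-electron pool midpoint and the site's semiquinone stability
  constant K = [SQ]²/([Q][QH₂]): E(Q/SQ) = Em_pool + (RT/2F) ln K. The
  native quinone-10 stability constant (2.28e-15) puts SQp near −343 mV;
  the analog constant (9.34e-9) near −148 mV. The SQn center is a stable
  semiquinone and uses a fixed +90 mV default.

## Transitions

Six reversible edge families connect the states:

* **Quinol oxidation at Q_p** (E_i → E_{i+1}, i = 0..4): a lumped
  two-electron step — quinol is oxidized, the first electron reduces
  cytochrome c through the Rieske protein and cytochrome c1 (assumed not
  rate-limiting), the second is deposited on the complex. Forward
  propensity n_Qp · kfQp(i,i+1) · β(QH₂@Q_p) · β(c³⁺@c-site), with
  rapid-equilibrium binding fractions β from competitive single-site
  binding polynomials over apparent (aqueous-phase) dissociation
  constants. n_Qp is 1 — only one Q_p site operates per turnover — except
  in singly antimycin-inhibited dimers (below).
* **Quinone reduction at Q_n** (E_i → E_{i−2}, i = 2..5): requires the
  substate with an SQn and a reduced bH on the same (uninhibited)
  monomer; propensity kfQn(i,i−2) · β(Q@Q_n) · P(SQn_m ∧ bH_m | E_i)
  summed over active monomers. The edge carries the two translocated
  charges (+2FΔψ) and the n-side proton uptake.
* **Superoxide formation** (E_i → E_{i−1}, i = 1..5): the Q_p-site
  semiquinone electron reduces O₂. From E1..E4 the semiquinone is formed
  by reverse electron flow from reduced bL (the *semireverse* mode); from
  E5, where the low-potential chain is full, quinol oxidation leaves a
  semiquinone with no internal acceptor and its electron leaves as
  superoxide (the *semiforward* mode). Propensity
  k_O2 · [O₂] · P(SQp | E_i) · β(Q@Q_p). Making the semiforward mode an
  explicit E5 → E4 edge (rather than a stateless event) is a deliberate
  design choice: it is the only formulation in which E5 has an exit when
  the Q_n sites are blocked, so the antimycin-saturated enzyme reaches a
  distributed steady state instead of collecting irreversibly in E5.

Every reverse propensity is constructed from the forward one so that
kf/kr = exp(−ΔG_total/RT), where ΔG_total combines the standard edge free
energy (G_ens differences, pool/cytochrome/O₂ midpoints at pH 7, the
two-sided pH terms and Δψ) with the concentration terms carried by the
binding fractions and the [O₂⁻]/[O₂] ratio. Detailed balance at
equilibrium and cycle closure to the net-reaction free energy
(QH₂ + 2c³⁺ + 2H⁺_n ⇌ Q + 2c²⁺ + 4H⁺_p, 2 charges) follow by
construction and are verified by tests.

**Antimycin A.** Binding to the two Q_n sites is independent and, by
default, stoichiometrically tight (occupancy p = min(ratio, 1); a
mass-action mode is available), giving binomial dimer classes f0, f1, f2.
Classes are solved separately and mixed linearly: an unbound dimer runs
one Q_p site; a singly bound dimer loses one Q_n monomer but operates
both Q_p sites (n_Qp = 2), the kinetic signature of cross-monomer
electron equilibration; a doubly bound dimer has no Q_n edges, its quinol
oxidation rates are divided by βAAr (edges feeding the semireverse-capable
states, i = 0..3) and βAAf (the edge feeding E5), and all flux passes
through the superoxide bypass. When an assay would also record the
cytochrome c reduced by the released superoxide, the reported rate is
J_c + J_SO (exactly 2·J_SO for the bypass-only class).

**Steady state.** The six-state generator M (the E-state master-equation
matrix) is solved for its stationary distribution by SVD null space on
the connected component containing E0, after scaling by the largest
propensity; unreachable states carry zero probability, a degenerate
(multi-dimensional) null space raises with a diagnostic. Net fluxes are
propensity-weighted sums over edges; at steady state the electrons
balance: J_c = 2·J_Qn + J_SO_sr + J_SO_sf.

## Parameters

The shipped table (`bc1dimer/data/default_parameters.json`) carries the
fitted adjustable block: per-state rate constants kfQp(i,i+1) (s⁻¹, 4.14
to 3.15e3) and kfQn(i,i−2) (s⁻¹, 6.98e3 to 9.21e9), the antimycin factors
βAAr = 344 and βAAf = 5, apparent dissociation constants for
decylubiquinone, ubiquinone-2, nonyl-ubiquinone and mixed-pool analogs
plus cytochrome c (with and without Mg²⁺), the Coulomb energies
ΔG_bHbL = 11.6 and ΔG_bLbL = 5.3 kJ/mol, the two semiquinone stability
constants, and one initial percent-oxidized value per calibration
dataset. Native quinone-10 dissociation constants are not measurable
directly; the defaults follow the standard structural/thermodynamic
estimates — Q_p-site QH₂ and Q near-equal in the low-millimolar range
(1e-3 M), Q_n-site QH₂ ~100-fold tighter than Q (1e-5 vs 1e-3 M).

Fixed block defaults: Em(bL) = −60, Em(bH) = +80, Em(SQn) = +90 mV, pool
two-electron couple +90 mV for all species, cytochrome c +260 mV,
O₂/O₂⁻ −160 mV; T = 298.15 K; F = 96.485 kJ/(mol·V). All are overridable
from a user parameter file.

**The superoxide rate constant k_O2** (default 1e14 M⁻¹s⁻¹) is an
*apparent* second-order constant, not the free-semiquinone + O₂ literature
value (~1e7 M⁻¹s⁻¹). The propensity multiplies three strongly sub-unity
factors — P(SQp|E_i) (10⁻⁴–10⁻³ with the analog stability constant) and
β(Q@Q_p) (~10⁻⁷ with the molar-scale apparent Q_p-site constant for Q) —
so the free-species constant would put all superoxide fluxes around
10⁻⁹ s⁻¹ per dimer and, more importantly, leave E5 without an effective
exit: the uninhibited steady state under near-fully-reduced analog
conditions would sit almost entirely in E5, invalidating the six-state
truncation this model is built on. The default is therefore calibrated as
the smallest decade for which E5 occupancy stays marginal (~1%) across
the physiological surface and the calibration conditions, keeping the
truncation self-consistent. The trade-off is that absolute superoxide
rates (s⁻¹ per dimer) run higher than a per-milligram conversion with
typical bc1 protein contents (80–500 pmol/mg) would suggest; ratios,
orderings and peak positions — the quantities this package is used for —
do not depend on the overall scale, but absolute per-mg rates should be
treated as uncalibrated.

An optional Rieske-protonation factor 1/(1 + 10^(pH_p − pK)), pK 7.6,
can multiply the high-potential-chain rates; it is off by default, with
the equilibrium p-side pH terms carrying the pH dependence instead.

## Scenarios and experiments

Built-in scenarios reproduce the standard reconstituted-vesicle panel
(ubiquinol-2 analog pool 50 μM at its fitted initial redox state, 50 μM
oxidized cytochrome c, air-saturated buffer): control Δψ = 200 mV with a
15 mV pH-gradient equivalent (alkaline matrix, ΔpH expressed through its
2.3RT/F millivolt equivalent), FCCP 0/0, nigericin 215/0, valinomycin
0/15, and an antimycin scenario (control conditions, both Q_n sites
blocked, superoxide-mediated cytochrome c reduction included in the
reported rate). A de-energized anoxic scenario with no cytochrome c
exercises the pure state-space limit (both fluxes exactly zero). The
physiological surface uses native-quinone constants: 20 mM Q pool,
cytochrome c 20% reduced, pH 7/7, 30 μM O₂, 100 pM O₂⁻, Δψ 0–215 mV ×
reduced fraction 0.02–0.98 (11 × 13 grid — sizes chosen to resolve the
surface while keeping a full run in seconds).

The Q-redox inversion treats the pool reduced fraction as the unknown:
the flux–redox curve is evaluated on a grid, its maximum located, and a
bracketing root (Brent) is sought on the requested branch; an unreachable
target returns an explicit no-solution result. The Complex I check
ΔG = ΔG°′ + RT ln([NAD⁺][QH₂]/([NADH][Q])) + 4FΔp with ΔG°′ = −74.3
kJ/mol flags reverse electron transport when positive.

## Estimation harness and synthetic data

The synthetic generator emulates the four calibration archetypes —
substrate titration of cytochrome c reduction, superoxide versus membrane
potential, superoxide versus pool redox for the antimycin-saturated
complex, and an antimycin titration of the dimer population — by running
the model itself and applying multiplicative log-normal noise
(y = model · exp(σz), default σ = 0.05, seeded; σ = 0 returns the exact
curves). Default 8 points per dataset. Because the data are generated by
the same model, passing recovery tests demonstrates identifiability and
optimizer correctness, **not** agreement with laboratory data; the
generator reproduces none of the real-data complications (baseline
nonenzymatic analog oxidation, instrument drift, correlated errors,
unknown pool redox).

The cost is a per-dataset-normalized weighted SSE plus a difference
penalty λ·[Var(ln kfQp) + Var(ln kfQn)] that keeps the site rate
constants mutually similar; λ defaults to 1e-3, putting the penalty near
1% of the data term at the shipped optimum. Local sensitivities are
normalized elasticities |(p/J)∂J/∂p| by central differences (default
relative step 1%), averaged over nonzero outputs and ranked. Fitting
works in log10 space (the parameters span 15 orders of magnitude) inside
box bounds: a seeded Metropolis simulated-annealing pass with geometric
cooling, then L-BFGS-B refinement; the same seed reproduces the
trajectory exactly.

Known identifiability limits, visible in the shipped tests: the
ubiquinol-2 binding constants and the per-dataset initial-redox
parameters lie on a correlation ridge, so joint five-parameter recovery
at 5% noise leaves those constants determined only to within a factor of
~2 even when the fit converges to a better-than-truth cost.

## Numerical choices

* Boltzmann weights use max-shift stabilization (Coulomb + Δψ terms can
  span > 40 RT).
* Configuration enumeration is bitmask-ordered, giving a deterministic
  canonical configuration order.
* The stationary solve tolerates propensities spanning ~15 decades by
  matrix scaling; the residual contract ‖Mx‖∞ ≤ 1e-10 · max propensity is
  asserted against a brute-force null-space oracle in tests, and a
  three-state instance is cross-checked against a seeded Markov-jump
  (Gillespie) simulation.
* Tiny negative probabilities from roundoff (< 1e-14) are clipped to
  zero and renormalized.
* [O₂] = 0 cleanly silences both superoxide modes (no 0/0 ambiguity).

## Known limitations

* The Rieske protein and cytochrome c1 are not occupiable centers; the
  high-potential chain is lumped into the Q_p oxidation step.
* Binding constants are apparent, aqueous-phase values; no membrane
  partitioning is modeled.
* With the shipped analog constants, the Q_n-site enzyme–substrate
  fraction is ~1e-8 at micromolar pools, so under near-fully-reduced
  analog conditions the uninhibited complex loads to E4 and its turnover
  runs through the superoxide-coupled edges rather than the Q_n cycle;
  cytochrome c reduction and superoxide production then scale together.
  Consequences visible in the acceptance checks: the singly-inhibited
  dimer accelerates cytochrome c reduction ~1.9× but superoxide by the
  same factor, the population-maximum stimulation is ~1.35×, the
  antimycin-saturated superoxide peak sits at ~54% oxidized, and E5
  reaches ~1.4% in the extreme high-Δψ, 98%-reduced corner of the native
  surface. These are properties of this formulation with these constants,
  not tuned outcomes.
* Pre-steady-state kinetics and single-molecule trajectories are out of
  scope (a jump simulation exists only as a test oracle).
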