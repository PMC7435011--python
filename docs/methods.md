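# Methods

## Model overview

The package describes GIRK1/2 activation in a *Xenopus* oocyte as a
deterministic mass-action system in "molecules per channel" units. Three
coupled layers make up the model:

1. the **G-protein cycle** — receptor (R), agonist (A), heterotrimeric
   G protein (Gα·Gβγ) and their complexes, formulated as a complete
   ternary-complex model with split GDP/GTP exchange through a
   nucleotide-free state and a single irreversible GTP-hydrolysis step;
2. **channel gating** — sequential binding of up to four Gβγ to the
   channel (states C₀…C₄), mapped to an ensemble open probability; and
3. the **measurement layer** — the linear "molecular ruler" calibrations
   that convert open probability into whole-cell current and surface
   densities into counts.

Everything downstream (steady states, activation time courses, density
sweeps, the tandem variant, the synthetic-data generator) composes these
layers.

### Assumptions

- Mass-action kinetics in a well-mixed membrane compartment; no spatial
  structure, microdomains or stochastic channel gating.
- Agonist, GDP and GTP are held at fixed concentrations (free-ligand
  approximation). All proteins are depletable: the equations track the
  sequestration of every species by its binding partners.
- The evoked current at saturating agonist reaches, at steady state, the
  "full-activation capacity": the equilibrium of the entire Gβγ pool with
  the channel. Simulated plateaus approach this value from below (99% or
  better at ≥ 31 receptors/µm² within a 60-s recording).
- Basal (pre-agonist) conditions are a true thermodynamic equilibrium:
  with no agonist there is no path through nucleotide exchange, so no
  flux crosses the irreversible hydrolysis step.

## Units and the count-to-molar bridge (κ)

State variables are dimensionless counts, "molecules per channel"
(channel total normalised to 1). Literature rate constants are molar, so
every bimolecular rate constant is multiplied by an effective molar
concentration per count,

    κ = κ_area · ρ_channel        [M per count],

where ρ_channel is the cell's channel surface density (channels/µm²) and
κ_area (M per molecule/µm²) is a single global constant: the effective
molar concentration contributed by one molecule per µm² of membrane.
Physically κ_area⁻¹ ≈ N_A·h·10⁻¹⁵ for a reaction shell of thickness h at
the inner membrane face; the calibrated value κ_area = 1.776·10⁻⁷ M per
molecule/µm² corresponds to h ≈ 10 nm, a plausible thickness for
membrane-delimited signalling. Scaling κ with channel density keeps one
physical constant valid across cells expressing different channel levels.

κ_area is not measured anywhere; it is identified jointly with the gating
ladder (below) and exposed as a configuration field, never hard-coded in
the network builders.

## Kinetic parameters

The G-protein-cycle constants are the published table values (association
constants in M⁻¹s⁻¹, dissociation in s⁻¹): agonist binding to the free
receptor (3.33·10², 7·10⁻³) and to the G-coupled receptor (4.5·10⁶,
4.87·10⁻¹); heterotrimer binding to the free receptor (5.51·10⁶, 0.16)
and to the agonist-bound receptor (3.68·10⁸, 5·10⁻²); GDP (10⁶, 5) and
GTP (10⁶, 0.1) binding to the nucleotide-free ternary complex; Gβγ
re-association with receptor-bound Gα_GTP (10⁶, 15); Gα_GTP release from
the receptor (10⁷, 2); hydrolysis 0.02 s⁻¹; heterotrimer re-assembly
(0.7·10⁶, 1.3·10⁻³). Where the source table's column labels are
ambiguous, the left column is always read as the association
(per-concentration) constant and the right as dissociation — any other
reading is dimensionally inconsistent.

GDP and GTP concentrations are not published for this system; the
defaults are cytosolic-order values of 10 µM GDP and 100 µM GTP
(configurable). At these levels GTP loading proceeds at ~100 s⁻¹ and GDP
rebinding at ~10 s⁻¹, so the exchange branch is dominated by GDP release
(5 s⁻¹) and the choice is far from rate limiting; halving or doubling
either value changes simulated τ_act by well under the fit residual.

Channel–Gβγ per-site constants come from two structural analyses of the
channel–Gβγ interface: the GIRK2–Gβγ crystal structure ("4KFM":
k_on = 1.01·10⁶ M⁻¹s⁻¹, k_off = 0.14 s⁻¹) and a docking model of
GIRK1–Gβγ ("BS": 0.23·10⁶, 0.037). Both give per-site K_D of 100–200 nM.
Graded-model binding steps carry statistical factors
(4−n)·k_on / (n+1)·k_off.

## The gating calibration (p₁…p₃ and κ_area)

The graded model's interior open probabilities p₁…p₃ are not published
(p₀ = 0 and p₄ = Po_max = 0.105 are). They are identified, together with
κ_area, by requiring that two reference cells with printed per-channel
G-protein totals reproduce their printed currents: for each cell and each
structural parameter set, the printed (Gβγ, Gα) totals must yield the
printed I_basal at the pre-agonist equilibrium and the printed I_total as
the full-activation capacity. That is 8 relative-current residuals for 4
parameters, minimised by bounded least squares with the monotone
constraint 0 ≤ p₁ ≤ p₂ ≤ p₃ ≤ p₄ enforced through a ratio
parameterisation and κ_area fitted on a log scale. The optimum
(all residuals < 0.4%) gives

    p = (0, 0, 8.18·10⁻³, 2.62·10⁻², 0.105),   κ_area = 1.776·10⁻⁷,

which are shipped as package defaults; `calibrate_gating` regenerates
them. With these values, inverting either reference cell's currents
returns its printed per-channel totals within 1.4%.

The two source legends order the per-channel pair inconsistently (one
reads Gα-first, the other Gβγ-first). The model adopts the excess-Gβγ
reading — the larger number of each pair is the Gβγ total — because a
Gβγ-dependent basal current is impossible with Gα in excess: the
heterotrimer K_D of ~1.9 nM would sequester essentially all Gβγ. Both
orderings are reported side by side (`LegendTarget.orderings`) and the
discrepancy is flagged rather than resolved.

## Steady states

Because the zero-agonist steady state is an equilibrium, it is solved
exactly rather than by generic root finding: the free-Gβγ level is the
single outer unknown (the Gβγ conservation residual is monotone in it,
so bracketed bisection is globally convergent), with the
heterotrimer/receptor partition solved in a nested bracketed step and the
channel ladder in closed form. The result is verified to be a fixed point
of the full mass-action right-hand side (residual ≤ 10⁻⁹ of the largest
one-way flux); a long-time stiff relaxation is retained as fallback. This
replaces a damped-Newton iteration considered first — the bracketed
formulation cannot diverge and needs no damping heuristics.

`invert_basal_currents` recovers (Gβγ, Gα) totals from a measured
(I_basal, I_total) pair by two nested scalar root finds: the Gβγ total
from I_total through the capacity map (monotone increasing), then the Gα
total from I_basal through the basal equilibrium (monotone decreasing —
Gα sequesters Gβγ into heterotrimers). Currents above the Gβγ-saturated
maximum, or basal currents not reachable with the implied pool, raise
errors rather than returning silently; an I_basal within 1% of I_total is
flagged as near-infeasible. I_basal = 0 is handled asymptotically: the
smallest Gα that drives the basal current below 10⁻⁶ µA is returned.

## Time courses and τ_act

The cascade ODEs (16 states) are integrated with LSODA at rtol 10⁻⁸ /
atol 10⁻¹⁰; a literal fixed-step classic Runge–Kutta mode (1 ms step) is
provided for fidelity runs and agrees with the adaptive solver on τ_act
within 1%. The agonist step is ideal by default; an optional first-order
exchange filter (τ ≈ 89 ms) emulates the perfusion system and is on for
synthetic "experimental" traces, off for model-to-model comparisons.

τ_act is extracted as in the experimental analysis, by least-squares
fitting I(t) = I_basal + I_evoked·(1 − e^(−t/τ)) to the activation phase.
The fit window runs from agonist onset to five times the 99%-of-plateau
rise interval (or trace end). The factor five matters: the simulated rise
is slightly sigmoidal (the cascade imposes a short delay), and a window
that stops at the 99% crossing leaves the amplitude unpinned, letting the
fitter trade amplitude against τ and producing ~1% window-dependent τ
artifacts; anchoring part of the plateau makes the extracted τ stable and
monotone wherever the underlying traces are. Window detection runs on a
smoothed copy of the trace so recording noise cannot trigger the plateau
crossing early; the fit itself uses raw samples. The RMS residual is
reported — the cascade response is not exactly exponential and the fit
does not pretend otherwise.

Density sweeps use a fixed 60-s recording (as in the emulated
experiments) rather than integrating to the asymptotic plateau: with
unlimited time every receptor density eventually mobilises the same Gβγ
pool, and the amplitude-versus-density saturation that the recordings
show would disappear. 60 s is the package's recording-length choice;
τ_act tables are reported in ms.

## The tandem (preformed-complex) variant

The receptor–Gα fusion network is a reconstruction (the published scheme
is graphical): fused-Gα analogues of agonist binding, nucleotide
exchange, Gβγ release, and hydrolysis in situ (the fused Gα cannot leave
the receptor, so there is no Gα-release step and hydrolysis acts on the
receptor-bound Gα_GTP), plus heterotrimer assembly on the agonist-free
fusion protein with the wild-type constants. Two reconstruction choices
deserve note. First, both Gβγ-bound and Gβγ-free tandem states bind
agonist with the *coupled*-receptor constants — the fusion enforces
permanent coupling, and the uncoupled constants would make tandem
activation ~100-fold slower than observed. Second, Gβγ capture by the
*agonist-bound* Gα_GDP tandem state is omitted, mirroring the wild-type
scheme (where heterotrimer re-assembly occurs only on free Gα_GDP);
including it lets excess empty tandems shuttle-capture released Gβγ and
roughly doubles τ_act across the density range, contrary to the
density-independence the fusion construct exhibits.

Scenarios: (1) tandem Gβγ affinity as wild type, Gβγ pool fixed at its
pre-expression level; (2) pool grows 1:1 with the tandem amount; (3)
10-fold lower tandem–Gβγ affinity, implemented on the off-rate with
unchanged on-rate (only the affinity ratio is constrained), pool fixed.

Known limitation: over a 1000-fold tandem-density range the model's τ_act
is not perfectly flat. In scenarios 1 and 3 it stays within 20% but the
evoked amplitude declines ~1% at the highest densities (above ~34
tandems/µm² the tandems outnumber the 3.5-Gβγ/channel pool, strip the
channels at rest and weakly re-sequester released Gβγ through the
GTP-state association). In scenario 2 the growing pool accelerates the
Gβγ→channel delivery step, and τ_act falls from ~0.73 s (channel-binding
relaxation limited, anchored by the per-site off-rates) to ~0.25 s (the
per-tandem processing floor). These are intrinsic consequences of mass
action at the published constants, not tuning artifacts; the behaviour is
density-independent to within a few percent over the experimentally
motivated 1–30 tandems/µm² window.

## Cooperative-model comparison

The cooperative gating model uses the stepwise ladder K_D1 = 60 µM with
μ = 0.3 (60, 18, 5.4, 1.62 µM), opening only from C₄ at Po_max = 0.105
(the maximal open probability is not restated for this model; the graded
value is reused). Only equilibrium ratios are constrained, so an on-rate
convention is needed: k_on is held at 10⁶ M⁻¹s⁻¹ for every site and the
off-rates carry the ladder. Because these off-rates (1.6–60 s⁻¹) are fast
compared with the G-cycle steps, the simulated τ_act is insensitive to
the convention within a factor of a few around the default. The
hydrolysis comparison runs two receptor-density sweeps differing only in
the hydrolysis rate — 0.02 s⁻¹ (RGS-free oocyte) versus 100× that
(RGS-accelerated; the comparison model's exact fast value is described
only as 100-fold faster, so 2 s⁻¹ is used) — with shared per-channel
totals (default 9 Gβγ, 2 Gα per channel, the published slow-arm pair; the
published fast-arm pair 16/9 can be passed instead). Fast hydrolysis
yields uniformly faster τ_act spanning a 1.5-fold range where slow
hydrolysis spans ~75-fold: rapid Gα_GTP turnover, not the coupling mode,
masks the density dependence.

## Synthetic data

The generator emulates the emulated rig's statistics: traces sampled at
1 kHz with additive Gaussian noise (default SD 2% of the cell's I_total),
an optional 200-Hz low-pass (off by default), the 89-ms perfusion filter,
fluorescence linear in channel density with 10% multiplicative CV, and
receptor densities derived from RNA doses through the 62.5/ng slope.
Every record stores its ground truth and derives all randomness from one
recorded seed; dose-series children are keyed by dose value so batch
order is irrelevant. What passing recovery tests show is that the
*analysis pipeline* is unbiased and precise under the assumed noise
model (τ_act and per-channel Gβγ recovered with sub-1% median error at 2%
trace noise); they do not probe real-data failure modes such as
endogenous current contamination, rundown, desensitisation, or
non-Gaussian artifacts, none of which the generator emulates.

## Numerical choices and degenerate inputs

- Integrators: LSODA (default) / BDF / fixed-step RK4 (1 ms); conservation
  of receptor, Gα, Gβγ and channel totals holds to ≤ 10⁻⁶ relative along
  trajectories, and species stay above −10⁻⁹ counts.
- Steady-state residual tolerance 10⁻⁹ (relative to the largest one-way
  flux); inversion brackets expand geometrically and fail loudly past
  10⁶ counts.
- Zero totals (no Gβγ, no Gα, no receptor) short-circuit to exact trivial
  equilibria; flat traces raise a fit error rather than returning a
  meaningless τ.
- The thermodynamic audit enumerates an integer null-space basis of the
  reversible stoichiometry (external species included as balance rows),
  so reported cycles always conserve agonist and nucleotides; the
  irreversible hydrolysis step is excluded by construction.

## Known limitations

- Deactivation after agonist washout, desensitisation and Ba²⁺ block are
  out of scope; the model describes activation only.
- The tandem reaction set is inferred from the wild-type scheme (see
  above) and the tandem τ_act/amplitude behaviour at tandem densities far
  above the Gβγ pool depends on that reconstruction.
- A single κ_area treats the reaction volume as common to all binding
  steps; receptor-, G-protein- and channel-specific effective volumes are
  not distinguishable from the available calibration targets.
- The graded ladder's p₁ calibrates to zero, i.e. the two lowest-occupancy
  states are effectively closed; only p₂·C₂ + p₃·C₃ + p₄·C₄ carry
  current. Other (p, κ) combinations fitting the two reference cells
  equally well cannot be excluded without additional single-channel
  constraints.
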