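# Methods

## The model

`raftsignal` implements a compartmental, rule-based kinetic model of the
earliest events in FcεRI (high-affinity IgE receptor) signaling on
RBL-2H3 cells, extended with a two-compartment description of the plasma
membrane: an ordered **raft** compartment made of many identical transient
disks, and the remaining disordered **nonraft** membrane.

The chemistry is the classical membrane-proximal cascade:

1. Constitutive association of the Lyn kinase unique domain with the
   unphosphorylated receptor β-chain.
2. A bivalent ligand binds receptor α-chains and crosslinks receptors into
   dimers; a monovalent hapten competes for the same sites and breaks
   aggregates up.
3. Receptor-associated Lyn *trans*-phosphorylates the β and γ ITAMs of the
   partner receptor in a dimer (distinct rates for unique-domain-anchored
   and SH2-anchored Lyn).
4. Lyn SH2 binds phospho-β; Syk tandem-SH2 binds phospho-γ. A bound SH2
   domain occludes its phosphotyrosine from phosphatases ("protection by
   binding").
5. Receptor-bound Syk *trans*-autophosphorylates the activation loop of Syk
   on the partner receptor.
6. Receptor-bound Syk phosphorylates the scaffold LAT with effective
   Michaelis–Menten kinetics; Grb2 SH2 binds (and protects) phospho-LAT.
7. Every *naked* (unbound) phosphosite dephosphorylates at a base rate
   `k_dephos = 20 /s` (naked phosphotyrosine lifetime ≤ 0.05 s), scaled by
   the **protection factor α ∈ [0, 1]** inside rafts (α = 0: phosphatases
   fully excluded from rafts; α = 1: no protection). Lyn catalysis is
   five-fold slower outside rafts.

Membrane complexes carry a raft/nonraft location attribute and exchange
between the compartments as whole units: raft → nonraft at the raft
turnover rate `1/λ` (λ = raft lifetime, default 10 s) and nonraft → raft at
the class entry rate `k₊N` fixed by the equilibrium partition coefficient ρ
through `ρ = λ/(λ + 1/(k₊N))`. Partition classes, in precedence order:
ligand-crosslinked dimers (ρ = 0.85, extrapolated from Triton X-100
solubilization data), Lyn bound to a monomeric receptor (partitions as
Lyn), free Lyn and LAT (ρ = 0.85, palmitoylation-driven), monomeric
receptors (ρ = 0.30, the raft coverage — indifferent). Cytosolic binders
(Syk, Grb2) never change the class. A palmitoylation-site Lyn mutant
partitions at ρ = 0.06 and does not confer raft preference on a receptor it
is bound to.

Because the compartments are well mixed but unequal in area, bimolecular
membrane–membrane association is concentrated by co-confinement: rates are
scaled by the inverse area fraction (1/0.3 in rafts, 1/0.7 outside), and
the LAT Michaelis constant is scaled by the compartment's area fraction.
A configuration switch (`area_concentration_scaling`) disables this for
sensitivity checks.

## Network generation

Rules are expanded from seed species (free receptor, Lyn, Syk, LAT, Grb2,
bath ligand/hapten) to closure. Species are connected bond graphs with
per-site internal states; canonical labels are computed by brute-force
minimization over same-type molecule permutations and the ligand's arm
symmetry (complexes here never exceed a handful of molecules, so this is
exact and cheap). Statistical factors come from counting distinct rule
embeddings; isomorphic products are merged.

Two structural choices reproduce the published network size exactly
(348 species and 3,447 unidirectional reactions for the stimulation-phase
network; the hapten-extended network is 381/3,647):

- **Syk carries a single phosphosite** (the activation loop). The two-site
  base-model structure is available via `syk_linker_site: true`, but the
  one-site form is what the published species count implies:
  32 monomeric + 136 dimeric receptor complexes + free Lyn + 3 LAT states,
  ×2 locations, + 2 free Syk states + Grb2 + ligand = 348.
- **The LAT kinase pool is receptor-bound Syk** — any Syk engaged on
  phospho-γ, monomeric or aggregated receptor, regardless of activation
  state. This also explains the model's sensitivity of LAT
  dephosphorylation to the receptor–Syk off-rate: after hapten-induced
  disaggregation, monomer-bound Syk keeps phosphorylating LAT until it
  dissociates.

Extracellular species (ligand, hapten) are held at constant molar
concentration; their abundances multiply rate constants at compile time and
are never depleted.

## Simulation

The mass-action/Michaelis–Menten ODEs (~700 dynamic species for the
hapten network) are stiff — naked-phosphotyrosine turnover at 20 /s sits
next to ligand equilibration over minutes — and are integrated with BDF and
an analytic sparse Jacobian assembled from the reaction arrays (default
`rtol 1e-7`, `atol 1e-3` molecules/cell; abundances span 1–10⁶). Steady
state is declared when ‖dx/dt‖/‖x‖ < 10⁻⁸ /s, probed on geometrically
growing windows up to 10⁴ s; non-convergence is flagged, not raised.
Conservation of each protein total is preserved to better than 10⁻⁶
relative over full two-phase runs. Observables are fractions of each
protein phosphorylated (bound-and-phosphorylated counts as
phosphorylated); `fceri` pools the β and γ ITAMs.

## Transient-trap diffusion limit

The entry rate demanded by (ρ, λ) must not exceed what diffusion can
supply. The diffusion-limited capture rate for transient disk traps is
derived from the mean capture time of a diffuser in the annulus
`s ≤ r ≤ b` (absorbing at the raft edge `s`, reflecting at
`b = 1/√(πN)`), with trap renewal at rate `1/λ` relocating the diffuser
uniformly over the disk of radius `b` around the newly formed raft —
instant capture with probability `(s/b)²` (a raft forms around the
protein), otherwise a uniform restart in the annulus. The self-consistent
solution of the backward equation involves modified Bessel functions `I₀,
I₁, K₀, K₁` of argument `r/√(Dλ)` (exponentially scaled evaluations keep
short lifetimes stable), with `D = 10⁻⁸ cm²/s` — raft diffusion dominates
protein diffusion, so one limit serves all proteins. The closed form is
validated in the test suite against an independent finite-difference PDE
oracle (0.2% agreement) and against the analytic steady-trap limit as
λ → ∞. With the default geometry the minimum permissible lifetime for
ρ = 0.85 is 0.0161 s at 100 nm raft radius and 1.73 s at 1000 nm.

Note on the 1000 nm raft count: 30% coverage of an 8×10⁻⁶ cm² membrane
holds 76 one-micron disks, not the ~250 sometimes quoted — 250 such rafts
would cover nearly the whole membrane, and the published minimum-lifetime
values at that size only follow from N = 76.

## Parameters

Copy numbers are RBL-2H3 values: 4×10⁵ receptors, 2.8×10⁴ active Lyn
(limiting), 4×10⁵ Syk. Ligand/hapten binding uses hapten–antibody kinetics
(site on-rate 10⁸ /M/s, off-rates 0.5–1 /s, site K_D 5 nM): the fast bond
turnover is what makes hapten-induced receptor disaggregation, and hence
dephosphorylation, rapid. The receptor–Syk off-rate is 0.13 /s
(`faeder-default`) with a 0.20 /s variant (`reduced-syk-lifetime`, a 35%
shorter complex lifetime).

Constants that the source literature does not print (the LAT/Grb2 arm —
LAT and Grb2 copy numbers, the Syk→LAT kcat/K_M, Grb2 on/off — plus the
Lyn binding kinetics) were fixed once by requiring the model to reproduce
the published behavioural anchors: the ~5 nM crosslinking optimum, the ~6 s
β and ~11 s γ dephosphorylation half-lives, the steady-state
phosphorylation fold-changes between protection levels, and the
palmitoylation-mutation effect. Two constraints shaped the Lyn kinetics in
particular:

- The constitutive Lyn–receptor complex must outlive the raft exchange
  cycle (`kmL = 0.04 /s`), otherwise free Lyn's compartment distribution is
  slaved to its binding partners and Lyn's own partition coefficient —
  the entire lever of the palmitoylation-mutation experiment — becomes
  dynamically irrelevant.
- The published fold-changes and the published coincidence of β
  dephosphorylation curves across protection levels pull in opposite
  directions: the fold-changes require a phospho-β pool comparable to the
  Lyn pool, and Lyn exhaustion then makes the protected share of that pool
  α-dependent, which separates the normalized curves by ~0.1 at their
  steepest point. The shipped defaults favor the jointly-constrained
  optimum (fold-changes, half-lives and mutation effect); the residual
  curve separation is visible in the corresponding test.

All defaults live in `src/raftsignal/data/defaults.yaml` with units and
per-entry provenance notes; every value is overridable from a config file.

## Synthetic data

`generate_dephos_dataset` emulates hapten-inhibition immunoblot time
courses: the simulated normalized receptor and LAT curves sampled at
0–120 s (default ten timepoints) and multiplied by independent
lognormal mean-one factors (densitometry noise is ratio-scale; default
CV 0.10). What it does *not* emulate: correlated lane effects, baseline
subtraction artifacts, or saturation of the detection — recovery results
therefore speak to the identifiability of α under idealized noise, not to
any particular blotting protocol. `fit_alpha` mirrors the discrete
protection-level comparisons of the original analysis: a grid search over
α minimizing the pooled sum of squared residuals, with no continuous
optimizer and no uncertainty beyond the SSR profile. At CV 0.05 the true
α = 0.2 is recovered in ≥ 90% of seeded replicates against the grid
{0, 0.05, 0.1, 0.2, 0.5, 1}.

## Numerical and design notes

- Raft counts are rounded to the nearest integer; densities stay real.
- The minimum-lifetime root search runs on a log grid over
  λ ∈ [10⁻⁴, 10³] s with relative tolerance 10⁻⁴; if the demand never
  reaches the diffusion limit (weakly partitioning classes), the minimum is
  reported as 0 (no constraint).
- The α = 1 compartment-collapse equivalence holds exactly only when the
  split is dynamically neutral (every class partitioned at the raft
  coverage, confinement scaling on); with raft-philic classes,
  co-confinement genuinely concentrates reactants — by design, not error.
- Degenerate inputs: zero Lyn yields a valid model whose phospho-observables
  stay identically zero; normalizing a hapten time course with a zero
  initial phospho-pool raises a configuration error naming the observable.
- Half-lives are the first 0.5-crossing of the normalized curve with
  log-linear interpolation between grid points.

## Problem sizes

Default analyses run on one CPU in seconds to a few minutes: network
generation ~0.5 s; one steady state 1–3 s; one hapten time course ~1 s.
The test suite's heavier studies (α-grids of hapten curves, 50-replicate
recovery) reuse session-level caches of the simulated curves.

## Known limitations

- No receptor internalization or down-regulation: stimulated
  phosphorylation settles at an elevated steady state instead of adapting.
- Lyn activation-loop regulation is implicit (the fixed five-fold nonraft
  activity reduction); only the receptor-available active Lyn fraction is
  modelled.
- Aggregates are capped at dimers (bivalent ligand); no ligand-induced
  raft formation or coalescence; rafts are monodisperse disks; the
  simulation is deterministic (no stochastic fluctuations at
  few-molecules-per-raft occupancy).
- The LAT arm is a minimal scaffold (one tyrosine, single Grb2, no further
  downstream assembly).
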