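# Canonical parameter set for the raft-compartment FcERI signaling model.
#
# Units convention: copy numbers are molecules per cell; rate constants for
# membrane/cytosol bimolecular steps are per molecule per second (the model
# tracks amounts, not concentrations); bath ligand/hapten binding constants
# are per molar per second and bath concentrations are molar and constant
# (no depletion).  Sources: the base-model publication (Faeder et al. 2003,
# J Immunol 170:3769, "fceri_ji" parameterization) for everything inherited
# from it; RBL-2H3 measurements cited inline for raft geometry and
# partitioning; extension constants (LAT/Grb2 arm) are model estimates
# chosen to reproduce the published behaviour of the extended model, see
# docs/methods.md.

copy_numbers:
  rec_total:   {value: 4.0e+5, units: "molecules/cell", source: "RBL-2H3 FcERI surface count (base model)"}
  lyn_total:   {value: 2.8e+4, units: "molecules/cell", source: "active Lyn available to receptor, Wofsy et al. estimate"}
  syk_total:   {value: 4.0e+5, units: "molecules/cell", source: "Syk available to receptor (base model)"}
  lat_total:   {value: 2.5e+5, units: "molecules/cell", source: "model estimate, receptor-scale abundance"}
  grb2_total:  {value: 1.0e+6, units: "molecules/cell", source: "abundant cytosolic adaptor, model estimate"}

ligand:
  kp1: {value: 1.0e+8, units: "/M/s", source: "bivalent DNP-ligand on-rate per site (hapten-antibody scale); site KD 5 nM puts the crosslinking optimum near 5 nM"}
  km1: {value: 0.5, units: "/s",   source: "DNP-IgE bond off-rate; fast dissociation underlies rapid hapten-induced disaggregation"}
  kp2: {value: 2.5e-4, units: "/molecule/s", source: "2D crosslinking rate, base model (2.5e-1 per 1000 molecules/s)"}
  km2: {value: 0.5, units: "/s",   source: "crosslink dissociation; same DNP-IgE bond as km1"}

hapten:
  kon_hapten:  {value: 1.0e+7, units: "/M/s", source: "monovalent DCT hapten on-rate; at 100 uM the receptor occupancy is saturating and insensitive to this value"}
  koff_hapten: {value: 1.0,    units: "/s",   source: "DCT off-rate scale"}

lyn:
  kpL:  {value: 1.0e-7, units: "/molecule/s", source: "constitutive Lyn unique-domain association with unphosphorylated beta; slow turnover so the complex outlives raft exchange"}
  kmL:  {value: 0.04,   units: "/s", source: "constitutive-complex lifetime ~25 s, long against the raft exchange cycle; leaves roughly half of available Lyn receptor-associated"}
  kpLs: {value: 5.0e-5, units: "/molecule/s", source: "Lyn SH2 binding to phospho-beta (base model)"}
  kmLs: {value: 0.12,   units: "/s", source: "Lyn SH2 off-rate; sets the slow branch of hapten-inhibition beta decay (half-life ~5 s)"}
  lyn_nonraft_activity_factor: {value: 0.2, units: "dimensionless", source: "five-fold reduced Lyn kinase activity outside rafts (Young et al.)"}

syk:
  kpS: {value: 2.5e-5, units: "/molecule/s", source: "Syk tandem-SH2 binding to phospho-gamma"}
  syk_off_rate: {value: 0.13, units: "/s", source: "receptor-Syk dissociation, base model; 0.20 in the reduced-Syk-lifetime variant (35% shorter complex lifetime)"}

transphosphorylation:
  pLb:  {value: 3.5,   units: "/s", source: "constitutive-Lyn -> partner beta"}
  pLbs: {value: 7.0,  units: "/s", source: "SH2-anchored Lyn -> partner beta (enhanced over constitutive)"}
  pLg:  {value: 1.0,   units: "/s", source: "constitutive-Lyn -> partner gamma (base model)"}
  pLgs: {value: 3.0,   units: "/s", source: "SH2-anchored Lyn -> partner gamma (base model)"}
  pLS:  {value: 30.0,  units: "/s", source: "Lyn -> Syk linker on partner receptor (base model; used only when syk_linker_site is enabled)"}
  pLSs: {value: 100.0, units: "/s", source: "SH2-anchored Lyn -> Syk linker (base model; linker variant only)"}
  pSS:  {value: 100.0, units: "/s", source: "Syk -> partner Syk activation loop (base model)"}
  pSSs: {value: 200.0, units: "/s", source: "activated Syk -> partner Syk activation loop (base model)"}

dephosphorylation:
  k_dephos: {value: 20.0, units: "/s", source: "naked ITAM phosphotyrosine mean lifetime 0.05 s or less (base-model estimate); nonraft base rate"}
  k_dephos_cytosol: {value: 20.0, units: "/s", source: "cytosolic phosphatase rate on free Syk (base model)"}
  alpha: {value: 0.2, units: "dimensionless", source: "ratio of raft to nonraft dephosphorylation rate; 0 = absolute protection, 1 = none"}

lat_arm:
  kcat_syk_lat: {value: 0.5, units: "/s", source: "Michaelis-Menten turnover of receptor-bound Syk on LAT; extension estimate"}
  km_syk_lat:   {value: 1.0e+5, units: "molecules/cell", source: "Michaelis constant, whole-membrane equivalent; extension estimate"}
  kpG: {value: 1.7e-6, units: "/molecule/s", source: "Grb2 SH2 on phospho-LAT; ~1e6 /M/s at ~1 pL cytosol"}
  kmG: {value: 0.2,    units: "/s", source: "Grb2 SH2 off-rate; SH2-phosphopeptide scale, extension estimate"}

partitioning:
  rho_monomer: {value: 0.30, units: "fraction", source: "unaggregated FcERI indifferent to rafts: raft fraction equals raft coverage"}
  rho_dimer:   {value: 0.85, units: "fraction", source: "aggregated FcERI, extrapolating Triton X-100 solubilization (65.6% at 0.06%, 52.9% at 0.1% detergent) to zero detergent"}
  rho_lyn:     {value: 0.85, units: "fraction", source: "wild-type palmitoylated Lyn; 0.32/0.06 (WT/palmitoylation mutant) in the exogenous-expression experiment"}
  rho_lat:     {value: 0.85, units: "fraction", source: "dually palmitoylated LAT, as Lyn and aggregated receptor"}

raft:
  raft_radius:  {value: 1.0e-5, units: "cm", source: "100 nm raft disk radius"}
  coverage:     {value: 0.30,   units: "fraction", source: "raft compartment occupies ~30% of the RBL plasma membrane"}
  cell_area:    {value: 8.0e-6, units: "cm^2", source: "RBL-2H3 surface area; gives ~8,000 rafts at 100 nm and 30% coverage"}
  raft_lifetime: {value: 10.0,  units: "s", source: "mean raft lifetime; reported range milliseconds to minutes"}
  diffusion_coefficient: {value: 1.0e-8, units: "cm^2/s", source: "raft diffusion coefficient (Pralle et al.); dominates protein diffusion"}

model_flags:
  syk_linker_site: {value: false, units: "bool", source: "single activation-loop phosphosite on Syk reproduces the published network size; enable for the two-site base-model structure"}
  area_concentration_scaling: {value: true, units: "bool", source: "scale membrane-membrane association by 1/area-fraction (co-confinement concentrates reactants)"}
  lyn_palmitoylation_mutant: {value: false, units: "bool", source: "mutant Lyn partitions at rho 0.06 and does not confer raft preference on bound monomeric receptor"}
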