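# Model and methods

`tumorcpm` simulates avascular and vascular tumor growth, tumor-induced
angiogenesis, and the response to chemotherapy and targeted therapy in a
three-dimensional multiscale framework.  This note records the model, its
assumptions, the parameters that matter, the numerical choices, and the
known limitations — at the level of detail a user needs to judge what a
simulation result does and does not show.

## Intracellular scale: the Boolean signalling network

Each cell carries a Boolean network of 39 nodes: six external
receptor/suppressor inputs (integrin, RTK, E-cadherin, Wnt, APC, NF1),
29 internal effectors spanning the Ras–ERK, PI3K–Akt and Wnt/β-catenin
pathways, and four output nodes read as the phenotype code (cell growth,
proliferation, apoptosis, migration).  The rule table ships as a TSV
resource (`data/signaling_rules.tsv`); rules are AND/OR/NOT expressions of
parent nodes.

* **Update scheme.** Synchronous updates with the six external inputs held
  frozen.  With frozen inputs the internal wiring is acyclic, so every
  trajectory reaches a unique fixed point; empirically the longest
  convergence takes ~12 updates.  An asynchronous random-order mode exists
  (`step_async`) for robustness exploration only.
* **Attractor readout.** For a fixed point the four output bits are read
  directly; for a limit cycle a bit is ON only if ON in every cycle state
  (strict-AND).  The conservative readout matters only in principle — the
  shipped network produces fixed points.
* **Reachable phenotypes.** Over all 2^6 input configurations and sampled
  initial internal states, exactly four codes occur: 1100 (growth +
  proliferation), 1101 (+ migration), 0010 and 0011 (apoptosis, the latter
  a readout variant with the migration bit set).  The map is a pure
  function of the six input bits; `input_output_map` asserts this by
  sampling.  The ensemble census (`robustness_scan`) packs 64 trajectories
  per machine word, which makes 10^5-sample censuses take seconds and the
  exhaustive 2^29 enumeration feasible in chunks (guarded by default).
* **β-catenin rule.** The printed dependence ("Wnt Or Akt And Not cadherin
  And Not APC") is parenthesised as (Wnt ∨ Akt) ∧ ¬cadherin ∧ ¬APC, the
  reading consistent with the migratory attractor appearing exactly when
  cadherin is lost.

## Cellular scale: the Potts model

Cells are voxel domains on a 3D lattice (4 µm voxels; the reference domain
is 150×150×200 ≙ 600×600×800 µm³).  The effective energy sums four terms:

* **Adhesion** `Σ J(τ,τ′)(1−δ_{σσ′})` over neighbouring voxel pairs of
  different cells; the type matrix J is the calibrated table (EC–EC 5,
  EC–tumor 30, tumor–tumor 8, tumor–necrotic 10, cell–medium 10–12,
  medium–medium 6).  The medium–medium entry is ambiguous in its printed
  source (6 vs 66); it never enters the dynamics (a single medium entity)
  and is config-exposed.
* **Growth** `Σ γ_e (v − V_T)²` with per-type elasticity (proliferating
  and migrating 8, quiescent 2, EC 0.8).
* **Continuity**: a cell must remain one face-connected component.  The
  printed Kronecker form is degenerate as written; it is operationalised as
  (a) a hard guard in the dynamics — copy attempts that would locally
  disconnect the losing cell are rejected via a 3×3×3 simple-point check —
  plus (b) a penalty α = 300 per fragmented cell in the energy audit and
  the brute-force Hamiltonian used by the oracle tests.
* **Chemotaxis**: for a copy attempt by a motile cell, χ·(C(target) −
  C(source)) is added to ΔH (standard copy-attempt contract; χ ≤ 0).
  Migrating tumor cells read the nutrient field; activated endothelial
  cells read VEGF.  Because this term is a drive rather than a state
  function, the brute-force Hamiltonian excludes it and its contract is
  tested separately in closed form.

Dynamics: per Monte Carlo step (MCS), as many random voxel copy attempts
as lattice sites; ΔH ≤ 0 accepted, else accepted with probability
e^(−ΔH/T_m), T_m = 10.  One MCS represents one minute of real time at the
reference clock.

**Effective chemotaxis weights.** The catalogue potentials (χ ≈ −1.5×10⁶)
act, in their native units, on concentration differences many orders of
magnitude below the pg/voxel field scale used here; applied literally they
overwhelm every other term and destroy volume control.  The dynamics
therefore use calibrated effective weights (`chi_m` = −10, `chi_ec` =
−2000 by default) chosen so a typical near-tumor gradient contributes
O(10) energy units — the same order as T_m — preserving the intended
drift.  The catalogue values remain available as constants for the
unit-contract API (`chemotaxis_delta`).

**Growth and division.** A licensed cycling cell raises its target volume
at a rate that doubles the 64-voxel initial volume in one cell-cycle time
(24 h, the fastest cycle), saturating at 2× the initial volume.  When the
*actual* volume reaches 2× the initial volume the cell divides along a
random plane through its centroid (median split, ties to the parent; a
post-split sweep re-unites stray fragments).  The parent's target resets
to the initial volume; the daughter inherits type and target under a new
id.  Cell-cycle licensing requires the proliferation phenotype *and* an
active E-cadherin input (junction contact ≥ T_Cadherin): proliferation
depends on the binding of adhesive proteins, which is what makes freshly
seeded, dissociated cells pause until they have aggregated (the slow first
growth phase).  The licensing gate is config-exposed
(`proliferation_requires_cadherin`).

## Extracellular scale: transport fields

Three scalar fields on the cell lattice (canonical unit pg/voxel):
nutrient n (D = 10³ µm²/s), VEGF V (D = 10 µm²/s, decay 0.9375 h⁻¹), drug
c (D = 1.5×10³ µm²/s, decay half-life 6 h — no tabulated value exists;
config-exposed).  Uptake terms are piecewise per the governing equations:
linear in the local concentration below a per-voxel cap, capped above it,
zero outside the consuming cell type (tumor cells for nutrient, ECs for
VEGF, proliferative tumor cells for drug).  Sources: vessels supply
nutrient (the vessel-surface condition is implemented as a Dirichlet clamp
of EC voxels at n₀ = 4.6 pg/voxel); hypoxic tumor voxels secrete VEGF at
s_V = 0.035 pg/voxel per reference MCS ("hypoxic" = quiescent or necrotic
by default, restrictable by flag); vessels release drug while an infusion
window is active.

**Unit bridges.** The physical parameter table mixes mol/cell/s rates with
pg/pixel concentrations and thresholds.  Two explicit conversion constants
bridge them, both logged in run configs:

* `mol_to_pg` (nutrient; default 1.2×10²⁰ pg/mol together with a linear
  uptake coefficient of 100 s⁻¹) is calibrated so that nutrient
  concentration falls below the RTK threshold (4.48×10⁻³ pg/voxel, three
  orders below the supply level) within a few cell layers of consuming
  tissue.  That short penetration depth is what the published
  threshold-to-supply ratio implies, and it is what produces a hypoxic,
  VEGF-secreting core at the tens-of-micrometre scale and growth arrest at
  the ~150 µm scale.
* `drug_mol_to_pg` (default 2.5×10¹³ pg/mol, linear uptake coefficient
  10⁻⁵ s⁻¹) keeps therapeutic concentrations in the dose-proportional
  uptake regime below the κ_P cap, so cumulative exposure separates the
  dose arms.  Drug doses share no physical unit link with nutrient
  turnover, hence the separate bridge.

**Numerics.** The nutrient field is quasi-steady relative to the MCS clock
and is relaxed each step by explicit FTCS sub-steps at the stability limit
(D·Δt/Δx² ≤ 1/6), warm-started from the previous step, stopping at a
relative-change tolerance or a sub-step cap.  Decay is applied as an exact
exponential factor per sub-step (operator splitting), so a decay-only
field follows V₀e^(−kt) to round-off.  No-flux faces use clamped ghosts,
which makes pure diffusion conserve mass to round-off.  VEGF and drug
evolve on the minutes-to-hours scale of one MCS; they take one
unconditionally stable backward-Euler step per MCS (matrix-free conjugate
gradient on the 7-point Laplacian, warm-started), with capped uptake
applied explicitly and clamped so no voxel is overdrawn.  Uptake never
drives a concentration negative anywhere.

**Avascular culture mode.** For spheroid scenarios without vessels the
domain faces are clamped at n₀ (fresh medium outside).  A `culture` mode
also exists in which ECM voxels replenish toward n₀ at a finite rate,
emulating rate-limited perfusion; it is config-exposed but not the fixture
default.

## Cell-state coupling

Per MCS and per cell: E-cadherin is ON when the boundary fraction touching
other viable tumor cells reaches T_Cadherin = 0.3; integrin is ON when the
ECM-contact fraction reaches T_ITG = 0.3; Wnt is ON when the cadherin
contact fraction falls below T_Wnt = 0.15 (Wnt signalling is licensed by
cadherin loss); RTK is ON when the mean nutrient over the cell reaches
T_RTK (quiescent cells need the higher T_RTK_Q = 2×T_RTK to re-enter the
cycle — hysteresis).  The exact quantity these thresholds act on is not
fixed by their source; the contact-fraction reading is a design choice and
is config-exposed.

The network phenotype governs cycling cells: 1100 → proliferative; 1101 →
migrating (nutrient chemotaxis); 0010/0011 → apoptosis (target volume 0,
removal on shrink-out — interior cells that lose all ECM contact die this
way, a detachment-death channel that continuously turns over the deep
interior).  Nutrient starvation acts through a separate state machine that
takes precedence over the network for survival decisions: RTK loss sends
P/M cells to quiescence (not apoptosis); sustained hypoxia (τ_N = 2 days)
leads to necrosis; necrotic cells are absorbing and are cleared (shrunk
away) after τ_clear = 3 days.  Neither τ has a tabulated value; both are
config-exposed.  A quiescent cell that is re-fed above T_RTK_Q re-enters
the cycle.

Endothelial cells activate when their mean VEGF reaches T_v = 9.5×10⁻⁴
pg/voxel; activation is sticky and makes the cell tip-capable (VEGF
chemotaxis).  VE-cadherin contact inhibition suppresses stalk growth: an
activated EC may proliferate only while its EC–EC boundary fraction is
below θ_VE.  The default θ_VE = 0.25 separates tip segments (~0.15
junction fraction in the discretised vessel geometry) from mid-vessel
stalk segments (~0.30); the published default of 0.65 never binds for this
geometry.  θ_VE ≥ 1 disables inhibition (degenerate configuration).

## Therapy

**Chemotherapy.** Doses are per body-surface area and map linearly onto
the vascular source interval (5 µg/m² → 2.55×10⁻¹⁶, 10 µg/m² → 5.1×10⁻¹⁶
mol/cell/s); each cycle infuses for 24 h from the cycle start (the window
length is a design choice; its source is silent).  Only
proliferative/migrating cells take drug up, so hypoxic quiescent cells are
transiently protected — they become vulnerable after re-entering the cycle
when rim death restores their nutrient supply.  Cumulative uptake above
θ₁ forces mitotic arrest (drug-induced quiescence); above θ₂ the cell is
directly necrotic; an arrested cell progresses to necrosis after a delay
(2 days by default) even without further uptake, reflecting that the
damage is committed.  θ₁ = 17 and θ₂ = 42 (internal exposure units) were
calibrated once by the committed procedure in
`scripts/calibrate_kill_thresholds.py`: θ₁ sits at the 90th percentile of
per-cell exposure under the low 5 µg/m² dose, so the low dose arrests only
the most exposed decile (treatment failure) while the two-fold higher
exposure at 10 µg/m² drives the arrest→death cascade through the whole
population (eradication).

**Targeted therapy.** Receptor blockade forces the listed inputs (RTK,
integrin, E-cadherin and/or Wnt) OFF in every tumor cell's network
evaluation during the block window; no pharmacokinetics is modelled.
Blocking RTK or integrin lands every cell in the apoptosis attractor
within one re-evaluation cycle.  Cells caught mid-shrink when a block is
lifted re-establish their homeostatic target volume and regrow.

**FKC.** The fraction of killed cells, FKC(t) = therapy-attributable
deaths up to t over (viable cells at therapy start + births since),
clamped to [0,1].  On a well-mixed toy population with constant kill
hazard it tracks 1 − e^(−kt); this closed form is the sanity oracle.

**Outcome classes** from the daily trace: eradicated (no viable tumor
cells), dormant (volume within ±20 % of the post-therapy nadir for ≥30
days), relapse (regrowth past the pre-therapy volume after a nadir),
failure (monotone growth through therapy).

## Scaled study conditions

Full-scale runs (150×150×200, 1 MCS = 1 min, multi-week courses) are
multi-hour computations.  The test fixtures scale two things and nothing
else: the lattice (50³ avascular spheroid; 28³ vascularized tumor with a
regular plexus of straight vessels) and the clock (1 MCS = 1 h via
`minutes_per_mcs`, with the growth schedule, state-machine clocks and PDE
step sizes all tied to the same clock).  The spheroid fixture seeds ~35
dissociated 64-voxel cells that must aggregate before cycling, emulating
how a spheroid culture is started; its growth course shows the
slow–fast–decelerating phase structure, and it decelerates toward a
stationary size (~100 µm here) that is reproducible across seeds, with
the hypoxic VEGF-secreting core forming first.  True arrest at the 150 µm
diameter of the full-scale setting, and angiogenesis onset near day 33,
belong to the full-scale geometry and are not asserted by the scaled
tests.

## What the synthetic data does not show

All inputs are synthetic: the vessel plexus is an idealised regular array
(its published counterpart specifies only "regular structure"), the
spheroid is seeded from identical 64-voxel cells, and no experimental
growth-curve or histology data enters the pipeline.  Passing tests
demonstrate internal consistency — energy bookkeeping, transport closed
forms, the signalling map, and the qualitative ordering of therapeutic
outcomes — not quantitative agreement with any measured tumor.  Cell-size
dispersion, vessel remodelling and blood flow, interstitial pressure,
immune response and resistance evolution are all outside the model.

## Numerical and degenerate-input choices

* Explicit FTCS sub-steps use a 0.9 safety factor on the stability limit;
  requesting an unstable step raises an error carrying the required
  sub-step count.
* The implicit transport solve uses CG with rtol 10⁻⁶, warm-started from
  the previous field; non-convergence raises rather than silently
  continuing.
* Ties in the division plane go to the parent; a 1-voxel cell defers
  division; removing the last voxel of a cell deletes it from the
  registry.
* A zero-dose chemotherapy protocol (and a targeted protocol with an empty
  block set) is normalised to the null protocol, making such runs bitwise
  identical to untreated runs at equal seed.
* The run stops cleanly with an `overflow` flag when the main tumor mass
  (largest face-connected component) reaches a domain face; stray single
  migrating cells at the wall do not end the run.
* Growth-phase segmentation fits a continuous 3-segment piecewise-linear
  model to log-volume by least squares over a breakpoint grid, requiring
  at least 4 samples per segment; a constant trace yields zero slopes.

## Known limitations

* The chemotaxis magnitudes and the two unit bridges are calibrated, not
  derived; they are single config entries and every run records them.
* The compressed clock (1 MCS = 1 h) under-resolves membrane fluctuation
  dynamics relative to the reference clock; interface roughness and cell
  shapes are correspondingly coarser in scaled runs.
* Cumulative drug exposure is tallied once per MCS from the quasi-static
  field, a first-order approximation of the continuous uptake integral;
  the kill thresholds are calibrated under the same approximation.
* The Q→P re-entry hysteresis uses a threshold ratio of 2 with no
  independent source; oscillatory P↔Q churn at the hypoxic boundary is
  damped but not eliminated.
* The sensitivity statement that a low cadherin threshold (< 0.2) fully
  inhibits proliferation is not reproduced: under the junction-licensing
  reading implemented here, a lower threshold makes licensing easier, not
  harder.  No single-threshold reading we found satisfies both that
  statement and the phenotype map; the map took precedence.
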