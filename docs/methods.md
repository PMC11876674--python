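# Methods

## Model structure and assumptions

The simulator couples four layers, integrated as one deterministic ODE
system per treatment arm:

1. **Plasma PK.** Each agent follows a one-compartment model with
   first-order absorption (`ka`, 1/h) and elimination (`ke`, 1/h) and an
   apparent distribution volume per kg body weight (`V/F`, L/kg). Doses are
   mg/kg, so body weight cancels analytically. The concentration after a
   full schedule is the linear superposition of single-dose curves; it is
   evaluated in closed form (including the i.v.-bolus `ka → ∞` and
   flip-flop `ka = ke` limits), not integrated numerically. Drug binding
   and tumour penetration are not modelled separately; they are implicit in
   the effect potencies.

2. **Effect compartments.** Every pharmacodynamic action is mediated by a
   level `X` obeying `dX/dt = u_x C(t) − Cl_x X`. Because the effect
   clearances (0.15–0.45/h here) are slower than drug elimination, effects
   outlast exposure — the mechanism by which intermittent regimens (e.g.
   one week on / one week off) retain activity between dosing blocks.
   Effects start at zero (treatment-naïve animals).

3. **DDR damage system.** SSB and DSB are population-average levels (in
   arbitrary damage units, DAU) over the proliferating cells — scalar
   states, not per-cohort quantities. Phase-restricted actions are gated
   continuously by occupancy: the ATRi SSB effect and the SSB→DSB
   conversion by the current S-phase fraction of live proliferating cells,
   the checkpoint override by the S+G2+M fraction. Each damage species has
   two parallel repair pathways (PARP- and ATR-mediated), each scaled by
   `σ(I) = e^−I/(1+e^−I)` of its inhibitory effect and by `1 − def_i` for
   its genetic deficiency. `σ(0) = 1/2` makes the two intact pathways sum
   to the baseline rate and caps single-pathway disruption at 50% — the
   structural source of synthetic lethality. `def4` (HR deficiency) acts
   through the whole cycle, on the rationale that HR-deficient cells route
   damage into error-prone alternatives regardless of phase.

4. **Virtual tumour.** A sphere with a proliferating shell of fixed
   thickness and a quiescent/necrotic core. Proliferating cells traverse
   G1→S→G2→M as chains of first-order sub-compartments (3 per phase),
   doubling at mitotic exit. Immediate death removes live cells to a dead
   pool; delayed death commits them to "doomed" cohorts that keep cycling
   and die at their n_gen-th division (default 3, configurable 1–5). Cells
   in excess of the shell's geometric capacity — live and doomed alike —
   are drafted (proportionally from G1) into quiescence and re-enter G1 if
   the tumour shrinks; quiescent cells neither cycle nor take damage flux,
   and cannot be killed. Dead material clears at a first-order rate, so
   regression is gradual. Volume = all cell-equivalents / packing density.

Immediate and delayed death act as additive, competing hazards on live
proliferating cells; whether they compete or act on disjoint subpopulations
is not observable at the TGI level, and additive hazards are the neutral
choice.

## Cell-cycle rate calibration

For a cyclic chain with stage rates `k_j` and doubling at mitosis, the
Malthusian rate λ solves `∏_j (1 + λ/k_j) = 2`. Setting
`k_j = n_sub/(f_phase · t_doub)` (mean transit time = `t_doub`) yields a
population doubling time ~3% *shorter* than `t_doub` (for 12 equal stages,
`λ = 12(2^{1/12} − 1)/t_doub` vs `ln 2/t_doub`). All stage rates are
therefore rescaled by a single factor, solved at construction, so the
asymptotic doubling time equals `t_doub` exactly; the steady stage
occupancy (used for initial conditions and the gating fractions) is the
corresponding balanced-growth eigenvector.

## Parameters

Tumour- and drug-level parameters with a calibrated provenance: `t_doub`
(27–34 h across the HBCx-9 studies), `r_ssb = 5e-4 DAU/h`, `def4`
(10–30% in HBCx-9; >0.8 for BRCA-mutant panel members), and the mechanism
blocks for rucaparib (`i_p_ssb = i_p_dsb = 5`, `i_p_fork = 0.5`,
`cl_p = 0.15`, `cl_p_fork = 0.45`), talazoparib (100, 170, same
clearances) and gartisertib (`i_a_ssb = 7`, `i_a_dsb = i_a_ssb/2`,
`o_a = 20`, `cl_a = 0.15`). The PARPi SSB/DSB potencies are tied, and the
ATRi DSB potency is half its SSB potency (ATM partially backs up DSB repair
under ATR loss); both couplings are overridable defaults.

The remaining rate constants are **synthetic defaults**, chosen once so the
model's qualitative regimes match the biology the parameters encode, and
marked as such in the code:

| parameter | default | rationale |
|---|---|---|
| `r_dsb` | 1e-6 DAU/h | endogenous DSB rare vs SSB |
| `r_conv` | 0.005 /h | baseline S-phase conversion small |
| `rep_ssb` | 0.5 /h | SSB repair fast vs generation (SSB* ≈ 1e-3 DAU) |
| `rep_dsb` | 1.0 /h | vehicle DSB* ≈ 3e-6 DAU; vehicle death hazard ≈ 1e-4/h, <0.5% of growth |
| `r_kill^(G1,S,G2,M)` | 10, 50, 25, 50 /DAU/h | replication/mitosis most vulnerable; scale set so def4 ≈ 0.9 under saturating PARPi gives hazard ≈ growth rate (regression), def4 ≈ 0.2 gives ≲15% growth inhibition |
| `r_delay_kill` | 0.01 /DAU/h | baseline delayed death minor without checkpoint override |
| shell thickness | 0.2 mm | vehicle 100 → ≈4000 mm³ over 6 weeks (surface-limited growth at realistic speed) |
| cell density | 1e6 /mm³ | standard 10⁹ cells/cm³ |
| dead-material clearance | 0.01 /h | regression over days, not hours |
| quiescence exchange | 0.2 /h | shell/core partition relaxes within a day |
| plasma PK (`ka`, `ke`, `V/F`) | per drug, see `DEFAULT_PK` | plausible mouse oral kinetics; **not** fitted values |

Because the PK parameters and the fixed rates above are synthetic, specific
published TGI curves are not quantitatively reproducible; the package's
validated claims are structural (the 50% repair cap, equation constants),
numerical (oracle agreement, exact doubling time) and ordinal (combination
≤ monotherapies, response monotone in potency and in def4, talazoparib
stronger than rucaparib at matched exposure).

## Numerics

Fixed-step classical RK4 on the coupled system, steps aligned to dose-event
kinks and observation days, `dt_max = 0.1 h` by default; the state is
clamped non-negative after each step and non-finite states raise with the
failure time. Concentrations enter the RHS analytically via a per-interval
two-exponential representation (exact, stable: only decaying exponentials).
Halving the step from 1.0 h to 0.5 h changes day-level volumes by <0.05%;
behavioural and sweep tests run at `dt_max = 0.5 h` with 21–28-day
horizons, which keeps a full arm simulation under ~0.5 s. Stability
requires `dt_max ≲ 2.8/k_max`; with default phase fractions the fastest
stage rate is ≈ 50/t_doub per hour, so 0.5 h is safe for `t_doub ≥ 15 h`.

The calibration objective is the RMSE of log10 volume over matched days,
averaged over arms (multiplicative error structure; arm means, not
animals). Optimisation is bounded trust-region least squares on the stacked
log-residual vector with seeded multistart; only tumour-side parameters can
be freed — drug parameters are structurally fixed. def1–def3 default to
zero and are freed only explicitly. Non-convergence flags the result rather
than raising.

## Synthetic-study generator

Emulates the design of preclinical TGI studies: arms of N = 7–9 animals,
28–42-day windows, a lognormal multiplier on each animal's doubling time
(ln-sd 0.10 — doubling time carries most within-arm variability),
multiplicative lognormal observation noise (0.05 log10 units by default),
and censoring of all records after the first measurement above a welfare
cap (2000 mm³). One seeded generator per study, animals drawn in fixed
order: a fixed seed is bit-reproducible. The generator does *not* emulate
real per-animal correlation structure beyond the shared growth-rate
multiplier, measurement-schedule irregularities, or post-washout
heterogeneity in regrowth — so passing recovery tests demonstrates the
fitting machinery under the stated noise model, not robustness to every
feature of real colony data.

## Known limitations

- Damage is population-averaged over proliferating cells; per-cohort damage
  (a documented alternative) would let recently born and long-damaged cells
  differ.
- Quiescent cells cannot be killed; treatment acts on the shell only.
- No acquired resistance, no ATM/DNA-PK signalling, no PARP-trapping
  species, no two-compartment or nonlinear PK, no mixed-effects population
  layer.
- The model targets the treatment window; post-treatment divergence
  (regrowth heterogeneity after washout) is expected and not modelled.
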