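# Methods

## Scope and model structure

`dsbfold` treats periplasmic oxidative folding in *E. coli* as a mass-action
reaction network driven by a constant substrate influx. Substrates are
grouped into three folding-difficulty categories by the relative position of
their bonded cysteines; each category i has pools UF_i (unfolded, reduced),
MFP_i (mis-oxidised) and FP_i (correctly folded). The enzyme moieties are
DsbA (oxidised/reduced), DsbB (oxidised/reduced), the pooled isomerases
DsbC+DsbG (reduced/oxidised) and DsbD (reduced/oxidised).

Reactions (rates per minute, concentrations in molecules per cell):

- R1_i: synthesis, d[UF_i]/dt += v_i (zeroth order).
- R2: DsbBr → DsbBo at k2·[DsbBr]. Quinone is a clamped boundary pool; its
  level is folded into k2, making the reaction pseudo-first-order.
- R3: DsbAr + DsbBo → DsbAo + DsbBr at k3·[DsbAr]·[DsbBo].
- R4/R5_i: UF_i + DsbAo → p_i FP_i + (1−p_i) MFP_i + DsbAr at
  k45_i·[UF_i]·[DsbAo], with p = 1.0, 0.5, 0.0 for cat1/2/3. The correct and
  incorrect oxidations share one rate constant; only the outcome split
  differs.
- R6/R7/R8_i: MFP_i + DsbCGr at k678_i·[MFP_i]·[DsbCGr], splitting into
  f_success → FP_i, f_futile → MFP_i (no net change), and f_reduce → UF_i
  with DsbCGr → DsbCGo. Only the reduction branch oxidises the isomerase;
  isomerisation itself is electron-neutral.
- R9: DsbCGo + DsbDr → DsbCGr + DsbDo at k9·[DsbCGo]·[DsbDr].
- R10: DsbDo → DsbDr at k10·[DsbDo] (thioredoxin clamped, as for R2).

No explicit enzyme–substrate complexes are modelled: the association
constants are apparent second-order constants, and saturation kinetics are
out of scope. The futile branch R7 is represented explicitly (rather than
rescaling k678) so that isomerase occupancy accounting includes it.

f_futile = 1/3 by assumption (a deliberately conservative futile-cycle
frequency); the remaining flux is split evenly, f_success = f_reduce = 1/3,
as nothing constrains the ratio — both are configurable.

### Numerical treatment

The four enzyme redox pairs are conserved moieties. The integrator works on
a reduced state containing one member of each pair (13 states for the native
model), reconstructing the partner as total − x on output, so the
conservation sums hold *exactly* (to floating round-off) on every trajectory
rather than to solver tolerance. Integration uses LSODA with rtol 1e-8
(1e-7 inside the inference loop, 1e-10 where tests compare against an
independent Euler integration) and an absolute tolerance scaled to the
largest pool. Steady states are located by a warm-up integration followed by
a Newton root solve on the reduced system without the (unboundedly growing)
FP pools; steady-state flux balances (R2 = R3 = ΣR4+R5 and
R8-reduce = R9 = R10) then hold to ~1e-14 relative.

## Units and conversions

Cell volume is estimated from growth rate with two linear regressions:
V[µm³] = 1.44·µ + 1.90 (calibrated 0.1–1.9 h⁻¹, used for coverage
evaluation) and V = 1.83·µ + 1.74 (calibrated 0.1–1.0 h⁻¹, used for
concentration conversion). Out-of-range growth rates warn rather than fail.
Copies per cell convert to molarity via copies/(N_A·V·f), where f is a
compartment fraction (default 1.0 whole-cell; 0.2 approximates the
periplasm). Which volume the 5–30 µM DsbA literature bracket refers to is
not settled; both conversions are exposed and neither is asserted as
canonical. Association constants convert between M⁻¹s⁻¹ and
(molecules/cell)⁻¹min⁻¹ through the same volume.

Proteome coverage compares reported total copies against density·V with a
configurable protein density, default 3.0×10⁶ proteins/µm³ — an
approximation of published whole-cell protein-count calculations. Proteomes
at or above 50% coverage pass (boundary inclusive); proteomes without a
reported growth rate cannot be evaluated and are excluded.

## Disulfide counting and classification

Bond evidence from multiple sources is merged on (protein, cys_a, cys_b)
with 1-based Uniprot residue numbering. Counting rules for quantitative
demand: alternative partners of one cysteine collapse to a single counted
bond — implemented as connected components of the intramolecular bond graph,
a conservative choice that matches all documented cases; a cysteine pairing
with its twin on another protein copy counts 0.5; bonds between different
proteins count 0. The maximum potential bond count of a sequence is
⌊#Cys/2⌋.

Per-bond categories: intermolecular (including self-pairs) → cat4; exactly
two cysteines on the protein → cat1; bonded cysteines adjacent in the sorted
list of all cysteine positions → cat2; otherwise cat3. "Consecutive" means
adjacent in that sorted list regardless of sequence distance. A protein with
several bonds takes its hardest non-cat4 category for demand accounting
(per-bond categories are retained). cat4 is tabulated but excluded from
kinetic demand.

One documented ambiguity: the source literature's periplasmic bond breakdown
(140 consecutive + 12 non-consecutive + 22 of a third kind out of 174) only
sums correctly if the third kind is *inter*molecular, although the
accompanying text says "intramolecular"; the package follows the arithmetic
reading.

The periplasmic restriction keeps proteins located "secreted" or "secreted
outer membrane"; proteins absent from the location table are dropped by
default (a keep-with-warning mode exists). Folding demand multiplies each
protein's bond count by its copies per cell and sums per category.

## Membrane-enzyme estimation

DsbB and DsbD are chronically under-reported in proteomics. Their abundance
is estimated from ribosome-footprint synthesis rates assuming a shared
abundance/synthesis ratio across Dsb proteins: the ratio is computed for
anchor enzymes (DsbA and DsbG by default; DsbC can be added), aggregated by
arithmetic mean (geometric mean optional; whether the original analysis
averaged or regressed is unknown, so both exist and the mean is default),
and applied to the membrane enzymes' synthesis rates. Measured values are
never overwritten unless forced, and estimates whose anchor ratios spread
more than twofold are flagged high-variance.

## Viability criteria and minimal-rate inference

A condition is *feasible* under a parameter set if a simulation starting
with empty substrate pools and fully active enzymes satisfies, over one
reported doubling time t_d = ln2/µ:

1. accumulation ≤ 0.5% per substrate species: (UF_i + MFP_i at t_d) divided
   by cumulative synthesis v_i·t_d (an alternative normalisation by the
   standing pool N_i = v_i/µ is available as a config switch; cumulative
   synthesis is the default);
2. doubling time ≤ 1.05·t_d, where the theoretical doubling time is when
   cumulative FP output reaches ln2·N — the amount a steady-state cell
   synthesises per doubling period under dilution-balance influx v = µN.
   This convention makes the unconstrained limit equal the reported doubling
   time exactly.

Substrates start at zero rather than at a steady-state pool: a steady-state
initial condition would depend on the candidate parameters under test and
would contaminate the accumulation metric at t = 0; the zero start is
conservative and makes the metric well defined.

The minimal-rate search runs in two deterministic phases between zero and a
biochemical ceiling (default 10⁶ M⁻¹s⁻¹ for association constants, converted
at the periplasmic volume; 6×10³ min⁻¹ for the first-order constants):

1. each of the nine rate constants is bisected to 1% relative tolerance with
   all others held at the ceiling, yielding the minimal requirement each
   reaction imposes *given full support from the rest of the network* — a
   bound that no feasible parameter set can undercut, and therefore provably
   ≤ any true parameter set;
2. the vector of minima is scaled up uniformly (log-bisection on the scale
   factor, capped at the ceilings) until joint feasibility is restored.

A sequential coordinate-descent schedule was rejected: minimising k2 first
hands its entire slack to the DsbB pool, after which the required k3 inflates
by orders of magnitude (the oxidised-DsbB fraction collapses), producing
"minimal" constants above plausible true values and making the result depend
on cycle order. The two-phase schedule is restart-stable, order-free, and
keeps every reported constant interpretable as (scaled) per-reaction minimal
requirement. Reactions that are individually dispensable over one doubling
time — e.g. isomerase regeneration when the standing DsbC/DsbG pool already
covers a full generation of reduction flux — legitimately infer to ~0.

Pseudo-first-order rates multiply each association constant by its partner
pool: R3 uses total DsbB, R4/R5 total DsbA, R6–8 the pooled DsbC+DsbG; R2 is
already first-order. Rate-table summaries use linear-interpolation quartiles
(type-7), which the inter-quartile fold row depends on.

## Recombinant capacity

The recombinant substrate joins the network as a fourth substrate class
sharing its category's rate constants and correct-fold probability, with
enzyme levels and rate constants frozen (no regulatory adaptation). Its
synthesis rate is bisected (1% relative tolerance, upper bound 10× the
cell's total protein synthesis rate) to the largest value at which every
*native* species stays within the 0.5% accumulation threshold; whether the
recombinant's own backlog also counts is configurable and off by default.
Results are percentages of total protein synthesis µ·N_total, so values
above 100% are meaningful. A condition already at threshold reports zero
capacity, flagged rather than silent. Note that conditions parameterised at
their *inferred minimal* constants sit at the accumulation boundary by
construction and have essentially no headroom; meaningful capacity estimates
use the condition's actual (provided) constants.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of its spec (seed included); per-stage RNG
substreams keep outputs stable under call reordering. Defaults, chosen once:

- 2000 background proteins with log-normal abundances (σ = 2.0 natural-log),
  rescaled so total copies equal density·V(µ) exactly — generated proteomes
  pass the coverage filter by construction unless the low-coverage variant
  (45% of total) is requested; growth rates 0.1–1.9 h⁻¹ (default 0.7).
- Dsb enzymes injected at mean literature ppm (DsbA 696, DsbB 139, DsbC 144,
  DsbD 29, DsbG 27) with 15% log-normal jitter between conditions.
- 80 disulfide proteins, category mix 2/3 : 7/30 : 1/10 (cat1/2/3) plus 5%
  intermolecular, 90% periplasmic; cysteine counts 2–6. The disulfide
  sub-proteome is rescaled so abundance-weighted bonds total 0.3% of all
  protein copies — the absolute periplasmic bond count is not published, and
  this scale reproduces the observed regime where Dsb substrate flux is a
  small fraction of total synthesis and minimal pseudo-first-order rates
  land near 0.1–100 min⁻¹.
- Three evidence pseudo-sources observe each bond independently with a
  logistic detection probability in log10 abundance (midpoint 100 copies,
  max 0.95), echoing the better cross-study agreement for abundant proteins.
- Ground-truth rate constants are analytic minimal scales (flux divided by
  the relevant pool products or backlog caps) times per-parameter margins
  drawn log-uniformly from 30–180×, the bracket implied by comparing minimal
  de novo folding rates (~1 min⁻¹) with measured DsbA kinetics (0.5–3 s⁻¹).
  Every emitted condition is verified feasible under its own rates by
  simulation before use.

The generator does not emulate measurement noise on abundances, shared-cell
covariance between enzymes and growth rate, protein turnover (the influx is
dilution-only), or realistic cysteine spacing statistics. Passing tests
therefore demonstrate correctness of the computational machinery and the
stated invariants on data of realistic shape and scale — not that the
specific published per-condition rate values would be recovered from the
original proteomes, which ship with neither the package nor the annotation
supplement.

## Problem sizes

The test suite runs 20 seeded ground-truth conditions through generation,
inference, re-simulation, conservation, flux-balance and capacity checks;
the acceptance script uses a 10-condition panel. These sizes give stable
pass/fail behaviour for every property tested while keeping a full run in
the minutes range.

## Known limitations

- Apparent constants are lower bounds on biochemical constants; they are not
  fits to kinetic assay data.
- No thermodynamics/redox potentials, no chaperone activity, no sulfenic-acid
  chemistry, no Sec-translocon limits, no saturation kinetics.
- The isomerase pool merges DsbC and DsbG despite their different substrate
  specificities.
- Pseudo-first-order R3 uses the total DsbB pool; the instantaneous oxidised
  fraction varies along trajectories.
- The connected-component bond-counting rule undercounts proteins whose
  bond graph contains chains admitting multiple simultaneous disulfides.
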