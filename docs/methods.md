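# Methods

## The circuit model

The cross-antagonism-with-autoregulation (CAA) motif couples two
transcription factors, A and B. Each factor activates its own promoter and
represses the promoter of the other, so the circuit behaves as a
decision-making element: committed states have one factor high and the
other silenced. The implementation follows the two-reporter yeast
realization of the motif, in which A and B are TetR-derived
activator/repressor pairs reading tetO operator arrays and the two sides
are carried on separately integrating plasmids, so each side has its own
gene dosage (promoter copy number).

Each side `i` of the reaction network consists of:

* an aggregate three-state promoter counter over the `copies_i` gene
  copies: free, activator-bound, repressor-bound (states sum to `copies_i`
  at all times — conservation is enforced by the stoichiometry);
* mRNA and protein as separate species, so transcription and translation
  have independent rates and lifetimes.

Reactions per side (opposite side `j`): activator binding at
`k_act_on * free * P_i(P_i-1)/2`, repressor binding at
`k_rep_on * free * P_j(P_j-1)/2`, the reverse unbindings at `k_*_off`,
transcription at `alpha_active`, `alpha_basal`, or `alpha_repressed` per
promoter copy depending on its state, translation at `beta` per mRNA, and
first-order decay `delta_m`, `delta_p`. Binding is non-sequestering
(protein is not consumed by occupancy; protein counts exceed promoter
copies by two orders of magnitude in every regime of interest).

**Dimeric binding.** The binding propensities are driven by the dimer pair
count `P(P-1)/2`, not the monomer count. This is both the biology (TetR
family factors dimerize through a dedicated dimerization domain and bind
operator DNA only as dimers) and a structural requirement: with monomeric
(first-order) binding the mean-field steady-state conditions reduce to two
conics in the (P_A, P_B) plane, which can intersect in at most four
points, while a tristable phase (three stable states plus the two
separating saddles) needs five. A Hill-coefficient-2 binding law is the
minimal scheme that admits the tristable regime the motif is known for.

**Bursting.** Promoter switching is slow relative to transcription
(`k_act_off = k_rep_off = 1/h` against `alpha_active = 60 mRNA/h`), so
active periods emit bursts of mRNA. This ordering is what lets single-copy
circuits commit stochastically to exclusive states well before the
deterministic dynamics would.

### Default parameter sets

Units are per hour; the time horizon default is 16 h, matching the
experimental endpoint the analysis emulates. The defaults were chosen by a
grid search over (alpha_basal, K_act, K_rep) constrained to the bursting
ordering, requiring the strong set to be mean-field tristable and the weak
set monostable; they were frozen before any downstream result was
computed.

| parameter | strong | weak | meaning |
|---|---|---|---|
| `copies_A`, `copies_B` | 1 | 1 | promoter copies per side |
| `k_act_on` | 5e-4 | 5e-4 | activator binding, per dimer pair |
| `k_act_off` | 1.0 | 1.0 | activator unbinding |
| `k_rep_on` | 1e-4 | 2.5e-5 | repressor binding |
| `k_rep_off` | 1.0 | 5.0 | repressor unbinding |
| `alpha_active` | 60 | 60 | mRNA/h per activator-bound copy |
| `alpha_basal` | 6 | 6 | mRNA/h per free copy |
| `alpha_repressed` | 0 | 1.8 | mRNA/h per repressor-bound copy |
| `beta` | 10 | 10 | protein per mRNA per hour |
| `delta_m` | 3 | 3 | mRNA decay (half-life ~14 min) |
| `delta_p` | 0.7 | 0.7 | protein decay/dilution (half-life ~1 h) |

Equivalently `K_act = 2000` dimer pairs (half-activation near P = 63) and
`K_rep = 1e4` (strong) or `2e5` (weak). "Strong" repression silences a
bound promoter completely (`alpha_repressed = 0`, slow unbinding — the
recruitment-style repressor); "weak" repression is steric occlusion with a
30% leak relative to basal and 20-fold weaker binding.

## Mean-field analysis

Promoter occupancies equilibrate in the deterministic limit, giving a
4-dimensional field in (mRNA_A, P_A, mRNA_B, P_B) with occupancy
fractions proportional to (1, pair(P_i)/K_act, pair(P_j)/K_rep). The
stochastic model deliberately violates this quasi-equilibrium (that is
where bursting comes from); the mean-field reduction is used only for the
fixed-point structure, which is insensitive to the switching timescales.

Fixed points are found by a multi-start root search (scipy's MINPACK
hybrid method) from a log-spaced grid of protein levels (default 50+
starts covering 0.1 to three times the maximal expression scale), merged
at relative tolerance 1e-6, accepted at residual norm 1e-8, and classified
by the numerically-differenced Jacobian (stable iff max Re eigenvalue
< -1e-9). With the strong defaults this yields five fixed points: two
exclusive stable states at (P_A, P_B) = (272.5, 6.6) and (6.6, 272.5), a
stable symmetric intermediate at (225.1, 225.1), and the two saddles
between them. The weak defaults yield a single stable state at
(269.8, 269.8). Interpolating the repression parameters from the strong to
the weak set (log-linear in the binding rates, linear in the leak)
collapses the count monotonically 3 -> 1 with no reentrant tristability.

## Stochastic engine

Exact direct-method SSA (no tau-leaping; the state space is at most ten
species). The inner loop is numba-compiled; randomness is the Mersenne
Twister as exposed by numba's `np.random`, seeded explicitly per run, so a
(network, initial state, horizon, seed) tuple is bit-reproducible across
platforms. Ensemble runs use seeds `base_seed + i`, making every member
individually re-runnable. Endpoints are the state at `t_end` (last event
carried forward), not time averages; a warning is emitted when `t_end`
falls below `10/min(delta_m, delta_p)`.

## Dosage sweep

Endpoint ensembles over a grid of copy-number pairs, classified into
quadrants against per-channel thresholds. Thresholds are self-calibrated
as the geometric mean of the highest and lowest stable fixed-point protein
levels (strong defaults: theta = 42.5); for monostable parameter sets the
fallback is ten times the basal protein level. Cross-mode comparisons
(weak vs strong) share the strong-derived thresholds so that "high" means
the same expression level in both sweeps — a common quadrant definition,
as when pie charts for all conditions share axes. Exact threshold equality
counts as high.

The headline behavior at 1000 runs/cell, 16 h: the double-high fraction
rises monotonically along the (c, c) diagonal (~11% at single copy to
~71% at five copies), the summed exclusive fraction falls (~87% to ~29%),
and weak repression at single copy is double-high biased (~72%) relative
to strong (~11%). The mechanism is averaging over promoter copies: a side
with one promoter is silenced whenever that single promoter is
repressor-bound, while five copies are essentially never all bound at
once.

## Multi-operator promoters

An m-site tetO array is modelled as m independent, identical operator
sites, each unbound / activator-bound / repressor-bound (3^m
configurations; the occupancy class (n_act, n_rep) is multinomial in the
per-site probabilities). No cooperativity is assumed between the tandem
repeats.

The observation this module formalizes is qualitative — few operator
sites make the promoter switch-like, many make it graded — so the
activity function is configurable, with a documented default family:

    activity = alpha_repressed * (n_rep/m)
             + [alpha_basal + (alpha_active - alpha_basal) * n_act/m]
               * [(1 - n_rep/m)(1 - s) + s * 1{n_rep = 0}]

`s` interpolates graded repression (s = 0: each bound repressor removes
its share) to dominant repression (s = 1: any bound repressor silences).
At m = 1 the family reduces exactly to the three aggregate promoter-state
rates for every s.

**Default dominance s = 0.5, and how "graded" is measured.** Two
operational signatures are used: (i) the normalized configurational
variance of activity at balanced concentrations, which decreases strictly
in m for s <= 0.5 (the averaging effect proper) but *increases* in m at
s = 1, where a single repressor silences all m sites at once; and (ii) the
maximum slope of expected activity along the repressor-competition
dose-response — activator pinned at its binding scale, repressor swept,
slope taken against log(act/rep) — which is smaller at m = 7 than at
m = 2 for s = 0.5. The symmetric scan (both species varied against each
other) is *not* a usable signature: for independent identical sites the
expected activity is a multinomially-smoothed version of its large-m
limit, and since the smoothing weakens as m grows, its maximum slope is
non-decreasing in m for every activity function of the occupancy fractions
(verified numerically across six families). The graded-vs-switch-like
contrast is therefore a statement about fluctuations and about near-balance
repressor competition, not about the symmetric mean dose-response; the
defaults are the point of the family where both signatures hold.

An opt-in network variant (`build_multisite_network`) drives transcription
directly by the closed-form expected activity of the occupancy model
(promoter configurations treated as equilibrated), replacing the
aggregate three-state promoter in the SSA.

## Profile clustering

The flow pipeline consumes pre-gated per-event (GFP, mCherry) tables, one
per clone. Steps and defaults, each configurable where the upstream
protocol is unstated:

* **Trim**: rank-based per-channel outlier removal at the 0.5/99.5
  percentiles; an event must survive on both channels. Rank-based
  trimming makes the removed count exactly computable and ties
  deterministic.
* **Axes**: log10 transform (flow fluorescence spans decades) with a floor
  clamp at 1 a.u.; global ranges from the pooled 0.1-99.9 percentiles so
  all profiles share one grid.
* **Bin**: equal-width n x n histogram, half-open bins with the last bin
  closed, out-of-range events clamped to edge bins; n = 10 for clustering,
  n = 100 for density plots; grids normalized to unit mass so every clone
  carries the same weight.
* **Distance**: Manhattan (L1) between grids; disjoint normalized
  profiles saturate at distance 2.
* **PAM**: hand-implemented BUILD + SWAP with best-improvement swaps and
  lowest-index tie-breaking, so results are deterministic (the seed
  argument exists for interface compatibility and is never consulted).
  On small instances drawn like the pipeline's own data, PAM attains the
  exhaustive-minimum medoid cost essentially always; on structureless
  uniform point clouds any swap-based local search (including the
  reference R implementation) can stall in local optima.
* **Model selection**: mean silhouette over a (n, k) grid; singleton
  clusters score 0; identical-profile datasets are flagged degenerate.
* **Masks**: per-cluster unweighted mean of member grids.

## Synthetic data

The experimental flow and dPCR raw data are not publicly deposited, so the
generators emulate the statistical structure the analysis assumes. Clone
profiles are mixtures of up to four log-normal populations at the
canonical quadrant centers (10^2 and 10^4 a.u. for low/high, sd 0.15
log10 units, 20,000 events/clone by default). Archetypes are the 15
non-empty presence/absence patterns of the four populations, single
populations first; beyond 15, weight-skewed variants of the
multi-population patterns keep layouts distinct. Per-clone jitter moves
population centers to emulate clone-to-clone variation in state placement.
The generators do **not** emulate instrument effects — spillover,
autofluorescence, doublets, acquisition drift — so pipeline recovery on
synthetic data demonstrates the statistical machinery, not robustness to
flow artifacts. dPCR counts are binomial draws at Poisson positive
probabilities with a known true copy ratio (reference occupancy 0.3,
20,000 partitions by default).

## Digital PCR

Copies per genome = lambda_target / lambda_reference x reference copies,
with lambda = -ln(1 - positive fraction) and the reference defaulting to a
single-copy gene in a haploid host. The 95% CI is the delta method applied
on the log-ratio scale (log-normal interval): closed-form, positive by
construction, and with empirical coverage ~94-95% (never observed below
90%) for occupancies in [0.05, 1.5] at 5,000+ partitions. Saturated
measurements raise; all-negative targets return a zero estimate with a
zero-width interval and a warning.

## Problem sizes and numerical conventions

Simulation endpoints use the 16 h horizon with all-promoters-free,
zero-expression initial conditions (the induction-release protocol the
model emulates; neither is externally specified, so both are documented
package defaults). The shipped analyses use 1000 runs per sweep cell; the
clustering benchmark uses 4 archetypes x 25 clones at 2,000 events per
clone over 20 seeds (the generator default of 20,000 events per clone is
kept for data emulation; recovery is already exact at 2,000); dPCR
coverage uses 200 replicate assays per copy number at 20,000 partitions.
Root-finding tolerances, merge radii and stability thresholds are module
constants stated above. Known limitations: the aggregate promoter treats
gene copies as indistinguishable (exact for mass-action propensities);
the mean-field reduction ignores bursting by construction; silhouette
model selection is a heuristic and inherits its known bias toward
well-separated, equal-size clusters.
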