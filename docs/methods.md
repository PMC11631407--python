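# Methods

## The refuge model

The deterministic core is a logistic growth model with an explicit mixing
rate,

    dN/dt = N [ (R + μ)(1 − N/q) − s(1 + μ) ],

where `N` is population density (CFU/ml in the experimental mapping), `R`
the nutrient-driven growth rate, `s` the stressor-induced mortality rate,
`μ ≥ 0` the mixing rate (0 = static, 1 = fully mixed; treated as continuous
and configurable), and `q > 0` the competition/capacity scale. Mixing
enters twice, with opposite sign: it adds to the growth term (nutrient
circulation) and multiplies the mortality term (loss of spatial refuges).
The model is mean-field — refuges are not resolved spatially, only their
aggregate effect through `μ`.

Rearranged, the model is logistic with intrinsic rate
`r = R + μ − s(1 + μ)` and carrying capacity `K = q·r/(R + μ)`, so all
analysis is closed-form: the interior equilibrium is `N* = K`, the
eigenvalue at extinction is `r` and at the interior state exactly `−r`
(mutually exclusive stability), and the persistence boundary is
`R = μ(s − 1) + s`. Units of `R`, `s`, `μ` are arbitrary; only the
dimensionless structure matters for the phase diagram.

**Boundary convention.** `r = 0` is classified *extinct*: the neutral case
has no stable interior equilibrium. Phase-diagram cells are evaluated at
the supplied grid points; points exactly on a boundary take the
extinct-side label.

**Integration.** `integrate_ode` uses adaptive Runge–Kutta (scipy RK45)
with relative tolerance 1e-8 and absolute tolerance `1e-12·q`; callers
needing deep-decay accuracy (densities near the absolute tolerance) can
tighten both. Negative excursions are clipped to zero, with a warning when
they exceed ten times the absolute tolerance.

**Structural variants.** Two alternative forms probe robustness of the
persistence structure and are reconstructions of a verbal argument, not
transcriptions: `capacity_mixing` moves nutrients/mixing into the capacity
term, `dN/dt = N[R(1 − N/(q(1+μ))) − s(1+μ)]`; `growth_stressor` lets the
stressor divide growth instead of adding mortality,
`dN/dt = N(R+μ)(1−N/q)/(1+s(1+μ)) − δN`, with a baseline turnover `δ`
(default 0). With `δ = 0` that variant persists for every `s` — there is no
extinction threshold — so the unique-monotone-threshold property is
exercised at `δ = 0.5`. Thresholds are located by bisection on the sign of
the per-capita growth rate evaluated at `N = 1e-9·q`, which shifts the root
by O(1e-9) relative to the `N → 0⁺` limit.

## The serial-transfer simulator

Each replicate is a 200 µl well inoculated at 1e4 CFU/ml and propagated
for 20 daily cycles. The cycle is: deterministic within-day growth under
the model (per-genotype, with a shared competition bracket — total density
against `q`); Poisson seeding of resistant mutants with mean `u` times the
net wild-type divisions of the day; a binomial bottleneck at the transfer
dilution (1%); and, on sampling days, Poisson plating. Demographic noise
within the day is neglected deliberately: at the densities involved
(≥ 1e4 cells between bottlenecks) it is dwarfed by the three modelled
stochastic steps. Counts are 64-bit integers; the deterministic growth
endpoint is rounded half-to-even before any stochastic draw, and with
noise disabled the simulator reduces exactly to iterated
integrate-then-dilute cycles.

**Extinction as observation.** A population is called extinct when three
undiluted 20 µl plates all show zero colonies — a Poisson zero on 60 µl —
giving the operational detection limit 1/0.06 ≈ 16.7 CFU/ml. Extinction of
the underlying counts is absorbing.

**Resistance phenotype.** A resistant mutant experiences mortality
`min(s, s_resistant)` (resistance never hurts in benign media) and growth
`R(1 − cost)`. Evolutionary rescue is scored only when a replicate is alive
at the final transfer *with the resistant genotype at ≥ 50% frequency*;
survival of the wild type alone is ecological rescue. Rescue probabilities
carry Wilson binomial confidence intervals.

**Calibration.** The factor→rate mapping is a documented calibration chosen
so the eight design cells straddle the persistence boundary the way the
experimental density trajectories do; the constants are not measurements:

| factor | level | value |
|---|---|---|
| salinity | control / high | s = 0.2 / 1.8 |
| nutrients | high / low | R = 2.4 / 0.24 (1:10, mirroring the medium dilution) |
| mixing | static / shaken | μ = 0 / 1 |
| capacity | — | q = 1e9 CFU/ml |
| day length | — | 120 model time units per 24 h cycle |

With these values the low-density eigenvalue is positive in every
control-salinity cell and, among high-salinity cells, only in
high-nutrient/static (+0.6; shaken high-nutrient is −0.2, static
low-nutrient −1.56, shaken low-nutrient −2.36). Because the model's rates
carry arbitrary units, the within-day time span is a free unit choice;
120 units/day is the smallest round value at which the weakest persisting
cell (low-nutrient static control, r = 0.04) outgrows the hundredfold daily
dilution (`r·T > ln 100`). Random streams derive from one root seed via
`SeedSequence(seed, spawn_key=(treatment_index, replicate))`, so replicates
are reproducible independently of execution order.

The cumulative generation count of the protocol is
`n_transfers · log2(1/dilution)`; twenty 1% transfers give
20·log2(100) ≈ 132.9, conventionally rounded to 133.

## Fitness and community statistics

Relative fitness is the difference of Malthusian parameters,
`S = ln(evolved_end/evolved_start) − ln(ancestor_end/ancestor_start)`;
zero and negative counts are rejected (detection-limit substitution is the
caller's decision, not silently applied). Phenotypes are standardized by
subtracting the relevant ancestor's mean.

PERMANOVA follows the distance-based one-way formulation: with
`SS_total = (1/n)Σ_{i<j} d²_ij` and `SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²_ij`,

    pseudo-F = [ (SS_total − SS_within)/(a − 1) ] / [ SS_within/(n − a) ].

Only the one-factor design is supported. Sampled permutations draw labels
uniformly (group sizes preserved) and report `p = (count + 1)/(n_perm + 1)`
with default `n_perm = 9999` and an explicit seed; exhaustive mode
enumerates all distinct label assignments and reports the exact fraction
with the observed assignment included. Permuted statistics within 1e-12 of
the observed count as ≥ (ties favour the null). The Jaccard distance of two
all-zero profiles is 0 by convention (with a warning): clones with no
retained mutations are identical, not undefined. One-sample tests against
the ancestor baseline are thin wrappers over standard routines
(`scipy.stats.ttest_1samp`, Bonferroni via statsmodels), with an optional
sign-flip permutation alternative.

## GenomeDiff post-processing

The parser honours SNP/DEL/INS mutation lines of the GenomeDiff dialect
(tab-separated: type, id, parent-ids, seq_id, 1-based position, then the
type-specific field and `key=value` annotations `gene_name=`, `snp_type=`,
`evidence=`). Other line types are skipped with a warning. Evidence grades
(consensus/marginal/unassigned) ride on the mutation lines themselves.

Mutation identity for pooling and subtraction is
`(seq_id, position, mutation_class, allele_detail)` — mutation-level
semantics, so nearby-but-different coordinates are never merged. Ancestral
pooling takes the union over all ancestor clones *including* marginal and
unassigned entries (the point is masking lab-strain divergence and mapping
artefacts, so permissiveness is conservative). Subtraction drops every
occurrence of a pooled key in every evolved clone and is idempotent and
order-independent.

The spectrum counts *unique* retained mutations (a mutation shared by
several clones counts once); per-clone tallies use per-clone occurrences
and include zero-mutation clones from the roster. Percentages are rounded
half away from zero to one decimal; raw counts are emitted alongside
because one-decimal percentages of a denominator of 35 are lossy.
Unique-locus counts and the population×locus incidence matrix consider by
default only coding-disrupting records (non-synonymous and nonsense SNPs,
insertions, deletions); a flag includes synonymous/intergenic records. A
locus is a treatment-specific parallel target when its column sums to ≥ 2
over one treatment's populations and 0 over the other's.

## Synthetic data

The GenomeDiff fixture set is a deterministic constraint assembly: a
hand-designed allocation of abstract mutations to 6 ancestors and 36
evolved clones that satisfies, simultaneously, 78 unique evolved mutations,
43 pooled ancestral, 35 retained (11 deletions / 4 insertions / 20 SNPs;
15 non-synonymous, 1 synonymous, 3 intergenic, 1 nonsense), unique loci
5 (control) and 16 (high), PFLU_4551 mutated in 12 of 18 control clones
across 5 of 6 control populations and in no high clone, seven high clones
with zero retained mutations, and per-clone counts spanning 0–5 with
median 1. Naive random generation cannot hit these jointly, so randomness
is confined to nuisance fields (positions, alleles, locus names); the
seed changes bytes, never counts. Every written fixture is immediately
re-verified by the real pipeline; a mismatch raises with the failing
constraints listed. A published figure caption disagrees with the
accompanying text on the PFLU_4551 clone count (13/18 vs 12/18); the
fixture follows the text's 12/18.

Competition tables draw all four counts as Poisson around expectations
whose log-ratio difference equals the planted S (default ancestor growth
×100 from a start count of 1e5, where the log-Poisson bias ≈ 1/(2λ) is
negligible). OD tables plant a crossed evolution-history × assay-salinity
interaction with the (+, −, −, +) sign pattern (adapted to the salinity
evolved under, maladapted to the other; default effect 0.15 OD with
Gaussian noise 0.05, floored at 0). Motility tables shift designated
mutant clones on swarming only (default +8 mm on an ancestral 22 mm halo,
noise 1.5 mm).

What the generators do *not* emulate: genuine demographic noise within
growth cycles, linkage between mutations and the simulated phenotypes,
evidence lines or marginal-call structure of real variant callers,
clone-to-clone phenotype correlation beyond group means, and measurement
drift. Passing tests therefore demonstrate correctness of the analysis
machinery under the stated generative assumptions, not robustness to every
pathology of real data.

## Problem sizes and numerical checks

The heavy verification runs use: 100 random parameter draws for closed-form
oracle agreement (≤ 1e-6 relative error, solver tightened to rtol 1e-10 for
deep-decay draws); 10,000 draws for the classify-versus-ODE-fate dichotomy
(integrated to `t = 30/|r|` at rtol 1e-6, ample for a 1%-of-`N*` fate
call); 20 seeds of the full 8-cell × 6-replicate experiment for the
survival pattern (≥ 90% of seeds must match); 100,000 sampled permutations
against exhaustive enumeration on eight instances with n ≤ 7; 600
simulated null datasets (n = 12, 199 permutations) for type-I error; and
1,000 replicates per planted S ∈ {−0.5, 0, 0.5} for estimator recovery
(bias < 0.01 at counts ≥ 1e5). Parameter draws exclude |r| < 0.05: on the
boundary the fate is decided at infinite time and no finite integration
can classify it.

## Known limitations

* The model is mean-field; refuge geometry, biofilm dynamics and spatial
  gradients are compressed into `μ`.
* The calibration reproduces the qualitative survival pattern, not the
  experiment's absolute densities or extinction timing (simulated doomed
  cells die faster than real ones).
* The two-genotype rescue extension tracks a single resistant class; real
  rescue may be polygenic and involve standing variation.
* Multi-factor PERMANOVA designs, mixed-effects models and likelihood-ratio
  machinery are out of scope; standard statistics packages cover them.
* The GD dialect covers SNP/DEL/INS only; MOB/AMP/CON/INV lines are
  skipped (none occur in the retained set this package targets).
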