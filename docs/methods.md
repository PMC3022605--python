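# Methods

## The model

Two unlinked diploid loci are tracked.  The D locus is the ancestral
sex-determining locus: its two allele copies' summed steady-state expression
S_D sets phenotypic sex against the threshold theta.  The R locus carries a
potential upstream regulator: ancestral a (no regulatory domain, Z=0) and
mutant A (Z=1), which regulates exactly those D alleles that carry a matching
input site (m+, m-, f+, f- with I = +/-1 toward A; m and f have none).

Expression of allele copy i is the fixed point of
`S_i = sigma(sum_j I_ij Z_j S_j + k T_i)` with `sigma(x) = 1/(1+exp(-h x))`,
the sum running over all four allele copies of the genotype, so a homozygous
regulator contributes double dose (A/A shifts a regulated copy's input by
+/- 2 sigma(k T_A)).  For the feed-forward topologies used throughout (R
regulates D, nothing regulates R) the fixed point is closed-form: R copies sit
at sigma(k T), D copies at sigma(dose + k T).  A general damped fixed-point
solver (damping 0.5, tolerance 1e-12, cap 1e5 iterations, initial conditions
S_i(0) = sigma(k T_i)) handles arbitrary topologies including autoregulation;
on the feed-forward subclass it agrees with the closed forms to 1e-10 on a
50x50 (k, h) grid (tested).

Sex: the ancestral heterozygote (m/f) has S_D = sigma(k)+sigma(-k) = 1 and the
ancestral homozygote (f/f) 2 sigma(k); theta is their midpoint,
sigma(k) + 1/2.  The genotype on the high side of theta develops as the
homogametic sex; exact ties go to the heterogametic sex.  Under ancestral male
heterogamety this is literally "S_D > theta => female, otherwise male".

Fitness: viability `W = 1 + dS_D * w_sex`, where dS_D is measured against the
background genotype *of the same phenotypic sex* as the genotype under
evaluation (the two Table-style background genotypes have W = 1 exactly).  A
novel genotype whose sex has no distinct background under extreme parameters
never arises in practice because both backgrounds' sexes are verified before a
run (a contradiction marks the run degenerate-background).  With |w| < 1/2 and
|dS_D| < 2 every W is strictly positive.

## Ancestral female heterogamety

The main construction is XY-like (heterozygous males).  The ZW-like option
swaps the constitutive roles: heterozygous females carry the dominant
low-output allele (the f family takes T = -1, the m family T = +1) and males
are homozygous for the high allele, so the high-expression side of theta is
now male.  This is the only reading under which transitions of the
sex-determining locus occur for exactly the f+ and m- variant pairs, the
mirror image of f- and m+ under male heterogamety.  It makes every female-het
run the exact structural mirror of a male-het run of the letter-swapped pair
with w_M and w_F interchanged; the equivalence is implemented from first
principles and verified run-for-run in the tests rather than implemented via
the mapping.

## Population recursion

Infinite population, non-overlapping generations, fixed 1:1 sex ratio,
frequency-independent viability selection.  Order of events per generation:
juvenile frequencies x W renormalized within each sex (adults); sex-specific
gamete pools under free recombination; random union of gametes; threshold sex
assignment of each zygote genotype; renormalization of each sex to 1.
Convergence is `e(t) = max_G |p(t) - p(t-1)| < 1e-12` measured on within-sex
*adult* genotype frequencies (the post-selection quantities; measuring on
juvenile tables moves convergence by at most a generation, and the choice is
isolated in one place in the kernel).  Genotypes below 1e-15 are pruned each
generation - numerical hygiene far below the 0.1% classification threshold.

Mutants enter at 0.5% allele frequency = 1% genotype frequency of the
heterozygous carrier in the heterogametic sex.

### Acceleration

Runs near invasion boundaries or at large k (saturated sigmoids, effective
selection coefficients down to ~1e-10) genuinely need upwards of 1e9 plain
generations.  Rather than iterating a cap of 1e11 generations, the compiled
kernel applies safeguarded extrapolation at checkpoints every 64 iterations:

* exponential invasion of rare mutant-linked components: per-coordinate
  log-space fast-forward until the largest such component reaches ~10%,
  guarded by a sustained-growth test (decelerating growth means approach to an
  interior equilibrium and is never fast-forwarded);
* geometric decay toward an attractor (block ratio r < 1, chord direction
  persistent): per-coordinate Aitken extrapolation to the limit, displacement
  capped at 0.3 per coordinate so a noisy ratio cannot fling the state;
  an alternating-sign variant covers dominant negative ratios;
* near-linear drift (|r - 1| tiny): bounded forward jump of at most 0.02
  total displacement.

Spiral (complex-eigenvalue) approaches fail the direction-persistence test and
are left to plain iteration.  After every jump the state is clipped to the
simplex and iteration resumes; convergence is only ever declared when the map
itself yields e(t) < tol, so an extrapolation can at worst waste iterations,
never fabricate an equilibrium.  The default cap is 1e6 actual iterations of
the map (reported generation counts include jumped spans); in batches of
10,000 runs per pair, zero to a few runs per 100,000 hit the cap and are
tallied as degenerate rather than classified.  The kernel is compiled with
numba and falls back to the identical pure-Python source if unavailable;
the two are asserted equal in tests.

## Outcome classification

At equilibrium, genotypes at <= 1% within-sex frequency are removed (mutants
enter at 1%, so quasi-neutral runs whose dynamics stall below the stability
tolerance are correctly read as non-invasive).  If more than one male or
female genotype survives, the run is a protected polymorphism and a looser
0.1% filter is used to report all participating genotypes.  Otherwise:
population identical to the ancestral background = non-invasive; D locus
monomorphic across survivors = transition (sex now segregates at R);
anything else = recruitment.  Heterogamety change compares which sex is
heterozygous at the current sex-determining locus with the ancestral
heterogametic sex.  Fitness patterns classify the novel survivors' W per sex
as >1, <1 or =1, with =1 arising exactly (no novel genotype in that sex, or a
novel genotype with dS_D = 0, e.g. the regulator fixed beside an unregulated
D allele); the >1/<1 comparisons use a 1e-12 tolerance.  Exactly-boundary
frequencies are removed by the <= filter via a 1e-10 float guard.

## (k, h) regions

Each pair's region numeral is computed from the sign pattern of S_D - theta
over its diagnostic novel genotypes (the genotypes whose sex switches as k
grows), via closed-form expression - not hard-coded boundary curves.  The
pattern->numeral tables are anchored to the published outcome rows; only the
f-down/then-A pair's numbering is fully enumerated in print, the rest are
reconstructed and verified against the region ordering along k (regions form
contiguous bands I, II, ... with increasing k; analytically impossible
patterns are absent on a dense grid).  Runs landing exactly on a boundary
(measure zero) take the label of the computed sign.

## Monte-Carlo protocol

Per pair: independent runs with h ~ U(1.6, 4.6) (the biologically realistic
sigmoid-steepness range), k ~ U(0, 3) (no new behavior above 3),
w_M, w_F ~ U(-1/2, 1/2) (keeps W > 0), fixed per run; theta computed once per
run.  Default batch size 10,000 runs, matching the published protocol; the
test suite uses 1,000-run pilots with proportionally widened statistical
tolerances so the default suite stays in the minutes range.  Each run draws
from an independent substream keyed by (seed, run index), so batches are
bit-reproducible and order-independent regardless of execution order.

T_A = -1 (low constitutive expression of the regulator) is exposed as an
option and is qualitatively equivalent: the dose per A copy becomes
sigma(-k), weakening regulation, but the same outcome menu and structural
constraints hold (tested).

Back mutations: for aA/X pairs the R locus is monomorphic, which structurally
forbids transitions.  `apply_back_mutation` reintroduces the null a allele at
0.5% allele frequency into the heterogametic sex of the *evolved* population
(stage one may have flipped heterogamety) and re-classifies; transitions then
occur for the f- and m+ variants only (tested).

## What the replication does and does not show

All inputs are generated internally from the stated distributions; there is
no external data.  The replication therefore tests the model's internal
consistency and this implementation's fidelity - agreement of the recursion
with closed-form invasion conditions, and of 10,000-run tallies with the
published cell counts within binomial noise.  Published counts are themselves
single Monte-Carlo draws: for the a->A/f->f- Region-I cell the analytic
expectation is ~3309/10^4 while the printed value is 3227, about 1.7 SD low,
so two-draw comparisons can occasionally exceed a +/-3 single-draw-SD band
even for an exact implementation.  Nothing here speaks to how well the
sigmoid steady-state model describes any real regulatory network.

## Known limitations

No drift (infinite population), no linkage, no recurrent mutation, no
sex-ratio evolution, no direct fitness effects of the R locus.  Classification
thresholds (1% / 0.1%) are protocol constants, not biology.  The generation
counts reported for accelerated runs are estimates of the plain-iteration
equivalent (exact for the jump spans, approximate for Aitken tails) and are
intended for diagnostics, not analysis.
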