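"""R-locus back mutation (A -> a) re-enabling a sex-determination transition.

Transitions need polymorphism at the R locus, so aA/X pairs (A fixed in the
background) cannot transition directly.  A null back mutation restores R
variation; for the m+ (and f-) variants this lets sex determination move to
the R locus, while f+ and m- stay constrained.
"""

from sdnetevo import (
    FitnessParams,
    NetworkParams,
    apply_back_mutation,
    build_background,
    classify_outcome,
    evaluate_universe,
    get_pair,
    introduce_mutant,
    iterate_to_equilibrium,
)

pair = get_pair("aA/mm+")
params = NetworkParams(h=3.0, k=1.0)
fit = FitnessParams(w_m=-0.3, w_f=-0.3)

evals = evaluate_universe(pair, params, fit)
state = introduce_mutant(build_background(pair, params), pair)
res1 = iterate_to_equilibrium(state, evals)
rec1 = classify_outcome(res1, pair, evals)
print(f"stage 1 ({pair.id}): {rec1.outcome}; males {rec1.evolved_males}, "
      f"females {rec1.evolved_females}")

res2, rec2 = apply_back_mutation(res1, pair, params, fit)
print(f"stage 2 (+ A->a back mutation): {rec2.outcome}; "
      f"males {rec2.evolved_males}, females {rec2.evolved_females}")
print(
    "\nAfter m+ is recruited, reintroducing the null a allele creates a/A\n"
    "males whose m+/m+ expression stays below theta while A/A;m+/m+ is\n"
    "female: sex determination has moved to the R locus."
)
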