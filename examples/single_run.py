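"""One evolutionary run, from mutant introduction to classified equilibrium.

Introduces the A mutant at 0.5% allele frequency into f->f-/a->A background
males at (k=0.8, h=3) with selection favoring lower D-locus expression in
both sexes, then iterates the two-locus recursion to e(t) < 1e-12.
"""

from sdnetevo import get_pair, run_single

pair = get_pair("ff-/aA")
rec = run_single(pair, h=3.0, k=0.8, w_m=-0.25, w_f=-0.1)

print(f"pair {pair.id}: males {pair.bg_het.name}, females {pair.bg_hom.name}, "
      f"mutant {pair.mutant.name} at 1% of males")
print(f"parameters: h={rec.h} k={rec.k} w_M={rec.w_m} w_F={rec.w_f}")
print(f"region {rec.region}; converged after ~{rec.generations:.0f} generations")
print(f"outcome: {rec.outcome}"
      + (" with heterogamety change" if rec.heterogamety_change else ""))
print(f"evolved males:   {', '.join(rec.evolved_males)}")
print(f"evolved females: {', '.join(rec.evolved_females)}")
print(f"fitness pattern {rec.fitness_pattern} (W_M={rec.w_male:.4f}, W_F={rec.w_female:.4f})")
print(
    "\nThe m allele is lost: heterozygous a/A;f-/f- males now determine sex at\n"
    "the R locus (a transition), with no change in which sex is heterogametic."
)
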