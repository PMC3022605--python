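"""Ancestral female heterogamety (ZW-like) mirrors the male-heterogamety model.

Under female heterogamety the constitutive roles swap (heterozygous females
carry the dominant low-output f allele; males are homozygous high-output
m/m) and the high-expression side of theta develops as the homogametic male.
Every run then mirrors a male-heterogamety run of the letter-swapped pair
with w_M and w_F interchanged -- so transitions occur only with f->f+/a->A
and m->m-/a->A.
"""

from sdnetevo import get_pair, mirror_pair_id, run_single

pid = "ff+/aA"
fpair = get_pair(pid, heterogamety="female")
mpair = get_pair(mirror_pair_id(pid))  # mm+/aA under male heterogamety

h, k, w_m, w_f = 3.0, 0.5, -0.2, -0.2
rf = run_single(fpair, h, k, w_m, w_f)
rm = run_single(mpair, h, k, w_f, w_m)  # mirrored run: w_M/w_F swapped

print(f"female heterogamety, {pid}: {rf.outcome}"
      + (" + heterogamety change" if rf.heterogamety_change else ""))
print(f"  males {rf.evolved_males}, females {rf.evolved_females}")
print(f"male heterogamety mirror, {mpair.id}: {rm.outcome}"
      + (" + heterogamety change" if rm.heterogamety_change else ""))
print(f"  males {rm.evolved_males}, females {rm.evolved_females}")
print("\nThe two runs agree outcome-for-outcome with sexes and m/f letters swapped.")
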