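# sdnetevo

Evolution of diploid sex-determination gene networks: how an unlinked
regulator gets recruited into an existing sex-determination system, and when
that recruitment rewires the system — moving the sex-determining locus,
flipping heterogamety, or stabilizing multiple male/female genotypes.

The package is for population geneticists and systems biologists studying the
turnover of sex-determination mechanisms (the *Sxl*/*tra*/*dsx*-style cascades
of insects and their analogues in fish, frogs and worms), where sex and
fitness are emergent properties of gene expression rather than assumptions
attached to genotypes.

## Model

Each allele *i* is a regulatory identity: a constitutive output sign
*T<sub>i</sub>* ∈ {−1, +1}, a regulatory capability *Z<sub>i</sub>* ∈ {0, 1},
and input sensitivities *I<sub>i,j</sub>* ∈ {−1, 0, +1}.  Expression of each
allele copy relaxes to the fixed point of

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>i</sub>* = σ(Σ<sub>j</sub> *I<sub>i,j</sub> Z<sub>j</sub> S<sub>j</sub>* + *k T<sub>i</sub>*),&nbsp;&nbsp;&nbsp;σ(x) = 1/(1+e<sup>−hx</sup>),

with the sum over all allele copies in the diploid genotype (a homozygous
regulator contributes twice), *k* > 0 the constitutive-expression constant and
*h* the sigmoid steepness.  The ancestral sex-determining locus **D**
segregates a dominant low allele m (*T* = −1) and a high allele f (*T* = +1);
summed D output S<sup>D</sup> above the threshold θ = σ(k) + 1/2 gives a
female, otherwise a male — so m/f males and f/f females.  An unlinked locus
**R** carries a non-regulatory allele a; its mutant A gains the ability to
regulate D-locus variants (m<sup>±</sup>, f<sup>±</sup>) that carry the
matching site.  Fitness is viability selection on expression change:
*W* = 1 + ΔS<sup>D</sup>·*w*<sub>M/F</sub> relative to the same-sex background
genotype.

Eight background/mutant orders complete the new regulatory connection
(`aA/ff-` … `mm+/aA`).  For each, an infinite-population two-locus recursion
(random mating, unlinked loci, 1:1 sex ratio) is iterated from a 0.5% mutant
allele frequency until the maximum per-genotype frequency change satisfies
e(t) < 10⁻¹², and the equilibrium is classified as non-invasive, recruitment,
or transition of sex determination to the R locus, with flags for
heterogamety change and protected polymorphism.

## Worked example

```bash
$ sdnetevo demo
```

walks the f→f⁻/a→A pair through its three (k, h) regions (h = 3):

```
k=0.80 h=3.0 w_M=-0.25 w_F=-0.10 -> Region I: transition
   evolved males: a/A;f-/f-; females: a/a;f-/f-

k=2.00 h=3.0 w_M=+0.05 w_F=-0.30 -> Region II: transition + heterogamety change
   evolved males: A/A;f-/f-; females: a/A;f-/f-

k=2.60 h=3.0 w_M=-0.20 w_F=-0.20 -> Region III: recruitment
   evolved males: A/A;m/f-; females: A/A;f-/f-
```

At low k the regulator's effect is strong: down-regulated f⁻/f⁻ homozygotes
fall below θ and become male, the m allele is lost, and the R locus takes over
sex determination (Region I: dominant masculinizer A; Region II: recessive
masculinizer, so heterogamety flips to female).  At high k regulation is weak,
no genotype changes sex, and A is simply recruited.

From Python:

```python
from sdnetevo import get_pair, run_single
rec = run_single(get_pair("ff-/aA"), h=3.0, k=0.8, w_m=-0.25, w_f=-0.1)
rec.outcome            # 'transition'
rec.evolved_males      # ('a/A;f-/f-',)
rec.w_male             # 1.0434 = 1 + dS_D * w_M of the evolved male
```

The `examples/` scripts cover each capability: expression and thresholds,
single runs, region maps, Monte-Carlo tallies, back mutations, and ancestral
female heterogamety.  The `sdnetevo` CLI (`run`, `summarize`, `scan`, `demo`)
writes TSV records, outcome tables and region maps.

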