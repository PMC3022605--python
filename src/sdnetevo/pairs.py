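"""The eight cis/trans mutation pairs and their background populations.

A regulatory connection from the R locus to the D locus needs two mutations:
the trans gain-of-function a->A at R, and a cis variant (m+, m-, f+ or f-) at
D that carries the matching binding site.  One of the two is assumed fixed in
the background state; the other is the mutant whose fate is followed.  The
eight background/mutant orders are::

    aA/ff-  aA/ff+  aA/mm-  aA/mm+     (A fixed first, cis mutant introduced)
    ff-/aA  ff+/aA  mm-/aA  mm+/aA     (cis variant fixed first, A introduced)

Canonical ids are the ASCII forms above; the unicode forms used in print
(e.g. ``"a→A/f→f⁻"``) are accepted and normalized.

Under ancestral female heterogamety the same ids apply with the m/f roles
mirrored (heterozygous females carry the dominant low-output f allele,
males are homozygous high-output m/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .alleles import AlleleSpec, Genotype, build_catalog
from .errors import InvalidParameterError
from .sexdet import FEMALE, MALE, homogametic_sex

PAIR_IDS = (
    "aA/ff-",
    "aA/ff+",
    "aA/mm-",
    "aA/mm+",
    "ff-/aA",
    "ff+/aA",
    "mm-/aA",
    "mm+/aA",
)

#: pairs that can yield transitions of the sex-determining locus
#: (cis variant fixed first, mutant A segregating) under male heterogamety
TRANSITION_CAPABLE_MALE_HET = ("ff-/aA", "mm+/aA")
#: and the mirrored set under ancestral female heterogamety
TRANSITION_CAPABLE_FEMALE_HET = ("ff+/aA", "mm-/aA")


def normalize_pair_id(text: str) -> str:
    """Map print forms like ``"a→A/f→f⁻"`` onto the canonical ascii id."""
    s = (
        text.strip()
        .replace("→", ">")
        .replace("⁺", "+")
        .replace("⁻", "-")
        .replace("^", "")
        .replace(" ", "")
        .replace(">", "")
    )
    if s not in PAIR_IDS:
        raise InvalidParameterError(
            f"unknown mutation pair {text!r}; expected one of {', '.join(PAIR_IDS)}"
        )
    return s


def mirror_pair_id(pair_id: str) -> str:
    """Swap the m/f letter of the cis variant, keeping its regulation sign.

    A female-heterogamety experiment on ``pair_id`` is the structural mirror
    of the male-heterogamety experiment on ``mirror_pair_id(pair_id)`` with
    sexes and w_M/w_F swapped.
    """
    pid = normalize_pair_id(pair_id)
    swap = {"f": "m", "m": "f"}
    a, b = pid.split("/")

    def flip(part: str) -> str:
        if part == "aA":
            return part
        return swap[part[0]] * 2 + part[2]

    return f"{flip(a)}/{flip(b)}"


@dataclass
class MutationPair:
    """One background/mutant experiment: allele universe, backgrounds, mutant.

    Built via :func:`get_pair`; fields after ``back_mutation`` are derived.
    """

    id: str
    heterogamety: str = MALE
    t_a: int = 1
    back_mutation: bool = False

    trans_first: bool = field(init=False)
    variant: str = field(init=False)
    r_alleles: tuple = field(init=False)
    d_alleles: tuple = field(init=False)
    catalog: dict = field(init=False)
    het_sex: str = field(init=False)
    hom_sex: str = field(init=False)
    bg_het: Genotype = field(init=False)
    bg_hom: Genotype = field(init=False)
    mutant: Genotype = field(init=False)
    bg_by_sex: dict = field(init=False)

    def __post_init__(self):
        pid = normalize_pair_id(self.id)
        self.id = pid
        self.het_sex = self.heterogamety
        self.hom_sex = homogametic_sex(self.heterogamety)
        bg_part, mut_part = pid.split("/")
        self.trans_first = bg_part == "aA"
        cis_part = mut_part if self.trans_first else bg_part
        parent, variant = cis_part[0], cis_part[0] + cis_part[2]
        self.variant = variant
        # dom: the low-output allele carried heterozygously by the heterogametic
        # sex (m under male, f under female heterogamety); hom: the high allele.
        dom = "m" if self.heterogamety == MALE else "f"
        hom = "f" if self.heterogamety == MALE else "m"
        if self.trans_first:
            self.r_alleles = ("a", "A") if self.back_mutation else ("A",)
            self.d_alleles = (dom, hom, variant)
            self.bg_het = Genotype.make("A", "A", dom, hom)
            self.bg_hom = Genotype.make("A", "A", hom, hom)
            if parent == hom:
                self.mutant = Genotype.make("A", "A", dom, variant)
            else:
                self.mutant = Genotype.make("A", "A", variant, hom)
        else:
            self.r_alleles = ("a", "A")
            if parent == dom:
                self.d_alleles = (variant, hom)
                self.bg_het = Genotype.make("a", "a", variant, hom)
                self.bg_hom = Genotype.make("a", "a", hom, hom)
            else:
                self.d_alleles = (dom, variant)
                self.bg_het = Genotype.make("a", "a", dom, variant)
                self.bg_hom = Genotype.make("a", "a", variant, variant)
            self.mutant = Genotype.make("a", "A", *self.bg_het.d)
        self.catalog = build_catalog(
            self.d_alleles,
            t_a=self.t_a,
            heterogamety=self.heterogamety,
            r_alleles=self.r_alleles,
        )
        self.bg_by_sex = {self.het_sex: self.bg_het, self.hom_sex: self.bg_hom}

    def all_genotypes(self) -> list[Genotype]:
        """Every genotype constructible from the pair's allele universe."""
        out = []
        for r1, r2 in combinations_with_replacement(self.r_alleles, 2):
            for d1, d2 in combinations_with_replacement(self.d_alleles, 2):
                out.append(Genotype.make(r1, r2, d1, d2))
        return out

    def with_back_mutation(self) -> "MutationPair":
        """The same experiment with the R-locus back mutation A->a enabled."""
        if not self.trans_first:
            raise InvalidParameterError(
                "back mutation applies to aA/X pairs (A fixed in the background)"
            )
        return MutationPair(self.id, self.heterogamety, self.t_a, back_mutation=True)


def get_pair(
    pair_id: str,
    heterogamety: str = MALE,
    t_a: int = 1,
    back_mutation: bool = False,
) -> MutationPair:
    """Build the :class:`MutationPair` for one of the eight canonical ids."""
    return MutationPair(pair_id, heterogamety, t_a, back_mutation)
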