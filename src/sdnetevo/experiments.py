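"""Experiment setup and outcome classification for the eight mutation pairs.

A run starts from the pair's background population (heterogametic sex fixed
for the Table-2 heterozygous background genotype, homogametic sex for the
homozygous one), introduces the mutant at 0.5% allele frequency (1% genotype
frequency) in the heterogametic sex, iterates the recursion to equilibrium
and classifies the outcome:

* non-invasive -- after removing genotypes at <= 1% within-sex frequency the
  population equals the ancestral background;
* recruitment -- the mutant connection is retained but sex determination
  stays at the D locus (D still segregates with sex);
* transition -- the D locus is monomorphic at equilibrium and sex segregates
  at the R locus;
* degenerate -- the run did not converge or lost one sex (reported, never
  silently dropped).

Runs retaining more than one male or female genotype after the 1% filter are
protected polymorphisms; a looser 0.1% filter is then used to report all
participating genotypes.  Each run is also placed in a (k, h) region from the
sign pattern of S_D - theta over the pair's diagnostic novel genotypes; the
Roman numerals follow the per-pair region maps (anchored to the published
outcome table; only the f-down/then-A pair's numbering is fully enumerated in
print, the others are reconstructed from the outcome rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alleles import LOCUS_D, LOCUS_R, Genotype
from .errors import DegenerateBackgroundError, InvalidParameterError
from .network import NetworkParams, d_locus_output
from .pairs import MutationPair
from .popgen import ConvergenceSpec, EquilibriumResult, PopulationState, iterate_to_equilibrium
from .sexdet import (
    FEMALE,
    MALE,
    FitnessParams,
    GenotypeEvaluation,
    assign_sex,
    evaluate_genotype,
    theta,
)

#: fitness-pattern labels (columns of the outcome table)
P_MALE_ONLY = "WM>1,WF=1"
P_FEMALE_ONLY = "WM=1,WF>1"
P_BOTH = "WM>1,WF>1"
P_MALE_CONFLICT = "WM>1,WF<1"
P_FEMALE_CONFLICT = "WM<1,WF>1"
P_OTHER = "other"
FITNESS_PATTERNS = (
    P_MALE_ONLY,
    P_FEMALE_ONLY,
    P_BOTH,
    P_MALE_CONFLICT,
    P_FEMALE_CONFLICT,
)

W_TOL = 1e-12  # tolerance for W >< 1; W == 1 arises exactly (no novel genotype)
FILTER_EPS = 1e-10  # float guard so "frequency <= 1%" removes an exactly-1% genotype


@dataclass
class OutcomeRecord:
    """Classified evolutionary fate of one run."""

    pair_id: str
    heterogamety: str
    outcome: str  # non_invasive | recruitment | transition | degenerate
    region: str
    heterogamety_change: bool
    protected_polymorphism: bool
    evolved_males: tuple
    evolved_females: tuple
    fitness_pattern: str
    w_male: float
    w_female: float
    h: float = float("nan")
    k: float = float("nan")
    w_m: float = float("nan")
    w_f: float = float("nan")
    t_a: int = 1
    run_index: int = -1
    seed: int = -1
    converged: bool = True
    generations: float = 0.0
    status: str = "converged"

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["evolved_males"] = "|".join(d["evolved_males"])
        d["evolved_females"] = "|".join(d["evolved_females"])
        return d


def evaluate_universe(
    pair: MutationPair,
    params: NetworkParams,
    fitness: FitnessParams,
) -> dict[Genotype, GenotypeEvaluation]:
    """Sex, dS_D and W for every genotype constructible in the pair's universe."""
    return {g: evaluate_genotype(g, pair, params, fitness) for g in pair.all_genotypes()}


def build_background(pair: MutationPair, params: NetworkParams) -> PopulationState:
    """Ancestral population: each sex fixed for its Table-2 background genotype.

    Verifies that the computed sexes of the background genotypes agree with
    their ancestral roles; a contradiction (possible only at degenerate
    parameter corners) raises :class:`DegenerateBackgroundError`.
    """
    th = theta(params)
    for sex, g in pair.bg_by_sex.items():
        got = assign_sex(d_locus_output(g, params, pair.catalog), th, pair.heterogamety)
        if got != sex:
            raise DegenerateBackgroundError(
                f"background genotype {g.name} computes as {got}, expected {sex}"
            )
    tables = {
        pair.het_sex: {pair.bg_het: 1.0},
        pair.hom_sex: {pair.bg_hom: 1.0},
    }
    return PopulationState(male=tables[MALE], female=tables[FEMALE], generation=0)


def introduce_mutant(state: PopulationState, pair: MutationPair) -> PopulationState:
    """Place the mutant heterozygote at 1% genotype frequency in the heterogametic sex.

    1% genotype frequency of the heterozygote equals the 0.5% mutant allele
    frequency at which mutants are inserted; the homogametic sex is untouched.
    """
    male = dict(state.male)
    female = dict(state.female)
    table = male if pair.het_sex == MALE else female
    table[pair.bg_het] = table.get(pair.bg_het, 0.0) - 0.01
    table[pair.mutant] = table.get(pair.mutant, 0.0) + 0.01
    if table[pair.bg_het] < 0:
        raise InvalidParameterError("background genotype below 1%; cannot introduce mutant")
    return PopulationState(male, female, state.generation)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _filter(table: dict, threshold: float) -> set:
    return {g for g, p in table.items() if p > threshold + FILTER_EPS}


def _sign_class(ws: list[float]) -> str:
    """gt / lt / eq / mixed versus W = 1.

    An empty set (no novel genotype in that sex) and a novel genotype whose
    expression change is exactly zero (e.g. the regulator fixed next to an
    unregulated D allele) both give the "= 1" class.
    """
    if not ws:
        return "eq"
    classes = set()
    for w in ws:
        if w > 1.0 + W_TOL:
            classes.add("gt")
        elif w < 1.0 - W_TOL:
            classes.add("lt")
        else:
            classes.add("eq")
    return classes.pop() if len(classes) == 1 else "mixed"


_PATTERN_MAP = {
    ("gt", "eq"): P_MALE_ONLY,
    ("eq", "gt"): P_FEMALE_ONLY,
    ("gt", "gt"): P_BOTH,
    ("gt", "lt"): P_MALE_CONFLICT,
    ("lt", "gt"): P_FEMALE_CONFLICT,
}


def classify_outcome(
    result: EquilibriumResult,
    pair: MutationPair,
    evaluations: dict[Genotype, GenotypeEvaluation],
    thresholds: tuple[float, float] = (0.01, 0.001),
) -> OutcomeRecord:
    """Classify one equilibrium per the outcome taxonomy in the module docstring."""
    region = label_region_from_evals(pair, evaluations)
    if result.status != "converged":
        return OutcomeRecord(
            pair.id, pair.heterogamety, "degenerate", region, False, False,
            (), (), P_OTHER, float("nan"), float("nan"),
            converged=False, generations=result.generations, status=result.status,
        )
    coarse, fine = thresholds
    surv_m = _filter(result.state.male, coarse)
    surv_f = _filter(result.state.female, coarse)
    pp = len(surv_m) > 1 or len(surv_f) > 1
    if pp:
        # include every genotype relevant to the polymorphism
        surv_m = _filter(result.state.male, fine)
        surv_f = _filter(result.state.female, fine)
    surv_by_sex = {MALE: surv_m, FEMALE: surv_f}
    anc_by_sex = {
        MALE: {pair.bg_by_sex[MALE]},
        FEMALE: {pair.bg_by_sex[FEMALE]},
    }
    evolved_m = tuple(sorted(g.name for g in surv_m))
    evolved_f = tuple(sorted(g.name for g in surv_f))

    novel = {
        sex: [g for g in surv_by_sex[sex] if g not in anc_by_sex[sex]]
        for sex in (MALE, FEMALE)
    }
    w_class = {sex: _sign_class([evaluations[g].W for g in novel[sex]]) for sex in novel}
    pattern = _PATTERN_MAP.get((w_class[MALE], w_class[FEMALE]), P_OTHER)

    def _w_of(sex: str) -> float:
        if not novel[sex]:
            return 1.0
        return max((evaluations[g].W for g in novel[sex]), key=lambda w: abs(w - 1.0))

    w_male, w_female = _w_of(MALE), _w_of(FEMALE)

    if not pp and surv_m == anc_by_sex[MALE] and surv_f == anc_by_sex[FEMALE]:
        return OutcomeRecord(
            pair.id, pair.heterogamety, "non_invasive", region, False, False,
            evolved_m, evolved_f, P_OTHER, 1.0, 1.0,
            generations=result.generations, status=result.status,
        )

    all_surv = surv_m | surv_f
    d_alleles = {a for g in all_surv for a in g.d}
    outcome = "transition" if len(d_alleles) == 1 else "recruitment"
    sd_locus = LOCUS_R if outcome == "transition" else LOCUS_D

    het_change = False
    het_sexes = [
        sex
        for sex in (MALE, FEMALE)
        if surv_by_sex[sex] and all(g.heterozygous_at(sd_locus) for g in surv_by_sex[sex])
    ]
    hom_sexes = [
        sex
        for sex in (MALE, FEMALE)
        if surv_by_sex[sex] and all(not g.heterozygous_at(sd_locus) for g in surv_by_sex[sex])
    ]
    if len(het_sexes) == 1 and len(hom_sexes) == 1 and het_sexes[0] != hom_sexes[0]:
        het_change = het_sexes[0] != pair.het_sex

    return OutcomeRecord(
        pair.id, pair.heterogamety, outcome, region, het_change, pp,
        evolved_m, evolved_f, pattern, w_male, w_female,
        generations=result.generations, status=result.status,
    )


# ---------------------------------------------------------------------------
# (k, h) regions
# ---------------------------------------------------------------------------


def _diagnostics(pair: MutationPair) -> tuple[list[Genotype], dict]:
    """Diagnostic novel genotypes and the sign-pattern -> numeral table.

    Patterns are tuples of booleans: True where the diagnostic genotype lies
    on the high (homogametic-sex) side of theta.  Written in dominance-role
    terms (dom = the low allele carried heterozygously by the heterogametic
    sex) so the same table serves both ancestral heterogamety settings.
    """
    dom = "m" if pair.heterogamety == MALE else "f"
    hom = "f" if pair.heterogamety == MALE else "m"
    x = pair.variant
    hom_variant = x[0] == hom

    def gt(r1, r2, d1, d2):
        return Genotype.make(r1, r2, d1, d2)

    if pair.trans_first:
        if hom_variant and x.endswith("-"):  # e.g. aA/ff- under male heterogamety
            diags = [gt("A", "A", hom, x), gt("A", "A", x, x)]
            table = {(False, False): "I", (False, True): "I",
                     (True, False): "II", (True, True): "III"}
        elif hom_variant:  # aA/ff+
            diags = [gt("A", "A", dom, x)]
            table = {(True,): "I", (False,): "II"}
        elif x.endswith("-"):  # aA/mm-: the down-regulated dominant allele never flips sex
            diags = []
            table = {(): "I"}
        else:  # aA/mm+
            diags = [gt("A", "A", x, hom), gt("A", "A", x, dom), gt("A", "A", x, x)]
            table = {(True, True, True): "I", (True, False, True): "II",
                     (True, False, False): "III", (False, False, False): "IV"}
    else:
        if hom_variant and x.endswith("-"):  # ff-/aA
            diags = [gt("a", "A", x, x), gt("A", "A", x, x)]
            table = {(False, False): "I", (False, True): "I",
                     (True, False): "II", (True, True): "III"}
        elif hom_variant:  # ff+/aA
            diags = [gt("A", "A", dom, x)]
            table = {(True,): "I", (False,): "II"}
        elif x.endswith("-"):  # mm-/aA
            diags = []
            table = {(): "I"}
        else:  # mm+/aA
            diags = [gt("a", "A", x, x), gt("A", "A", x, x), gt("A", "A", x, hom)]
            table = {(True, True, True): "I", (False, True, True): "II",
                     (False, False, True): "III", (False, False, False): "IV"}
    return diags, table


def label_region(pair: MutationPair, params: NetworkParams) -> str:
    """(k, h) region numeral from the sign pattern of S_D - theta over diagnostics."""
    diags, table = _diagnostics(pair)
    th = theta(params)
    high = tuple(
        bool(np.asarray(d_locus_output(g, params, pair.catalog) > th))
        for g in diags
    )
    return table.get(high, "?")


def label_region_from_evals(pair: MutationPair, evaluations) -> str:
    """Region numeral using already-computed genotype sexes (faster path)."""
    diags, table = _diagnostics(pair)
    hom_sex = pair.hom_sex
    high = tuple(evaluations[g].sex == hom_sex for g in diags)
    return table.get(high, "?")


def region_scan(pair: MutationPair, k_grid, h_grid):
    """Evaluate the region numeral on a (k, h) grid; returns an object array.

    Shape (len(h_grid), len(k_grid)); boundaries between regions are the
    sign-change contours of the diagnostic S_D - theta expressions.
    """
    diags, table = _diagnostics(pair)
    k = np.asarray(k_grid, float)[None, :]
    h = np.asarray(h_grid, float)[:, None]
    params = NetworkParams(h=h, k=k, t_a=pair.t_a)
    th = theta(params)
    highs = [np.asarray(d_locus_output(g, params, pair.catalog)) > th for g in diags]
    shape = np.broadcast_shapes(*(b.shape for b in highs)) if highs else (h.size, k.size)
    labels = np.empty(shape, dtype=object)
    if not highs:
        labels[...] = table[()]
        return labels
    stacked = np.stack([np.broadcast_to(b, shape) for b in highs], axis=-1)
    it = np.ndindex(shape)
    for idx in it:
        labels[idx] = table.get(tuple(bool(v) for v in stacked[idx]), "?")
    return labels


# ---------------------------------------------------------------------------
# back mutation and orderings
# ---------------------------------------------------------------------------


def apply_back_mutation(
    result: EquilibriumResult,
    pair: MutationPair,
    params: NetworkParams,
    fitness: FitnessParams,
    spec: ConvergenceSpec | None = None,
) -> tuple[EquilibriumResult, OutcomeRecord]:
    """Introduce the null allele a (A -> a back mutation) into an evolved population.

    Applies to aA/X pairs, whose first stage has the R locus fixed for A.  The
    a allele is placed at 0.5% allele frequency (1% genotype frequency of the
    a/A carrier of the currently most common heterogametic-sex genotype) and
    the recursion re-run and re-classified.
    """
    bpair = pair.with_back_mutation()
    evaluations = evaluate_universe(bpair, params, fitness)
    # the heterogametic sex of the *evolved* population: stage one may have
    # changed heterogamety, and the back mutation arises in whichever sex is
    # currently heterozygous at the sex-determining locus
    stage1 = classify_outcome(result, pair, evaluate_universe(pair, params, fitness))
    het_sex = pair.het_sex
    if stage1.heterogamety_change:
        het_sex = FEMALE if het_sex == MALE else MALE
    male = dict(result.state.male)
    female = dict(result.state.female)
    table = male if het_sex == MALE else female
    gmax = max(table, key=table.get)
    if "a" in gmax.r:
        raise InvalidParameterError("population already segregates the a allele")
    carrier = Genotype.make("a", gmax.r[0], *gmax.d)
    table[gmax] = table[gmax] - 0.01
    table[carrier] = table.get(carrier, 0.0) + 0.01
    state = PopulationState(male, female, 0)
    result2 = iterate_to_equilibrium(state, evaluations, spec or ConvergenceSpec())
    record = classify_outcome(result2, bpair, evaluations)
    return result2, record


def sd_ordering_report(pair: MutationPair, params: NetworkParams):
    """All constructible genotypes ordered by S_D, with sex labels.

    Returns a list of (genotype, S_D, sex) sorted by increasing S_D -- the
    orderings that determine where protected polymorphisms can arise (a
    heterozygote whose expression lies between the two homozygotes cannot be
    the most favored genotype in its sex).
    """
    th = theta(params)
    rows = []
    for g in pair.all_genotypes():
        s_d = float(d_locus_output(g, params, pair.catalog))
        rows.append((g, s_d, assign_sex(s_d, th, pair.heterogamety)))
    rows.sort(key=lambda row: row[1])
    return rows
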