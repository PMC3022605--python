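"""Infinite-population two-locus recursion with sex-specific viability selection.

One generation: viability selection within each sex (adult frequencies
proportional to juvenile frequency times W), formation of sex-specific gamete
pools under free recombination (unlinked loci, fair meiosis), random union of
gametes, threshold sex assignment of each zygote genotype, and renormalization
of each sex to 1 (the fixed 1:1 sex ratio).  The recursion runs until the
maximum per-genotype change in within-sex adult frequencies e(t) drops below
the stability tolerance (1e-12 by default).

:func:`next_generation` is the readable dictionary-based reference
implementation; :func:`iterate_to_equilibrium` delegates long runs to the
array kernel in :mod:`sdnetevo._kernel`, which applies safeguarded geometric
extrapolation so that runs whose plain recursion would need 1e9+ generations
finish in thousands of iterations.  Convergence is only ever declared from
the map itself reaching e(t) < tol, never from an extrapolated state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alleles import LOCUS_D, LOCUS_R, Genotype
from .errors import SdnetError, SexExtinctionError
from .sexdet import FEMALE, MALE, GenotypeEvaluation

PRUNE_DEFAULT = 1e-15


@dataclass
class PopulationState:
    """Within-sex genotype frequency tables (each summing to 1) plus a counter."""

    male: dict[Genotype, float]
    female: dict[Genotype, float]
    generation: int = 0

    def validate(self, atol: float = 1e-9) -> None:
        for label, table in (("male", self.male), ("female", self.female)):
            total = sum(table.values())
            if abs(total - 1.0) > atol:
                raise SdnetError(f"{label} frequencies sum to {total!r}, not 1")
            if any(p < 0 for p in table.values()):
                raise SdnetError(f"negative frequency in {label} table")

    def support(self) -> set[Genotype]:
        return {g for g, p in self.male.items() if p > 0} | {
            g for g, p in self.female.items() if p > 0
        }


@dataclass
class ConvergenceSpec:
    """Stopping rule for the recursion.

    tol: stability threshold on e(t) = max_G |p(t) - p(t-1)| over within-sex
        adult genotype frequencies.
    max_generations: cap on actual iterations of the map (extrapolation jumps
        are counted separately in the reported generation number).
    accelerate: enable geometric extrapolation through slow tails and sweeps.
    """

    tol: float = 1e-12
    max_generations: int = 1_000_000
    accelerate: bool = True
    check_every: int = 64
    prune: float = PRUNE_DEFAULT
    jump_span: float = 0.02


@dataclass
class EquilibriumResult:
    state: PopulationState
    converged: bool
    final_residual: float
    generations: float
    iterations: int
    status: str = "converged"
    trajectory: list | None = None


def gamete_distribution(g: Genotype) -> dict[tuple[str, str], float]:
    """Haplotype (R allele, D allele) probabilities under free recombination.

    Each of the four ordered picks (one allele per locus) has probability 1/4;
    duplicate haplotypes from homozygous loci are collapsed.
    """
    dist: dict[tuple[str, str], float] = {}
    for r in g.r:
        for d in g.d:
            key = (r, d)
            dist[key] = dist.get(key, 0.0) + 0.25
    return dist


def _adults(table: dict[Genotype, float], evaluations) -> dict[Genotype, float]:
    weighted = {g: p * evaluations[g].W for g, p in table.items() if p > 0}
    total = sum(weighted.values())
    return {g: v / total for g, v in weighted.items()}


def adult_frequencies(state: PopulationState, evaluations):
    """Post-selection (adult) frequency tables, the quantities e(t) tracks."""
    return _adults(state.male, evaluations), _adults(state.female, evaluations)


def next_generation(
    state: PopulationState,
    evaluations: dict[Genotype, GenotypeEvaluation],
    prune: float = PRUNE_DEFAULT,
) -> PopulationState:
    """Advance the population by one generation.

    ``evaluations`` must cover every genotype present and every producible
    zygote.  Raises :class:`SexExtinctionError` if all zygote mass falls on a
    single sex.
    """
    adults_m = _adults(state.male, evaluations)
    adults_f = _adults(state.female, evaluations)

    def pool(adults):
        acc: dict[tuple[str, str], float] = {}
        for g, p in adults.items():
            for hap, q in gamete_distribution(g).items():
                acc[hap] = acc.get(hap, 0.0) + p * q
        return acc

    pool_m, pool_f = pool(adults_m), pool(adults_f)
    zygotes: dict[Genotype, float] = {}
    for (rm, dm), pm in pool_m.items():
        for (rf, df), pf in pool_f.items():
            z = Genotype.make(rm, rf, dm, df)
            zygotes[z] = zygotes.get(z, 0.0) + pm * pf

    males: dict[Genotype, float] = {}
    females: dict[Genotype, float] = {}
    for g, p in zygotes.items():
        try:
            ev = evaluations[g]
        except KeyError:
            raise SdnetError(f"no evaluation for producible zygote {g.name}") from None
        (males if ev.sex == MALE else females)[g] = p
    sum_m, sum_f = sum(males.values()), sum(females.values())
    if sum_m <= 0.0 or sum_f <= 0.0:
        missing = "male" if sum_m <= 0.0 else "female"
        raise SexExtinctionError(f"all zygotes are one sex; no {missing}s produced")
    males = {g: p / sum_m for g, p in males.items()}
    females = {g: p / sum_f for g, p in females.items()}
    # numerical hygiene: drop vanishing genotypes, far below any classification threshold
    males = {g: p for g, p in males.items() if p >= prune}
    females = {g: p for g, p in females.items() if p >= prune}
    sm, sf = sum(males.values()), sum(females.values())
    males = {g: p / sm for g, p in males.items()}
    females = {g: p / sf for g, p in females.items()}
    return PopulationState(males, females, state.generation + 1)


def allele_frequencies(state: PopulationState) -> dict[str, dict[str, float]]:
    """Per-locus allele frequencies, unweighted mean of the two sexes."""
    out: dict[str, dict[str, float]] = {}
    for locus in (LOCUS_R, LOCUS_D):
        per_sex = []
        for table in (state.male, state.female):
            freqs: dict[str, float] = {}
            for g, p in table.items():
                for allele in g.alleles(locus):
                    freqs[allele] = freqs.get(allele, 0.0) + 0.5 * p
            per_sex.append(freqs)
        alleles = set(per_sex[0]) | set(per_sex[1])
        out[locus] = {
            a: 0.5 * (per_sex[0].get(a, 0.0) + per_sex[1].get(a, 0.0)) for a in alleles
        }
    return out


def _residual(prev_m, prev_f, cur_m, cur_f) -> float:
    e = 0.0
    for prev, cur in ((prev_m, cur_m), (prev_f, cur_f)):
        for g in set(prev) | set(cur):
            e = max(e, abs(prev.get(g, 0.0) - cur.get(g, 0.0)))
    return e


def iterate_to_equilibrium(
    initial: PopulationState,
    evaluations: dict[Genotype, GenotypeEvaluation],
    spec: ConvergenceSpec | None = None,
    record_trajectory: bool = False,
) -> EquilibriumResult:
    """Run the recursion until e(t) < tol or the iteration cap is reached.

    With ``spec.accelerate`` (default) the run is delegated to the compiled
    array kernel; trajectory recording forces the plain generation-by-
    generation path.  Non-convergence is reported, never silently classified.
    """
    spec = spec or ConvergenceSpec()
    if spec.accelerate and not record_trajectory:
        from ._kernel import iterate_compiled

        return iterate_compiled(initial, evaluations, spec)

    state = initial
    trajectory: list | None = [] if record_trajectory else None
    if record_trajectory:
        _record(trajectory, state)
    prev_m, prev_f = adult_frequencies(state, evaluations)
    resid = np.inf
    for iteration in range(1, spec.max_generations + 1):
        try:
            state = next_generation(state, evaluations, prune=spec.prune)
        except SexExtinctionError:
            return EquilibriumResult(
                state, False, resid, float(iteration), iteration, "sex_extinction", trajectory
            )
        if record_trajectory:
            _record(trajectory, state)
        cur_m, cur_f = adult_frequencies(state, evaluations)
        resid = _residual(prev_m, prev_f, cur_m, cur_f)
        prev_m, prev_f = cur_m, cur_f
        if resid < spec.tol:
            return EquilibriumResult(
                state, True, resid, float(iteration), iteration, "converged", trajectory
            )
    return EquilibriumResult(
        state,
        False,
        resid,
        float(spec.max_generations),
        spec.max_generations,
        "max_generations",
        trajectory,
    )


def _record(trajectory: list, state: PopulationState) -> None:
    for sex, table in ((MALE, state.male), (FEMALE, state.female)):
        for g, p in sorted(table.items(), key=lambda kv: kv[0].name):
            if p > 0:
                trajectory.append((state.generation, sex, g.name, p))


def write_trajectory_tsv(trajectory, path) -> None:
    """Write a (generation, sex, genotype, frequency) trajectory as TSV."""
    import pandas as pd

    df = pd.DataFrame(trajectory, columns=["generation", "sex", "genotype", "frequency"])
    df.to_csv(path, sep="\t", index=False)
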