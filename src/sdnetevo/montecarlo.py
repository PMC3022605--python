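"""Monte-Carlo batches over the model's parameter space.

For each mutation pair, runs are performed at parameter sets sampled
uniformly and independently: h in (1.6, 4.6) (the biologically realistic
sigmoid-steepness range), k in (0, 3) (no qualitatively new behavior occurs
above 3), and the selection coefficients w_M, w_F in (-1/2, 1/2) (keeping all
fitnesses positive given |dS_D| < 2).  Parameters stay fixed for a run's
whole duration and the threshold theta is computed once from (k, h).

The default batch size follows the published protocol of 10,000 independent
runs per pair.  Each run draws its parameters from an independent,
reproducible substream keyed by (seed, run_index), so batches are
bit-reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .alleles import Genotype
from .errors import InvalidParameterError
from .experiments import (
    FITNESS_PATTERNS,
    P_OTHER,
    OutcomeRecord,
    classify_outcome,
    label_region,
)
from .network import NetworkParams
from .pairs import MutationPair
from .popgen import ConvergenceSpec, EquilibriumResult
from .sexdet import FEMALE, MALE, GenotypeEvaluation, theta


@dataclass
class SamplingSpec:
    """Uniform parameter-sampling protocol for a batch of runs."""

    n_runs: int = 10_000
    seed: int = 0
    h_range: tuple = (1.6, 4.6)
    k_range: tuple = (0.0, 3.0)
    w_range: tuple = (-0.5, 0.5)


def sample_parameters(spec: SamplingSpec, run_index: int):
    """Deterministic (h, k, w_M, w_F) draw for one run.

    Each run uses the substream keyed by (seed, run_index); values are
    strictly inside the open sampling intervals.
    """
    rng = np.random.default_rng([spec.seed, run_index])

    def draw(lo, hi):
        v = rng.uniform(lo, hi)
        while not (lo < v < hi):  # open intervals; redraw boundary hits
            v = rng.uniform(lo, hi)
        return float(v)

    h = draw(*spec.h_range)
    k = draw(*spec.k_range)
    w_m = draw(*spec.w_range)
    w_f = draw(*spec.w_range)
    return h, k, w_m, w_f


def _expression_table(pair: MutationPair, params: NetworkParams) -> dict[Genotype, float]:
    """S_D for every universe genotype via the closed-form feed-forward solution.

    Scalar fast path equivalent to ``d_locus_output`` (asserted in tests).
    """
    h, k = float(params.h), float(params.k)
    cat = pair.catalog

    def sig(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-h * x))

    s_r = {rid: sig(k * cat[rid].T) for rid in pair.r_alleles}
    cache: dict = {}
    table: dict[Genotype, float] = {}
    for g in pair.all_genotypes():
        s = 0.0
        for dal in g.d:
            key = (g.r, dal)
            level = cache.get(key)
            if level is None:
                spec = cat[dal]
                x = k * spec.T
                for rid in g.r:
                    rspec = cat[rid]
                    x += spec.I.get(rid, 0) * rspec.Z * s_r[rid]
                level = sig(x)
                cache[key] = level
            s += level
        table[g] = s
    return table


def run_single(
    pair: MutationPair,
    h: float,
    k: float,
    w_m: float,
    w_f: float,
    *,
    spec: ConvergenceSpec | None = None,
    structure: _kernel.CompiledStructure | None = None,
    back_mutation: bool = False,
    run_index: int = -1,
    seed: int = -1,
) -> OutcomeRecord:
    """One complete run: background, mutant introduction, recursion, classification.

    With ``back_mutation`` (aA/X pairs only), a second stage introduces the
    null a allele into the evolved population's heterogametic sex and the
    re-equilibrated population is classified instead.
    """
    spec = spec or ConvergenceSpec()
    params = NetworkParams(h=h, k=k, t_a=pair.t_a)
    th = float(theta(params))
    table = _expression_table(pair, params)
    high_sex, low_sex = pair.hom_sex, pair.het_sex

    def _fill(record: OutcomeRecord) -> OutcomeRecord:
        record.h, record.k, record.w_m, record.w_f = h, k, w_m, w_f
        record.t_a = pair.t_a
        record.run_index, record.seed = run_index, seed
        return record

    sexes = {g: (high_sex if s > th else low_sex) for g, s in table.items()}
    if sexes[pair.bg_het] != pair.het_sex or sexes[pair.bg_hom] != pair.hom_sex:
        return _fill(
            OutcomeRecord(
                pair.id, pair.heterogamety, "degenerate", label_region(pair, params),
                False, False, (), (), P_OTHER, float("nan"), float("nan"),
                converged=False, generations=0.0, status="degenerate_background",
            )
        )
    s_ref = {MALE: table[pair.bg_by_sex[MALE]], FEMALE: table[pair.bg_by_sex[FEMALE]]}
    w_of = {MALE: w_m, FEMALE: w_f}
    evals: dict[Genotype, GenotypeEvaluation] = {}
    for g, s in table.items():
        sex = sexes[g]
        delta = s - s_ref[sex]
        evals[g] = GenotypeEvaluation(g, sex, delta, 1.0 + delta * w_of[sex])

    structure = structure or _kernel.compile_structure(list(table))
    G = len(structure.genotypes)
    W = np.empty(G)
    male_mask = np.zeros(G, dtype=np.bool_)
    female_mask = np.zeros(G, dtype=np.bool_)
    for g, gi in structure.index.items():
        ev = evals[g]
        W[gi] = ev.W
        male_mask[gi] = ev.sex == MALE
        female_mask[gi] = ev.sex == FEMALE
    fm0 = np.zeros(G)
    ff0 = np.zeros(G)
    het_vec, hom_vec = (fm0, ff0) if pair.het_sex == MALE else (ff0, fm0)
    het_vec[structure.index[pair.bg_het]] = 0.99
    het_vec[structure.index[pair.mutant]] = 0.01
    hom_vec[structure.index[pair.bg_hom]] = 1.0

    fm, ff, resid, status, iters, virtual = _kernel.run_compiled(
        structure, W, male_mask, female_mask, fm0, ff0, spec
    )
    result = EquilibriumResult(
        _kernel.arrays_to_state(structure, fm, ff),
        status == 0,
        float(resid),
        float(virtual),
        int(iters),
        _kernel._STATUS[int(status)],
    )
    record = classify_outcome(result, pair, evals)
    record.converged = result.converged
    if back_mutation and result.converged:
        from .experiments import apply_back_mutation
        from .sexdet import FitnessParams

        result2, record2 = apply_back_mutation(
            result, pair, params, FitnessParams(w_m, w_f), spec
        )
        record2.generations += record.generations
        record2.converged = result2.converged
        record = record2
    return _fill(record)


def run_batch(
    pair: MutationPair,
    sampling: SamplingSpec | None = None,
    spec: ConvergenceSpec | None = None,
    back_mutation: bool = False,
) -> list[OutcomeRecord]:
    """A batch of independent runs for one pair (default 10,000 runs)."""
    sampling = sampling or SamplingSpec()
    spec = spec or ConvergenceSpec()
    structure = _kernel.compile_structure(pair.all_genotypes())
    records = []
    for i in range(sampling.n_runs):
        h, k, w_m, w_f = sample_parameters(sampling, i)
        records.append(
            run_single(
                pair, h, k, w_m, w_f,
                spec=spec, structure=structure, back_mutation=back_mutation,
                run_index=i, seed=sampling.seed,
            )
        )
    return records


# ---------------------------------------------------------------------------
# tallies and IO
# ---------------------------------------------------------------------------

_COLUMNS = [
    "run_index", "pair", "heterogamety", "t_a", "h", "k", "w_m", "w_f",
    "outcome", "region", "heterogamety_change", "protected_polymorphism",
    "fitness_pattern", "evolved_males", "evolved_females",
    "w_male", "w_female", "converged", "generations", "status", "seed",
]


def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.to_dict()
        d["pair"] = d.pop("pair_id")
        rows.append(d)
    df = pd.DataFrame(rows)
    return df[[c for c in _COLUMNS if c in df.columns]]


def write_records_tsv(records, path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    for col in ("heterogamety_change", "protected_polymorphism", "converged"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().eq("true")
    return df


def summarize(records) -> pd.DataFrame:
    """Outcome-table-style tally for one pair: per-region outcome rows.

    Columns: the five fitness-pattern counts over invasive non-polymorphic
    runs, the protected-polymorphism count, and the non-invasive / degenerate
    remainders.  The outcome code (R/T plus H for a heterogamety change) and
    the evolved genotypes describe the modal invasive outcome of the region.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    if df.empty:
        return pd.DataFrame(
            columns=["pair", "region", "outcome", "evolved_males", "evolved_females",
                     *FITNESS_PATTERNS, "other_pattern", "protected_polymorphism",
                     "non_invasive", "degenerate", "total"]
        )
    if df["pair"].nunique() > 1:
        raise InvalidParameterError("summarize expects records from a single pair")
    rows = []
    for region, grp in df.groupby("region", sort=True):
        inv = grp[
            grp["outcome"].isin(["recruitment", "transition"])
            & ~grp["protected_polymorphism"]
        ]
        pp = grp[grp["protected_polymorphism"] & (grp["outcome"] != "degenerate")]
        if len(inv):
            modal = (
                inv.groupby(["outcome", "heterogamety_change",
                             "evolved_males", "evolved_females"])
                .size()
                .idxmax()
            )
            outcome, het_change, males, females = modal
            code = ("T" if outcome == "transition" else "R") + ("H" if het_change else "")
        else:
            code, males, females = "", "", ""
        row = {
            "pair": grp["pair"].iloc[0],
            "region": region,
            "outcome": code,
            "evolved_males": males,
            "evolved_females": females,
        }
        for pat in FITNESS_PATTERNS:
            row[pat] = int((inv["fitness_pattern"] == pat).sum())
        row["other_pattern"] = int((inv["fitness_pattern"] == P_OTHER).sum())
        row["protected_polymorphism"] = int(len(pp))
        row["non_invasive"] = int((grp["outcome"] == "non_invasive").sum())
        row["degenerate"] = int((grp["outcome"] == "degenerate").sum())
        row["total"] = int(len(grp))
        rows.append(row)
    return pd.DataFrame(rows)


def _canon_names(names) -> tuple:
    return tuple(sorted(Genotype.parse(n).name for n in names))


def count_cell(
    records,
    *,
    region: str | None = None,
    outcome: str | None = None,
    males=None,
    females=None,
    pattern: str | None = None,
    heterogamety_change: bool | None = None,
    protected_polymorphism: bool | None = False,
) -> int:
    """Count runs matching one outcome-table cell (full genotype names)."""
    males = _canon_names(males) if males is not None else None
    females = _canon_names(females) if females is not None else None
    n = 0
    for r in records:
        if region is not None and r.region != region:
            continue
        if outcome is not None and r.outcome != outcome:
            continue
        if protected_polymorphism is not None and r.protected_polymorphism != protected_polymorphism:
            continue
        if heterogamety_change is not None and r.heterogamety_change != heterogamety_change:
            continue
        if males is not None and tuple(sorted(r.evolved_males)) != males:
            continue
        if females is not None and tuple(sorted(r.evolved_females)) != females:
            continue
        if pattern is not None and r.fitness_pattern != pattern:
            continue
        n += 1
    return n
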