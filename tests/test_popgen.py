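"""Two-locus recursion: gametes, generation map, equilibrium iteration, kernel."""

import numpy as np
import pytest

from sdnetevo import (
    ConvergenceSpec,
    FitnessParams,
    Genotype,
    NetworkParams,
    PopulationState,
    allele_frequencies,
    build_background,
    evaluate_universe,
    gamete_distribution,
    introduce_mutant,
    iterate_to_equilibrium,
    next_generation,
    get_pair,
)
from sdnetevo._kernel import _iterate, _iterate_impl, compile_structure, run_compiled
from sdnetevo.sexdet import GenotypeEvaluation


def brute_force_next(state, evaluations):
    """Independent oracle: enumerate every mating and every Punnett outcome.

    Father x mother genotype pairs weighted by adult frequencies; each of the
    16 ordered allele picks (2 per locus per parent) has probability 1/16.
    """

    def adults(table):
        w = {g: p * evaluations[g].W for g, p in table.items() if p > 0}
        tot = sum(w.values())
        return {g: v / tot for g, v in w.items()}

    fathers, mothers = adults(state.male), adults(state.female)
    males, females = {}, {}
    for gf, pf in fathers.items():
        for gm, pm in mothers.items():
            for rf in gf.r:
                for df in gf.d:
                    for rm in gm.r:
                        for dm in gm.d:
                            child = Genotype.make(rf, rm, df, dm)
                            w = pf * pm / 16.0
                            tgt = males if evaluations[child].sex == "male" else females
                            tgt[child] = tgt.get(child, 0.0) + w
    sm, sf = sum(males.values()), sum(females.values())
    return (
        {g: p / sm for g, p in males.items()},
        {g: p / sf for g, p in females.items()},
    )


def _setup(pair_id, h, k, w_m, w_f):
    pair = get_pair(pair_id)
    params = NetworkParams(h=h, k=k)
    evals = evaluate_universe(pair, params, FitnessParams(w_m, w_f))
    state = introduce_mutant(build_background(pair, params), pair)
    return pair, params, evals, state


class TestGametes:
    @pytest.mark.parametrize(
        "geno,expected",
        [
            ("a/a;f/f", {("a", "f"): 1.0}),
            ("a/A;m/f-", {("a", "m"): 0.25, ("a", "f-"): 0.25, ("A", "m"): 0.25, ("A", "f-"): 0.25}),
            ("a/a;m/f", {("a", "m"): 0.5, ("a", "f"): 0.5}),
        ],
    )
    def test_free_recombination(self, geno, expected):
        dist = gamete_distribution(Genotype.parse(geno))
        assert dist == pytest.approx(expected)
        assert sum(dist.values()) == pytest.approx(1.0)


class TestNextGeneration:
    def test_ancestral_population_is_fixed_point(self):
        pair, params, evals, _ = _setup("ff-/aA", 3.0, 1.0, 0.2, -0.1)
        state = build_background(pair, params)
        nxt = next_generation(state, evals)
        assert nxt.male == pytest.approx(state.male)
        assert nxt.female == pytest.approx(state.female)

    def test_matches_brute_force_oracle(self):
        """Pool-based recursion equals full mating-table enumeration to 1e-12."""
        cases = [
            ("ff-/aA", 3.0, 1.0, 0.25, -0.3),
            ("ff-/aA", 2.2, 2.1, -0.4, 0.1),
            ("aA/mm+", 4.0, 0.7, 0.3, 0.3),
            ("aA/ff+", 1.8, 1.4, -0.2, 0.45),
        ]
        for pair_id, h, k, w_m, w_f in cases:
            pair, params, evals, state = _setup(pair_id, h, k, w_m, w_f)
            for _ in range(4):  # also exercise richer multi-genotype states
                got = next_generation(state, evals, prune=0.0)
                exp_m, exp_f = brute_force_next(state, evals)
                assert got.male == pytest.approx(exp_m, abs=1e-12)
                assert got.female == pytest.approx(exp_f, abs=1e-12)
                state = got

    def test_neutral_mutant_conserves_allele_frequencies(self):
        """w=0 and no sex change: allele frequencies constant for 1000 gens."""
        pair, params, evals, state = _setup("aA/mm-", 3.0, 2.0, 0.0, 0.0)
        start = allele_frequencies(state)
        for _ in range(1000):
            state = next_generation(state, evals)
        end = allele_frequencies(state)
        for locus in ("R", "D"):
            for allele, freq in start[locus].items():
                assert end[locus].get(allele, 0.0) == pytest.approx(freq, abs=1e-10)

    def test_ancestral_allele_frequencies(self):
        pair, params, evals, _ = _setup("aA/mm-", 3.0, 1.0, 0.1, 0.1)
        state = build_background(pair, params)
        freqs = allele_frequencies(state)
        assert freqs["D"] == pytest.approx({"m": 0.25, "f": 0.75})
        assert freqs["R"] == pytest.approx({"A": 1.0})

    def test_frequency_conservation_invariant(self, rng):
        pair, params, evals, state = _setup("mm+/aA", 3.4, 0.9, -0.35, 0.4)
        for _ in range(50):
            state = next_generation(state, evals)
            state.validate()


class TestIterateToEquilibrium:
    def test_ancestral_state_converges_immediately(self):
        pair, params, evals, _ = _setup("ff-/aA", 3.0, 1.0, 0.2, -0.1)
        res = iterate_to_equilibrium(build_background(pair, params), evals)
        assert res.converged
        assert res.final_residual < 1e-12
        assert res.generations <= 2

    def test_deleterious_mutant_eliminated(self):
        """aA/mm- with w_M>0: the down-regulated mutant declines to loss."""
        pair, params, evals, state = _setup("aA/mm-", 3.0, 1.0, 0.3, 0.1)
        mutant_freq = [state.male.get(pair.mutant, 0.0)]
        st = state
        for _ in range(200):
            st = next_generation(st, evals)
            mutant_freq.append(st.male.get(pair.mutant, 0.0))
        assert all(b <= a + 1e-15 for a, b in zip(mutant_freq, mutant_freq[1:]))
        res = iterate_to_equilibrium(state, evals)
        assert res.converged
        assert res.state.male == pytest.approx({pair.bg_het: 1.0})

    def test_favored_mutant_fixes(self):
        """aA/mm- with w_M<0: m- fixes among males, females stay f/f."""
        pair, params, evals, state = _setup("aA/mm-", 3.0, 1.0, -0.3, 0.1)
        res = iterate_to_equilibrium(state, evals)
        assert res.converged
        assert set(res.state.male) == {Genotype.parse("A/A;m-/f")}
        assert set(res.state.female) == {Genotype.parse("A/A;f/f")}

    def test_trajectory_recording(self):
        pair, params, evals, state = _setup("aA/mm-", 3.0, 1.0, 0.3, 0.1)
        res = iterate_to_equilibrium(
            state, evals, ConvergenceSpec(accelerate=False, max_generations=500),
            record_trajectory=True,
        )
        assert res.trajectory
        gens = {row[0] for row in res.trajectory}
        assert 0 in gens and 1 in gens
        assert {row[1] for row in res.trajectory} == {"male", "female"}

    def test_cap_reported_not_silent(self):
        pair, params, evals, state = _setup("ff-/aA", 3.0, 1.0, 0.2, -0.1)
        res = iterate_to_equilibrium(state, evals, ConvergenceSpec(max_generations=3))
        assert not res.converged
        assert res.status == "max_generations"


class TestKernel:
    def _arrays(self, pair, evals, state):
        struct = compile_structure(pair.all_genotypes())
        G = len(struct.genotypes)
        W = np.empty(G)
        mmask = np.zeros(G, bool)
        fmask = np.zeros(G, bool)
        for g, gi in struct.index.items():
            W[gi] = evals[g].W
            mmask[gi] = evals[g].sex == "male"
            fmask[gi] = evals[g].sex == "female"
        fm = np.zeros(G)
        ff = np.zeros(G)
        for g, p in state.male.items():
            fm[struct.index[g]] = p
        for g, p in state.female.items():
            ff[struct.index[g]] = p
        return struct, W, mmask, fmask, fm, ff

    def test_kernel_matches_dict_recursion(self):
        """Compiled step sequence equals next_generation exactly (no accel)."""
        pair, params, evals, state = _setup("mm+/aA", 3.1, 0.95, -0.2, 0.15)
        struct, W, mmask, fmask, fm, ff = self._arrays(pair, evals, state)
        n = 40
        spec = ConvergenceSpec(accelerate=False, max_generations=n, tol=0.0, prune=0.0)
        fm2, ff2, *_ = run_compiled(struct, W, mmask, fmask, fm, ff, spec)
        st = state
        for _ in range(n):
            st = next_generation(st, evals, prune=0.0)
        for g, gi in struct.index.items():
            assert fm2[gi] == pytest.approx(st.male.get(g, 0.0), abs=1e-12)
            assert ff2[gi] == pytest.approx(st.female.get(g, 0.0), abs=1e-12)

    def test_python_and_compiled_kernels_agree(self):
        pair, params, evals, state = _setup("aA/ff-", 2.5, 1.8, 0.3, -0.2)
        struct, W, mmask, fmask, fm, ff = self._arrays(pair, evals, state)
        args = (W, struct.gam, struct.pair2g, mmask, fmask)
        out_py = _iterate_impl(*args, fm.copy(), ff.copy(), 1e-12, 3000, 64, 1e-15, 0.02)
        out_nb = _iterate(*args, fm.copy(), ff.copy(), 1e-12, 3000, 64, 1e-15, 0.02)
        np.testing.assert_allclose(out_py[0], out_nb[0], atol=1e-13)
        np.testing.assert_allclose(out_py[1], out_nb[1], atol=1e-13)
        assert out_py[3] == out_nb[3]

    def test_acceleration_reaches_same_equilibrium(self):
        """Extrapolation jumps land on the attractor plain iteration reaches."""
        pair, params, evals, state = _setup("aA/mm-", 3.0, 1.9, -0.02, 0.01)
        fast = iterate_to_equilibrium(state, evals, ConvergenceSpec())
        slow = iterate_to_equilibrium(
            state, evals, ConvergenceSpec(accelerate=False, max_generations=2_000_000)
        )
        assert fast.converged and slow.converged
        assert fast.iterations < slow.iterations
        for g in set(fast.state.male) | set(slow.state.male):
            assert fast.state.male.get(g, 0.0) == pytest.approx(
                slow.state.male.get(g, 0.0), abs=1e-6
            )

    def test_determinism(self):
        pair, params, evals, state = _setup("ff+/aA", 2.9, 1.2, 0.31, 0.22)
        a = iterate_to_equilibrium(state, evals)
        b = iterate_to_equilibrium(state, evals)
        assert a.state.male == b.state.male
        assert a.state.female == b.state.female
        assert a.generations == b.generations


class TestLinkageEquilibrium:
    def test_neutral_two_locus_approaches_product_form(self):
        """Under neutrality the joint haplotype pool factorizes (D' -> 0)."""
        pair, params, evals, _ = _setup("ff-/aA", 3.0, 2.5, 0.0, 0.0)
        # start with strong association: A only with f- homozygote males
        state = PopulationState(
            male={Genotype.parse("a/A;m/f-"): 0.5, Genotype.parse("a/a;m/f-"): 0.5},
            female={Genotype.parse("a/a;f-/f-"): 1.0},
        )
        # neutrality here also requires no sex change among carriers: at k=2.5
        # every A-carrier keeps its ancestral sex class
        for _ in range(200):
            state = next_generation(state, evals)
        # within the male gamete pool, R and D alleles must be independent
        pool = {}
        for g, p in state.male.items():
            for hap, q in gamete_distribution(g).items():
                pool[hap] = pool.get(hap, 0.0) + p * q
        for r in ("a", "A"):
            for d in ("m", "f-"):
                p_r = sum(v for (rr, dd), v in pool.items() if rr == r)
                p_d = sum(v for (rr, dd), v in pool.items() if dd == d)
                assert pool.get((r, d), 0.0) == pytest.approx(p_r * p_d, abs=1e-10)
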