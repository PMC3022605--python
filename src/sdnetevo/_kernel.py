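"""Array-encoded generation kernel with safeguarded geometric extrapolation.

The dictionary recursion in :mod:`sdnetevo.popgen` is exact but slow for runs
whose selection coefficients are tiny: a sweep with effective strength s needs
O(1/s) plain generations, up to 1e9+ within the sampled parameter ranges.
This module encodes one experiment's closed genotype universe as small dense
arrays and iterates the identical map in a compiled loop, periodically
applying two safeguarded jumps along the trajectory:

* decaying tails (block-ratio r < 1): per-coordinate Aitken extrapolation to
  the geometric limit;
* slow sweeps (r >= 1, escape from an unstable fixed point or linear drift):
  bounded forward extrapolation by n steps, chosen so the jumped displacement
  stays below ``jump_span``.

After every jump the state is clipped to the simplex and plain iteration
resumes; convergence is only declared when the map itself yields
e(t) < tol on within-sex adult frequencies.  Status codes: 0 converged,
1 iteration cap reached, 2 sex extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alleles import Genotype, allele_sort_key
from .errors import SdnetError
from .popgen import ConvergenceSpec, EquilibriumResult, PopulationState
from .sexdet import MALE


def _iterate_impl(
    W,
    gam,
    pair2g,
    male_mask,
    female_mask,
    fm,
    ff,
    tol,
    max_iter,
    check_every,
    prune,
    jump_span,
):
    G = W.shape[0]
    H = gam.shape[1]
    am = np.zeros(G)
    af = np.zeros(G)
    am_prev = np.zeros(G)
    af_prev = np.zeros(G)
    pm = np.zeros(H)
    pf = np.zeros(H)
    z = np.zeros(G)
    # snapshots of the concatenated (male, female) state at checkpoints
    s0 = np.zeros(2 * G)
    s1 = np.zeros(2 * G)
    cur = np.zeros(2 * G)
    n_snap = 0
    last_jump = -(10**9)
    virtual = 0.0
    resid = 1.0
    status = 1
    iters = 0
    for it in range(max_iter):
        iters = it + 1
        # viability selection -> within-sex adult frequencies
        sm = 0.0
        sf = 0.0
        for g in range(G):
            am[g] = fm[g] * W[g]
            sm += am[g]
            af[g] = ff[g] * W[g]
            sf += af[g]
        for g in range(G):
            am[g] /= sm
            af[g] /= sf
        if it > 0:
            e = 0.0
            for g in range(G):
                d = am[g] - am_prev[g]
                if d < 0.0:
                    d = -d
                if d > e:
                    e = d
                d = af[g] - af_prev[g]
                if d < 0.0:
                    d = -d
                if d > e:
                    e = d
            resid = e
            if e < tol:
                status = 0
                break
        for g in range(G):
            am_prev[g] = am[g]
            af_prev[g] = af[g]
        # sex-specific gamete pools (free recombination)
        for hh in range(H):
            pm[hh] = 0.0
            pf[hh] = 0.0
        for g in range(G):
            if am[g] > 0.0 or af[g] > 0.0:
                for hh in range(H):
                    w = gam[g, hh]
                    if w != 0.0:
                        pm[hh] += am[g] * w
                        pf[hh] += af[g] * w
        # random union of gametes -> zygote genotype frequencies
        for g in range(G):
            z[g] = 0.0
        for i in range(H):
            if pm[i] != 0.0:
                for j in range(H):
                    z[pair2g[i, j]] += pm[i] * pf[j]
        # threshold sex assignment, 1:1 renormalization per sex
        zm_s = 0.0
        zf_s = 0.0
        for g in range(G):
            vm = z[g] if male_mask[g] else 0.0
            vf = z[g] if female_mask[g] else 0.0
            fm[g] = vm
            ff[g] = vf
            zm_s += vm
            zf_s += vf
        if zm_s <= 0.0 or zf_s <= 0.0:
            status = 2
            break
        tm = 0.0
        tf = 0.0
        for g in range(G):
            fm[g] /= zm_s
            ff[g] /= zf_s
            if fm[g] < prune:
                fm[g] = 0.0
            if ff[g] < prune:
                ff[g] = 0.0
            tm += fm[g]
            tf += ff[g]
        for g in range(G):
            fm[g] /= tm
            ff[g] /= tf
        virtual += 1.0

        # ---- extrapolation checkpoints ----
        if check_every > 0 and (it + 1) % check_every == 0:
            for g in range(G):
                cur[g] = fm[g]
                cur[G + g] = ff[g]
            if n_snap >= 2 and it - last_jump >= 2 * check_every:
                n1 = 0.0
                n2 = 0.0
                dot = 0.0
                n1sq = 0.0
                n2sq = 0.0
                for c in range(2 * G):
                    d1 = s1[c] - s0[c]
                    d2 = cur[c] - s1[c]
                    dot += d1 * d2
                    n1sq += d1 * d1
                    n2sq += d2 * d2
                    if d1 < 0.0:
                        d1 = -d1
                    if d1 > n1:
                        n1 = d1
                    if d2 < 0.0:
                        d2 = -d2
                    if d2 > n2:
                        n2 = d2
                if n1 > 0.0 and n2 > 0.0:
                    r = n2 / n1
                    # direction persistence of the trajectory chord; spiral
                    # (complex-eigenvalue) approaches have low |corr| and get
                    # no jump -- plain iteration handles their decay
                    corr = dot / math.sqrt(n1sq * n2sq)
                    jumped = False
                    # (0) geometric fast-forward of a slow exponential invasion:
                    # rare mutant-linked components grow multiplicatively, so
                    # extrapolate each in log space until the largest reaches
                    # ~10%, from where plain iteration completes the sweep
                    gmin = 1.0e300
                    cmax = 0.0
                    sustained = True
                    for c in range(2 * G):
                        if s1[c] > 1e-12 and cur[c] < 0.2 and cur[c] > s1[c] * (1.0 + 1e-9):
                            gc = cur[c] / s1[c]
                            if s0[c] > 1e-12:
                                g_prev = s1[c] / s0[c]
                                # decelerating growth = approach to an interior
                                # equilibrium, not an exponential invasion
                                if gc < g_prev * 0.9999 or g_prev <= 1.0:
                                    sustained = False
                            if gc < gmin:
                                gmin = gc
                            if cur[c] > cmax:
                                cmax = cur[c]
                    if sustained and 0.0 < cmax < 0.05 and gmin < 1.0e300 and gmin > 1.0 + 1e-9:
                        nfwd = math.log(0.1 / cmax) / math.log(gmin)
                        if nfwd >= 1.0:
                            for c in range(2 * G):
                                if (
                                    s1[c] > 1e-12
                                    and cur[c] < 0.2
                                    and cur[c] > s1[c] * (1.0 + 1e-9)
                                ):
                                    gc = cur[c] / s1[c]
                                    v = cur[c] * math.pow(gc, nfwd)
                                    if v > 0.5:
                                        v = 0.5
                                    cur[c] = v
                            jumped = True
                            virtual += nfwd * check_every
                    if jumped:
                        pass
                    elif r < 1.0 - 1e-6 and corr < -0.9:
                        # alternating geometric decay (dominant negative ratio)
                        lam = dot / n1sq
                        if -1.0 < lam < 0.0:
                            fac = lam / (1.0 - lam)
                            for c in range(2 * G):
                                v = cur[c] + (cur[c] - s1[c]) * fac
                                cur[c] = v if v > 0.0 else 0.0
                            jumped = True
                    elif r < 1.0 - 1e-6 and corr > 0.9:
                        # Aitken: per-coordinate geometric limit of the decay,
                        # displacement capped so a noisy ratio cannot fling the
                        # state; repeated capped jumps still converge geometrically
                        for c in range(2 * G):
                            d1 = s1[c] - s0[c]
                            d2 = cur[c] - s1[c]
                            if d1 * d2 > 0.0:
                                rc = d2 / d1
                                if rc < 1.0:
                                    step = d2 * rc / (1.0 - rc)
                                    if step > 0.3:
                                        step = 0.3
                                    elif step < -0.3:
                                        step = -0.3
                                    v = cur[c] + step
                                    cur[c] = v if v > 0.0 else 0.0
                        jumped = True
                        if r > 1e-12:
                            est = (
                                check_every
                                * math.log(max(tol, 1e-300) / n2)
                                / math.log(r)
                            )
                            if est > 0.0:
                                virtual += min(est, 1e13)
                    elif r > 1.0 + 1e-6 and corr > 0.98:
                        # bounded fast-forward through a slow escape/sweep
                        rb = 1.0 + jump_span * (r - 1.0) / (n2 * r)
                        b = math.log(rb) / math.log(r)
                        if b >= 1.0:
                            factor = r * (math.pow(r, b) - 1.0) / (r - 1.0)
                            for c in range(2 * G):
                                v = cur[c] + (cur[c] - s1[c]) * factor
                                cur[c] = v if v > 0.0 else 0.0
                            jumped = True
                            virtual += b * check_every
                    elif 1.0 - 1e-6 <= r <= 1.0 + 1e-6 and corr > 0.98:
                        # locally linear drift (|r - 1| tiny over the block)
                        b = jump_span / n2
                        if b > 1e12:
                            b = 1e12
                        if b >= 1.0:
                            for c in range(2 * G):
                                v = cur[c] + (cur[c] - s1[c]) * b
                                cur[c] = v if v > 0.0 else 0.0
                            jumped = True
                            virtual += b * check_every
                    if jumped:
                        tm = 0.0
                        tf = 0.0
                        for g in range(G):
                            tm += cur[g]
                            tf += cur[G + g]
                        if tm > 0.0 and tf > 0.0:
                            for g in range(G):
                                fm[g] = cur[g] / tm
                                ff[g] = cur[G + g] / tf
                            last_jump = it
                            n_snap = 0
                            continue
            for c in range(2 * G):
                s0[c] = s1[c]
                s1[c] = cur[c]
            if n_snap < 2:
                n_snap += 1
    return fm, ff, resid, status, iters, virtual


try:  # compile the identical source when numba is available
    from numba import njit

    _iterate = njit(cache=True)(_iterate_impl)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _iterate = _iterate_impl


@dataclass
class CompiledStructure:
    """Parameter-independent encoding of one closed genotype universe."""

    genotypes: list
    index: dict
    haplotypes: list
    gam: np.ndarray  # (G, H) gamete probabilities
    pair2g: np.ndarray  # (H, H) father-haplotype x mother-haplotype -> genotype


def compile_structure(genotypes) -> CompiledStructure:
    """Build the gamete and syngamy lookup tables for a genotype universe.

    The universe must be closed under random mating; it is expanded to the
    full cross of the R and D alleles present.
    """
    r_alleles = sorted({a for g in genotypes for a in g.r}, key=allele_sort_key)
    d_alleles = sorted({a for g in genotypes for a in g.d}, key=allele_sort_key)
    universe = []
    for i, r1 in enumerate(r_alleles):
        for r2 in r_alleles[i:]:
            for j, d1 in enumerate(d_alleles):
                for d2 in d_alleles[j:]:
                    universe.append(Genotype.make(r1, r2, d1, d2))
    universe = sorted(set(universe), key=lambda g: g.name)
    index = {g: i for i, g in enumerate(universe)}
    haplotypes = [(r, d) for r in r_alleles for d in d_alleles]
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    G, H = len(universe), len(haplotypes)
    gam = np.zeros((G, H))
    for g, gi in index.items():
        for r in g.r:
            for d in g.d:
                gam[gi, hap_index[(r, d)]] += 0.25
    pair2g = np.zeros((H, H), dtype=np.int64)
    for i, (r1, d1) in enumerate(haplotypes):
        for j, (r2, d2) in enumerate(haplotypes):
            pair2g[i, j] = index[Genotype.make(r1, r2, d1, d2)]
    return CompiledStructure(universe, index, haplotypes, gam, pair2g)


def run_compiled(
    structure: CompiledStructure,
    W: np.ndarray,
    male_mask: np.ndarray,
    female_mask: np.ndarray,
    fm0: np.ndarray,
    ff0: np.ndarray,
    spec: ConvergenceSpec,
):
    """Iterate the kernel from array initial conditions; returns raw arrays."""
    check = spec.check_every if spec.accelerate else 0
    return _iterate(
        W,
        structure.gam,
        structure.pair2g,
        male_mask,
        female_mask,
        fm0.copy(),
        ff0.copy(),
        spec.tol,
        spec.max_generations,
        check,
        spec.prune,
        spec.jump_span,
    )


_STATUS = {0: "converged", 1: "max_generations", 2: "sex_extinction"}


def iterate_compiled(
    initial: PopulationState,
    evaluations,
    spec: ConvergenceSpec,
) -> EquilibriumResult:
    """Dict-state front end to the kernel, mirroring iterate_to_equilibrium."""
    structure = compile_structure(list(initial.support()) + list(evaluations))
    G = len(structure.genotypes)
    W = np.empty(G)
    male_mask = np.zeros(G, dtype=np.bool_)
    female_mask = np.zeros(G, dtype=np.bool_)
    for g, gi in structure.index.items():
        try:
            ev = evaluations[g]
        except KeyError:
            raise SdnetError(f"no evaluation for producible genotype {g.name}") from None
        W[gi] = ev.W
        if ev.sex == MALE:
            male_mask[gi] = True
        else:
            female_mask[gi] = True
    fm0 = np.zeros(G)
    ff0 = np.zeros(G)
    for g, p in initial.male.items():
        fm0[structure.index[g]] = p
    for g, p in initial.female.items():
        ff0[structure.index[g]] = p
    fm, ff, resid, status, iters, virtual = run_compiled(
        structure, W, male_mask, female_mask, fm0, ff0, spec
    )
    state = arrays_to_state(structure, fm, ff, generation=int(min(virtual, 2**62)))
    return EquilibriumResult(
        state,
        status == 0,
        float(resid),
        float(virtual),
        int(iters),
        _STATUS[int(status)],
    )


def arrays_to_state(structure: CompiledStructure, fm, ff, generation: int = 0) -> PopulationState:
    male = {g: float(fm[i]) for g, i in structure.index.items() if fm[i] > 0}
    female = {g: float(ff[i]) for g, i in structure.index.items() if ff[i] > 0}
    return PopulationState(male, female, generation)
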