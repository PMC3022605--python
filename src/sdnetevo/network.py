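"""Steady-state expression of a diploid two-locus regulatory network.

Each allele copy i relaxes to the fixed point of

    S_i = sigma( sum_j I_{i,j} Z_j S_j + k T_i ),        sigma(x) = 1/(1+exp(-h x))

where the sum runs over all allele *copies* j in the genotype (diploid dose:
a homozygous regulator contributes twice) and k > 0 scales the constitutive
term.  For the feed-forward topologies used in the sex-determination model
(R regulates D, nothing regulates R) the fixed point is available in closed
form; :func:`steady_state_general` solves arbitrary topologies, including
autoregulation, by damped iteration from the unregulated levels
S_i(0) = sigma(k T_i).

All operations broadcast over numpy arrays of ``k`` and ``h``, which makes
parameter-grid scans cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .alleles import LOCUS_D, LOCUS_R, AlleleSpec, Genotype
from .errors import CatalogError, ConvergenceError, InvalidParameterError


def sigmoid(x, h):
    """The model sigmoid ``1 / (1 + exp(-h * x))``.

    Strictly increasing in ``x`` with output in the open interval (0, 1);
    ``sigmoid(0, h) == 0.5`` and ``sigmoid(x, h) + sigmoid(-x, h) == 1``.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("sigmoid: x must be finite")
    if not np.all(np.isfinite(h)) or np.any(h <= 0):
        raise InvalidParameterError("sigmoid: steepness h must be finite and > 0")
    out = expit(h * x)
    return float(out) if out.ndim == 0 else out


@dataclass
class NetworkParams:
    """Global network parameters.

    h: steepness of the sigmoid (dimensionless, > 0; sampled in (1.6, 4.6)).
    k: constitutive-expression constant (dimensionless, > 0; sampled in (0, 3)).
    t_a: constitutive sign of the regulator allele A (+1 by default).
    """

    h: float
    k: float
    t_a: int = 1

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if not np.all(np.isfinite(h)) or np.any(h <= 0):
            raise InvalidParameterError(f"h must be finite and > 0, got {self.h!r}")
        if not np.all(np.isfinite(k)) or np.any(k <= 0):
            raise InvalidParameterError(f"k must be finite and > 0, got {self.k!r}")
        if self.t_a not in (-1, 1):
            raise InvalidParameterError(f"t_a must be -1 or +1, got {self.t_a!r}")


@dataclass
class ExpressionProfile:
    """Per-allele-copy steady-state levels of one genotype.

    ``r_levels`` / ``d_levels`` follow the canonical (sorted) copy order of
    the genotype; every level is strictly in (0, 1).  ``s_d`` is the summed
    output of the two D-locus copies, strictly in (0, 2).
    """

    genotype: Genotype
    r_levels: tuple
    d_levels: tuple

    @property
    def s_d(self):
        return self.d_levels[0] + self.d_levels[1]


def _get_spec(catalog: dict[str, AlleleSpec], allele_id: str) -> AlleleSpec:
    try:
        return catalog[allele_id]
    except KeyError:
        raise CatalogError(f"allele {allele_id!r} not in catalog") from None


def _check_feedforward(g: Genotype, catalog) -> None:
    """Require R -> D regulation only: regulators are unregulated, D alleles non-regulatory."""
    present = set(g.r) | set(g.d)
    for rid in g.r:
        spec = _get_spec(catalog, rid)
        if any(v != 0 and j in present for j, v in spec.I.items()):
            raise InvalidParameterError(
                f"R allele {rid!r} is itself regulated; use steady_state_general"
            )
    for did in g.d:
        spec = _get_spec(catalog, did)
        if spec.Z != 0:
            raise InvalidParameterError(
                f"D allele {did!r} is regulatory; use steady_state_general"
            )


def steady_state_feedforward(g: Genotype, params: NetworkParams, catalog) -> ExpressionProfile:
    """Closed-form steady state for feed-forward (R regulates D) genotypes.

    Each R copy settles at its unregulated level sigma(k*T); each D copy at
    sigma(sum over both R copies of I*Z*S_R + k*T_D).  An unregulated D copy
    therefore reduces to sigma(k*T_D) exactly.
    """
    _check_feedforward(g, catalog)
    k, h = params.k, params.h
    r_specs = [_get_spec(catalog, rid) for rid in g.r]
    r_levels = tuple(sigmoid(k * np.asarray(spec.T, float), h) for spec in r_specs)
    d_levels = []
    for did in g.d:
        d_spec = _get_spec(catalog, did)
        x = k * np.asarray(d_spec.T, float)
        for spec, s_r in zip(r_specs, r_levels):
            x = x + d_spec.I.get(spec.id, 0) * spec.Z * s_r
        d_levels.append(sigmoid(x, h))
    return ExpressionProfile(g, r_levels, tuple(d_levels))


def steady_state_general(
    g: Genotype,
    params: NetworkParams,
    catalog,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 0.5,
) -> ExpressionProfile:
    """Fixed point of the expression map for arbitrary regulation topologies.

    Damped iteration S <- (1-d) S + d sigma(W S + k T) from the unregulated
    initial condition S_i(0) = sigma(k T_i).  The sum includes every allele
    copy in the genotype, so autoregulation and D -> R links are supported.
    """
    if not (0 < damping <= 1):
        raise InvalidParameterError(f"damping must be in (0, 1], got {damping!r}")
    k, h = params.k, params.h
    copies = [(LOCUS_R, rid) for rid in g.r] + [(LOCUS_D, did) for did in g.d]
    specs = [_get_spec(catalog, aid) for _, aid in copies]
    t_vec = [np.asarray(s.T, float) for s in specs]
    levels = [sigmoid(k * t, h) for t in t_vec]
    resid = np.inf
    for _ in range(max_iter):
        new = []
        for i, spec in enumerate(specs):
            x = k * t_vec[i]
            for j, other in enumerate(specs):
                x = x + spec.I.get(other.id, 0) * other.Z * levels[j]
            new.append(sigmoid(x, h))
        resid = max(float(np.max(np.abs(np.asarray(n) - np.asarray(o))))
                    for n, o in zip(new, levels))
        levels = [(1 - damping) * np.asarray(o, float) + damping * np.asarray(n, float)
                  for o, n in zip(levels, new)]
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"no fixed point within {max_iter} iterations (residual {resid:.3e})",
            residual=resid,
        )
    lv = [float(x) if np.ndim(x) == 0 else x for x in levels]
    return ExpressionProfile(g, (lv[0], lv[1]), (lv[2], lv[3]))


def d_locus_output(g: Genotype, params: NetworkParams, catalog):
    """Summed steady-state output S_D of the two D-locus copies (in (0, 2))."""
    return steady_state_feedforward(g, params, catalog).s_d
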