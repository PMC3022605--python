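"""Threshold sex assignment and expression-derived fitness.

Phenotypic sex is read off the summed D-locus output S_D against a threshold
theta = sigma(k) + 1/2, the midpoint between the two ancestral genotypes'
expression levels (heterozygote: 1; homozygote: 2 sigma(k)).  The genotype on
the high side of theta develops as the homogametic sex -- female under
ancestral male heterogamety (the XY-like case the sex rule "S_D > theta =>
female" describes), male under ancestral female heterogamety (the ZW-like
mirror).  Exact ties go to the heterogametic sex.

Fitness is frequency-independent viability derived from the expression change
a genotype shows relative to the background genotype of the same phenotypic
sex: W = 1 + dS_D * w_sex, with w_M, w_F the sex-specific selection
coefficients.  Background genotypes therefore have W = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import Genotype
from .errors import InvalidParameterError, SdnetError
from .network import NetworkParams, d_locus_output, sigmoid

MALE = "male"
FEMALE = "female"


def homogametic_sex(heterogamety: str) -> str:
    if heterogamety == MALE:
        return FEMALE
    if heterogamety == FEMALE:
        return MALE
    raise InvalidParameterError(f"heterogamety must be 'male' or 'female', got {heterogamety!r}")


def theta(params: NetworkParams):
    """Sex-determination threshold theta = sigma(k) + 1/2.

    Midpoint of the two ancestral expression levels (1 and 2 sigma(k));
    strictly between 1 and 1.5 for k > 0.
    """
    return sigmoid(params.k, params.h) + 0.5


def assign_sex(s_d, theta_value, heterogamety: str = MALE):
    """Phenotypic sex from S_D: the high side of theta is the homogametic sex.

    Under male heterogamety this is the rule "if S_D > theta then female,
    otherwise male"; ties go to the heterogametic sex.  Accepts scalars or
    arrays (returns an array of sex strings for array input).
    """
    high = homogametic_sex(heterogamety)
    low = heterogamety
    s_d = np.asarray(s_d)
    if s_d.ndim == 0:
        return high if float(s_d) > float(theta_value) else low
    return np.where(s_d > theta_value, high, low)


@dataclass
class FitnessParams:
    """Sex-specific selection coefficients on D-locus expression change.

    Sampled in (-1/2, 1/2); with |dS_D| < 2 this keeps every fitness
    W = 1 + dS_D * w strictly positive.
    """

    w_m: float
    w_f: float

    def __post_init__(self):
        if not (np.isfinite(self.w_m) and np.isfinite(self.w_f)):
            raise InvalidParameterError("selection coefficients must be finite")


@dataclass
class GenotypeEvaluation:
    """Sex, expression change and fitness of one genotype under fixed parameters."""

    genotype: Genotype
    sex: str
    delta_sd: float
    W: float


def reference_genotype(g: Genotype, pair, sex: str) -> Genotype:
    """Background-state genotype of the given phenotypic sex (Mutation-pair table roles)."""
    try:
        return pair.bg_by_sex[sex]
    except KeyError:
        raise SdnetError(f"no background genotype for sex {sex!r}") from None


def evaluate_genotype(
    g: Genotype,
    pair,
    params: NetworkParams,
    fitness: FitnessParams,
) -> GenotypeEvaluation:
    """Evaluate sex, dS_D and fitness of ``g`` within a mutation-pair experiment.

    dS_D is measured against the background genotype of the same phenotypic
    sex as ``g``; the matching selection coefficient then gives
    W = 1 + dS_D * w_sex.
    """
    s_d = d_locus_output(g, params, pair.catalog)
    th = theta(params)
    sex = assign_sex(s_d, th, pair.heterogamety)
    ref = reference_genotype(g, pair, sex)
    delta = float(s_d - d_locus_output(ref, params, pair.catalog))
    w = fitness.w_m if sex == MALE else fitness.w_f
    fit = 1.0 + delta * w
    if fit <= 0:
        raise InvalidParameterError(
            f"fitness W = {fit:.4g} <= 0 for {g.name}; |dS_D * w| must stay below 1"
        )
    return GenotypeEvaluation(g, sex, delta, fit)
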