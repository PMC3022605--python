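"""Allele catalogs and diploid genotypes.

An allele is a regulatory identity: a constitutive output sign ``T`` (low -1 /
high +1, scaled by the global constant ``k``), a regulatory-capability flag
``Z`` (1 if the allele's product can regulate other alleles), and an input map
``I`` giving the sign (+1 up, -1 down, 0 none) with which each *regulator*
allele acts on this allele.

Two loci are modelled: the ancestral sex-determining locus ``D`` (alleles
m, f and their regulable variants m+, m-, f+, f-) and an unlinked regulator
locus ``R`` (ancestral non-regulatory ``a`` and gain-of-function ``A``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CatalogError, InvalidParameterError

LOCUS_R = "R"
LOCUS_D = "D"

#: canonical display/sort order for the built-in alleles
ALLELE_ORDER = ("a", "A", "m", "m+", "m-", "f", "f+", "f-")


def allele_sort_key(allele_id: str):
    """Sort key giving the conventional display order (a < A < m-family < f-family)."""
    try:
        return (0, ALLELE_ORDER.index(allele_id))
    except ValueError:
        return (1, allele_id)


@dataclass
class AlleleSpec:
    """Regulatory identity of one allele.

    Parameters
    ----------
    id:
        Symbolic label, e.g. ``"f-"``.
    locus:
        ``"R"`` or ``"D"``.
    T:
        Constitutive output sign, -1 (low) or +1 (high).
    Z:
        1 if the allele codes a regulatory domain, else 0.
    I:
        Map regulator-allele-id -> sensitivity in {-1, 0, +1}.
    """

    id: str
    locus: str
    T: int
    Z: int
    I: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.locus not in (LOCUS_R, LOCUS_D):
            raise InvalidParameterError(f"locus must be 'R' or 'D', got {self.locus!r}")
        if self.T not in (-1, 1):
            raise InvalidParameterError(f"T must be -1 or +1, got {self.T!r}")
        if self.Z not in (0, 1):
            raise InvalidParameterError(f"Z must be 0 or 1, got {self.Z!r}")
        for j, v in self.I.items():
            if v not in (-1, 0, 1):
                raise InvalidParameterError(f"I[{self.id},{j}] must be in {{-1,0,+1}}, got {v!r}")


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid allele pair at each of the R and D loci.

    Allele pairs are stored canonically sorted, so ``x/y`` and ``y/x`` compare
    equal and hash identically.
    """

    r: tuple[str, str]
    d: tuple[str, str]

    @classmethod
    def make(cls, r1: str, r2: str, d1: str, d2: str) -> "Genotype":
        r = tuple(sorted((r1, r2), key=allele_sort_key))
        d = tuple(sorted((d1, d2), key=allele_sort_key))
        return cls(r, d)  # type: ignore[arg-type]

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        """Parse the string form ``"r1/r2;d1/d2"`` (e.g. ``"a/A;m/f-"``)."""
        try:
            r_part, d_part = text.strip().split(";")
            r1, r2 = r_part.split("/")
            d1, d2 = d_part.split("/")
        except ValueError as exc:
            raise InvalidParameterError(f"cannot parse genotype {text!r}") from exc
        return cls.make(r1, r2, d1, d2)

    @property
    def name(self) -> str:
        return f"{self.r[0]}/{self.r[1]};{self.d[0]}/{self.d[1]}"

    @property
    def d_name(self) -> str:
        """D-locus part alone (the form used when the R locus is monomorphic)."""
        return f"{self.d[0]}/{self.d[1]}"

    def alleles(self, locus: str) -> tuple[str, str]:
        if locus == LOCUS_R:
            return self.r
        if locus == LOCUS_D:
            return self.d
        raise InvalidParameterError(f"unknown locus {locus!r}")

    def heterozygous_at(self, locus: str) -> bool:
        pair = self.alleles(locus)
        return pair[0] != pair[1]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def build_catalog(
    d_alleles,
    *,
    t_a: int = 1,
    heterogamety: str = "male",
    r_alleles=("a", "A"),
) -> dict[str, AlleleSpec]:
    """Build an allele catalog for the requested allele universe.

    Under ancestral male heterogamety the dominant allele carried by the
    heterogametic sex is the low-output m (T=-1) and the homogametic allele is
    the high-output f (T=+1).  Under ancestral female heterogamety the roles
    swap: f becomes the low dominant allele of heterozygous females and m the
    high allele of homozygous males.  Variant superscripts always denote the
    sign with which the regulator A acts on the allele (+ up, - down).
    """
    if heterogamety not in ("male", "female"):
        raise InvalidParameterError(f"heterogamety must be 'male' or 'female', got {heterogamety!r}")
    if t_a not in (-1, 1):
        raise InvalidParameterError(f"T_A must be -1 or +1, got {t_a!r}")
    # base T per family; variants inherit the parent family's T
    t_m = -1 if heterogamety == "male" else 1
    t_f = -t_m
    base = {
        "a": AlleleSpec("a", LOCUS_R, T=1, Z=0),
        "A": AlleleSpec("A", LOCUS_R, T=t_a, Z=1),
        "m": AlleleSpec("m", LOCUS_D, T=t_m, Z=0),
        "f": AlleleSpec("f", LOCUS_D, T=t_f, Z=0),
        "m+": AlleleSpec("m+", LOCUS_D, T=t_m, Z=0, I={"A": 1}),
        "m-": AlleleSpec("m-", LOCUS_D, T=t_m, Z=0, I={"A": -1}),
        "f+": AlleleSpec("f+", LOCUS_D, T=t_f, Z=0, I={"A": 1}),
        "f-": AlleleSpec("f-", LOCUS_D, T=t_f, Z=0, I={"A": -1}),
    }
    catalog: dict[str, AlleleSpec] = {}
    for aid in tuple(r_alleles) + tuple(d_alleles):
        if aid not in base:
            raise CatalogError(f"unknown built-in allele {aid!r}")
        catalog[aid] = base[aid]
    return catalog


def catalog_from_dict(data: dict) -> dict[str, AlleleSpec]:
    """Build a catalog from a plain mapping (as read from JSON/YAML config).

    Expected form::

        {"alleles": [{"id": "A", "locus": "R", "T": 1, "Z": 1, "I": {}}, ...]}
    """
    catalog = {}
    for entry in data.get("alleles", []):
        spec = AlleleSpec(
            id=entry["id"],
            locus=entry["locus"],
            T=int(entry["T"]),
            Z=int(entry.get("Z", 0)),
            I={k: int(v) for k, v in entry.get("I", {}).items()},
        )
        catalog[spec.id] = spec
    if not catalog:
        raise InvalidParameterError("catalog config contains no alleles")
    return catalog


def load_catalog(path) -> dict[str, AlleleSpec]:
    """Load an allele catalog from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return catalog_from_dict(data)
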