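"""Domain types and probability-distribution primitives.

All distributions here are discrete maps from an *unphased* state (an
unordered pair of alleles or of founder-haplotype labels) to a probability.
States are canonicalized with :func:`canonical_unphased` so that the two
orderings of a pair always collapse onto a single key.

Coordinates are 1-based and fully closed, matching VCF ``POS``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

__all__ = [
    "TOL",
    "DEFAULT_FOUNDERS",
    "Variant",
    "HaplotypeSet",
    "FounderGenotypeDistribution",
    "DiplotypeDistribution",
    "InterpolationWeights",
    "GenotypeDistribution",
    "TransmissionDistribution",
    "ConsequenceAnnotation",
    "QueryRow",
    "canonical_unphased",
    "normalize_check",
    "ValidationError",
    "MissingDataError",
]

#: Tolerance for all probability equality comparisons.
TOL = 1e-9

#: Standard eight-founder panel labels (customizable everywhere).
DEFAULT_FOUNDERS = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")

PairKey = tuple[str, str]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class MissingDataError(KeyError):
    """Raised when a required founder distribution or annotation is absent."""


def canonical_unphased(allele_a: str, allele_b: str) -> PairKey:
    """Return the canonical unordered-pair key for two alleles or haplotypes.

    The key is the lexicographically sorted tuple, so ``(a, b)`` and
    ``(b, a)`` map to the same key.  For alleles where one is a prefix of
    the other (indels), the shorter string sorts first, which Python's
    string ordering already guarantees.

    Raises
    ------
    ValidationError
        If either string is empty.
    """
    if not allele_a or not allele_b:
        raise ValidationError("allele/haplotype labels must be non-empty strings")
    if allele_a <= allele_b:
        return (allele_a, allele_b)
    return (allele_b, allele_a)


def pair_display(key: PairKey) -> str:
    return f"{key[0]}/{key[1]}"


def normalize_check(dist: Union[Mapping, "ProbabilityDistribution"], tol: float = TOL) -> bool:
    """True iff the distribution's total mass is within ``tol`` of 1.

    Never mutates the distribution.  Distinguishes pruned (mass < 1) from
    unpruned states.

    Raises
    ------
    ValidationError
        If ``tol`` is not positive or any probability is negative.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    probs = dist.probs if isinstance(dist, ProbabilityDistribution) else dist
    total = 0.0
    for key, p in probs.items():
        if p < 0:
            raise ValidationError(f"negative probability {p} for state {key!r}")
        total += p
    return abs(total - 1.0) <= tol


def _validate_probs(probs: Mapping, *, allow_deficit: bool = True) -> None:
    total = 0.0
    for key, p in probs.items():
        if not (0.0 <= p <= 1.0 + TOL):
            raise ValidationError(f"probability {p} for state {key!r} outside [0, 1]")
        total += p
    if total > 1.0 + TOL:
        raise ValidationError(f"total probability {total} exceeds 1")
    if not allow_deficit and abs(total - 1.0) > TOL:
        raise ValidationError(f"total probability {total} != 1")


@dataclass(frozen=True)
class Variant:
    """A SNP or short indel (alleles 1-100 bp), VCF-anchored."""

    variant_id: int
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        alleles = (self.ref_allele, *self.alt_alleles)
        for a in alleles:
            if not a or len(a) > 100:
                raise ValidationError(f"allele {a!r} must be 1-100 bp")
        if not self.alt_alleles:
            raise ValidationError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValidationError("alt alleles must differ from the reference allele")
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise ValidationError("alt alleles must be unique")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    @property
    def variant_class(self) -> str:
        if all(len(a) == 1 for a in self.alleles):
            return "SNP"
        return "indel"

    @property
    def ref_span(self) -> tuple[int, int]:
        """Closed 1-based interval of reference bases covered by this variant."""
        return (self.pos, self.pos + len(self.ref_allele) - 1)


@dataclass(frozen=True)
class HaplotypeSet:
    """Ordered set of founder-strain labels composing every mosaic genome."""

    founders: tuple[str, ...] = DEFAULT_FOUNDERS

    def __post_init__(self) -> None:
        if len(set(self.founders)) != len(self.founders):
            raise ValidationError("founder names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.founders

    def __iter__(self):
        return iter(self.founders)

    def __len__(self) -> int:
        return len(self.founders)

    def unordered_pairs(self) -> list[PairKey]:
        """All unordered founder pairs (36 states for 8 founders)."""
        out = []
        for i, a in enumerate(self.founders):
            for b in self.founders[i:]:
                out.append(canonical_unphased(a, b))
        return out


class ProbabilityDistribution:
    """Base for all discrete unphased-state distributions."""

    probs: dict[PairKey, float]

    def total(self) -> float:
        return sum(self.probs.values())

    def is_normalized(self, tol: float = TOL) -> bool:
        return normalize_check(self.probs, tol)

    def max_states(self, tol: float = TOL) -> list[PairKey]:
        """States attaining the maximum probability, within ``tol``."""
        if not self.probs:
            return []
        best = max(self.probs.values())
        return [k for k, p in self.probs.items() if p >= best - tol]

    def items(self):
        return self.probs.items()

    def __getitem__(self, key: PairKey) -> float:
        return self.probs[key]

    def __len__(self) -> int:
        return len(self.probs)


def _canonical_probs(probs: Mapping) -> dict[PairKey, float]:
    out: dict[PairKey, float] = {}
    for key, p in probs.items():
        a, b = key
        k = canonical_unphased(a, b)
        out[k] = out.get(k, 0.0) + p
    return out


@dataclass
class FounderGenotypeDistribution(ProbabilityDistribution):
    """Per (variant, founder) distribution over unphased genotypes."""

    variant: Variant
    founder: str
    probs: dict[PairKey, float]

    def __post_init__(self) -> None:
        self.probs = _canonical_probs(self.probs)
        _validate_probs(self.probs)
        allowed = set(self.variant.alleles)
        for a, b in self.probs:
            if a not in allowed or b not in allowed:
                raise ValidationError(
                    f"genotype {a}/{b} uses alleles outside variant "
                    f"{self.variant.chrom}:{self.variant.pos} allele set"
                )

    @classmethod
    def point_mass(cls, variant: Variant, founder: str, allele_a: str, allele_b: str):
        return cls(variant, founder, {canonical_unphased(allele_a, allele_b): 1.0})


@dataclass
class DiplotypeDistribution(ProbabilityDistribution):
    """Per (strain, locus) distribution over unphased founder pairs."""

    strain: str
    chrom: str
    pos: int
    probs: dict[PairKey, float]
    source: str = "marker"  # marker | interpolated

    def __post_init__(self) -> None:
        if self.source not in ("marker", "interpolated"):
            raise ValidationError(f"unknown source {self.source!r}")
        self.probs = _canonical_probs(self.probs)
        _validate_probs(self.probs)


@dataclass(frozen=True)
class InterpolationWeights:
    """Distances (bp) from a variant to its flanking markers."""

    wl: float
    wr: float

    def __post_init__(self) -> None:
        if self.wl < 0 or self.wr < 0:
            raise ValidationError("marker distances must be non-negative")


@dataclass
class GenotypeDistribution(ProbabilityDistribution):
    """Per (strain, variant) distribution over unphased allele pairs.

    ``strain`` is a single name, or a 2-tuple for an F1 offspring.
    """

    strain: Union[str, tuple[str, str]]
    variant: Variant
    probs: dict[PairKey, float]

    def __post_init__(self) -> None:
        self.probs = _canonical_probs(self.probs)
        _validate_probs(self.probs)

    def heterozygous_mass(self) -> float:
        return sum(p for (a, b), p in self.probs.items() if a != b)


@dataclass
class TransmissionDistribution:
    """Per parent, probability of each transmissible allele (or haplotype)."""

    source: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        for a, p in self.probs.items():
            if not a:
                raise ValidationError("transmitted state label must be non-empty")
            if p < -TOL or p > 1 + TOL:
                raise ValidationError(f"transmission probability {p} outside [0, 1]")

    def total(self) -> float:
        return sum(self.probs.values())

    def items(self):
        return self.probs.items()

    def __getitem__(self, key: str) -> float:
        return self.probs[key]


REFERENCE_TERM = "reference"
UNANNOTATED_TERM = "unannotated"


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Predicted effect of one allele on one transcript."""

    chrom: str
    pos: int
    allele: str
    gene_id: str
    transcript_id: str
    term: str

    def __post_init__(self) -> None:
        if not self.allele:
            raise ValidationError("allele must be non-empty")
        if not self.term:
            raise ValidationError("consequence term must be non-empty")


@dataclass
class QueryRow:
    """One output record of the 12-column genotype-query schema."""

    variant_id: int
    chrom: str
    pos: int
    strain: Union[str, tuple[str, str]]
    allele_1: str
    allele_2: str
    prob: float
    is_max: bool = False
    gene_id: str = ""
    transcript_id: str = ""
    consequence_1: str = ""
    consequence_2: str = ""

    def __post_init__(self) -> None:
        if self.allele_1 > self.allele_2:
            raise ValidationError("allele_1 must not sort after allele_2")
        if not (0.0 < self.prob <= 1.0 + TOL):
            raise ValidationError(f"row probability {self.prob} outside (0, 1]")

    @property
    def group_key(self):
        return (self.variant_id, self.strain, self.gene_id, self.transcript_id)

    @property
    def zygosity(self) -> str:
        return "hom" if self.allele_1 == self.allele_2 else "het"
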