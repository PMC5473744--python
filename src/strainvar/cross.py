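"""F1 cross simulation from stored parent distributions.

Offspring genotype/diplotype distributions are computed on demand by
combining each parent's transmission distribution; transmission from the
two parents is independent.  Works identically for allele pairs and for
founder-haplotype pairs.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .core import (
    ConsequenceAnnotation,
    DiplotypeDistribution,
    FounderGenotypeDistribution,
    GenotypeDistribution,
    MissingDataError,
    REFERENCE_TERM,
    TransmissionDistribution,
    ValidationError,
    canonical_unphased,
)
from .imputation import _transmission_table

__all__ = [
    "strain_transmission",
    "f1_genotype",
    "f1_diplotype",
    "f1_consequence_prob",
]


def strain_transmission(parent_gt: GenotypeDistribution) -> TransmissionDistribution:
    """Distribution of the single allele a parent strain transmits.

    Each genotype contributes half a copy per allele; total mass equals the
    parent distribution's mass (< 1 if the parent was pruned).
    """
    if not parent_gt.probs:
        raise ValidationError("parent genotype distribution is empty")
    probs: dict[str, float] = {}
    for (a, b), p in parent_gt.probs.items():
        probs[a] = probs.get(a, 0.0) + p / 2.0
        probs[b] = probs.get(b, 0.0) + p / 2.0
    name = parent_gt.strain if isinstance(parent_gt.strain, str) else "/".join(parent_gt.strain)
    return TransmissionDistribution(source=name, probs=probs)


def _combine_transmissions(
    t1: Mapping[str, float], t2: Mapping[str, float]
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for a, p1 in t1.items():
        for b, p2 in t2.items():
            if p1 * p2 == 0.0:
                continue
            key = canonical_unphased(a, b)
            out[key] = out.get(key, 0.0) + p1 * p2
    return out


def f1_genotype(
    parent1_gt: GenotypeDistribution, parent2_gt: GenotypeDistribution
) -> GenotypeDistribution:
    """Unphased genotype distribution of the F1 offspring of two strains.

    For distinct alleles the two phased orderings sum; mass equals the
    product of the parents' masses (1 for unpruned inputs).
    """
    v1, v2 = parent1_gt.variant, parent2_gt.variant
    if (v1.chrom, v1.pos, v1.ref_allele) != (v2.chrom, v2.pos, v2.ref_allele):
        raise ValidationError(
            f"parent distributions refer to different variants: "
            f"{v1.chrom}:{v1.pos} vs {v2.chrom}:{v2.pos}"
        )
    t1 = strain_transmission(parent1_gt).probs
    t2 = strain_transmission(parent2_gt).probs
    probs = _combine_transmissions(t1, t2)
    return GenotypeDistribution(
        strain=(str(parent1_gt.strain), str(parent2_gt.strain)),
        variant=v1, probs=probs,
    )


def diplotype_transmission(parent_dip: DiplotypeDistribution) -> TransmissionDistribution:
    """Distribution of the founder haplotype a parent transmits at a locus."""
    if not parent_dip.probs:
        raise ValidationError("parent diplotype distribution is empty")
    probs: dict[str, float] = {}
    for (h, h2), p in parent_dip.probs.items():
        probs[h] = probs.get(h, 0.0) + p / 2.0
        probs[h2] = probs.get(h2, 0.0) + p / 2.0
    return TransmissionDistribution(source=parent_dip.strain, probs=probs)


def f1_diplotype(
    parent1_dip: DiplotypeDistribution, parent2_dip: DiplotypeDistribution
) -> DiplotypeDistribution:
    """Unphased diplotype distribution of the F1 offspring at a locus."""
    if (parent1_dip.chrom, parent1_dip.pos) != (parent2_dip.chrom, parent2_dip.pos):
        raise ValidationError(
            f"parent diplotypes refer to different loci: "
            f"{parent1_dip.chrom}:{parent1_dip.pos} vs "
            f"{parent2_dip.chrom}:{parent2_dip.pos}"
        )
    t1 = diplotype_transmission(parent1_dip).probs
    t2 = diplotype_transmission(parent2_dip).probs
    probs = _combine_transmissions(t1, t2)
    return DiplotypeDistribution(
        strain=f"{parent1_dip.strain}x{parent2_dip.strain}",
        chrom=parent1_dip.chrom, pos=parent1_dip.pos,
        probs=probs, source="interpolated",
    )


def f1_consequence_prob(
    parent_dip: DiplotypeDistribution,
    annotations: Iterable[ConsequenceAnnotation],
    founder_gts: Mapping[str, FounderGenotypeDistribution],
) -> dict[str, float]:
    """Per-consequence probability for the allele this parent transmits.

    Marginalizes over the parent's diplotype, haplotype transmission, and
    each founder's (possibly uncertain) genotype.  Reference alleles map to
    the literal term ``"reference"``.

    Raises
    ------
    MissingDataError
        If a transmissible non-reference allele has no annotation.
    """
    term_by_allele: dict[str, str] = {}
    variant = None
    for ann in annotations:
        term_by_allele[ann.allele] = ann.term

    hap_trans = diplotype_transmission(parent_dip).probs
    out: dict[str, float] = {}
    for hap, p_hap in hap_trans.items():
        if p_hap == 0.0:
            continue
        if hap not in founder_gts:
            raise MissingDataError(
                f"no founder genotype distribution for haplotype {hap!r} at "
                f"{parent_dip.chrom}:{parent_dip.pos}"
            )
        gt = founder_gts[hap]
        variant = gt.variant
        for allele, p_allele in _transmission_table(gt).items():
            if p_allele == 0.0:
                continue
            if allele == variant.ref_allele:
                term = REFERENCE_TERM
            elif allele in term_by_allele:
                term = term_by_allele[allele]
            else:
                raise MissingDataError(
                    f"allele {allele!r} at {variant.chrom}:{variant.pos} has no "
                    f"consequence annotation"
                )
            out[term] = out.get(term, 0.0) + p_hap * p_allele
    return out
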