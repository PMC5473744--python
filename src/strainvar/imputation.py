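"""Marker interpolation and haplotype-based genotype imputation.

The pipeline for one (strain, variant) pair:

1. interpolate the two flanking marker diplotype distributions onto the
   variant position;
2. split each unphased diplotype state into its equally likely phasings;
3. for every phased founder pair, multiply the independent per-haplotype
   allele-transmission probabilities;
4. collapse ordered allele pairs back onto unphased genotypes.

Each variant is imputed independently; no linkage across variants.
"""

from __future__ import annotations

import logging
from typing import Mapping

from .core import (
    TOL,
    DiplotypeDistribution,
    FounderGenotypeDistribution,
    GenotypeDistribution,
    InterpolationWeights,
    MissingDataError,
    ValidationError,
    Variant,
    canonical_unphased,
)

logger = logging.getLogger(__name__)

__all__ = [
    "interpolate_diplotype",
    "phase_diplotype",
    "transmission_prob",
    "genotype_given_phased_diplotype",
    "impute_diplotype",
    "impute_genotype",
    "genotype_from_diplotype",
    "prune_distribution",
    "PRUNE_THRESHOLD",
]

#: Default probability floor below which stored entries are dropped.
PRUNE_THRESHOLD = 0.001

#: Interpolation weight conventions.  ``proximal`` weights each marker by the
#: distance to the *opposite* marker, so a variant coinciding with a marker
#: takes that marker's distribution exactly.  ``as_printed`` applies the
#: distances to their own markers instead.
MODES = ("proximal", "as_printed")


def interpolate_diplotype(
    left: DiplotypeDistribution | None,
    right: DiplotypeDistribution | None,
    weights: InterpolationWeights,
    mode: str = "proximal",
) -> DiplotypeDistribution:
    """Linearly interpolate two flanking marker distributions.

    If only one flanking marker exists (variant outside the marker span),
    that marker's distribution is returned unchanged apart from its source
    tag.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if left is None and right is None:
        raise ValidationError("at least one flanking marker is required")
    if left is None or right is None:
        only = left if right is None else right
        return DiplotypeDistribution(
            strain=only.strain, chrom=only.chrom, pos=only.pos,
            probs=dict(only.probs), source="interpolated",
        )
    if left.strain != right.strain or left.chrom != right.chrom:
        raise ValidationError("flanking markers must share strain and chromosome")

    wl, wr = weights.wl, weights.wr
    if wl + wr == 0:
        if left.probs != right.probs:
            raise ValidationError(
                "co-located markers with differing distributions must be merged upstream"
            )
        return DiplotypeDistribution(
            strain=left.strain, chrom=left.chrom, pos=left.pos,
            probs=dict(left.probs), source="interpolated",
        )

    # complements computed as 1 - x so the weights sum to exactly 1.0
    if mode == "proximal":
        a_left = wr / (wl + wr)
    else:  # as_printed
        a_left = wl / (wl + wr)
    a_right = 1.0 - a_left

    keys = set(left.probs) | set(right.probs)
    probs = {}
    for k in keys:
        p = a_left * left.probs.get(k, 0.0) + a_right * right.probs.get(k, 0.0)
        if p > 0.0:
            probs[k] = p
    return DiplotypeDistribution(
        strain=left.strain, chrom=left.chrom, pos=left.pos,
        probs=probs, source="interpolated",
    )


def phase_diplotype(unphased: DiplotypeDistribution) -> dict[tuple[str, str], float]:
    """Split unphased diplotype mass over equally likely phasings.

    Heterozygous states contribute half their mass to each ordering;
    homozygous states keep full mass in their single phasing.  Total mass
    is preserved exactly.
    """
    phased: dict[tuple[str, str], float] = {}
    for (h, h2), p in unphased.probs.items():
        if h == h2:
            phased[(h, h2)] = phased.get((h, h2), 0.0) + p
        else:
            phased[(h, h2)] = phased.get((h, h2), 0.0) + p / 2.0
            phased[(h2, h)] = phased.get((h2, h), 0.0) + p / 2.0
    return phased


def transmission_prob(founder_gt: FounderGenotypeDistribution, allele: str) -> float:
    """Probability that the founder haplotype transmits ``allele``.

    Marginalizes over the founder's (possibly uncertain, possibly
    heterozygous) genotype; either copy is transmitted with equal chance.
    """
    if allele not in founder_gt.variant.alleles:
        raise ValidationError(
            f"allele {allele!r} not in variant "
            f"{founder_gt.variant.chrom}:{founder_gt.variant.pos} allele set"
        )
    total = 0.0
    for (a, b), p in founder_gt.probs.items():
        copies = (a == allele) + (b == allele)
        total += (copies / 2.0) * p
    return total


def _transmission_table(
    founder_gt: FounderGenotypeDistribution,
) -> dict[str, float]:
    """Allele -> transmission probability, restricted to nonzero entries."""
    table: dict[str, float] = {}
    for (a, b), p in founder_gt.probs.items():
        table[a] = table.get(a, 0.0) + p / 2.0
        table[b] = table.get(b, 0.0) + p / 2.0
    return table


def genotype_given_phased_diplotype(
    dip: tuple[str, str],
    founder_gts: Mapping[str, FounderGenotypeDistribution],
    variant: Variant,
) -> dict[tuple[str, str], float]:
    """Ordered allele-pair distribution conditional on a phased diplotype.

    Maternal and paternal alleles are transmitted independently, so the
    probability of (a, a') is the product of the two per-haplotype
    transmission probabilities.
    """
    h, h2 = dip
    for founder in (h, h2):
        if founder not in founder_gts:
            raise MissingDataError(
                f"no founder genotype distribution for {founder!r} at "
                f"{variant.chrom}:{variant.pos}"
            )
    t1 = _transmission_table(founder_gts[h])
    t2 = _transmission_table(founder_gts[h2])
    out: dict[tuple[str, str], float] = {}
    for a, p1 in t1.items():
        for a2, p2 in t2.items():
            if p1 * p2 > 0.0:
                out[(a, a2)] = out.get((a, a2), 0.0) + p1 * p2
    return out


def _default_founder_gt(
    variant: Variant, founder: str, strict: bool
) -> FounderGenotypeDistribution:
    if strict:
        raise MissingDataError(
            f"no founder genotype distribution for {founder!r} at "
            f"{variant.chrom}:{variant.pos}"
        )
    logger.debug(
        "founder %s absent at %s:%d; assuming homozygous reference",
        founder, variant.chrom, variant.pos,
    )
    return FounderGenotypeDistribution.point_mass(
        variant, founder, variant.ref_allele, variant.ref_allele
    )


def impute_diplotype(
    strain: str,
    variant: Variant,
    left: DiplotypeDistribution | None,
    right: DiplotypeDistribution | None,
    mode: str = "proximal",
) -> DiplotypeDistribution:
    """Diplotype distribution at a variant position, by marker interpolation."""
    if left is None and right is None:
        raise ValidationError(
            f"no flanking markers for strain {strain!r} on {variant.chrom}"
        )
    if left is not None and right is not None:
        weights = InterpolationWeights(
            wl=variant.pos - left.pos, wr=right.pos - variant.pos
        )
    else:
        weights = InterpolationWeights(0, 0)
    dip = interpolate_diplotype(left, right, weights, mode=mode)
    return DiplotypeDistribution(
        strain=strain, chrom=variant.chrom, pos=variant.pos,
        probs=dip.probs, source="interpolated",
    )


def impute_genotype(
    strain: str,
    variant: Variant,
    left: DiplotypeDistribution | None,
    right: DiplotypeDistribution | None,
    founder_gts: Mapping[str, FounderGenotypeDistribution],
    mode: str = "proximal",
    strict: bool = False,
) -> GenotypeDistribution:
    """Unphased genotype distribution for a strain at a variant.

    Composes marker interpolation, phasing, independent per-haplotype
    allele transmission, and unphasing.  With unpruned inputs the result
    sums to 1 within ``TOL``.

    A founder absent from ``founder_gts`` is treated as homozygous
    reference (VCF convention for non-variant samples) unless ``strict``.
    """
    dip = impute_diplotype(strain, variant, left, right, mode=mode)
    return genotype_from_diplotype(strain, variant, dip, founder_gts, strict=strict)


def genotype_from_diplotype(
    strain: str,
    variant: Variant,
    dip: DiplotypeDistribution,
    founder_gts: Mapping[str, FounderGenotypeDistribution],
    strict: bool = False,
) -> GenotypeDistribution:
    """Unphased genotype distribution given an already-resolved diplotype."""
    phased_dip = phase_diplotype(dip)

    gts = dict(founder_gts)
    for h, h2 in phased_dip:
        for founder in (h, h2):
            if founder not in gts:
                gts[founder] = _default_founder_gt(variant, founder, strict)

    # Cache per-founder transmission tables; phased diplotypes come in
    # symmetric pairs so ordered-pair products are reused heavily.
    tables = {f: _transmission_table(gts[f]) for f in {h for k in phased_dip for h in k}}

    unphased: dict[tuple[str, str], float] = {}
    for (h, h2), pd in phased_dip.items():
        if pd == 0.0:
            continue
        t1, t2 = tables[h], tables[h2]
        for a, p1 in t1.items():
            contrib = pd * p1
            if contrib == 0.0:
                continue
            for a2, p2 in t2.items():
                if p2 == 0.0:
                    continue
                key = canonical_unphased(a, a2)
                unphased[key] = unphased.get(key, 0.0) + contrib * p2
    return GenotypeDistribution(strain=strain, variant=variant, probs=unphased)


def prune_distribution(dist, threshold: float = PRUNE_THRESHOLD):
    """Drop entries with probability below ``threshold``.

    Remaining probabilities are **not** renormalized, so pruned
    distributions may sum to less than 1.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValidationError(f"prune threshold must be in [0, 1), got {threshold}")
    if threshold == 0.0:
        return dist
    kept = {k: p for k, p in dist.probs.items() if p >= threshold}
    if isinstance(dist, DiplotypeDistribution):
        return DiplotypeDistribution(
            strain=dist.strain, chrom=dist.chrom, pos=dist.pos,
            probs=kept, source=dist.source,
        )
    if isinstance(dist, GenotypeDistribution):
        return GenotypeDistribution(strain=dist.strain, variant=dist.variant, probs=kept)
    if isinstance(dist, FounderGenotypeDistribution):
        return FounderGenotypeDistribution(
            variant=dist.variant, founder=dist.founder, probs=kept
        )
    raise ValidationError(f"cannot prune object of type {type(dist).__name__}")
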