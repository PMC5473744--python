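"""Uncertainty-preserving functional-consequence annotation.

Annotation replicates genotype records per overlapping (gene, transcript)
and attaches a per-allele consequence term; it never re-weights
probabilities, so each transcript group carries the full genotype
distribution.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .core import (
    TOL,
    ConsequenceAnnotation,
    GenotypeDistribution,
    MissingDataError,
    QueryRow,
    REFERENCE_TERM,
    UNANNOTATED_TERM,
)

logger = logging.getLogger(__name__)

__all__ = ["annotate_genotype_rows", "flag_is_max"]


def _term_lookup(
    annotations: Iterable[ConsequenceAnnotation],
) -> dict[tuple[str, str], dict[str, str]]:
    """(gene_id, transcript_id) -> {allele: term}."""
    groups: dict[tuple[str, str], dict[str, str]] = {}
    for ann in annotations:
        groups.setdefault((ann.gene_id, ann.transcript_id), {})[ann.allele] = ann.term
    return groups


def annotate_genotype_rows(
    gt: GenotypeDistribution,
    annotations: Iterable[ConsequenceAnnotation],
    strict: bool = False,
) -> list[QueryRow]:
    """Expand a genotype distribution into annotated query rows.

    Emits one row per (genotype state x gene x transcript).  Each allele's
    consequence is looked up per transcript; the reference allele always
    yields the literal term ``"reference"``.  A non-reference allele with
    no annotation for a transcript yields ``"unannotated"`` with a logged
    warning (or an error in ``strict`` mode).  A variant with no
    annotations at all is emitted once per genotype state with empty gene
    and transcript fields.

    Row probability equals the genotype state's probability; ``is_max``
    flags are set per transcript group.
    """
    groups = _term_lookup(annotations)
    if not groups:
        groups = {("", ""): {}}

    variant = gt.variant
    ref = variant.ref_allele
    rows: list[QueryRow] = []
    for (gene_id, transcript_id), terms in sorted(groups.items()):
        for (a1, a2), prob in sorted(gt.probs.items()):
            if prob <= 0.0:
                continue
            cons = []
            for allele in (a1, a2):
                if allele == ref:
                    cons.append(REFERENCE_TERM)
                elif allele in terms:
                    cons.append(terms[allele])
                else:
                    if strict:
                        raise MissingDataError(
                            f"allele {allele!r} at {variant.chrom}:{variant.pos} "
                            f"unannotated for transcript {transcript_id!r}"
                        )
                    logger.warning(
                        "allele %s at %s:%d unannotated for transcript %s",
                        allele, variant.chrom, variant.pos, transcript_id,
                    )
                    cons.append(UNANNOTATED_TERM)
            rows.append(
                QueryRow(
                    variant_id=variant.variant_id,
                    chrom=variant.chrom,
                    pos=variant.pos,
                    strain=gt.strain,
                    allele_1=a1,
                    allele_2=a2,
                    prob=prob,
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    consequence_1=cons[0],
                    consequence_2=cons[1],
                )
            )
    return flag_is_max(rows)


def flag_is_max(rows: Sequence[QueryRow]) -> list[QueryRow]:
    """Set ``is_max`` per (variant, strain, gene, transcript) group.

    Every row whose probability is within tolerance of its group's maximum
    is flagged; ties mark all tied rows, so max-only filters may keep more
    than one row per group.
    """
    maxima: dict[tuple, float] = {}
    for row in rows:
        key = row.group_key
        if key not in maxima or row.prob > maxima[key]:
            maxima[key] = row.prob
    out = list(rows)
    for row in out:
        row.is_max = row.prob >= maxima[row.group_key] - TOL
    return out
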