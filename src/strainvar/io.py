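"""Readers and writers for external formats, plus build-time filtering.

Supported dialects
------------------
* Founder variants: standard VCF 4.x with one sample per founder (GT
  required; PL/GL optional for likelihood mode).  A VEP-style ``CSQ``
  INFO field is parsed for consequences when present.
* Marker diplotype probabilities: long-format CSV with header
  ``strain,chrom,pos,marker,hap1,hap2,prob``; ``#``-prefixed comment
  lines are ignored.
* Exons: BED (0-based half-open) or GFF3 (1-based closed), normalized
  internally to 1-based closed intervals carrying a gene id.
* Consequences: 5-column TSV ``chrom,pos,allele,gene_id:transcript_id,term``.
* Query output: CSV dumps, one file per chromosome.
"""

from __future__ import annotations

import bisect
import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
from cyvcf2 import VCF

from .core import (
    ConsequenceAnnotation,
    DiplotypeDistribution,
    FounderGenotypeDistribution,
    QueryRow,
    ValidationError,
    Variant,
    canonical_unphased,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExonIndex",
    "read_exons",
    "read_founder_vcf",
    "read_consequence_tsv",
    "read_marker_diplotypes",
    "MarkerMap",
    "filter_buildable_variants",
    "write_query_csv",
    "read_query_csv",
    "GENOTYPE_COLUMNS",
    "GENOTYPE_CROSS_COLUMNS",
    "DIPLOTYPE_COLUMNS",
    "DIPLOTYPE_CROSS_COLUMNS",
    "EXON_WINDOW",
]

#: Flanking window (bp) around exons inside which variants are buildable.
EXON_WINDOW = 100


# ---------------------------------------------------------------------------
# Exon intervals


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based closed
    end: int
    gene_id: str


class ExonIndex:
    """Per-chromosome sorted exon intervals with windowed overlap queries."""

    def __init__(self, exons: Iterable[Exon]):
        self._by_chrom: dict[str, list[Exon]] = {}
        for exon in exons:
            if exon.end < exon.start:
                raise ValidationError(f"exon end < start: {exon}")
            self._by_chrom.setdefault(exon.chrom, []).append(exon)
        self._starts: dict[str, list[int]] = {}
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda e: (e.start, e.end))
            self._starts[chrom] = [e.start for e in lst]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def exons(self, chrom: str) -> list[Exon]:
        return list(self._by_chrom.get(chrom, []))

    def gene_ids(self) -> list[str]:
        return sorted({e.gene_id for lst in self._by_chrom.values() for e in lst})

    def overlapping(
        self, chrom: str, start: int, end: int, window: int = EXON_WINDOW
    ) -> list[Exon]:
        """Exons whose +/- ``window`` expansion intersects [start, end] (closed)."""
        lst = self._by_chrom.get(chrom, [])
        out = []
        for exon in lst:
            if exon.start - window <= end and start <= exon.end + window:
                out.append(exon)
        return out

    def in_window(self, chrom: str, start: int, end: int, window: int = EXON_WINDOW) -> bool:
        return bool(self.overlapping(chrom, start, end, window))


def read_exons(path: Union[str, Path]) -> ExonIndex:
    """Load exon intervals from BED or GFF3, keyed on gene id.

    BED: columns chrom, start (0-based), end (half-open), name; the name is
    the gene id (an optional ``:transcript`` suffix is stripped).
    GFF3: ``exon`` features; the gene id is taken from ``gene_id=`` or
    ``Parent=`` attributes.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return ExonIndex(_iter_gff3(path))
    return ExonIndex(_iter_bed(path))


def _iter_bed(path: Path) -> Iterator[Exon]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed BED line: {line!r}")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            gene_id = name.split(":", 1)[0]
            yield Exon(chrom=chrom, start=start0 + 1, end=end, gene_id=gene_id)


def _iter_gff3(path: Path) -> Iterator[Exon]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValidationError(f"malformed GFF3 line: {line!r}")
            if fields[2].lower() != "exon":
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            gene_id = attrs.get("gene_id") or attrs.get("Parent", "").split(",")[0]
            yield Exon(
                chrom=fields[0], start=int(fields[3]), end=int(fields[4]),
                gene_id=gene_id,
            )


# ---------------------------------------------------------------------------
# Founder VCF


def _phred_to_probs(pl: Sequence[float]) -> np.ndarray:
    raw = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
    return raw / raw.sum()


def _genotype_order(n_alleles: int) -> list[tuple[int, int]]:
    """VCF PL genotype ordering: index(j,k) = k(k+1)/2 + j for j <= k."""
    out = []
    for k in range(n_alleles):
        for j in range(k + 1):
            out.append((j, k))
    return out


def read_founder_vcf(
    path: Union[str, Path],
    founders: Sequence[str] | None = None,
    likelihood_mode: bool = False,
) -> Iterator[
    tuple[Variant, dict[str, FounderGenotypeDistribution], list[ConsequenceAnnotation]]
]:
    """Stream founder variant records from a VCF.

    By default each founder's GT becomes a point-mass genotype
    distribution (heterozygous calls preserved); with ``likelihood_mode``
    the PL (or GL) field is converted to a normalized genotype
    distribution instead.  Records with missing or malformed GT for a
    founder are skipped for that founder with a logged warning; the
    founder then falls back to homozygous reference downstream.

    Consequence annotations are parsed from a VEP-style CSQ INFO field if
    the header declares one.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if founders is None:
        founders = samples
    missing = [f for f in founders if f not in samples]
    if missing:
        raise ValidationError(
            f"founder sample(s) {missing} not in VCF; available: {samples}"
        )
    sample_idx = {f: samples.index(f) for f in founders}
    csq_fields = _csq_format(vcf)

    for vid, record in enumerate(vcf):
        alts = tuple(a for a in record.ALT if a and a != "<NON_REF>")
        if not alts:
            continue
        try:
            variant = Variant(
                variant_id=vid,
                chrom=record.CHROM,
                pos=record.POS,
                ref_allele=record.REF,
                alt_alleles=alts,
            )
        except ValidationError as exc:
            logger.warning("skipping record %s:%s: %s", record.CHROM, record.POS, exc)
            continue
        alleles = variant.alleles

        pl = None
        if likelihood_mode:
            try:
                pl = record.format("PL")
            except KeyError:
                pl = None
            if pl is None:
                try:
                    gl = record.format("GL")
                    pl = None if gl is None else -10.0 * gl
                except KeyError:
                    pl = None

        gts = record.genotypes  # [allele_1, allele_2, phased] per sample
        founder_dists: dict[str, FounderGenotypeDistribution] = {}
        for founder, idx in sample_idx.items():
            if pl is not None and not np.all(pl[idx] < 0):
                probs_arr = _phred_to_probs(np.clip(pl[idx], 0, 1000))
                order = _genotype_order(len(alleles))
                probs = {}
                for (j, k), p in zip(order, probs_arr):
                    if p > 0:
                        key = canonical_unphased(alleles[j], alleles[k])
                        probs[key] = probs.get(key, 0.0) + float(p)
                founder_dists[founder] = FounderGenotypeDistribution(
                    variant=variant, founder=founder, probs=probs
                )
                continue
            call = gts[idx]
            a1, a2 = call[0], call[1]
            if a1 < 0 or a2 < 0 or a1 >= len(alleles) or a2 >= len(alleles):
                logger.warning(
                    "founder %s has missing/malformed GT at %s:%d; skipped",
                    founder, variant.chrom, variant.pos,
                )
                continue
            founder_dists[founder] = FounderGenotypeDistribution.point_mass(
                variant, founder, alleles[a1], alleles[a2]
            )

        annotations = _parse_csq(record, variant, csq_fields)
        yield variant, founder_dists, annotations


def _csq_format(vcf: VCF) -> list[str] | None:
    try:
        info = vcf.get_header_type("CSQ")
    except KeyError:
        return None
    desc = info.get("Description", "")
    if "Format:" in desc:
        fmt = desc.split("Format:", 1)[1].strip().strip('"')
        return [f.strip() for f in fmt.split("|")]
    return ["Allele", "Consequence", "Gene", "Transcript"]


def _parse_csq(record, variant: Variant, csq_fields: list[str] | None):
    if csq_fields is None:
        return []
    raw = record.INFO.get("CSQ")
    if not raw:
        return []
    annotations = []
    for entry in str(raw).split(","):
        values = entry.split("|")
        fields = dict(zip(csq_fields, values))
        allele = fields.get("Allele", "")
        term = fields.get("Consequence", "")
        gene = fields.get("Gene", "")
        transcript = fields.get("Transcript") or fields.get("Feature", "")
        if not allele or not term:
            continue
        annotations.append(
            ConsequenceAnnotation(
                chrom=variant.chrom, pos=variant.pos, allele=allele,
                gene_id=gene, transcript_id=transcript,
                term=term.split("&")[0] if "&" in term else term,
            )
        )
    return annotations


def read_consequence_tsv(path: Union[str, Path]) -> list[ConsequenceAnnotation]:
    """Load the 5-column consequence TSV.

    Columns: chrom, pos, allele, ``gene_id:transcript_id``, term.
    ``#``-prefixed lines are comments.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValidationError(f"expected 5 TSV columns, got: {line!r}")
            chrom, pos, allele, feature, term = fields
            gene_id, _, transcript_id = feature.partition(":")
            out.append(
                ConsequenceAnnotation(
                    chrom=chrom, pos=int(pos), allele=allele,
                    gene_id=gene_id, transcript_id=transcript_id, term=term,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Marker diplotypes

MARKER_COLUMNS = ["strain", "chrom", "pos", "marker", "hap1", "hap2", "prob"]

#: Per-marker probability sums inside this band are accepted silently
#: (upstream HMM output tolerance); outside it a warning is logged.
MARKER_SUM_BAND = (0.98, 1.02)


class MarkerMap:
    """Sorted marker diplotype distributions, indexed by (strain, chrom)."""

    def __init__(self, markers: Iterable[DiplotypeDistribution]):
        self._by_key: dict[tuple[str, str], list[DiplotypeDistribution]] = {}
        for m in markers:
            self._by_key.setdefault((m.strain, m.chrom), []).append(m)
        self._positions: dict[tuple[str, str], list[int]] = {}
        for key, lst in self._by_key.items():
            positions = [m.pos for m in lst]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValidationError(
                    f"marker positions for strain {key[0]!r} on {key[1]!r} "
                    f"must be strictly increasing"
                )
            self._positions[key] = positions

    @property
    def strains(self) -> list[str]:
        return sorted({s for s, _ in self._by_key})

    def chroms(self, strain: str) -> list[str]:
        return sorted({c for s, c in self._by_key if s == strain})

    def markers(self, strain: str, chrom: str) -> list[DiplotypeDistribution]:
        return list(self._by_key.get((strain, chrom), []))

    def flanking(
        self, strain: str, chrom: str, pos: int
    ) -> tuple[DiplotypeDistribution | None, DiplotypeDistribution | None]:
        """Nearest markers at-or-left and at-or-right of ``pos``.

        A marker exactly at ``pos`` is returned on both sides.  Outside
        the marker span one side is None.
        """
        key = (strain, chrom)
        if key not in self._by_key:
            return None, None
        positions = self._positions[key]
        lst = self._by_key[key]
        i = bisect.bisect_right(positions, pos)
        left = lst[i - 1] if i > 0 else None
        if left is not None and left.pos == pos:
            return left, left
        right = lst[i] if i < len(lst) else None
        return left, right


def read_marker_diplotypes(path: Union[str, Path], founders: Sequence[str] | None = None):
    """Stream per-(strain, marker) diplotype distributions from long CSV.

    Rows sharing (strain, chrom, pos) are grouped into one distribution;
    reversed haplotype orderings merge onto the unordered key.
    """
    known = set(founders) if founders is not None else None

    def records() -> Iterator[DiplotypeDistribution]:
        with open(path) as fh:
            reader = csv.reader(line for line in fh if not line.startswith("#"))
            header = next(reader)
            if [h.strip() for h in header] != MARKER_COLUMNS:
                raise ValidationError(
                    f"expected marker CSV header {MARKER_COLUMNS}, got {header}"
                )
            current_key = None
            probs: dict = {}
            marker_name = ""
            for row in reader:
                if not row:
                    continue
                strain, chrom, pos, marker, hap1, hap2, prob = row
                pos = int(pos)
                p = float(prob)
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"marker probability {p} outside [0, 1] at {marker}"
                    )
                if known is not None and (hap1 not in known or hap2 not in known):
                    raise ValidationError(
                        f"unknown founder in marker row {row}; known: {sorted(known)}"
                    )
                key = (strain, chrom, pos)
                if key != current_key:
                    if current_key is not None:
                        yield _finish_marker(current_key, probs, marker_name)
                    current_key, probs, marker_name = key, {}, marker
                pair = canonical_unphased(hap1, hap2)
                probs[pair] = probs.get(pair, 0.0) + p
            if current_key is not None:
                yield _finish_marker(current_key, probs, marker_name)

    return records()


def _finish_marker(key, probs, marker_name) -> DiplotypeDistribution:
    strain, chrom, pos = key
    total = sum(probs.values())
    if not (MARKER_SUM_BAND[0] <= total <= MARKER_SUM_BAND[1]):
        logger.warning(
            "marker %s (%s %s:%d) probabilities sum to %.4f",
            marker_name, strain, chrom, pos, total,
        )
    scale = 1.0 / total if total > 1.0 else 1.0
    return DiplotypeDistribution(
        strain=strain, chrom=chrom, pos=pos,
        probs={k: p * scale for k, p in probs.items()}, source="marker",
    )


def load_marker_map(path: Union[str, Path], founders: Sequence[str] | None = None) -> MarkerMap:
    return MarkerMap(read_marker_diplotypes(path, founders))


# ---------------------------------------------------------------------------
# Build filter


def filter_buildable_variants(
    records: Iterable[
        tuple[Variant, dict[str, FounderGenotypeDistribution], list[ConsequenceAnnotation]]
    ],
    exons: ExonIndex,
    window: int = EXON_WINDOW,
    founders: Sequence[str] | None = None,
):
    """Keep variants that are exonic (+/- window), founder-polymorphic SNPs/indels.

    An indel intersects the window if any reference-spanned base does.
    Polymorphism means not all founder genotype distributions are
    identical; founders absent from a record count as homozygous
    reference when ``founders`` names the full panel.
    """
    for variant, founder_gts, annotations in records:
        start, end = variant.ref_span
        if not exons.in_window(variant.chrom, start, end, window):
            continue
        states = {tuple(sorted(d.probs.items())) for d in founder_gts.values()}
        if founders is not None and any(f not in founder_gts for f in founders):
            ref_key = canonical_unphased(variant.ref_allele, variant.ref_allele)
            states.add(((ref_key, 1.0),))
        if len(states) < 2:
            continue
        yield variant, founder_gts, annotations


# ---------------------------------------------------------------------------
# Query CSV

GENOTYPE_COLUMNS = [
    "variant_id", "chrom", "pos", "strain", "allele_1", "allele_2",
    "prob", "is_max", "gene_id", "transcript_id", "consequence_1", "consequence_2",
]
GENOTYPE_CROSS_COLUMNS = [
    "variant_id", "chrom", "pos", "strain_1", "strain_2", "allele_1", "allele_2",
    "prob", "is_max", "gene_id", "transcript_id", "consequence_1", "consequence_2",
]
DIPLOTYPE_COLUMNS = [
    "variant_id", "chrom", "pos", "strain", "haplotype_1", "haplotype_2",
    "prob", "is_max",
]
DIPLOTYPE_CROSS_COLUMNS = [
    "variant_id", "chrom", "pos", "strain_1", "strain_2", "haplotype_1",
    "haplotype_2", "prob", "is_max",
]


def _row_record(row: QueryRow, kind: str) -> list:
    strains = (
        list(row.strain) if isinstance(row.strain, tuple) else [row.strain]
    )
    base = [row.variant_id, row.chrom, row.pos, *strains, row.allele_1, row.allele_2,
            repr(row.prob), str(row.is_max).lower()]
    if kind.startswith("diplotype"):
        return base
    return base + [row.gene_id, row.transcript_id, row.consequence_1, row.consequence_2]


def write_query_csv(rows: Iterable[QueryRow], path: Union[str, Path], kind: str = "genotype") -> None:
    """Write rows in the documented column order for the query ``kind``.

    ``kind`` is one of genotype, genotype_cross, diplotype,
    diplotype_cross.  Diplotype outputs substitute haplotype columns and
    carry no gene/transcript/consequence fields.
    """
    columns = {
        "genotype": GENOTYPE_COLUMNS,
        "genotype_cross": GENOTYPE_CROSS_COLUMNS,
        "diplotype": DIPLOTYPE_COLUMNS,
        "diplotype_cross": DIPLOTYPE_CROSS_COLUMNS,
    }[kind]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            writer.writerow(_row_record(row, kind))


def read_query_csv(path: Union[str, Path]) -> list[QueryRow]:
    """Read back a query CSV written by :func:`write_query_csv`."""
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        is_cross = "strain_1" in header
        is_diplotype = "haplotype_1" in header
        rows = []
        for rec in reader:
            fields = dict(zip(header, rec))
            strain = (
                (fields["strain_1"], fields["strain_2"]) if is_cross else fields["strain"]
            )
            a1 = fields["haplotype_1"] if is_diplotype else fields["allele_1"]
            a2 = fields["haplotype_2"] if is_diplotype else fields["allele_2"]
            rows.append(
                QueryRow(
                    variant_id=int(fields["variant_id"]),
                    chrom=fields["chrom"],
                    pos=int(fields["pos"]),
                    strain=strain,
                    allele_1=a1,
                    allele_2=a2,
                    prob=float(fields["prob"]),
                    is_max=fields["is_max"] == "true",
                    gene_id=fields.get("gene_id", ""),
                    transcript_id=fields.get("transcript_id", ""),
                    consequence_1=fields.get("consequence_1", ""),
                    consequence_2=fields.get("consequence_2", ""),
                )
            )
    return rows
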