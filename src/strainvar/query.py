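"""Per-chromosome embedded store and the four query types.

The store is a directory of single-file SQLite databases, one per
chromosome, each indexed by (variant_id, strain), plus a JSON manifest.
Genotype and diplotype distributions are pruned at build time and stored
un-renormalized.  F1 cross queries are computed on demand from the stored
parent distributions rather than materialized.
"""

from __future__ import annotations

import json
import logging
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from . import cross as cross_mod
from .annotation import annotate_genotype_rows, flag_is_max
from .core import (
    TOL,
    ConsequenceAnnotation,
    DiplotypeDistribution,
    FounderGenotypeDistribution,
    GenotypeDistribution,
    QueryRow,
    ValidationError,
    Variant,
    canonical_unphased,
)
from .imputation import (
    PRUNE_THRESHOLD,
    genotype_from_diplotype,
    impute_diplotype,
    prune_distribution,
)
from .io import (
    ExonIndex,
    filter_buildable_variants,
    load_marker_map,
    read_consequence_tsv,
    read_exons,
    read_founder_vcf,
    write_query_csv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantStore",
    "build_store",
    "query_genotype",
    "query_diplotype",
    "query_genotype_cross",
    "query_diplotype_cross",
    "residual_het_summary",
    "reference_identity_summary",
    "consequence_spectrum",
    "RESIDUAL_HET_CUTOFF",
]

#: A variant counts as residually heterozygous when its total heterozygous
#: genotype probability is at least this value.
RESIDUAL_HET_CUTOFF = 0.25

_SCHEMA = """
CREATE TABLE variants (
    variant_id INTEGER PRIMARY KEY,
    pos INTEGER NOT NULL,
    end_pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alts TEXT NOT NULL
);
CREATE TABLE genotypes (
    variant_id INTEGER NOT NULL,
    strain TEXT NOT NULL,
    allele_1 TEXT NOT NULL,
    allele_2 TEXT NOT NULL,
    prob REAL NOT NULL
);
CREATE INDEX idx_gt ON genotypes (variant_id, strain);
CREATE TABLE diplotypes (
    variant_id INTEGER NOT NULL,
    strain TEXT NOT NULL,
    hap_1 TEXT NOT NULL,
    hap_2 TEXT NOT NULL,
    prob REAL NOT NULL
);
CREATE INDEX idx_dip ON diplotypes (variant_id, strain);
CREATE TABLE consequences (
    variant_id INTEGER NOT NULL,
    allele TEXT NOT NULL,
    gene_id TEXT NOT NULL,
    transcript_id TEXT NOT NULL,
    term TEXT NOT NULL
);
CREATE INDEX idx_csq ON consequences (variant_id);
CREATE TABLE exons (
    gene_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
"""


def _chrom_sort_key(chrom: str):
    stripped = chrom.lower().removeprefix("chr")
    if stripped.isdigit():
        return (0, int(stripped), "")
    return (1, 0, stripped)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int

    @classmethod
    def parse(cls, text: str) -> "Region":
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.strip())
        if not m:
            raise ValidationError(
                f"region must look like chrom:start-end, got {text!r}"
            )
        start, end = int(m.group(2)), int(m.group(3))
        if start < 1 or end < start:
            raise ValidationError(f"bad region bounds in {text!r}")
        return cls(m.group(1), start, end)


class VariantStore:
    """Directory of per-chromosome SQLite databases plus a manifest."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        manifest_path = self.root / "manifest.json"
        if not manifest_path.exists():
            raise ValidationError(f"no manifest.json under {self.root}")
        with open(manifest_path) as fh:
            self.manifest = json.load(fh)
        self._conns: dict[str, sqlite3.Connection] = {}

    # -- manifest accessors

    @property
    def chroms(self) -> list[str]:
        return list(self.manifest["chroms"])

    @property
    def founders(self) -> list[str]:
        return list(self.manifest["founders"])

    @property
    def strains(self) -> list[str]:
        return list(self.manifest["strains"])

    @property
    def all_strains(self) -> list[str]:
        return self.strains + self.founders

    @property
    def reference_strain(self) -> str:
        return self.manifest["reference_strain"]

    def conn(self, chrom: str) -> sqlite3.Connection:
        if chrom not in self.chroms:
            raise ValidationError(
                f"chromosome {chrom!r} not in store; available: {self.chroms}"
            )
        if chrom not in self._conns:
            self._conns[chrom] = sqlite3.connect(self.root / f"chrom_{chrom}.db")
        return self._conns[chrom]

    def close(self) -> None:
        for conn in self._conns.values():
            conn.close()
        self._conns.clear()

    # -- lookups

    def validate_strains(self, strains: Sequence[str]) -> list[str]:
        if not strains:
            raise ValidationError("at least one strain is required")
        unknown = [s for s in strains if s not in self.all_strains]
        if unknown:
            raise ValidationError(
                f"unknown strain(s) {unknown}; valid: {self.all_strains}"
            )
        return list(strains)

    def variant(self, chrom: str, variant_id: int) -> Variant:
        row = self.conn(chrom).execute(
            "SELECT variant_id, pos, ref, alts FROM variants WHERE variant_id=?",
            (variant_id,),
        ).fetchone()
        if row is None:
            raise ValidationError(f"variant_id {variant_id} not on {chrom}")
        return Variant(
            variant_id=row[0], chrom=chrom, pos=row[1],
            ref_allele=row[2], alt_alleles=tuple(row[3].split(",")),
        )

    def variants_in_region(self, region: Region) -> list[Variant]:
        rows = self.conn(region.chrom).execute(
            "SELECT variant_id, pos, ref, alts FROM variants "
            "WHERE end_pos >= ? AND pos <= ? ORDER BY variant_id",
            (region.start, region.end),
        ).fetchall()
        return [
            Variant(variant_id=r[0], chrom=region.chrom, pos=r[1],
                    ref_allele=r[2], alt_alleles=tuple(r[3].split(",")))
            for r in rows
        ]

    def variants_for_genes(self, genes: Sequence[str]) -> list[Variant]:
        known: set[str] = set()
        out: list[Variant] = []
        for chrom in self.chroms:
            conn = self.conn(chrom)
            known.update(
                g for (g,) in conn.execute("SELECT DISTINCT gene_id FROM exons")
            )
            for gene in genes:
                rows = conn.execute(
                    "SELECT DISTINCT v.variant_id, v.pos, v.ref, v.alts "
                    "FROM variants v JOIN exons e "
                    "ON v.end_pos >= e.start - 100 AND v.pos <= e.end + 100 "
                    "WHERE e.gene_id = ? ORDER BY v.variant_id",
                    (gene,),
                ).fetchall()
                out.extend(
                    Variant(variant_id=r[0], chrom=chrom, pos=r[1],
                            ref_allele=r[2], alt_alleles=tuple(r[3].split(",")))
                    for r in rows
                )
        unknown = [g for g in genes if g not in known]
        if unknown:
            raise ValidationError(
                f"unknown gene(s) {unknown}; valid genes: {sorted(known)}"
            )
        seen = set()
        unique = []
        for v in sorted(out, key=lambda v: v.variant_id):
            if v.variant_id not in seen:
                seen.add(v.variant_id)
                unique.append(v)
        return unique

    def variants_by_id(self, variant_ids: Sequence[int]) -> list[Variant]:
        out = []
        for chrom in self.chroms:
            lo, hi = self.manifest["id_ranges"][chrom]
            for vid in variant_ids:
                if lo <= vid <= hi:
                    out.append(self.variant(chrom, vid))
        found = {v.variant_id for v in out}
        missing = [vid for vid in variant_ids if vid not in found]
        if missing:
            raise ValidationError(f"unknown variant_id(s): {missing}")
        return sorted(out, key=lambda v: v.variant_id)

    def all_variants(self, chrom: str) -> list[Variant]:
        rows = self.conn(chrom).execute(
            "SELECT variant_id, pos, ref, alts FROM variants ORDER BY variant_id"
        ).fetchall()
        return [
            Variant(variant_id=r[0], chrom=chrom, pos=r[1],
                    ref_allele=r[2], alt_alleles=tuple(r[3].split(",")))
            for r in rows
        ]

    def genotype(self, variant: Variant, strain: str) -> GenotypeDistribution | None:
        rows = self.conn(variant.chrom).execute(
            "SELECT allele_1, allele_2, prob FROM genotypes "
            "WHERE variant_id=? AND strain=?",
            (variant.variant_id, strain),
        ).fetchall()
        if not rows:
            return None
        return GenotypeDistribution(
            strain=strain, variant=variant,
            probs={canonical_unphased(a1, a2): p for a1, a2, p in rows},
        )

    def diplotype(self, variant: Variant, strain: str) -> DiplotypeDistribution | None:
        rows = self.conn(variant.chrom).execute(
            "SELECT hap_1, hap_2, prob FROM diplotypes "
            "WHERE variant_id=? AND strain=?",
            (variant.variant_id, strain),
        ).fetchall()
        if not rows:
            return None
        return DiplotypeDistribution(
            strain=strain, chrom=variant.chrom, pos=variant.pos,
            probs={canonical_unphased(h1, h2): p for h1, h2, p in rows},
            source="interpolated",
        )

    def annotations(self, variant: Variant) -> list[ConsequenceAnnotation]:
        rows = self.conn(variant.chrom).execute(
            "SELECT allele, gene_id, transcript_id, term FROM consequences "
            "WHERE variant_id=? ORDER BY gene_id, transcript_id, allele",
            (variant.variant_id,),
        ).fetchall()
        return [
            ConsequenceAnnotation(
                chrom=variant.chrom, pos=variant.pos, allele=a,
                gene_id=g, transcript_id=t, term=term,
            )
            for a, g, t, term in rows
        ]

    def founder_genotypes(self, variant: Variant) -> dict[str, FounderGenotypeDistribution]:
        out = {}
        for founder in self.founders:
            gt = self.genotype(variant, founder)
            if gt is not None:
                out[founder] = FounderGenotypeDistribution(
                    variant=variant, founder=founder, probs=dict(gt.probs)
                )
        return out

    # -- dumps

    def dump(self, out_dir: Union[str, Path]) -> list[Path]:
        """Write per-chromosome genotype and diplotype CSV dumps."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for chrom in self.chroms:
            variants = self.all_variants(chrom)
            gt_rows: list[QueryRow] = []
            dip_rows: list[QueryRow] = []
            for variant in variants:
                anns = self.annotations(variant)
                for strain in self.all_strains:
                    gt = self.genotype(variant, strain)
                    if gt is not None:
                        gt_rows.extend(annotate_genotype_rows(gt, anns))
                    dip = self.diplotype(variant, strain)
                    if dip is not None:
                        dip_rows.extend(_diplotype_rows(dip, variant))
            gt_path = out_dir / f"genotype_chrom_{chrom}.csv"
            dip_path = out_dir / f"diplotype_chrom_{chrom}.csv"
            write_query_csv(gt_rows, gt_path, kind="genotype")
            write_query_csv(dip_rows, dip_path, kind="diplotype")
            paths.extend([gt_path, dip_path])
        return paths


# ---------------------------------------------------------------------------
# Build


def build_store(
    founder_vcf: Union[str, Path],
    marker_csv: Union[str, Path],
    exons_path: Union[str, Path],
    out_dir: Union[str, Path],
    consequence_tsv: Union[str, Path, None] = None,
    founders: Sequence[str] | None = None,
    prune_threshold: float = PRUNE_THRESHOLD,
    mode: str = "proximal",
    reference_strain: str | None = None,
) -> VariantStore:
    """Impute all (strain, buildable variant) distributions and persist them.

    One SQLite database per chromosome; variant ids are assigned in
    ascending (chromosome, position, alt alleles) order, so identical
    inputs always produce identical stores.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exons = read_exons(exons_path)
    markers = load_marker_map(marker_csv, founders)
    strains = markers.strains

    records = list(
        filter_buildable_variants(
            read_founder_vcf(founder_vcf, founders), exons, founders=founders
        )
    )
    logger.info("build: %d buildable variants, %d strains", len(records), len(strains))
    if founders is None:
        founders = sorted(
            {f for _, gts, _ in records for f in gts}
        )
    founders = list(founders)

    side_annotations: dict[tuple[str, int], list[ConsequenceAnnotation]] = {}
    if consequence_tsv is not None:
        for ann in read_consequence_tsv(consequence_tsv):
            side_annotations.setdefault((ann.chrom, ann.pos), []).append(ann)

    records.sort(key=lambda rec: (_chrom_sort_key(rec[0].chrom), rec[0].pos, rec[0].alt_alleles))
    chroms = sorted({rec[0].chrom for rec in records}, key=_chrom_sort_key)

    if reference_strain is None:
        reference_strain = _detect_reference(records, founders)

    id_ranges: dict[str, tuple[int, int]] = {}
    next_id = 1
    for chrom in chroms:
        chrom_records = [rec for rec in records if rec[0].chrom == chrom]
        db_path = out_dir / f"chrom_{chrom}.db"
        if db_path.exists():
            db_path.unlink()
        conn = sqlite3.connect(db_path)
        conn.executescript(_SCHEMA)

        for gene_id, exon_list in _exons_for_chrom(exons, chrom).items():
            conn.executemany(
                "INSERT INTO exons (gene_id, start, end) VALUES (?,?,?)",
                [(gene_id, s, e) for s, e in exon_list],
            )

        first_id = next_id
        for variant, founder_gts, vcf_annotations in chrom_records:
            variant = Variant(
                variant_id=next_id, chrom=variant.chrom, pos=variant.pos,
                ref_allele=variant.ref_allele, alt_alleles=variant.alt_alleles,
            )
            next_id += 1
            conn.execute(
                "INSERT INTO variants (variant_id, pos, end_pos, ref, alts) "
                "VALUES (?,?,?,?,?)",
                (variant.variant_id, variant.pos, variant.ref_span[1],
                 variant.ref_allele, ",".join(variant.alt_alleles)),
            )

            anns = list(vcf_annotations) + side_annotations.get(
                (variant.chrom, variant.pos), []
            )
            conn.executemany(
                "INSERT INTO consequences (variant_id, allele, gene_id, "
                "transcript_id, term) VALUES (?,?,?,?,?)",
                [(variant.variant_id, a.allele, a.gene_id, a.transcript_id, a.term)
                 for a in anns],
            )

            # founders: own VCF distribution + certain self diplotype
            for founder in founders:
                if founder in founder_gts:
                    gt_probs = founder_gts[founder].probs
                else:
                    ref = variant.ref_allele
                    gt_probs = {canonical_unphased(ref, ref): 1.0}
                pruned = {k: p for k, p in gt_probs.items() if p >= prune_threshold} \
                    if prune_threshold > 0 else gt_probs
                conn.executemany(
                    "INSERT INTO genotypes VALUES (?,?,?,?,?)",
                    [(variant.variant_id, founder, k[0], k[1], p)
                     for k, p in sorted(pruned.items())],
                )
                conn.execute(
                    "INSERT INTO diplotypes VALUES (?,?,?,?,?)",
                    (variant.variant_id, founder, founder, founder, 1.0),
                )

            for strain in strains:
                left, right = markers.flanking(strain, variant.chrom, variant.pos)
                if left is None and right is None:
                    logger.warning(
                        "no markers for strain %s on %s; skipped", strain, chrom
                    )
                    continue
                dip = impute_diplotype(strain, variant, left, right, mode=mode)
                gt = genotype_from_diplotype(strain, variant, dip, founder_gts)
                dip = prune_distribution(dip, prune_threshold)
                gt = prune_distribution(gt, prune_threshold)
                conn.executemany(
                    "INSERT INTO diplotypes VALUES (?,?,?,?,?)",
                    [(variant.variant_id, strain, k[0], k[1], p)
                     for k, p in sorted(dip.probs.items())],
                )
                conn.executemany(
                    "INSERT INTO genotypes VALUES (?,?,?,?,?)",
                    [(variant.variant_id, strain, k[0], k[1], p)
                     for k, p in sorted(gt.probs.items())],
                )
        conn.commit()
        conn.close()
        id_ranges[chrom] = (first_id, next_id - 1)

    manifest = {
        "chroms": chroms,
        "founders": founders,
        "strains": strains,
        "reference_strain": reference_strain,
        "prune_threshold": prune_threshold,
        "mode": mode,
        "id_ranges": id_ranges,
        "n_variants": next_id - 1,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("build: wrote %d chromosome stores under %s", len(chroms), out_dir)
    return VariantStore(out_dir)


def _exons_for_chrom(exons: ExonIndex, chrom: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for exon in exons.exons(chrom):
        out.setdefault(exon.gene_id, []).append((exon.start, exon.end))
    return {g: sorted(v) for g, v in sorted(out.items())}


def _detect_reference(records, founders) -> str:
    """Founder most often homozygous for the VCF REF allele."""
    scores = {f: 0 for f in founders}
    for variant, founder_gts, _ in records:
        ref_key = canonical_unphased(variant.ref_allele, variant.ref_allele)
        for f in founders:
            gt = founder_gts.get(f)
            if gt is None or gt.probs.get(ref_key, 0.0) > 0.5:
                scores[f] += 1
    return max(founders, key=lambda f: (scores[f], -founders.index(f)))


# ---------------------------------------------------------------------------
# Queries


def _resolve_variants(
    store: VariantStore,
    region: str | Region | None,
    genes: Sequence[str] | None,
    variant_ids: Sequence[int] | None,
) -> list[Variant]:
    given = [x is not None for x in (region, genes, variant_ids)]
    if sum(given) != 1:
        raise ValidationError(
            "exactly one of region, genes, variant_ids must be given"
        )
    if region is not None:
        if isinstance(region, str):
            region = Region.parse(region)
        return store.variants_in_region(region)
    if genes is not None:
        return store.variants_for_genes(genes)
    return store.variants_by_id(variant_ids)


def apply_restrictions(
    rows: Iterable[QueryRow],
    max_only: bool = False,
    prob_threshold: float | None = None,
    zygosity: str | None = None,
    consequences: Sequence[str] | None = None,
    consequence_mode: str = "either",
) -> list[QueryRow]:
    """Conjunctive secondary restrictions; order-independent by design."""
    if zygosity is not None and zygosity not in ("hom", "het"):
        raise ValidationError("zygosity must be 'hom' or 'het'")
    if consequence_mode not in ("either", "both"):
        raise ValidationError("consequence_mode must be 'either' or 'both'")
    wanted = set(consequences) if consequences else None
    out = []
    for row in rows:
        if max_only and not row.is_max:
            continue
        if prob_threshold is not None and row.prob < prob_threshold:
            continue
        if zygosity is not None and row.zygosity != zygosity:
            continue
        if wanted is not None:
            hits = (row.consequence_1 in wanted, row.consequence_2 in wanted)
            keep = all(hits) if consequence_mode == "both" else any(hits)
            if not keep:
                continue
        out.append(row)
    return out


def query_genotype(
    store: VariantStore,
    strains: Sequence[str],
    region: str | Region | None = None,
    genes: Sequence[str] | None = None,
    variant_ids: Sequence[int] | None = None,
    **restrictions,
) -> list[QueryRow]:
    """Annotated genotype rows for the selected strains and variants."""
    strains = store.validate_strains(strains)
    variants = _resolve_variants(store, region, genes, variant_ids)
    rows: list[QueryRow] = []
    for variant in variants:
        anns = store.annotations(variant)
        for strain in strains:
            gt = store.genotype(variant, strain)
            if gt is not None:
                rows.extend(annotate_genotype_rows(gt, anns))
    return apply_restrictions(rows, **restrictions)


def _diplotype_rows(dip: DiplotypeDistribution, variant: Variant) -> list[QueryRow]:
    rows = [
        QueryRow(
            variant_id=variant.variant_id, chrom=variant.chrom, pos=variant.pos,
            strain=dip.strain, allele_1=h1, allele_2=h2, prob=p,
        )
        for (h1, h2), p in sorted(dip.probs.items())
        if p > 0
    ]
    return flag_is_max(rows)


def query_diplotype(
    store: VariantStore,
    strains: Sequence[str],
    region: str | Region | None = None,
    genes: Sequence[str] | None = None,
    variant_ids: Sequence[int] | None = None,
    **restrictions,
) -> list[QueryRow]:
    """Diplotype rows (haplotype pairs, no transcript or consequence fields)."""
    restrictions.pop("consequences", None)
    strains = store.validate_strains(strains)
    variants = _resolve_variants(store, region, genes, variant_ids)
    rows: list[QueryRow] = []
    for variant in variants:
        for strain in strains:
            dip = store.diplotype(variant, strain)
            if dip is not None:
                rows.extend(_diplotype_rows(dip, variant))
    return apply_restrictions(rows, **restrictions)


def _cross_pair(strains: Sequence[str]) -> tuple[str, str]:
    if len(strains) != 2:
        raise ValidationError("cross queries take exactly two strains")
    return strains[0], strains[1]


def query_genotype_cross(
    store: VariantStore,
    strains: Sequence[str],
    region: str | Region | None = None,
    genes: Sequence[str] | None = None,
    variant_ids: Sequence[int] | None = None,
    **restrictions,
) -> list[QueryRow]:
    """Simulated F1 genotype rows for a two-strain cross."""
    s1, s2 = _cross_pair(store.validate_strains(strains))
    variants = _resolve_variants(store, region, genes, variant_ids)
    rows: list[QueryRow] = []
    for variant in variants:
        gt1 = store.genotype(variant, s1)
        gt2 = store.genotype(variant, s2)
        if gt1 is None or gt2 is None:
            continue
        f1 = cross_mod.f1_genotype(gt1, gt2)
        rows.extend(annotate_genotype_rows(f1, store.annotations(variant)))
    return apply_restrictions(rows, **restrictions)


def query_diplotype_cross(
    store: VariantStore,
    strains: Sequence[str],
    region: str | Region | None = None,
    genes: Sequence[str] | None = None,
    variant_ids: Sequence[int] | None = None,
    **restrictions,
) -> list[QueryRow]:
    """Simulated F1 diplotype rows for a two-strain cross."""
    restrictions.pop("consequences", None)
    s1, s2 = _cross_pair(store.validate_strains(strains))
    variants = _resolve_variants(store, region, genes, variant_ids)
    rows: list[QueryRow] = []
    for variant in variants:
        d1 = store.diplotype(variant, s1)
        d2 = store.diplotype(variant, s2)
        if d1 is None or d2 is None:
            continue
        f1 = cross_mod.f1_diplotype(d1, d2)
        for row in _diplotype_rows(f1, variant):
            row.strain = (s1, s2)
            rows.append(row)
    return apply_restrictions(rows, **restrictions)


# ---------------------------------------------------------------------------
# Summary statistics


def residual_het_summary(
    store: VariantStore, strains: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per (strain, chromosome) fraction of variants still likely segregating.

    A variant counts when its total heterozygous-genotype probability is
    at least :data:`RESIDUAL_HET_CUTOFF`.
    """
    strains = store.validate_strains(store.strains if strains is None else strains)
    records = []
    for chrom in store.chroms:
        conn = store.conn(chrom)
        for strain in strains:
            rows = conn.execute(
                "SELECT variant_id, SUM(prob) FROM genotypes "
                "WHERE strain=? AND allele_1 != allele_2 GROUP BY variant_id",
                (strain,),
            ).fetchall()
            het = sum(
                1 for _, p in rows if p is not None and p >= RESIDUAL_HET_CUTOFF - TOL
            )
            (n_variants,) = conn.execute("SELECT COUNT(*) FROM variants").fetchone()
            records.append(
                {
                    "strain": strain,
                    "chrom": chrom,
                    "n_variants": n_variants,
                    "proportion_het": het / n_variants if n_variants else 0.0,
                }
            )
    return pd.DataFrame.from_records(records)


def reference_identity_summary(
    store: VariantStore,
    strains: Sequence[str] | None = None,
    reference_strain: str | None = None,
    method: str = "ml",
) -> float:
    """Fraction of (strain, variant) pairs identical to the reference.

    ``method='ml'``: a pair counts when a maximum-probability genotype is
    homozygous reference (ties involving the reference count).
    ``method='weighted'``: mean probability of the homozygous-reference
    genotype instead.
    """
    if method not in ("ml", "weighted"):
        raise ValidationError("method must be 'ml' or 'weighted'")
    strains = store.validate_strains(store.strains if strains is None else strains)
    del reference_strain  # identity is defined against the VCF REF allele
    total = 0
    identical = 0.0
    for chrom in store.chroms:
        conn = store.conn(chrom)
        ref_of = dict(conn.execute("SELECT variant_id, ref FROM variants"))
        for strain in strains:
            rows = conn.execute(
                "SELECT variant_id, allele_1, allele_2, prob FROM genotypes "
                "WHERE strain=?",
                (strain,),
            ).fetchall()
            by_variant: dict[int, list] = {}
            for vid, a1, a2, p in rows:
                by_variant.setdefault(vid, []).append((a1, a2, p))
            for vid in ref_of:
                total += 1
                states = by_variant.get(vid)
                if not states:
                    continue
                ref = ref_of[vid]
                if method == "weighted":
                    identical += sum(
                        p for a1, a2, p in states if a1 == ref and a2 == ref
                    )
                else:
                    best = max(p for _, _, p in states)
                    if any(
                        a1 == ref and a2 == ref and p >= best - TOL
                        for a1, a2, p in states
                    ):
                        identical += 1
    if total == 0:
        raise ValidationError("store holds no variants")
    return identical / total


def consequence_spectrum(
    store: VariantStore, strains: Sequence[str] | None = None
) -> pd.DataFrame:
    """Probability-weighted share of each non-reference consequence term.

    Each annotated genotype row contributes its probability to every
    distinct non-reference term it carries; shares are normalized to sum
    to 1 over terms.
    """
    strains = store.validate_strains(store.strains if strains is None else strains)
    mass: dict[str, float] = {}
    for chrom in store.chroms:
        for variant in store.all_variants(chrom):
            anns = store.annotations(variant)
            for strain in strains:
                gt = store.genotype(variant, strain)
                if gt is None:
                    continue
                for row in annotate_genotype_rows(gt, anns):
                    terms = {row.consequence_1, row.consequence_2}
                    terms.discard("reference")
                    terms.discard("")
                    for term in terms:
                        mass[term] = mass.get(term, 0.0) + row.prob
    total = sum(mass.values())
    records = [
        {"consequence": term, "share": (m / total if total else 0.0)}
        for term, m in sorted(mass.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame.from_records(records, columns=["consequence", "share"])
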