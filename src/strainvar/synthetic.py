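"""Ground-truthed synthetic input sets.

Generates the four input files every other module consumes — founder VCF,
consequence TSV, exon BED, and marker diplotype CSV — together with the
ground truth used by recovery tests.  A single integer seed governs all
randomness; every output file records it in a header comment.

The mosaic and panel generators are coupled: strain mosaics are drawn
first, and founder alleles are then assigned so that any founder pair
forming a residually heterozygous segment actually differs at the
variants inside that segment.  This makes the residual-heterozygosity
rate of the emitted data match the requested parameter rather than being
diluted by allele sharing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import DEFAULT_FOUNDERS, ValidationError, canonical_unphased

__all__ = [
    "SyntheticGenome",
    "PanelTruth",
    "MosaicTruth",
    "SyntheticDataset",
    "simulate_cc_mosaics",
    "simulate_founder_panel",
    "simulate_dataset",
    "CONSEQUENCE_VOCABULARY",
]

CONSEQUENCE_VOCABULARY = (
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "splice_region_variant",
    "3_prime_UTR_variant",
)
_CONSEQUENCE_WEIGHTS = (0.25, 0.3, 0.02, 0.2, 0.08, 0.08, 0.04, 0.03)

_BASES = ("A", "C", "G", "T")
_WINDOW = 100


@dataclass(frozen=True)
class SyntheticGenome:
    """Chromosome names and lengths shared by all generated inputs."""

    chroms: tuple[str, ...] = ("1", "2")
    lengths: tuple[int, ...] = (5_000_000, 5_000_000)

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.chroms.index(chrom)]


@dataclass
class Segment:
    start: int  # closed, 1-based
    end: int
    state: tuple[str, str]  # canonical founder pair

    @property
    def is_het(self) -> bool:
        return self.state[0] != self.state[1]


@dataclass
class MosaicTruth:
    """True piecewise-constant diplotype mosaic per (strain, chrom)."""

    segments: dict[tuple[str, str], list[Segment]]

    def state(self, strain: str, chrom: str, pos: int) -> tuple[str, str]:
        segs = self.segments[(strain, chrom)]
        starts = [s.start for s in segs]
        i = bisect.bisect_right(starts, pos) - 1
        return segs[i].state

    def strains(self) -> list[str]:
        return sorted({s for s, _ in self.segments})


@dataclass
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    founder_alleles: dict[str, tuple[str, str]]  # founder -> unphased genotype
    in_window: bool
    genes: tuple[str, ...] = ()


@dataclass
class PanelTruth:
    variants: list[VariantTruth]
    founders: tuple[str, ...]

    def buildable(self) -> list[VariantTruth]:
        out = []
        for v in self.variants:
            if not v.in_window:
                continue
            if len(set(v.founder_alleles.values())) < 2:
                continue
            out.append(v)
        return out


@dataclass
class SyntheticDataset:
    vcf_path: Path
    bed_path: Path
    consequence_path: Path
    marker_path: Path
    genome: SyntheticGenome
    founders: tuple[str, ...]
    panel: PanelTruth
    mosaic: MosaicTruth
    seed: int


# ---------------------------------------------------------------------------
# Mosaics


def simulate_cc_mosaics(
    genome: SyntheticGenome,
    founders: Sequence[str] = DEFAULT_FOUNDERS,
    n_strains: int = 20,
    markers_per_chrom: int = 50,
    recomb_rate: float = 5.0,
    residual_het_rate: float = 0.0,
    uncertainty_level: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[MosaicTruth, dict[tuple[str, str], dict[int, dict]]]:
    """Draw strain mosaics and their (possibly blurred) marker emissions.

    ``recomb_rate`` is the expected number of breakpoints per chromosome
    (Poisson).  A fraction ``residual_het_rate`` of segments carries a
    heterozygous founder pair.  Marker distributions put ``1 -
    uncertainty_level`` on the true state and share the remainder between
    two confusion states that each have one haplotype in common with the
    truth.  Breakpoints are bracketed by an extra marker pair at adjacent
    base positions, so every variant sees two flanking markers in the same
    true segment.

    Returns the truth and a nested dict
    ``(strain, chrom) -> {marker pos -> {state: prob}}``.
    """
    if not (0.0 <= residual_het_rate <= 1.0):
        raise ValidationError("residual_het_rate must be in [0, 1]")
    if not (0.0 <= uncertainty_level < 1.0):
        raise ValidationError("uncertainty_level must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    founders = tuple(founders)
    strains = [f"CC{i + 1:03d}" for i in range(n_strains)]

    segments: dict[tuple[str, str], list[Segment]] = {}
    emissions: dict[tuple[str, str], dict[int, dict]] = {}
    for strain in strains:
        for chrom, length in zip(genome.chroms, genome.lengths):
            n_breaks = rng.poisson(recomb_rate)
            breaks = sorted(
                set(int(b) for b in rng.integers(2, length, size=n_breaks))
            )
            bounds = [1, *breaks, length + 1]
            segs = []
            for lo, hi in zip(bounds, bounds[1:]):
                if rng.random() < residual_het_rate:
                    f1, f2 = rng.choice(len(founders), size=2, replace=False)
                    state = canonical_unphased(founders[f1], founders[f2])
                else:
                    f = founders[int(rng.integers(len(founders)))]
                    state = (f, f)
                segs.append(Segment(start=lo, end=hi - 1, state=state))
            segments[(strain, chrom)] = segs

            grid = sorted(
                {int(p) for p in np.linspace(1, length, markers_per_chrom)}
            )
            marker_positions = set(grid)
            for b in breaks:
                marker_positions.add(b - 1)
                marker_positions.add(b)
            starts = [s.start for s in segs]
            marker_probs: dict[int, dict] = {}
            for pos in sorted(marker_positions):
                state = segs[bisect.bisect_right(starts, pos) - 1].state
                marker_probs[pos] = _blur_state(
                    state, founders, uncertainty_level, rng
                )
            emissions[(strain, chrom)] = marker_probs

    return MosaicTruth(segments=segments), emissions


def _blur_state(
    state: tuple[str, str],
    founders: tuple[str, ...],
    uncertainty: float,
    rng: np.random.Generator,
) -> dict[tuple[str, str], float]:
    if uncertainty == 0.0:
        return {state: 1.0}
    others = [f for f in founders if f not in state]
    if not others:
        return {state: 1.0}
    probs = {state: 1.0 - uncertainty}
    anchors = (state[0], state[1])
    picks = rng.choice(len(others), size=min(2, len(others)), replace=False)
    share = uncertainty / len(picks)
    for anchor, j in zip(anchors, picks):
        confusion = canonical_unphased(anchor, others[int(j)])
        probs[confusion] = probs.get(confusion, 0.0) + share
    return probs


def write_marker_csv(
    emissions: dict[tuple[str, str], dict[int, dict]],
    path: Path,
    genome: SyntheticGenome,
    seed: int,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#seed={seed}\n")
        fh.write("strain,chrom,pos,marker,hap1,hap2,prob\n")
        for strain in sorted({s for s, _ in emissions}):
            for chrom in genome.chroms:
                marker_probs = emissions.get((strain, chrom))
                if not marker_probs:
                    continue
                for i, pos in enumerate(sorted(marker_probs)):
                    name = f"m{chrom}_{pos}"
                    for (h1, h2), p in sorted(marker_probs[pos].items()):
                        fh.write(
                            f"{strain},{chrom},{pos},{name},{h1},{h2},{p!r}\n"
                        )


# ---------------------------------------------------------------------------
# Founder panel


def _generate_genes(
    genome: SyntheticGenome, n_variants: int, rng: np.random.Generator
):
    """Per chromosome: non-overlapping genes, each with 1-3 exons."""
    genes = []  # (chrom, gene_id, [(start, end)], n_transcripts)
    for chrom, length in zip(genome.chroms, genome.lengths):
        n_genes = max(3, n_variants // 25)
        span = length // n_genes
        for i in range(n_genes):
            gene_start = i * span + int(rng.integers(1000, max(2000, span // 4)))
            gene_id = f"ENSG{chrom}{i:05d}"
            n_exons = int(rng.integers(1, 4))
            exons = []
            cursor = gene_start
            for _ in range(n_exons):
                ex_len = int(rng.integers(200, 800))
                exons.append((cursor, min(cursor + ex_len - 1, length)))
                cursor += ex_len + int(rng.integers(500, 2000))
            n_transcripts = int(rng.integers(1, 3))
            genes.append((chrom, gene_id, exons, n_transcripts))
    return genes


def _window_union(exons: list[tuple[int, int]], window: int) -> list[tuple[int, int]]:
    expanded = sorted((max(1, s - window), e + window) for s, e in exons)
    merged: list[list[int]] = []
    for s, e in expanded:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _in_intervals(intervals: list[tuple[int, int]], pos: int) -> bool:
    i = bisect.bisect_right([s for s, _ in intervals], pos) - 1
    return i >= 0 and intervals[i][0] <= pos <= intervals[i][1]


@dataclass
class _PanelLayout:
    genes: list  # (chrom, gene_id, [(start, end)], n_transcripts)
    genes_by_chrom: dict[str, list]
    windows_by_chrom: dict[str, list[tuple[int, int]]]
    positions_by_chrom: dict[str, list[int]]


def _panel_layout(
    genome: SyntheticGenome,
    n_variants: int,
    fraction_outside: float,
    rng: np.random.Generator,
) -> _PanelLayout:
    genes = _generate_genes(genome, n_variants, rng)
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {}
    genes_by_chrom: dict[str, list] = {}
    for chrom, gene_id, exons, n_tx in genes:
        genes_by_chrom.setdefault(chrom, []).append((gene_id, exons, n_tx))
        windows_by_chrom.setdefault(chrom, []).extend(_window_union(exons, _WINDOW))
    for chrom in windows_by_chrom:
        windows_by_chrom[chrom] = _window_union(windows_by_chrom[chrom], 0)

    positions_by_chrom: dict[str, list[int]] = {}
    for chrom, length in zip(genome.chroms, genome.lengths):
        windows = windows_by_chrom.get(chrom, [])
        n_outside = int(round(n_variants * fraction_outside))
        n_inside = n_variants - n_outside
        positions: set[int] = set()
        window_lengths = np.array([e - s + 1 for s, e in windows], dtype=float)
        while len(positions) < n_inside:
            wi = int(rng.choice(len(windows), p=window_lengths / window_lengths.sum()))
            s, e = windows[wi]
            positions.add(int(rng.integers(s, e + 1)))
        guard = _window_union(windows, _WINDOW + 10)
        while len(positions) < n_inside + n_outside:
            pos = int(rng.integers(1, length))
            if not _in_intervals(guard, pos):
                positions.add(pos)
        positions_by_chrom[chrom] = sorted(positions)
    return _PanelLayout(genes, genes_by_chrom, windows_by_chrom, positions_by_chrom)


def _panel_from_layout(
    layout: _PanelLayout,
    genome: SyntheticGenome,
    out_dir: Path,
    founders: tuple[str, ...],
    het_rate: float,
    indel_rate: float,
    seed: int,
    rng: np.random.Generator,
    het_constraints: dict[tuple[str, int], list[tuple[str, str]]],
) -> tuple[Path, Path, Path, PanelTruth]:
    variants: list[VariantTruth] = []
    for chrom in genome.chroms:
        windows = layout.windows_by_chrom.get(chrom, [])
        for pos in layout.positions_by_chrom.get(chrom, []):
            variants.append(
                _draw_variant(chrom, pos, founders, het_rate, indel_rate,
                              windows, layout.genes_by_chrom.get(chrom, []),
                              het_constraints.get((chrom, pos), []), rng)
            )
    truth = PanelTruth(variants=variants, founders=founders)

    vcf_path = out_dir / "founders.vcf"
    bed_path = out_dir / "exons.bed"
    tsv_path = out_dir / "consequences.tsv"
    _write_vcf(vcf_path, genome, founders, truth, seed)
    _write_bed(bed_path, genome, layout.genes, seed)
    _write_consequences(tsv_path, genome, truth, layout.genes_by_chrom, seed, rng)
    return vcf_path, bed_path, tsv_path, truth


def simulate_founder_panel(
    genome: SyntheticGenome,
    out_dir: Path,
    n_variants: int = 500,
    founders: Sequence[str] = DEFAULT_FOUNDERS,
    het_rate: float = 0.0,
    indel_rate: float = 0.1,
    fraction_outside: float = 0.1,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    het_constraints: dict[tuple[str, int], list[tuple[str, str]]] | None = None,
) -> tuple[Path, Path, Path, PanelTruth]:
    """Generate founder VCF, consequence TSV, and exon BED.

    ``n_variants`` is per chromosome.  A fraction ``fraction_outside`` of
    variants is placed more than 100 bp from every exon, to exercise the
    build filter.  ``het_constraints`` maps (chrom, pos) to founder pairs
    that must carry different alleles there (used by the coupled dataset
    generator to realize residual heterozygosity faithfully).

    Returns (vcf_path, bed_path, tsv_path, truth).
    """
    for name, rate in (("het_rate", het_rate), ("indel_rate", indel_rate),
                       ("fraction_outside", fraction_outside)):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {rate}")
    if rng is None:
        rng = np.random.default_rng(seed)
    founders = tuple(founders)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = _panel_layout(genome, n_variants, fraction_outside, rng)
    return _panel_from_layout(
        layout, genome, out_dir, founders, het_rate, indel_rate, seed, rng,
        het_constraints or {},
    )


def _draw_variant(chrom, pos, founders, het_rate, indel_rate, windows,
                  chrom_genes, must_differ, rng) -> VariantTruth:
    ref = _BASES[rng.integers(4)]
    if rng.random() < indel_rate:
        if rng.random() < 0.5:  # insertion
            extra = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
            alts: list[str] = [ref + extra]
        else:  # deletion
            tail = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
            ref = ref + tail
            alts = [ref[0]]
    else:
        alts = [rng.choice([b for b in _BASES if b != ref])]

    # random carrier subset, then enforce must-differ founder pairs
    allele_of = {
        f: (alts[0] if rng.random() < 0.4 else ref) for f in founders
    }
    if all(a == ref for a in allele_of.values()):
        allele_of[founders[int(rng.integers(len(founders)))]] = alts[0]
    for _ in range(12):
        conflicts = [(f1, f2) for f1, f2 in must_differ if allele_of[f1] == allele_of[f2]]
        if not conflicts:
            break
        for f1, f2 in conflicts:
            flip = f2 if rng.random() < 0.5 else f1
            allele_of[flip] = alts[0] if allele_of[flip] == ref else ref
    else:
        # odd-cycle constraints need a third allele
        second = None
        for base in _BASES:
            if base != ref[0]:
                cand = base + ref[1:] if len(ref) > 1 else base
                if cand not in alts and cand != ref:
                    second = cand
                    break
        if second is not None:
            alts.append(second)
            for f1, f2 in must_differ:
                if allele_of[f1] == allele_of[f2]:
                    allele_of[f2] = second

    genotypes: dict[str, tuple[str, str]] = {}
    constrained = {f for pair in must_differ for f in pair}
    for f in founders:
        a = allele_of[f]
        if f not in constrained and rng.random() < het_rate:
            other = ref if a != ref else alts[0]
            genotypes[f] = canonical_unphased(a, other)
        else:
            genotypes[f] = (a, a)

    end = pos + len(ref) - 1
    in_window = any(s <= end and pos <= e for s, e in windows)
    overlapping = tuple(
        gene_id
        for gene_id, exons, _ in chrom_genes
        if any(s - _WINDOW <= end and pos <= e + _WINDOW for s, e in exons)
    )
    return VariantTruth(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
        founder_alleles=genotypes, in_window=in_window, genes=overlapping,
    )


def _write_vcf(path, genome, founders, truth, seed) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##synthetic_seed={seed}\n")
        for chrom, length in zip(genome.chroms, genome.lengths):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(founders) + "\n"
        )
        for v in truth.variants:
            alleles = [v.ref, *v.alts]
            calls = []
            for f in founders:
                a1, a2 = v.founder_alleles[f]
                calls.append(f"{alleles.index(a1)}/{alleles.index(a2)}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def _write_bed(path, genome, genes, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"#seed={seed}\n")
        for chrom in genome.chroms:
            for g_chrom, gene_id, exons, _ in genes:
                if g_chrom != chrom:
                    continue
                for start, end in exons:
                    fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene_id}\n")


def _write_consequences(path, genome, truth, genes_by_chrom, seed, rng) -> None:
    weights = np.array(_CONSEQUENCE_WEIGHTS)
    weights = weights / weights.sum()
    with open(path, "w") as fh:
        fh.write(f"#seed={seed}\n")
        for v in truth.variants:
            if not v.genes:
                continue
            gene_info = {g: (exons, n_tx) for g, exons, n_tx in genes_by_chrom[v.chrom]}
            for gene_id in v.genes:
                _, n_tx = gene_info[gene_id]
                for t in range(n_tx):
                    transcript_id = f"{gene_id}T{t + 1}"
                    for alt in v.alts:
                        term = CONSEQUENCE_VOCABULARY[
                            int(rng.choice(len(CONSEQUENCE_VOCABULARY), p=weights))
                        ]
                        fh.write(
                            f"{v.chrom}\t{v.pos}\t{alt}\t"
                            f"{gene_id}:{transcript_id}\t{term}\n"
                        )


# ---------------------------------------------------------------------------
# Coupled dataset


def simulate_dataset(
    out_dir: Path,
    seed: int = 0,
    genome: SyntheticGenome | None = None,
    founders: Sequence[str] = DEFAULT_FOUNDERS,
    n_strains: int = 20,
    n_variants: int = 500,
    markers_per_chrom: int = 50,
    recomb_rate: float = 5.0,
    het_rate: float = 0.0,
    indel_rate: float = 0.1,
    fraction_outside: float = 0.1,
    residual_het_rate: float = 0.0,
    uncertainty_level: float = 0.0,
) -> SyntheticDataset:
    """Generate a complete, mutually consistent synthetic input set.

    Mosaics are drawn first; the founder panel then honours the
    must-differ constraints implied by heterozygous mosaic segments, so
    that the emitted residual heterozygosity matches
    ``residual_het_rate``.
    """
    genome = genome or SyntheticGenome()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    founders = tuple(founders)

    mosaic, emissions = simulate_cc_mosaics(
        genome, founders=founders, n_strains=n_strains,
        markers_per_chrom=markers_per_chrom, recomb_rate=recomb_rate,
        residual_het_rate=residual_het_rate,
        uncertainty_level=uncertainty_level, rng=rng, seed=seed,
    )

    # layout first, so het-segment constraints can be keyed on positions
    layout = _panel_layout(genome, n_variants, fraction_outside, rng)
    constraints: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for chrom in genome.chroms:
        for pos in layout.positions_by_chrom.get(chrom, []):
            for key, segs in mosaic.segments.items():
                if key[1] != chrom:
                    continue
                starts = [s.start for s in segs]
                seg = segs[bisect.bisect_right(starts, pos) - 1]
                if seg.is_het:
                    constraints.setdefault((chrom, pos), []).append(seg.state)

    vcf_path, bed_path, tsv_path, panel = _panel_from_layout(
        layout, genome, out_dir, founders, het_rate, indel_rate, seed, rng,
        constraints,
    )

    marker_path = out_dir / "markers.csv"
    write_marker_csv(emissions, marker_path, genome, seed)

    return SyntheticDataset(
        vcf_path=vcf_path, bed_path=bed_path, consequence_path=tsv_path,
        marker_path=marker_path, genome=genome, founders=founders,
        panel=panel, mosaic=mosaic, seed=seed,
    )
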