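import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from strainvar.core import (
    DiplotypeDistribution,
    FounderGenotypeDistribution,
    Variant,
    canonical_unphased,
)
from strainvar.query import build_store
from strainvar.synthetic import SyntheticGenome, simulate_dataset


@pytest.fixture
def variant():
    return Variant(variant_id=1, chrom="1", pos=1000, ref_allele="C", alt_alleles=("T",))


@pytest.fixture
def triallelic_variant():
    return Variant(
        variant_id=2, chrom="1", pos=2000, ref_allele="C", alt_alleles=("T", "G")
    )


def make_dip(strain, chrom, pos, probs, source="marker"):
    return DiplotypeDistribution(
        strain=strain, chrom=chrom, pos=pos,
        probs={canonical_unphased(*k): v for k, v in probs.items()},
        source=source,
    )


def make_founder_gt(variant, founder, probs):
    return FounderGenotypeDistribution(
        variant=variant, founder=founder,
        probs={canonical_unphased(*k): v for k, v in probs.items()},
    )


@pytest.fixture(scope="session")
def small_genome():
    return SyntheticGenome(chroms=("1", "2"), lengths=(2_000_000, 2_000_000))


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, small_genome):
    """Modest synthetic dataset with uncertainty and residual heterozygosity."""
    return simulate_dataset(
        tmp_path_factory.mktemp("synth"),
        seed=11,
        genome=small_genome,
        n_strains=8,
        n_variants=120,
        markers_per_chrom=25,
        recomb_rate=4.0,
        het_rate=0.02,
        indel_rate=0.1,
        fraction_outside=0.15,
        residual_het_rate=0.08,
        uncertainty_level=0.1,
    )


@pytest.fixture(scope="session")
def store(tmp_path_factory, dataset):
    return build_store(
        dataset.vcf_path,
        dataset.marker_path,
        dataset.bed_path,
        tmp_path_factory.mktemp("store"),
        consequence_tsv=dataset.consequence_path,
        founders=list(dataset.founders),
    )


@pytest.fixture(scope="session")
def exact_dataset(tmp_path_factory, small_genome):
    """Fully certain dataset: point-mass markers, no residual or founder het."""
    return simulate_dataset(
        tmp_path_factory.mktemp("synth_exact"),
        seed=7,
        genome=small_genome,
        n_strains=6,
        n_variants=80,
        markers_per_chrom=20,
        recomb_rate=4.0,
        het_rate=0.0,
        indel_rate=0.1,
        fraction_outside=0.1,
        residual_het_rate=0.0,
        uncertainty_level=0.0,
    )


@pytest.fixture(scope="session")
def exact_store(tmp_path_factory, exact_dataset):
    return build_store(
        exact_dataset.vcf_path,
        exact_dataset.marker_path,
        exact_dataset.bed_path,
        tmp_path_factory.mktemp("store_exact"),
        consequence_tsv=exact_dataset.consequence_path,
        founders=list(exact_dataset.founders),
    )
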