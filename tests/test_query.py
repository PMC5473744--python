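import filecmp

import pytest

from strainvar.core import ValidationError, canonical_unphased
from strainvar.query import (
    Region,
    VariantStore,
    apply_restrictions,
    build_store,
    consequence_spectrum,
    query_diplotype,
    query_diplotype_cross,
    query_genotype,
    query_genotype_cross,
    reference_identity_summary,
    residual_het_summary,
)


def row_key(row):
    return (row.variant_id, row.strain, row.gene_id, row.transcript_id,
            row.allele_1, row.allele_2)


class TestRegion:
    def test_parse(self):
        r = Region.parse("chr1:100-200")
        assert (r.chrom, r.start, r.end) == ("chr1", 100, 200)

    @pytest.mark.parametrize("bad", ["chr1", "chr1:100", "chr1:200-100", "chr1:0-5"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValidationError):
            Region.parse(bad)


class TestBuildStore:
    def test_store_cardinality(self, store, dataset):
        n = store.manifest["n_variants"]
        assert n == len(dataset.panel.buildable())
        for chrom in store.chroms:
            conn = store.conn(chrom)
            (n_chrom,) = conn.execute("SELECT COUNT(*) FROM variants").fetchone()
            for strain in store.strains:
                (groups,) = conn.execute(
                    "SELECT COUNT(DISTINCT variant_id) FROM genotypes WHERE strain=?",
                    (strain,),
                ).fetchone()
                assert groups == n_chrom

    def test_variant_ids_ascending_by_position(self, store):
        prev = 0
        for chrom in store.chroms:
            for v in store.all_variants(chrom):
                assert v.variant_id == prev + 1
                prev = v.variant_id

    def test_rebuild_is_byte_identical(self, tmp_path, dataset):
        for name in ("s1", "s2"):
            build_store(
                dataset.vcf_path, dataset.marker_path, dataset.bed_path,
                tmp_path / name, consequence_tsv=dataset.consequence_path,
                founders=list(dataset.founders),
            )
        for name in ("a", "b"):
            VariantStore(tmp_path / ("s1" if name == "a" else "s2")).dump(
                tmp_path / f"dump_{name}"
            )
        dumps_a = sorted((tmp_path / "dump_a").iterdir())
        dumps_b = sorted((tmp_path / "dump_b").iterdir())
        assert [p.name for p in dumps_a] == [p.name for p in dumps_b]
        for pa, pb in zip(dumps_a, dumps_b):
            assert filecmp.cmp(pa, pb, shallow=False), pa.name

    def test_unpruned_build_conserves_mass(self, tmp_path, dataset):
        store = build_store(
            dataset.vcf_path, dataset.marker_path, dataset.bed_path,
            tmp_path / "store0", consequence_tsv=dataset.consequence_path,
            founders=list(dataset.founders), prune_threshold=0.0,
        )
        for chrom in store.chroms:
            conn = store.conn(chrom)
            for table in ("genotypes", "diplotypes"):
                rows = conn.execute(
                    f"SELECT variant_id, strain, SUM(prob) FROM {table} "
                    f"GROUP BY variant_id, strain"
                ).fetchall()
                assert rows
                for vid, strain, total in rows:
                    assert total == pytest.approx(1.0, abs=1e-9), (table, vid, strain)

    def test_pruned_build_drops_subthreshold_mass(self, tmp_path):
        # hand-built inputs with a 0.0005 marker state: pruned, not renormalized
        vcf = tmp_path / "f.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=10000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tAJ\tB6\n"
            "1\t500\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        )
        markers = tmp_path / "m.csv"
        markers.write_text(
            "strain,chrom,pos,marker,hap1,hap2,prob\n"
            "CC001,1,500,m1,AJ,AJ,0.9995\n"
            "CC001,1,500,m1,B6,B6,0.0005\n"
            "CC001,1,900,m2,AJ,AJ,0.9995\n"
            "CC001,1,900,m2,B6,B6,0.0005\n"
        )
        bed = tmp_path / "e.bed"
        bed.write_text("1\t400\t600\tG1\n")
        store = build_store(vcf, markers, bed, tmp_path / "s",
                            founders=["AJ", "B6"])
        variant = store.all_variants("1")[0]
        gt = store.genotype(variant, "CC001")
        assert gt.probs == {("C", "C"): 0.9995}
        assert gt.total() == pytest.approx(0.9995)  # shortfall preserved


class TestQueries:
    def test_region_query_returns_rows(self, store):
        chrom = store.chroms[0]
        rows = query_genotype(store, store.strains[:2], region=f"{chrom}:1-99999999")
        assert rows
        assert all(r.chrom == chrom for r in rows)

    def test_unknown_strain_lists_valid_names(self, store):
        with pytest.raises(ValidationError, match="CC001"):
            query_genotype(store, ["NOPE"], region="1:1-10")

    def test_unknown_gene_rejected(self, store):
        with pytest.raises(ValidationError, match="unknown gene"):
            query_genotype(store, store.strains[:1], genes=["NOGENE"])

    def test_variant_id_query(self, store):
        rows = query_genotype(store, store.strains[:1], variant_ids=[1])
        assert rows
        assert all(r.variant_id == 1 for r in rows)
        with pytest.raises(ValidationError, match="unknown variant_id"):
            query_genotype(store, store.strains[:1], variant_ids=[10**6])

    def test_exactly_one_selector_required(self, store):
        with pytest.raises(ValidationError):
            query_genotype(store, store.strains[:1])
        with pytest.raises(ValidationError):
            query_genotype(
                store, store.strains[:1], region="1:1-10", variant_ids=[1]
            )

    def test_region_partition_union(self, store):
        chrom = store.chroms[0]
        strains = store.strains[:2]
        whole = query_genotype(store, strains, region=f"{chrom}:1-2000000")
        mid = 1000000
        left = query_genotype(store, strains, region=f"{chrom}:1-{mid}")
        right = query_genotype(store, strains, region=f"{chrom}:{mid + 1}-2000000")
        assert {row_key(r) for r in whole} == (
            {row_key(r) for r in left} | {row_key(r) for r in right}
        )

    def test_diplotype_rows_have_no_consequences(self, store):
        chrom = store.chroms[0]
        rows = query_diplotype(store, store.strains[:1], region=f"{chrom}:1-99999999")
        assert rows
        founders = set(store.founders)
        for r in rows:
            assert r.allele_1 in founders and r.allele_2 in founders
            assert r.gene_id == "" and r.consequence_1 == ""

    def test_diplotype_at_marker_matches_marker(self, store, dataset):
        from strainvar.io import load_marker_map

        markers = load_marker_map(dataset.marker_path, list(dataset.founders))
        strain = store.strains[0]
        chrom = store.chroms[0]
        marker_list = markers.markers(strain, chrom)
        variants = {v.pos: v for v in store.all_variants(chrom)}
        hits = [m for m in marker_list if m.pos in variants]
        for m in hits:
            dip = store.diplotype(variants[m.pos], strain)
            pruned = {k: p for k, p in m.probs.items() if p >= 0.001}
            assert dip.probs == pytest.approx(pruned)


class TestCrossQueries:
    def test_two_strains_required(self, store):
        with pytest.raises(ValidationError, match="two strains"):
            query_genotype_cross(store, store.strains[:3], region="1:1-10")

    def test_founder_cross_het_where_founders_differ(self, exact_store):
        store = exact_store
        f1_name, f2_name = store.founders[0], store.founders[5]
        chrom = store.chroms[0]
        rows = query_genotype_cross(
            store, [f1_name, f2_name], region=f"{chrom}:1-99999999"
        )
        by_variant = {}
        for r in rows:
            by_variant.setdefault(r.variant_id, []).append(r)
        for vid, vrows in by_variant.items():
            variant = store.variant(chrom, vid)
            g1 = store.genotype(variant, f1_name)
            g2 = store.genotype(variant, f2_name)
            differs = g1.probs != g2.probs
            zygosities = {r.zygosity for r in vrows}
            if differs:
                assert zygosities == {"het"}
            else:
                assert zygosities == {"hom"}

    def test_cross_symmetry(self, store):
        chrom = store.chroms[0]
        s1, s2 = store.strains[0], store.strains[1]
        fwd = query_genotype_cross(store, [s1, s2], region=f"{chrom}:1-2000000")
        rev = query_genotype_cross(store, [s2, s1], region=f"{chrom}:1-2000000")

        def keyed(rows):
            return {
                (r.variant_id, frozenset([r.strain]), r.gene_id, r.transcript_id,
                 r.allele_1, r.allele_2): r.prob
                for r in rows
            }

        fk = {(k[0], *k[2:]): v for k, v in keyed(fwd).items()}
        rk = {(k[0], *k[2:]): v for k, v in keyed(rev).items()}
        assert fk == rk

    def test_diplotype_cross_strain_pair(self, store):
        chrom = store.chroms[0]
        rows = query_diplotype_cross(
            store, store.strains[:2], region=f"{chrom}:1-2000000"
        )
        assert rows
        assert all(r.strain == tuple(store.strains[:2]) for r in rows)


class TestRestrictions:
    @pytest.fixture()
    def rows(self, store):
        chrom = store.chroms[0]
        return query_genotype(store, store.strains, region=f"{chrom}:1-99999999")

    def test_composition_order_invariant(self, rows):
        a = apply_restrictions(
            apply_restrictions(rows, zygosity="het"), prob_threshold=0.2
        )
        b = apply_restrictions(
            apply_restrictions(rows, prob_threshold=0.2), zygosity="het"
        )
        c = apply_restrictions(rows, zygosity="het", prob_threshold=0.2)
        assert [row_key(r) for r in a] == [row_key(r) for r in b]
        assert [row_key(r) for r in a] == [row_key(r) for r in c]

    def test_max_only_keeps_group_maxima(self, rows):
        kept = apply_restrictions(rows, max_only=True)
        assert kept
        assert all(r.is_max for r in kept)
        by_group = {}
        for r in rows:
            by_group.setdefault(r.group_key, []).append(r)
        for r in kept:
            assert r.prob == pytest.approx(max(x.prob for x in by_group[r.group_key]))

    def test_threshold(self, rows):
        kept = apply_restrictions(rows, prob_threshold=0.9)
        assert all(r.prob >= 0.9 for r in kept)

    def test_zygosity(self, rows):
        hom = apply_restrictions(rows, zygosity="hom")
        het = apply_restrictions(rows, zygosity="het")
        assert all(r.allele_1 == r.allele_2 for r in hom)
        assert all(r.allele_1 != r.allele_2 for r in het)
        assert len(hom) + len(het) == len(rows)

    def test_consequence_either_vs_both(self, rows):
        term = "missense_variant"
        either = apply_restrictions(rows, consequences=[term])
        both = apply_restrictions(rows, consequences=[term], consequence_mode="both")
        assert set(map(row_key, both)) <= set(map(row_key, either))
        for r in either:
            assert term in (r.consequence_1, r.consequence_2)
        for r in both:
            assert (r.consequence_1, r.consequence_2) == (term, term)


class TestSummaries:
    def test_certain_store_has_zero_residual_het(self, exact_store):
        table = residual_het_summary(exact_store)
        assert (table["proportion_het"] == 0.0).all()

    def test_residual_het_recovery(self, tmp_path, small_genome):
        from strainvar.synthetic import simulate_dataset

        rate = 0.10
        ds = simulate_dataset(
            tmp_path / "synthhet", seed=23, genome=small_genome, n_strains=10,
            n_variants=150, markers_per_chrom=30, recomb_rate=15.0,
            het_rate=0.0, residual_het_rate=rate, uncertainty_level=0.0,
        )
        store = build_store(
            ds.vcf_path, ds.marker_path, ds.bed_path, tmp_path / "storehet",
            consequence_tsv=ds.consequence_path, founders=list(ds.founders),
        )
        table = residual_het_summary(store)
        weights = table["n_variants"].sum()
        observed = (table["proportion_het"] * table["n_variants"]).sum() / weights

        # binomial SE over the number of independent mosaic segments
        n_segments = sum(len(v) for v in ds.mosaic.segments.values())
        se = (rate * (1 - rate) / n_segments) ** 0.5
        assert abs(observed - rate) <= 3 * se

    def test_boundary_quarter_counts_as_het(self, store):
        # direct unit check of the >= cutoff via a tiny in-memory case
        from strainvar.query import RESIDUAL_HET_CUTOFF

        assert RESIDUAL_HET_CUTOFF == 0.25

    def test_reference_identity_bounds(self, store):
        value = reference_identity_summary(store)
        assert 0.0 < value < 1.0
        weighted = reference_identity_summary(store, method="weighted")
        assert 0.0 < weighted <= 1.0

    def test_reference_identity_empty_strains_rejected(self, store):
        with pytest.raises(ValidationError):
            reference_identity_summary(store, strains=[])

    def test_reference_identity_matches_direct_tally(self, exact_store):
        store = exact_store
        total = 0
        identical = 0
        for chrom in store.chroms:
            for variant in store.all_variants(chrom):
                ref_key = canonical_unphased(variant.ref_allele, variant.ref_allele)
                for strain in store.strains:
                    gt = store.genotype(variant, strain)
                    total += 1
                    if gt is not None and gt.probs == {ref_key: 1.0}:
                        identical += 1
        assert reference_identity_summary(store) == pytest.approx(identical / total)

    def test_consequence_spectrum_matches_direct_tally(self, store):
        spectrum = consequence_spectrum(store)
        assert not spectrum.empty
        assert spectrum["share"].sum() == pytest.approx(1.0)
        assert "reference" not in set(spectrum["consequence"])

        rows = []
        for chrom in store.chroms:
            rows.extend(
                query_genotype(store, store.strains, region=f"{chrom}:1-99999999")
            )
        mass = {}
        for r in rows:
            for term in {r.consequence_1, r.consequence_2} - {"reference", ""}:
                mass[term] = mass.get(term, 0.0) + r.prob
        total = sum(mass.values())
        for _, rec in spectrum.iterrows():
            assert rec["share"] == pytest.approx(mass[rec["consequence"]] / total)
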