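import filecmp

import numpy as np
import pandas as pd
import pytest

from genesat.gene_model import GeneAssignment, GeneRegion
from genesat.ld_panel import (
    EmptyLDError,
    GeneSnpSet,
    LDMatrix,
    PanelVariant,
    build_bundles,
    build_gene_set,
    compute_ld,
    harmonize,
    load_panel,
    prune_perfect,
    read_bundles,
)
from genesat.snpset_tests import adaptive_test
from genesat.sumstats import SummaryStatRecord

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5\tS6
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\t0/0\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/0\t0/1\t1/1
1\t300\trs3\tA\tC\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\t1/1\t0/1\t0/0
1\t400\trs4\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/1\t0/0\t0/2
1\t500\trs5\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/0\t0/1\t0/0
"""

EXPECTED_DOSAGES = {
    "rs1": [0, 1, 2, 1, 0, 2],
    "rs2": [1, 0, 2, 0, 1, 2],
    "rs3": [0, np.nan, 1, 2, 1, 0],
}


@pytest.fixture
def panel_vcf(tmp_path):
    path = tmp_path / "panel.vcf"
    path.write_text(VCF_TEXT)
    return path


def gwas_record(rsid, pos, effect, other, z):
    rec = SummaryStatRecord(
        rsid=rsid, chrom="1", pos=pos, effect_allele=effect, other_allele=other,
        odds_ratio=1.1, se=0.1,
    )
    rec.z = z
    return rec


class TestLoadPanel:
    def test_biallelic_snvs_only_with_skip_counts(self, panel_vcf):
        variants, skipped = load_panel(panel_vcf)
        assert [v.rsid for v in variants] == ["rs1", "rs2", "rs3"]
        assert skipped["multiallelic"] == 1
        assert skipped["indel_or_other"] == 1

    def test_dosages_match_fixture(self, panel_vcf):
        variants, _ = load_panel(panel_vcf)
        for v in variants:
            np.testing.assert_array_equal(v.dosages, EXPECTED_DOSAGES[v.rsid])

    def test_region_filter_and_empty_region(self, panel_vcf):
        variants, _ = load_panel(panel_vcf, region=("1", 150, 350))
        assert [v.rsid for v in variants] == ["rs2", "rs3"]
        empty, _ = load_panel(panel_vcf, region=("2", 1, 10**9))
        assert empty == []

    def test_missing_file_is_input_error(self, tmp_path):
        from genesat.ld_panel import InputError

        with pytest.raises(InputError):
            load_panel(tmp_path / "nope.vcf")


class TestHarmonize:
    def assignment(self, records):
        gene = GeneRegion("G1", "1", 1, 1000)
        return GeneAssignment(gene=gene, members=records)

    def test_effect_allele_is_alt_keeps_sign(self, panel_vcf):
        variants, _ = load_panel(panel_vcf)
        h = harmonize(self.assignment([gwas_record("rs1", 100, "A", "G", 1.3)]), variants)
        assert h.z.tolist() == [1.3]
        assert not h.flipped[0]

    def test_effect_allele_is_ref_flips_sign(self, panel_vcf):
        variants, _ = load_panel(panel_vcf)
        h = harmonize(self.assignment([gwas_record("rs1", 100, "G", "A", 1.3)]), variants)
        assert h.z.tolist() == [-1.3]
        assert h.flipped[0]
        assert h.counts["flipped"] == 1

    def test_incompatible_allele_pair_dropped(self, panel_vcf):
        variants, _ = load_panel(panel_vcf)
        h = harmonize(self.assignment([gwas_record("rsX", 100, "A", "C", 1.3)]), variants)
        assert h.m == 0
        assert h.counts["dropped_incompatible"] == 1

    def test_unmatched_position_dropped(self, panel_vcf):
        variants, _ = load_panel(panel_vcf)
        h = harmonize(self.assignment([gwas_record("rsY", 999, "A", "G", 1.3)]), variants)
        assert h.counts["dropped_unmatched"] == 1


class TestComputeLD:
    def test_identical_and_mirrored_vectors(self):
        a = PanelVariant("1", 1, "a", "A", "G", np.array([0, 1, 2, 1, 0, 2.0]))
        b = PanelVariant("1", 2, "b", "A", "G", np.array([0, 1, 2, 1, 0, 2.0]))
        c = PanelVariant("1", 3, "c", "A", "G", np.array([2, 1, 0, 1, 2, 0.0]))
        ld, _ = compute_ld([a, b, c])
        assert ld.r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert ld.r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self, rng):
        dosages = rng.integers(0, 3, size=(3, 6)).astype(float)
        dosages[0, 0] = 0  # keep some variation but deterministic shape
        variants = [
            PanelVariant("1", i + 1, f"v{i}", "A", "G", dosages[i]) for i in range(3)
        ]
        ld, _ = compute_ld(variants)
        expected = np.corrcoef(dosages)
        np.testing.assert_allclose(ld.r, expected, atol=1e-12)
        ld.check()

    def test_monomorphic_dropped(self):
        mono = PanelVariant("1", 1, "mono", "A", "G", np.zeros(6))
        a = PanelVariant("1", 2, "a", "A", "G", np.array([0, 1, 2, 1, 0, 2.0]))
        b = PanelVariant("1", 3, "b", "A", "G", np.array([0, 0, 2, 1, 0, 1.0]))
        ld, mono_idx = compute_ld([mono, a, b])
        assert mono_idx == [0]
        assert ld.snp_ids == ["a", "b"]

    def test_pairwise_complete_with_missing(self):
        a = PanelVariant("1", 1, "a", "A", "G", np.array([0, 1, 2, np.nan, 0, 2.0]))
        b = PanelVariant("1", 2, "b", "A", "G", np.array([0, 1, 2, 1, np.nan, 2.0]))
        ld, _ = compute_ld([a, b])
        mask = ~np.isnan(a.dosages) & ~np.isnan(b.dosages)
        expected = np.corrcoef(a.dosages[mask], b.dosages[mask])[0, 1]
        assert ld.r[0, 1] == pytest.approx(expected, abs=1e-12)


def make_gene_set(z, r, positions=None):
    m = len(z)
    positions = positions or list(range(100, 100 + m))
    snps = pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(m)],
            "pos": positions,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "z": z,
        }
    )
    return GeneSnpSet(
        gene_id="G1", chrom="1", z=np.asarray(z, float),
        ld=LDMatrix(snp_ids=list(snps["rsid"]), r=np.asarray(r, float)), snps=snps,
    )


class TestPrunePerfect:
    def test_perfect_pair_drops_later_snp(self):
        r = np.eye(3)
        r[0, 2] = r[2, 0] = 1.0
        pruned = prune_perfect(make_gene_set([1.0, 2.0, 3.0], r))
        assert pruned.ld.snp_ids == ["rs0", "rs1"]
        assert pruned.z.tolist() == [1.0, 2.0]
        assert pruned.provenance["pruned"] == 1

    def test_below_threshold_unchanged(self):
        r = np.array([[1.0, 0.95], [0.95, 1.0]])
        pruned = prune_perfect(make_gene_set([1.0, 2.0], r))
        assert pruned.m == 2

    def test_transitive_chain_keeps_only_first(self):
        r = np.ones((3, 3))
        with pytest.raises(EmptyLDError):
            prune_perfect(make_gene_set([1.0, 2.0, 3.0], r))
        # brute force over all greedy orders confirms a single survivor
        survivors = {
            tuple(
                j for j in order
                if all(abs(r[i, j]) < 0.9999 for i in order[: order.index(j)])
            )
            for order in [(0, 1, 2)]
        }
        assert survivors == {(0,)}

    def test_is_projection(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((6, 4))
        r = np.corrcoef(np.column_stack([base[:, 0], base[:, 0], base.T[1:].T]).T)
        gs = make_gene_set(rng.standard_normal(5), r)
        once = prune_perfect(gs)
        twice = prune_perfect(once)
        np.testing.assert_array_equal(once.z, twice.z)
        np.testing.assert_array_equal(once.ld.r, twice.ld.r)


class TestBundles:
    def make_sets(self, rng):
        sets = []
        for chrom, gid in (("1", "GENE_A"), ("1", "GENE_B"), ("2", "GENE_C")):
            m = 4
            base = rng.standard_normal((50, m))
            r = np.corrcoef(base.T)
            sets.append(
                GeneSnpSet(
                    gene_id=gid, chrom=chrom, z=rng.standard_normal(m),
                    ld=LDMatrix([f"{gid}_s{i}" for i in range(m)], r),
                    snps=pd.DataFrame(
                        {
                            "rsid": [f"{gid}_s{i}" for i in range(m)],
                            "pos": np.arange(m) * 10 + 1,
                            "effect_allele": ["A"] * m,
                            "other_allele": ["G"] * m,
                            "z": rng.standard_normal(m),
                        }
                    ),
                    start=1, end=1000,
                )
            )
        return sets

    def test_round_trip_bit_exact(self, tmp_path, rng):
        sets = self.make_sets(rng)
        build_bundles(sets, tmp_path / "b")
        loaded = {gs.gene_id: gs for gs in read_bundles(tmp_path / "b")}
        assert set(loaded) == {"GENE_A", "GENE_B", "GENE_C"}
        for gs in sets:
            got = loaded[gs.gene_id]
            np.testing.assert_array_equal(got.z, gs.z)
            np.testing.assert_array_equal(got.ld.r, gs.ld.r)

    def test_two_writes_byte_identical(self, tmp_path, rng):
        sets = self.make_sets(rng)
        build_bundles(sets, tmp_path / "b1")
        build_bundles(sets, tmp_path / "b2")
        cmp = filecmp.dircmp(tmp_path / "b1", tmp_path / "b2")
        assert not cmp.diff_files

        def walk(dc):
            assert not dc.diff_files and not dc.left_only and not dc.right_only
            for sub in dc.subdirs.values():
                walk(sub)

        walk(cmp)

    def test_empty_bundle_valid(self, tmp_path):
        build_bundles([], tmp_path / "b")
        assert read_bundles(tmp_path / "b") == []


class TestFlipInvariance:
    def test_allele_recoding_leaves_p_values_unchanged(self, panel_vcf):
        """Swapping a panel variant's REF/ALT (dosage -> 2 - dosage) flips z
        and the LD row/col signs but not any gene p-value."""
        variants, _ = load_panel(panel_vcf)
        gene = GeneRegion("G1", "1", 1, 1000)
        records = [
            gwas_record("rs1", 100, "A", "G", 1.1),
            gwas_record("rs2", 200, "T", "C", -0.7),
            gwas_record("rs3", 300, "C", "A", 0.4),
        ]
        base = build_gene_set(harmonize(GeneAssignment(gene, list(records)), variants))

        flipped_panel = []
        for v in variants:
            if v.rsid == "rs2":
                flipped_panel.append(
                    PanelVariant(v.chrom, v.pos, v.rsid, v.alt_allele, v.ref_allele,
                                 2.0 - v.dosages)
                )
            else:
                flipped_panel.append(v)
        flip = build_gene_set(harmonize(GeneAssignment(gene, list(records)), flipped_panel))

        idx = base.ld.snp_ids.index("rs2")
        assert flip.z[idx] == pytest.approx(-base.z[idx], abs=1e-12)
        signs = np.ones(base.m)
        signs[idx] = -1
        np.testing.assert_allclose(flip.ld.r, base.ld.r * np.outer(signs, signs), atol=1e-12)

        # recoding EVERY variant leaves the harmonized model (z, R)
        # equivalent (z -> -z, R unchanged), so no p-value may move
        all_flipped = [
            PanelVariant(v.chrom, v.pos, v.rsid, v.alt_allele, v.ref_allele,
                         2.0 - v.dosages)
            for v in variants
        ]
        full = build_gene_set(harmonize(GeneAssignment(gene, list(records)), all_flipped))
        np.testing.assert_allclose(full.z, -base.z, atol=1e-12)
        np.testing.assert_allclose(full.ld.r, base.ld.r, atol=1e-12)
        res_base = adaptive_test(base.z, base.ld.r)
        res_full = adaptive_test(full.z, full.ld.r)
        for attr in ("p_st", "p_s2t", "T", "p_at"):
            assert getattr(res_full, attr) == pytest.approx(
                getattr(res_base, attr), abs=1e-10
            )
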