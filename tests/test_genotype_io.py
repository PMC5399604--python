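import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tagarray.genotype_io as gio
from tagarray import (
    FilterRules,
    GenotypeMatrix,
    HaplotypeMatrix,
    Site,
    compute_maf,
    drop_samples_prune_private,
    filter_sites,
    merge_single_sample_vcfs,
    read_vcf,
    write_vcf,
)
from conftest import make_genotypes, make_haps, make_sites


def ann_table(sites, maf=0.2, design=0.9, scaffold=False, must=False):
    ids = [s.id for s in sites]
    return pd.DataFrame(
        {
            "id": ids,
            "maf": [maf] * len(ids) if np.isscalar(maf) else maf,
            "design_score": [design] * len(ids) if np.isscalar(design) else design,
            "on_scaffold": [scaffold] * len(ids) if np.isscalar(scaffold) else scaffold,
            "must_include": [must] * len(ids) if np.isscalar(must) else must,
        }
    )


class TestVCFRoundTrip:
    def test_phased_roundtrip_bit_exact(self, tmp_path):
        h = make_haps([[0, 1, 1], [1, 0, 1], [0, 0, 0], [1, 1, 0]])
        path = tmp_path / "phased.vcf"
        write_vcf(h, path)
        back = read_vcf(path)
        assert isinstance(back, HaplotypeMatrix)
        assert np.array_equal(back.haps, h.haps)
        assert [s.key for s in back.sites] == [s.key for s in h.sites]
        assert back.samples == h.samples

    def test_missing_genotype_gives_genotype_matrix(self, tmp_path):
        g = make_genotypes([[0, 1], [gio.MISSING, 2]])
        path = tmp_path / "unphased.vcf"
        write_vcf(g, path)
        back = read_vcf(path)
        assert isinstance(back, GenotypeMatrix)
        assert np.array_equal(back.gt, g.gt)

    def test_phased_dimensions(self, tmp_path):
        # 2 phased diploid samples, 3 biallelic records -> 4 x 3 haplotypes
        h = make_haps(np.zeros((4, 3), dtype=np.uint8) + np.eye(4, 3, dtype=np.uint8))
        path = tmp_path / "dims.vcf"
        write_vcf(h, path)
        back = read_vcf(path)
        assert back.haps.shape == (4, 3)

    def test_region_filter(self, tmp_path):
        h = make_haps([[0, 1, 0], [1, 0, 1]], positions=[100, 5000, 9000])
        path = tmp_path / "r.vcf"
        write_vcf(h, path)
        back = read_vcf(path, region="1:4000-9500")
        assert [s.pos for s in back.sites] == [5000, 9000]


class TestMultiallelicPolicy:
    def _write_multi(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\t.\tA\tG,T\t.\t.\t.\tGT\t1|2\n"
        )
        return path

    def test_reject_raises(self, tmp_path):
        with pytest.raises(gio.UnsupportedInputError, match="multiallelic"):
            read_vcf(self._write_multi(tmp_path))

    def test_split_yields_one_site_per_alt(self, tmp_path):
        back = read_vcf(self._write_multi(tmp_path), multiallelic="split")
        assert back.haps.shape[1] == 2
        assert [s.alt for s in back.sites] == ["G", "T"]
        assert np.array_equal(back.haps, [[1, 0], [0, 1]])

    def test_skip_drops_record(self, tmp_path):
        back = read_vcf(self._write_multi(tmp_path), multiallelic="skip")
        assert back.n_sites == 0


class TestMergeSingleSampleVCFs:
    def _single(self, tmp_path, name, sites, gts):
        g = GenotypeMatrix(sites, [name], np.array([gts], dtype=np.int8))
        keep = [j for j, v in enumerate(gts) if v > 0]  # variant-only deliverable
        path = tmp_path / f"{name}.vcf"
        write_vcf(g.subset_sites(keep), path)
        return path

    def test_backfill_and_count_conservation(self, tmp_path):
        universe = make_sites(3)
        pa = self._single(tmp_path, "A", universe, [1, 0, 2])
        pb = self._single(tmp_path, "B", universe, [0, 1, 0])
        merged = merge_single_sample_vcfs([pa, pb], universe)
        assert merged.samples == ["A", "B"]
        assert np.array_equal(merged.gt, [[1, 0, 2], [0, 1, 0]])
        # per-sample het / hom-alt counts conserved by the merge
        assert (merged.gt == 1).sum() == 2 and (merged.gt == 2).sum() == 1

    def test_zero_inputs(self):
        universe = make_sites(2)
        merged = merge_single_sample_vcfs([], universe)
        assert merged.gt.shape == (0, 2)
        assert [s.id for s in merged.sites] == [s.id for s in universe]

    def test_conflicting_alleles_rejected(self, tmp_path):
        universe = make_sites(1)
        other = [Site("1", universe[0].pos, "A", "T")]
        path = tmp_path / "bad.vcf"
        write_vcf(GenotypeMatrix(other, ["X"], np.array([[1]], dtype=np.int8)), path)
        with pytest.raises(gio.InconsistentSiteError):
            merge_single_sample_vcfs([path], universe)


class TestDropSamplesPrunePrivate:
    def test_private_variant_pruned(self):
        g = make_genotypes([[1, 1], [0, 1], [0, 1]])
        out = drop_samples_prune_private(g, {"s0"})
        assert out.samples == ["s1", "s2"]
        assert out.n_sites == 1  # site 0 was private to s0

    def test_empty_drop_is_identity(self):
        g = make_genotypes([[1, 0], [0, 2]])
        out = drop_samples_prune_private(g, set())
        assert out.samples == g.samples
        assert np.array_equal(out.gt, g.gt)

    def test_shared_variant_retained(self):
        g = make_genotypes([[1], [0], [1]])
        out = drop_samples_prune_private(g, {"s0"})
        assert out.n_sites == 1

    def test_unknown_sample_errors(self):
        g = make_genotypes([[1]])
        with pytest.raises(KeyError):
            drop_samples_prune_private(g, {"nope"})


class TestComputeMAF:
    @pytest.mark.parametrize(
        "haps,expected",
        [
            ([[0], [0], [1], [1]], 0.5),
            ([[0], [0], [0], [0]], 0.0),
        ],
    )
    def test_haplotype_examples(self, haps, expected):
        assert compute_maf(make_haps(haps))[0] == pytest.approx(expected)

    def test_diploid_direct_count(self):
        # 5 diploids, one het: p = 1/10
        g = make_genotypes([[0], [0], [0], [0], [1]])
        assert compute_maf(g)[0] == pytest.approx(0.1)

    def test_missing_excluded_from_denominator(self):
        g = make_genotypes([[1], [0], [gio.MISSING]])
        assert compute_maf(g)[0] == pytest.approx(0.25)

    def test_all_missing_policy(self):
        g = make_genotypes([[gio.MISSING], [gio.MISSING]])
        with pytest.raises(gio.UndefinedMAFError):
            compute_maf(g)
        assert np.isnan(compute_maf(g, on_all_missing="nan")[0])

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_allele_swap_and_reorder_invariance(self, gts):
        g = make_genotypes([[v] for v in gts])
        base = compute_maf(g)[0]
        flipped = make_genotypes([[2 - v] for v in gts])
        assert compute_maf(flipped)[0] == pytest.approx(base)
        perm = make_genotypes([[v] for v in reversed(gts)])
        assert compute_maf(perm)[0] == pytest.approx(base)


class TestFilterSites:
    def test_reason_precedence_and_partition(self):
        h = make_haps(np.tile([[0], [1]], (1, 5)).reshape(2, 5) * 0 + np.array(
            [[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], dtype=np.uint8))
        ann = ann_table(
            h.sites,
            maf=[0.3, 0.009, 0.3, 0.3, 0.3],
            design=[0.49, 0.49, 0.9, 0.9, 0.9],
            scaffold=[True, False, False, False, False],
        )
        rules = FilterRules(
            maf_min=0.01,
            design_min=0.5,
            exclude_scaffold=True,
            exclude_ids=frozenset([h.sites[3].id]),
        )
        kept, reasons = filter_sites(h, ann, rules)
        assert reasons[h.sites[0].id] == "scaffold"  # scaffold outranks design score
        assert reasons[h.sites[1].id] == "design_score"  # design outranks MAF
        assert reasons[h.sites[3].id] == "excluded"
        assert kept.n_sites + len(reasons) == h.n_sites
        assert set(kept.site_ids).isdisjoint(reasons)

    def test_design_score_floor(self):
        h = make_haps([[0], [1]])
        ann = ann_table(h.sites, maf=0.3, design=0.49)
        _, reasons = filter_sites(h, ann, FilterRules(maf_min=0.01, design_min=0.5))
        assert reasons == {h.sites[0].id: "design_score"}

    def test_maf_cutoff(self):
        h = make_haps([[0], [1]])
        ann = ann_table(h.sites, maf=0.009)
        _, reasons = filter_sites(h, ann, FilterRules(maf_min=0.01))
        assert reasons == {h.sites[0].id: "low_maf"}

    def test_all_rules_disabled_identity(self):
        h = make_haps([[0, 1], [1, 0]])
        ann = ann_table(h.sites)
        kept, reasons = filter_sites(h, ann, FilterRules())
        assert kept.site_ids == h.site_ids
        assert reasons == {}

    def test_missing_annotation_errors(self):
        h = make_haps([[0], [1]])
        ann = ann_table(make_sites(1, start=999))
        with pytest.raises(gio.MissingAnnotationError):
            filter_sites(h, ann, FilterRules(maf_min=0.01))
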