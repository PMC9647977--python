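"""VCF reading, polarization, site/genotype filters, annotations."""

import numpy as np
import pandas as pd
import pytest

from bottleload import (FilterSpec, annotate_sites, apply_site_filters,
                        load_annotations, polarize_to_ancestral, read_vcf,
                        restrict_complete_cases, write_vcf)
from bottleload.callset import MISSING, CallsetError, impact_from_ann

from conftest import make_callset


# -- reading -----------------------------------------------------------------

def test_read_vcf_parses_biallelic_snps(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    # 8 records: 1 indel + 1 triallelic skipped -> 6 SNP sites
    assert cs.n_sites == 6
    assert cs.provenance["records_skipped_non_biallelic_snp"] == 2
    assert list(cs.sites["pos"]) == [100, 200, 303, 500, 150, 250]
    np.testing.assert_array_equal(cs.G[0], [1, 2])       # 0/1, 1/1 vs ALT
    assert cs.G[3, 0] == MISSING                          # ./. genotype
    assert "chr1" in cs.vcf_fields.indels
    cs.validate()


def test_read_vcf_unknown_sample_errors(toy_vcf):
    with pytest.raises(CallsetError, match="s2"):
        read_vcf(toy_vcf, {"s1": "popA"})


def test_vcf_roundtrip(tmp_path, toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    out = tmp_path / "rt.vcf"
    write_vcf(cs, out)
    again = read_vcf(out, toy_pops)
    pd.testing.assert_frame_equal(cs.sites, again.sites)
    np.testing.assert_array_equal(cs.G, again.G)


# -- polarization ------------------------------------------------------------

def test_polarize_keeps_flips_and_drops():
    cs = make_callset("chr1", [10, 20, 30], [[0, 1], [2, 0], [1, 1]],
                      ref=["A", "C", "G"], alt=["G", "T", "A"], polarized=False)
    og = {("chr1", 10): "A",   # ancestral = REF: unchanged
          ("chr1", 20): "T",   # ancestral = ALT: flip, d -> 2-d
          ("chr1", 30): "C"}   # matches neither: dropped
    out = polarize_to_ancestral(cs, og)
    assert out.n_sites == 2
    assert out.provenance["polarize_dropped"] == 1
    np.testing.assert_array_equal(out.G, [[0, 1], [0, 2]])
    assert list(out.sites["ref"]) == ["A", "T"]
    assert list(out.sites["alt"]) == ["G", "C"]


def test_polarize_flip_preserves_missing():
    cs = make_callset("chr1", [10], [[MISSING, 2]], ref=["A"], alt=["G"],
                      polarized=False)
    out = polarize_to_ancestral(cs, {("chr1", 10): "G"})
    np.testing.assert_array_equal(out.G, [[MISSING, 0]])


def test_polarize_involution_on_dosages():
    """Flipping the ancestral assignment twice returns the original dosages."""
    rng = np.random.default_rng(0)
    G = rng.integers(-1, 3, size=(30, 6)).astype(np.int8)
    pos = np.arange(1, 31) * 10
    cs = make_callset("chr1", pos, G, ref=["A"] * 30, alt=["G"] * 30, polarized=False)
    once = polarize_to_ancestral(cs, {("chr1", int(p)): "G" for p in pos})
    assert list(once.sites["alt"]) == ["A"] * 30  # alleles swapped
    twice = polarize_to_ancestral(once, {("chr1", int(p)): "A" for p in pos})
    np.testing.assert_array_equal(twice.G, cs.G)


def test_polarize_from_info_aa(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    out = polarize_to_ancestral(cs, "AA")
    # chr2:150 has AA=T matching neither allele -> dropped
    assert out.n_sites == 5
    # chr1:200 AA=T equals ALT: dosages flip (0/0, 0/1) -> (2, 1)
    row = out.sites.index[(out.sites["chrom"] == "chr1") & (out.sites["pos"] == 200)][0]
    np.testing.assert_array_equal(out.G[row], [2, 1])


# -- filters -----------------------------------------------------------------

def test_qual_filter_removes_low_quality(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    out = apply_site_filters(cs, FilterSpec(min_qual=30, min_depth_frac=None,
                                            max_depth_mult=None, indel_pad_bp=0,
                                            ab_low=None))
    assert 200 not in list(out.sites["pos"])  # QUAL 25 < 30
    assert out.provenance["dropped_qual"] == 1


def test_indel_proximity_filter(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    out = apply_site_filters(cs, FilterSpec(min_qual=None, min_depth_frac=None,
                                            max_depth_mult=None, indel_pad_bp=5,
                                            ab_low=None))
    # SNP at 303 is 3 bp from the indel at 300 -> removed
    assert 303 not in list(out.sites["pos"])
    assert out.provenance["dropped_indel_pad"] == 1


def test_allelic_balance_masks_het_genotypes(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    out = apply_site_filters(cs, FilterSpec(min_qual=None, min_depth_frac=None,
                                            max_depth_mult=None, indel_pad_bp=0))
    # chr2:250 s1 is het with AB = 3/20 = 0.15 < 0.2 -> missing
    i = out.sites.index[(out.sites["chrom"] == "chr2") & (out.sites["pos"] == 250)][0]
    assert out.G[i, 0] == MISSING
    # chr1:500 s2 het AB = 4/20 = 0.2 -> boundary excluded -> missing
    j = out.sites.index[(out.sites["chrom"] == "chr1") & (out.sites["pos"] == 500)][0]
    assert out.G[j, 1] == MISSING
    assert out.provenance["genotypes_masked_balance"] == 2


def test_depth_filter_masks_per_genotype():
    cs = make_callset("chr1", [10, 20, 30], [[1, 1], [1, 1], [1, 1]], polarized=False)
    from bottleload.callset import VcfFields

    depth = np.array([[20.0, 20.0], [2.0, 20.0], [20.0, 100.0]])
    cs.vcf_fields = VcfFields(qual=np.full(3, 60.0), depth=depth,
                              ref_depth=np.full((3, 2), 10.0))
    out = apply_site_filters(cs, FilterSpec(min_qual=None, indel_pad_bp=0, ab_low=None))
    # sample means: 14, ~46.7; site2 s1 below mean/3, site3 s2 above 2x mean
    assert out.G[1, 0] == MISSING
    assert out.G[2, 1] == MISSING
    assert out.n_sites == 3  # depth masking never deletes whole sites


def test_mask_bed_and_scaffold_exclusion():
    cs = make_callset(["chr1", "chr1", "chrZ"], [100, 250, 50],
                      [[1, 1], [1, 1], [1, 1]], polarized=False)
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [199], "end": [250]})  # 0-based
    out = apply_site_filters(cs, FilterSpec(min_qual=None, min_depth_frac=None,
                                            max_depth_mult=None, indel_pad_bp=0,
                                            ab_low=None, mask_beds=[bed],
                                            excluded_scaffolds=["chrZ"]))
    assert list(out.sites["pos"]) == [100]
    assert out.provenance["dropped_mask"] == 1
    assert out.provenance["dropped_scaffold"] == 1


def test_filtering_is_idempotent(toy_vcf, toy_pops):
    cs = read_vcf(toy_vcf, toy_pops)
    spec = FilterSpec(min_qual=30, min_depth_frac=None, max_depth_mult=None)
    once = apply_site_filters(cs, spec)
    twice = apply_site_filters(once, spec)
    pd.testing.assert_frame_equal(once.sites, twice.sites)
    np.testing.assert_array_equal(once.G, twice.G)


def test_enabled_filter_without_field_errors():
    cs = make_callset("chr1", [10], [[1, 1]], polarized=False)
    with pytest.raises(CallsetError, match="QUAL"):
        apply_site_filters(cs, FilterSpec(min_qual=30, min_depth_frac=None,
                                          max_depth_mult=None, ab_low=None))


# -- complete cases ----------------------------------------------------------

def test_restrict_complete_cases():
    cs = make_callset("chr1", [10, 20, 30],
                      [[0, 1], [MISSING, 2], [1, 0]])
    out = restrict_complete_cases(cs)
    assert list(out.sites["pos"]) == [10, 30]
    assert (out.G != MISSING).all()
    assert out.provenance["dropped_incomplete"] == 1
    # no missing anywhere -> identity
    again = restrict_complete_cases(out)
    pd.testing.assert_frame_equal(out.sites, again.sites)


def test_restrict_complete_cases_all_missing_warns():
    cs = make_callset("chr1", [10], [[MISSING, 1]])
    out = restrict_complete_cases(cs)
    assert out.n_sites == 0


# -- annotations -------------------------------------------------------------

def test_load_annotations_and_alignment(tmp_path):
    gerp = tmp_path / "gerp.tsv"
    gerp.write_text("#chrom\tpos\tgerp\nchr1\t100\t6.1\nchr1\t200\t0.5\n")
    impact = tmp_path / "impact.tsv"
    impact.write_text("#chrom\tpos\timpact\nchr1\t100\tHIGH\nchr1\t300\tMODERATE\n")
    ann = load_annotations(gerp, impact)
    assert ann.loc[("chr1", 100), "gerp"] == 6.1
    assert ann.loc[("chr1", 100), "impact"] == "HIGH"

    cs = make_callset("chr1", [100, 200, 250], np.ones((3, 2)))
    aligned = annotate_sites(cs, ann)
    assert list(aligned["annotated"]) == [True, True, False]  # 250 unannotated


def test_duplicate_annotation_rows_error(tmp_path):
    gerp = tmp_path / "gerp.tsv"
    gerp.write_text("#chrom\tpos\tgerp\nchr1\t100\t6.1\nchr1\t100\t2.0\n")
    with pytest.raises(CallsetError, match="duplicate"):
        load_annotations(gerp_source=gerp)


def test_impact_from_ann_field():
    ann = "G|missense_variant|MODERATE|GENE1|g1|transcript|t1|protein_coding"
    assert impact_from_ann(ann) == "MODERATE"
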