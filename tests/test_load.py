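"""GERP binning, relative load, total and realised coding load."""

import numpy as np
import pytest

from bottleload import (GerpBins, gerp_category, load_summary, realised_load,
                        relative_load_gerp, total_load, zygosity_counts)
from bottleload.callset import MISSING
from bottleload.load import UNSCORED, gerp_site_mask, segregating_sites

from conftest import make_callset


# -- binning -----------------------------------------------------------------

@pytest.mark.parametrize("score,expected", [
    (6.5, ">5.88"),      # top-percentile category
    (0.5, "0-1"),        # low scores treated as neutral
    (3.0, "3-5"),        # lower edge inclusive under [lo, hi)
    (2.999, "1-3"),
    (5.2, ">5"),
    (-0.5, UNSCORED),    # negative scores excluded from load
])
def test_gerp_category_assignment(score, expected):
    assert gerp_category(score) == expected


def test_gerp_bins_validation():
    with pytest.raises(ValueError):
        GerpBins(edges=(0, 3, 1))
    with pytest.raises(ValueError):
        GerpBins(edges=(0, 1, 3, 5), top=4.0)


def test_top_bin_is_subset_of_open_bin():
    scores = np.array([4.0, 5.0, 5.5, 5.88, 6.0, 7.5])
    top = gerp_site_mask(scores, ">5.88")
    open_bin = gerp_site_mask(scores, ">5")
    assert (open_bin | top == open_bin).all()
    assert top.sum() == 2 and open_bin.sum() == 5


# -- relative load -----------------------------------------------------------

def test_relative_load_hand_values():
    # het at score 6.0, hom at 7.0 -> (6 + 14) / 3
    cs = make_callset("chr1", [10, 20], [[1], [2]])
    scores = np.array([6.0, 7.0])
    assert relative_load_gerp(cs, "s0", scores) == pytest.approx(20.0 / 3.0)
    # all-homozygous sample: weighting collapses to the mean score
    cs2 = make_callset("chr1", [10, 20], [[2], [2]])
    assert relative_load_gerp(cs2, "s0", np.array([6.0, 8.0])) == pytest.approx(7.0)


def test_relative_load_undefined_without_derived_alleles():
    cs = make_callset("chr1", [10, 20], [[0], [0]])
    assert np.isnan(relative_load_gerp(cs, "s0", np.array([6.0, 7.0])))


def test_relative_load_excludes_negative_scores():
    cs = make_callset("chr1", [10, 20], [[2], [2]])
    assert relative_load_gerp(cs, "s0", np.array([-1.0, 4.0])) == pytest.approx(4.0)


def test_relative_load_chromosome_split_recombines():
    """Whole-callset value equals the dosage-weighted mean of per-chromosome values."""
    rng = np.random.default_rng(5)
    G = rng.integers(0, 3, size=(40, 1)).astype(np.int8)
    chroms = ["chr1"] * 20 + ["chr2"] * 20
    pos = np.concatenate([np.arange(1, 21) * 100, np.arange(1, 21) * 100])
    scores = rng.uniform(0, 8, size=40)
    cs = make_callset(chroms, pos, G)
    full = relative_load_gerp(cs, "s0", scores)
    parts = []
    for lo, hi in [(0, 20), (20, 40)]:
        sub = make_callset(["chr1"] * 20, pos[lo:hi], G[lo:hi])
        num = relative_load_gerp(sub, "s0", scores[lo:hi])
        den = float(G[lo:hi][scores[lo:hi] >= 0].sum())
        parts.append((num, den))
    recombined = sum(n * d for n, d in parts) / sum(d for _, d in parts)
    assert full == pytest.approx(recombined, rel=1e-12)


def test_derived_allele_counts_sum_over_bins():
    """Summing binned derived-allele counts over all GERP bins (top excluded:
    it nests inside >5) recovers the unbinned count for scores >= 0."""
    rng = np.random.default_rng(6)
    G = rng.integers(0, 3, size=(120, 2)).astype(np.int8)
    scores = rng.uniform(-2, 9, size=120)
    cs = make_callset("chr1", np.arange(1, 121) * 50, G)
    bins = GerpBins()
    exclusive = bins.interior_labels + [bins.open_label]
    for sample in cs.samples:
        total = 0
        for cat in exclusive:
            n_het, n_hom = zygosity_counts(cs, sample, gerp_site_mask(scores, cat))
            total += n_het + 2 * n_hom
        d = G[:, cs.sample_index(sample)].astype(int)
        assert total == d[scores >= 0].sum()


# -- coding load -------------------------------------------------------------

def _impact_callset():
    impact = np.array(["HIGH"] * 5 + ["MODERATE"] * 3 + ["LOW"] * 2, dtype=object)
    G = np.array([[1], [1], [1], [2], [2],     # HIGH: 3 het + 2 hom
                  [0], [1], [2],               # MODERATE
                  [0], [0]], dtype=np.int8)
    cs = make_callset("chr1", np.arange(1, 11) * 100, G)
    return cs, impact


def test_total_load_sites_and_alleles():
    cs, impact = _impact_callset()
    assert total_load(cs, "s0", impact, "HIGH", mode="sites") == 5
    assert total_load(cs, "s0", impact, "HIGH", mode="alleles") == 7
    assert total_load(cs, "s0", impact, "LOW") == 0
    with pytest.raises(ValueError):
        total_load(cs, "s0", impact, "BOGUS")


def test_realised_load_hand_values():
    # 5 hom of 10 segregating HIGH sites -> 5/20 = 0.25
    impact = np.array(["HIGH"] * 10, dtype=object)
    G = np.zeros((10, 2), dtype=np.int8)
    G[:5, 0] = 2
    G[:, 1] = 1  # keeps every site segregating in the cohort
    cs = make_callset("chr1", np.arange(1, 11) * 100, G)
    assert realised_load(cs, "s0", impact, "HIGH") == pytest.approx(0.25)
    # no homozygotes -> 0
    assert realised_load(cs, "s1", impact, "HIGH") == 0.0
    # all sites homozygous -> the attainable maximum 0.5
    G2 = np.full((10, 2), 1, dtype=np.int8)
    G2[:, 0] = 2
    cs2 = make_callset("chr1", np.arange(1, 11) * 100, G2)
    assert realised_load(cs2, "s0", impact, "HIGH") == pytest.approx(0.5)


def test_realised_load_undefined_without_segregating_sites():
    impact = np.array(["HIGH"], dtype=object)
    cs = make_callset("chr1", [100], [[2, 2]])  # fixed derived: not segregating
    assert segregating_sites(cs, impact, "HIGH") == 0
    assert np.isnan(realised_load(cs, "s0", impact, "HIGH"))


def test_realised_load_never_exceeds_half_randomized():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n_sites = int(rng.integers(2, 40))
        n_samples = int(rng.integers(2, 8))
        G = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
        impact = rng.choice(["HIGH", "MODERATE", "LOW"], size=n_sites).astype(object)
        cs = make_callset("chr1", np.arange(1, n_sites + 1) * 10, G)
        for cat in ("HIGH", "MODERATE"):
            for s in cs.samples:
                r = realised_load(cs, s, impact, cat)
                assert np.isnan(r) or 0.0 <= r <= 0.5
                t = total_load(cs, s, impact, cat, "sites")
                seg = segregating_sites(cs, impact, cat)
                if not np.isnan(r) and seg:
                    assert r <= t / (2 * seg) + 1e-12


def test_zygosity_counts_recount_oracle():
    rng = np.random.default_rng(8)
    G = rng.integers(0, 3, size=(60, 3)).astype(np.int8)
    mask = rng.random(60) < 0.5
    cs = make_callset("chr1", np.arange(1, 61) * 10, G)
    for s in cs.samples:
        n_het, n_hom = zygosity_counts(cs, s, mask)
        j = cs.sample_index(s)
        want_het = sum(1 for i in range(60) if mask[i] and G[i, j] == 1)
        want_hom = sum(1 for i in range(60) if mask[i] and G[i, j] == 2)
        assert (n_het, n_hom) == (want_het, want_hom)
        assert n_het + 2 * n_hom == sum(int(G[i, j]) for i in range(60) if mask[i])


def test_zygosity_counts_simple_cases():
    cs = make_callset("chr1", [10, 20, 30, 40], [[0], [1], [1], [2]])
    assert zygosity_counts(cs, "s0", np.ones(4, bool)) == (2, 1)
    assert zygosity_counts(cs, "s0", np.zeros(4, bool)) == (0, 0)


def test_load_summary_table(small_cohort):
    from bottleload import annotate_sites, load_annotations

    _, callset, ann_table, _ = small_cohort
    ann = annotate_sites(callset, load_annotations(
        gerp_source=ann_table[["chrom", "pos", "gerp"]],
        impact_source=ann_table[["chrom", "pos", "impact"]]))
    summary = load_summary(callset, ann)
    assert set(summary["kind"]) == {"gerp", "impact"}
    assert (summary["n_derived_alleles"]
            == summary["n_het"] + 2 * summary["n_hom"]).all()
    imp = summary[summary["kind"] == "impact"]
    ok = imp["realised_load"].dropna()
    assert ((ok >= 0) & (ok <= 0.5)).all()
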