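"""Independent brute-force oracles used by the test suite.

These deliberately use plain Python loops and direct rule application so that
they share no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations


def roh_segments_oracle(pos, dosage, p):
    """Direct enumeration of ROH segments from the window rules.

    Returns a list of (start_bp, end_bp, n_snps, n_het) tuples.  ``p`` is an
    ROHParams-like object.  Rules, applied literally: a window of
    ``window_snp`` consecutive SNPs is homozygous when it has <= window_het
    het and <= window_missing missing calls; a SNP is eligible when the
    fraction of full windows containing it that are homozygous is >=
    window_threshold (no full window -> ineligible); eligible runs are split
    at gaps > gap_kb; candidate runs must pass min_snp, min_kb, density and
    het-count constraints.
    """
    n = len(pos)
    het = [d == 1 for d in dosage]
    miss = [d == -1 for d in dosage]
    w = p.window_snp

    hom_win = []
    for k in range(n - w + 1):
        hom_win.append(sum(het[k:k + w]) <= p.window_het
                       and sum(miss[k:k + w]) <= p.window_missing)

    eligible = []
    for i in range(n):
        ks = range(max(0, i - w + 1), min(i, n - w) + 1)
        total = len(ks)
        if total <= 0:
            eligible.append(False)
            continue
        frac = sum(1 for k in ks if hom_win[k]) / total
        eligible.append(frac >= p.window_threshold)

    runs = []
    cur = None
    for i in range(n):
        if eligible[i]:
            if cur is None:
                cur = [i, i]
            elif pos[i] - pos[i - 1] > p.gap_kb * 1000:
                runs.append(cur)
                cur = [i, i]
            else:
                cur[1] = i
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)

    segments = []
    for i0, i1 in runs:
        n_snps = i1 - i0 + 1
        span = pos[i1] - pos[i0] + 1
        n_het = sum(1 for i in range(i0, i1 + 1) if het[i])
        if n_snps < p.min_snp:
            continue
        if span < p.min_kb * 1000:
            continue
        if span > p.density_kb * 1000 * n_snps:
            continue
        if n_het > p.max_het_in_segment:
            continue
        segments.append((int(pos[i0]), int(pos[i1]), n_snps, n_het))
    return segments


def mean_pairwise_diff_oracle(genotypes):
    """Average per-site pairwise haplotype difference by full enumeration.

    ``genotypes`` is a per-site list of dosages (0/1/2, -1 missing).  Each
    diploid genotype expands to two haplotypes (0/1 split arbitrarily for
    dosage 1 — only allele counts matter for differences).  Returns the sum
    over sites of the mean pairwise difference among non-missing haplotypes.
    """
    total = 0.0
    for site in genotypes:
        haps = []
        for d in site:
            if d == -1:
                continue
            haps.extend([1, 1] if d == 2 else ([0, 1] if d == 1 else [0, 0]))
        if len(haps) < 2:
            continue
        pairs = list(combinations(range(len(haps)), 2))
        diffs = sum(1 for i, j in pairs if haps[i] != haps[j])
        total += diffs / len(pairs)
    return total
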