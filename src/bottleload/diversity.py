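"""Per-individual heterozygosity, windowed nucleotide diversity, Tukey HSD.

Heterozygosity is reported as heterozygous sites per 1,000 callable bp,
counted directly from filtered genotypes.  Nucleotide diversity (pi) is the
mean pairwise difference per bp in non-overlapping 10-kb windows by default,
with the standard small-sample correction n/(n-1) applied per site.  Group
contrasts (historical vs modern populations) use Tukey's honestly-significant
-difference test on per-sample statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset


def het_per_kb(callset: CohortCallset, sample: str | None = None,
               callable_bp: float | None = None):
    """Heterozygous sites per 1,000 callable bp.

    ``callable_bp`` defaults to the per-sample value stored on the callset,
    or, failing that, to the number of callset sites (useful for synthetic
    data without a per-base coverage model).  Returns a float for one sample
    or a Series over all samples.
    """
    if sample is None:
        return pd.Series(
            {s: het_per_kb(callset, s, callable_bp) for s in callset.samples},
            name="het_per_kb")
    j = callset.sample_index(sample)
    if callable_bp is None:
        if callset.callable_bp and sample in callset.callable_bp:
            callable_bp = callset.callable_bp[sample]
        else:
            callable_bp = callset.n_sites
    if callable_bp is None or callable_bp <= 0:
        raise ValueError(f"callable_bp must be > 0 for sample {sample!r}")
    n_het = int((callset.G[:, j] == 1).sum())
    return n_het / callable_bp * 1000.0


def pi_windows(callset: CohortCallset, window_bp: int = 10_000,
               step_bp: int | None = None, per_population: bool = True) -> pd.DataFrame:
    """Windowed nucleotide diversity.

    Per window, pi = sum over sites of 2*p*(1-p) * n/(n-1) divided by
    ``window_bp``, where n is the number of non-missing haplotypes at the
    site and p the derived (ALT) allele frequency.  Windows tile each
    chromosome from position 1 to the last variant; with the default
    ``step_bp = window_bp`` they are non-overlapping.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step_bp = step_bp or window_bp
    groups = callset.pop_names() if per_population else [None]
    rows = []
    for chrom, block in callset.chrom_blocks():
        pos = callset.sites["pos"].to_numpy()[block]
        last = int(pos.max())
        for grp in groups:
            cols = callset.pop_index(grp) if grp else np.arange(callset.n_samples)
            g = callset.G[np.ix_(block, cols)]
            called = g != MISSING
            n = 2 * called.sum(axis=1)
            d = np.where(called, g, 0).sum(axis=1)
            ok = n >= 2
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(ok, d / np.maximum(n, 1), 0.0)
                site_pi = np.where(ok, 2.0 * p * (1 - p) * n / np.maximum(n - 1, 1), 0.0)
            start = 1
            while start <= last:
                end = start + window_bp - 1
                in_win = (pos >= start) & (pos <= end)
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "population": grp if grp else "all",
                             "pi": float(site_pi[in_win].sum()) / window_bp})
                start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "population", "pi"])


def pairwise_group_test(values, groups) -> pd.DataFrame:
    """Tukey HSD over all group pairs of a per-sample statistic.

    Returns one row per pair with the mean difference and the adjusted
    p-value from the studentized-range distribution.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    small = [str(l) for l, c in zip(labels, counts) if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 values: {small}")
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, groups)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": res.meandiffs,
        "p_adj": res.pvalues,
        "lower": res.confint[:, 0],
        "upper": res.confint[:, 1],
        "reject": res.reject,
    })
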