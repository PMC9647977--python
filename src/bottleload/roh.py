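"""Runs of homozygosity (ROH) by the PLINK-style sliding-window scan, and F_ROH.

The detector scores every window of ``window_snp`` consecutive SNPs as
homozygous when it contains at most ``window_het`` heterozygous and
``window_missing`` missing calls; a SNP is ROH-eligible when at least
``window_threshold`` of the windows containing it are homozygous; maximal
runs of eligible SNPs are split at inter-SNP gaps above ``gap_kb`` and kept
when they satisfy the segment-level constraints (min SNPs, min span, max kb
per SNP, max heterozygous calls).  F_ROH is the fraction of the analysed
autosomal genome covered by segments above a length threshold — a genomic
inbreeding coefficient.

Window-edge dialect: only full windows of ``window_snp`` SNPs are scored; at
chromosome ends a SNP's eligibility fraction is taken over however many full
windows actually contain it, and chromosomes shorter than one window yield no
eligible SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset

SEGMENT_COLUMNS = ("sample", "chrom", "start_bp", "end_bp", "length_bp", "n_snps", "n_het")


@dataclass(frozen=True)
class ROHParams:
    window_snp: int = 500
    window_het: int = 5
    window_missing: int = 0
    window_threshold: float = 0.05
    min_snp: int = 25
    min_kb: float = 100.0
    density_kb: float = 50.0
    gap_kb: float = 1000.0
    max_het_in_segment: int = 750

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp) < 1 or self.window_het < 0 \
                or self.window_missing < 0 or self.max_het_in_segment < 0:
            raise ValueError("ROH window/segment counts out of range")
        if not (0.0 < self.window_threshold <= 1.0):
            raise ValueError("window_threshold must be in (0, 1]")
        if min(self.min_kb, self.density_kb, self.gap_kb) <= 0:
            raise ValueError("min_kb, density_kb and gap_kb must be > 0")


#: The three published parameter sets plus a desk-scale preset for small
#: synthetic cohorts (sparser maps than a real 1-Gb genome).
PRESETS: dict[str, ROHParams] = {
    "window100": ROHParams(window_snp=100, window_het=1),
    "window250": ROHParams(window_snp=250, window_het=3),
    "main": ROHParams(window_snp=500, window_het=5),
    "desk": ROHParams(window_snp=25, window_het=1, min_snp=15, min_kb=10.0,
                      density_kb=50.0, gap_kb=1000.0, max_het_in_segment=3),
}


def detect_roh(callset: CohortCallset, sample: str, params: ROHParams) -> pd.DataFrame:
    """ROH segments for one sample; one row per segment, sorted by position."""
    j = callset.sample_index(sample)
    callset.validate()
    rows = []
    for chrom, block in callset.chrom_blocks():
        pos = callset.sites["pos"].to_numpy()[block]
        d = callset.G[block, j]
        het = d == 1
        miss = d == MISSING
        eligible = _eligible_snps(het, miss, params)
        for i0, i1 in _runs(eligible, pos, params.gap_kb * 1000.0):
            n_snps = i1 - i0 + 1
            span = int(pos[i1] - pos[i0] + 1)
            n_het = int(het[i0:i1 + 1].sum())
            if n_snps < params.min_snp or span < params.min_kb * 1000.0:
                continue
            if span > params.density_kb * 1000.0 * n_snps:
                continue
            if n_het > params.max_het_in_segment:
                continue
            rows.append({"sample": sample, "chrom": chrom, "start_bp": int(pos[i0]),
                         "end_bp": int(pos[i1]), "length_bp": span,
                         "n_snps": n_snps, "n_het": n_het})
    return pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS))


def _eligible_snps(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    n = len(het)
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    hom_win = ((ch[w:] - ch[:-w]) <= params.window_het) \
        & ((cm[w:] - cm[:-w]) <= params.window_missing)       # window k covers SNPs k..k+w-1
    cw = np.concatenate([[0], np.cumsum(hom_win)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    n_windows = hi - lo + 1
    n_hom = cw[hi + 1] - cw[lo]
    return n_hom / n_windows >= params.window_threshold


def _runs(eligible: np.ndarray, pos: np.ndarray, gap_bp: float):
    """Maximal runs of eligible SNPs, split at inter-SNP gaps above gap_bp."""
    out = []
    start = None
    for i, e in enumerate(eligible):
        if e and start is None:
            start = i
        elif e and pos[i] - pos[i - 1] > gap_bp:
            out.append((start, i - 1))
            start = i
        elif not e and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(eligible) - 1))
    return out


def detect_roh_all(callset: CohortCallset, params: ROHParams) -> pd.DataFrame:
    return pd.concat([detect_roh(callset, s, params) for s in callset.samples],
                     ignore_index=True)


def compute_froh(segments: pd.DataFrame, genome_bp: float,
                 min_length_bp: float = 100_000.0) -> float:
    """Fraction of the genome in ROH at least ``min_length_bp`` long."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    if len(segments) == 0:
        return 0.0
    lengths = segments["length_bp"].to_numpy()
    return float(lengths[lengths >= min_length_bp].sum() / genome_bp)


def froh_table(callset: CohortCallset, params: ROHParams, genome_bp: float,
               min_lengths_bp=(100_000.0, 2_000_000.0)) -> pd.DataFrame:
    """Per-sample F_ROH at each length threshold (default 100 kb and 2 Mb)."""
    rows = []
    for s in callset.samples:
        segs = detect_roh(callset, s, params)
        row = {"sample": s, "population": callset.populations[s],
               "n_segments": len(segs)}
        for m in min_lengths_bp:
            label = f"froh_{_fmt_bp(m)}"
            row[label] = compute_froh(segs, genome_bp, m)
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt_bp(bp: float) -> str:
    if bp >= 1_000_000 and bp % 1_000_000 == 0:
        return f"{int(bp // 1_000_000)}mb"
    if bp >= 1_000 and bp % 1_000 == 0:
        return f"{int(bp // 1_000)}kb"
    return f"{int(bp)}bp"


def roh_spectrum(segments: pd.DataFrame, bin_edges_bp) -> pd.DataFrame:
    """Histogram of segment lengths over half-open bins [lo, hi)."""
    edges = np.asarray(bin_edges_bp, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = segments["length_bp"].to_numpy() if len(segments) else np.empty(0)
    k = np.digitize(lengths, edges, right=False) - 1  # value == edge -> upper bin
    counts = [int(((k == b) & (lengths < edges[b + 1])).sum())
              for b in range(len(edges) - 1)]
    return pd.DataFrame({"lo_bp": edges[:-1], "hi_bp": edges[1:], "count": counts})
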