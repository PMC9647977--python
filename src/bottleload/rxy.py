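"""The R_xy derived-allele frequency-ratio statistic and variant sharing.

For a category C of sites and populations x and y with per-site derived
frequencies f_x and f_y:

    Freq_x(C) = sum over i in C of f_x[i] * (1 - f_y[i])
    Freq_y(C) = sum over i in C of f_y[i] * (1 - f_x[i])
    R_xy      = Freq_x(C) / Freq_y(C)

R_xy = 1 means no net frequency change between the populations; R_xy < 1
means the category's derived alleles are relatively rarer in x than in y
(e.g. purging in x when x descends from y).  Uncertainty is assessed with a
delete-one jack-knife across chromosomes, which are exchangeable units under
free interchromosomal assortment.

Site inclusion (default rule "pooled"): a site enters the sum when the
pooled x+y sample carries at least one derived allele.  The stricter rule
"each" (>= 1 derived allele in each population separately) is available but
excludes population-unique variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset import CohortCallset


@dataclass
class FreqTable:
    """Per-site derived-allele counts d and called-allele totals n per population."""

    sites: pd.DataFrame                 # chrom, pos (+ optional category column)
    d: dict[str, np.ndarray]
    n: dict[str, np.ndarray]

    @classmethod
    def from_callset(cls, callset: CohortCallset, categories=None) -> "FreqTable":
        """Build from a (polarized) callset; ``categories`` is an optional
        per-site label array (e.g. impact) stored as a 'category' column."""
        sites = callset.sites[["chrom", "pos"]].copy()
        if categories is not None:
            sites["category"] = np.asarray(categories, dtype=object)
        d, n = {}, {}
        for pop in callset.pop_names():
            d[pop], n[pop] = callset.derived_counts(pop)
        return cls(sites=sites, d=d, n=n)

    def __post_init__(self) -> None:
        for pop in self.d:
            if np.any(self.d[pop] > self.n[pop]) or np.any(self.d[pop] < 0):
                raise ValueError(f"invalid counts for population {pop!r}")

    def freq(self, pop: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.d[pop] / self.n[pop]
        return f

    def category_mask(self, category) -> np.ndarray:
        if category is None:
            return np.ones(len(self.sites), dtype=bool)
        if "category" not in self.sites.columns:
            raise ValueError("FreqTable has no category column")
        return (self.sites["category"].to_numpy() == category)


@dataclass
class RxySummary:
    pop_x: str
    pop_y: str
    category: object
    n_sites: int
    freq_x: float
    freq_y: float
    rxy: float
    chromosomes: list = field(default_factory=list)
    loo: np.ndarray | None = None           # leave-one-chromosome-out estimates
    pseudo: np.ndarray | None = None        # jack-knife pseudo-values
    jackknife_mean: float | None = None
    jackknife_se: float | None = None


def _included(freqs: FreqTable, pop_x: str, pop_y: str, category, site_rule: str) -> np.ndarray:
    mask = freqs.category_mask(category)
    mask &= (freqs.n[pop_x] > 0) & (freqs.n[pop_y] > 0)
    if site_rule == "pooled":
        mask &= (freqs.d[pop_x] + freqs.d[pop_y]) >= 1
    elif site_rule == "each":
        mask &= (freqs.d[pop_x] >= 1) & (freqs.d[pop_y] >= 1)
    else:
        raise ValueError("site_rule must be 'pooled' or 'each'")
    return mask


def _sums(freqs: FreqTable, pop_x: str, pop_y: str, mask: np.ndarray) -> tuple[float, float]:
    fx = freqs.freq(pop_x)[mask]
    fy = freqs.freq(pop_y)[mask]
    return float((fx * (1 - fy)).sum()), float((fy * (1 - fx)).sum())


def _ratio(freq_x: float, freq_y: float) -> float:
    if freq_y == 0.0:
        return float("inf") if freq_x > 0 else float("nan")
    return freq_x / freq_y


def rxy_point(freqs: FreqTable, pop_x: str, pop_y: str, category=None,
              site_rule: str = "pooled") -> RxySummary:
    """All-data point estimate of R_xy (no jack-knife)."""
    mask = _included(freqs, pop_x, pop_y, category, site_rule)
    freq_x, freq_y = _sums(freqs, pop_x, pop_y, mask)
    return RxySummary(pop_x=pop_x, pop_y=pop_y, category=category,
                      n_sites=int(mask.sum()), freq_x=freq_x, freq_y=freq_y,
                      rxy=_ratio(freq_x, freq_y))


def rxy_jackknife(freqs: FreqTable, pop_x: str, pop_y: str, category=None,
                  site_rule: str = "pooled") -> RxySummary:
    """R_xy with delete-one-chromosome jack-knife.

    Pseudo-values are m * R_all - (m-1) * R_(-c) for each of the m
    contributing chromosomes; the jack-knife mean and standard error are
    computed from them.  Chromosomes contributing no included site yield no
    pseudo-value; fewer than two contributing chromosomes is an error.
    """
    mask = _included(freqs, pop_x, pop_y, category, site_rule)
    chroms = freqs.sites["chrom"].to_numpy()
    contributing = list(pd.unique(chroms[mask]))
    if len(contributing) < 2:
        raise ValueError(f"jack-knife needs >= 2 contributing chromosomes, "
                         f"got {len(contributing)}")
    out = rxy_point(freqs, pop_x, pop_y, category, site_rule)
    m = len(contributing)
    loo = np.empty(m)
    for k, c in enumerate(contributing):
        sub = mask & (chroms != c)
        loo[k] = _ratio(*_sums(freqs, pop_x, pop_y, sub))
    pseudo = m * out.rxy - (m - 1) * loo
    out.chromosomes = contributing
    out.loo = loo
    out.pseudo = pseudo
    out.jackknife_mean = float(pseudo.mean())
    out.jackknife_se = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))
    return out


def sharing_summary(freqs: FreqTable, pop_a: str, pop_b: str, category=None) -> dict:
    """Between-population presence/fixation accounting for a site category.

    present = derived frequency > 0; fixed = frequency 1.  ``increased`` /
    ``decreased`` count sites (present in at least one population) whose
    derived frequency is higher / lower in ``pop_b`` than in ``pop_a``.
    """
    mask = freqs.category_mask(category)
    mask &= (freqs.n[pop_a] > 0) & (freqs.n[pop_b] > 0)
    fa = freqs.freq(pop_a)[mask]
    fb = freqs.freq(pop_b)[mask]
    present_a = fa > 0
    present_b = fb > 0
    either = present_a | present_b
    return {
        "total_a": int(present_a.sum()),
        "total_b": int(present_b.sum()),
        "shared": int((present_a & present_b).sum()),
        "unique_a": int((present_a & ~present_b).sum()),
        "unique_b": int((present_b & ~present_a).sum()),
        "fixed_a": int((fa == 1.0).sum()),
        "fixed_b": int((fb == 1.0).sum()),
        "fixed_both": int(((fa == 1.0) & (fb == 1.0)).sum()),
        "increased": int((either & (fb > fa)).sum()),
        "decreased": int((either & (fb < fa)).sum()),
    }
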