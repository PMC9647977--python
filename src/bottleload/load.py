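"""Per-individual mutational-load statistics.

Two families of proxies for genetic load are computed from derived-allele
dosages:

* **GERP-based relative load** — for a conservation-score category, the
  dosage-weighted mean GERP score of an individual's derived alleles
  (heterozygous sites count one allele, homozygous sites two).  Higher values
  mean a larger share of the individual's derived alleles sits at
  evolutionarily constrained sites.
* **Coding load** — for a SnpEff-style impact category, the *total load*
  (number of sites, or alleles, carrying a derived variant) and the
  *realised load* (homozygous derived sites over twice the category's
  segregating sites), the expressed portion of the burden.

Scores below zero are treated as putatively unconstrained and excluded from
all load computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset

IMPACT_CATEGORIES = ("LOW", "MODERATE", "HIGH", "MODIFIER")
UNSCORED = "unscored"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class GerpBins:
    """Conservation-score categories: interior bins [lo, hi), an open top bin,
    and an extra "top percentile" bin that overrides the open bin."""

    edges: tuple = (0.0, 1.0, 3.0, 5.0)
    top: float = 5.88

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.top < self.edges[-1]:
            raise ValueError("top-percentile threshold must be >= the last edge")

    @property
    def interior_labels(self) -> list[str]:
        return [f"{_fmt(lo)}-{_fmt(hi)}" for lo, hi in zip(self.edges, self.edges[1:])]

    @property
    def open_label(self) -> str:
        return f">{_fmt(self.edges[-1])}"

    @property
    def top_label(self) -> str:
        return f">{_fmt(self.top)}"

    @property
    def labels(self) -> list[str]:
        return self.interior_labels + [self.open_label, self.top_label]


DEFAULT_BINS = GerpBins()


def gerp_category(score: float, bins: GerpBins = DEFAULT_BINS) -> str:
    """Exclusive bin label for one score; the top-percentile bin wins over the
    open bin, and negative scores map to "unscored"."""
    if np.isnan(score) or score < bins.edges[0]:
        return UNSCORED
    if score > bins.top:
        return bins.top_label
    if score >= bins.edges[-1]:
        return bins.open_label
    k = int(np.digitize(score, bins.edges)) - 1
    return bins.interior_labels[k]


def gerp_site_mask(scores, category: str, bins: GerpBins = DEFAULT_BINS) -> np.ndarray:
    """Membership mask for a category; the open and top bins overlap
    (">5" contains ">5.88") as in the published category scheme."""
    scores = np.asarray(scores, dtype=float)
    valid = ~np.isnan(scores)
    if category == bins.top_label:
        return valid & (scores > bins.top)
    if category == bins.open_label:
        return valid & (scores >= bins.edges[-1])
    for lo, hi, lab in zip(bins.edges, bins.edges[1:], bins.interior_labels):
        if category == lab:
            return valid & (scores >= lo) & (scores < hi)
    raise ValueError(f"unknown GERP category {category!r}")


def _dosage(callset: CohortCallset, sample: str) -> np.ndarray:
    return callset.G[:, callset.sample_index(sample)]


def relative_load_gerp(callset: CohortCallset, sample: str, scores,
                       category: str | None = None,
                       bins: GerpBins = DEFAULT_BINS) -> float:
    """Dosage-weighted mean conservation score of the sample's derived alleles.

    numerator = sum of GERP scores of derived alleles (x2 at homozygous
    sites); denominator = number of derived alleles (homozygous sites count
    two).  NaN when the sample carries no derived allele in the category.
    """
    scores = np.asarray(scores, dtype=float)
    d = _dosage(callset, sample).astype(float)
    d[d == MISSING] = 0
    mask = ~np.isnan(scores) & (scores >= 0)
    if category is not None:
        mask &= gerp_site_mask(scores, category, bins)
    num = float((scores * d)[mask].sum())
    den = float(d[mask].sum())
    return num / den if den > 0 else float("nan")


def _impact_mask(impact, category: str) -> np.ndarray:
    if category not in IMPACT_CATEGORIES:
        raise ValueError(f"unknown impact category {category!r}; "
                         f"expected one of {IMPACT_CATEGORIES}")
    return np.asarray([str(i).upper() == category for i in impact])


def total_load(callset: CohortCallset, sample: str, impact, category: str,
               mode: str = "sites") -> int:
    """Burden of derived variants in an impact category, regardless of zygosity.

    ``mode="sites"`` counts sites with dosage > 0; ``mode="alleles"`` sums
    dosages.
    """
    if mode not in ("sites", "alleles"):
        raise ValueError("mode must be 'sites' or 'alleles'")
    mask = _impact_mask(impact, category)
    d = _dosage(callset, sample)
    d = np.where(d == MISSING, 0, d)[mask]
    return int((d > 0).sum()) if mode == "sites" else int(d.sum())


def segregating_sites(callset: CohortCallset, impact, category: str,
                      population: str | None = None) -> int:
    """Category sites segregating (0 < derived count < 2n called) in the
    cohort, or within one population."""
    mask = _impact_mask(impact, category)
    d, n = callset.derived_counts(population)
    seg = (d > 0) & (d < n)
    return int((seg & mask).sum())


def realised_load(callset: CohortCallset, sample: str, impact, category: str,
                  population_scope: str | None = None) -> float:
    """Expressed load: homozygous derived category sites over twice the
    category's segregating sites (cohort-wide by default; pass a population
    name to use population-wise segregating sites).  NaN when the category
    has no segregating site."""
    s_cat = segregating_sites(callset, impact, category, population_scope)
    if s_cat == 0:
        return float("nan")
    mask = _impact_mask(impact, category)
    dc, nc = callset.derived_counts(population_scope)
    mask &= (dc > 0) & (dc < nc)  # homozygotes counted over segregating sites only
    d = _dosage(callset, sample)
    n_hom = int(((d == 2) & mask).sum())
    return n_hom / (2.0 * s_cat)


def zygosity_counts(callset: CohortCallset, sample: str, site_mask) -> tuple[int, int]:
    """(n_het, n_hom) derived counts over an arbitrary site mask."""
    mask = np.asarray(site_mask, dtype=bool)
    d = _dosage(callset, sample)
    return int(((d == 1) & mask).sum()), int(((d == 2) & mask).sum())


def load_summary(callset: CohortCallset, annotations: pd.DataFrame,
                 bins: GerpBins = DEFAULT_BINS,
                 impact_categories=("MODERATE", "HIGH")) -> pd.DataFrame:
    """One row per (sample, category) with zygosity counts and load statistics.

    ``annotations`` must be aligned to callset site order with columns
    ``gerp`` and ``impact`` (see :func:`bottleload.callset.annotate_sites`).
    GERP-bin rows carry the relative load; impact rows carry total (site and
    allele modes) and realised load.
    """
    scores = annotations["gerp"].to_numpy(dtype=float)
    impact = annotations["impact"].to_numpy(dtype=object)
    rows = []
    for sample in callset.samples:
        pop = callset.populations[sample]
        for cat in bins.labels:
            mask = gerp_site_mask(scores, cat, bins)
            n_het, n_hom = zygosity_counts(callset, sample, mask)
            rows.append({
                "sample": sample, "population": pop, "kind": "gerp", "category": cat,
                "n_sites_derived": n_het + n_hom,
                "n_derived_alleles": n_het + 2 * n_hom,
                "n_het": n_het, "n_hom": n_hom,
                "relative_load": relative_load_gerp(callset, sample, scores, cat, bins),
                "total_load_sites": np.nan, "total_load_alleles": np.nan,
                "realised_load": np.nan,
            })
        for cat in impact_categories:
            mask = _impact_mask(impact, cat)
            n_het, n_hom = zygosity_counts(callset, sample, mask)
            rows.append({
                "sample": sample, "population": pop, "kind": "impact", "category": cat,
                "n_sites_derived": n_het + n_hom,
                "n_derived_alleles": n_het + 2 * n_hom,
                "n_het": n_het, "n_hom": n_hom,
                "relative_load": np.nan,
                "total_load_sites": total_load(callset, sample, impact, cat, "sites"),
                "total_load_alleles": total_load(callset, sample, impact, cat, "alleles"),
                "realised_load": realised_load(callset, sample, impact, cat),
            })
    return pd.DataFrame(rows)
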