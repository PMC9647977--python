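"""Cohort callsets: VCF I/O, outgroup polarization and site/genotype filtering.

The central container is :class:`CohortCallset`, a dense derived-allele dosage
matrix (sites x samples, values 0/1/2 or -1 for missing) together with site
coordinates, allele labels and a sample -> population map.  Filtering follows
the usual resequencing conventions for historical/modern cohorts: a QUAL
threshold, exclusion of SNPs close to indels, per-genotype depth bounds
relative to the sample mean, allelic-balance bounds for heterozygotes, BED
masks (repeats, CpG) and removal of sex-linked scaffolds, followed by a
complete-case restriction so every downstream statistic sees the same sites in
every individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("bottleload")

MISSING = -1
SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class CallsetError(ValueError):
    pass


@dataclass
class VcfFields:
    """Per-record/per-genotype auxiliary fields needed by the filters."""

    qual: np.ndarray | None = None          # (n_sites,) float, nan if absent
    depth: np.ndarray | None = None         # (n_sites, n_samples) float, nan missing
    ref_depth: np.ndarray | None = None     # (n_sites, n_samples) reference-supporting reads
    aa: np.ndarray | None = None            # (n_sites,) object: ancestral allele (INFO/AA)
    ann_impact: np.ndarray | None = None    # (n_sites,) object: impact parsed from ANN
    indels: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (k, 2) 1-based spans

    def subset(self, mask: np.ndarray) -> "VcfFields":
        def cut(a):
            return None if a is None else a[mask]

        return VcfFields(
            qual=cut(self.qual),
            depth=cut(self.depth),
            ref_depth=cut(self.ref_depth),
            aa=cut(self.aa),
            ann_impact=cut(self.ann_impact),
            indels=self.indels,
        )


@dataclass
class CohortCallset:
    """Dosage matrix plus site and sample metadata.

    ``G[i, j]`` is the number of ALT (or, after polarization, derived) alleles
    carried by sample ``j`` at site ``i``; ``-1`` marks a missing genotype.
    Sites are strictly sorted by (chrom, pos) with chromosomes in order of
    first appearance.
    """

    samples: list[str]
    populations: dict[str, str]
    sites: pd.DataFrame
    G: np.ndarray
    polarized: bool = False
    callable_bp: dict[str, float] | None = None
    provenance: dict = field(default_factory=dict)
    vcf_fields: VcfFields | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_index(self, population: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.samples) if self.populations[s] == population]
        if not idx:
            raise CallsetError(f"no samples in population {population!r}")
        return np.asarray(idx)

    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise CallsetError(f"unknown sample {sample!r}") from None

    def chrom_blocks(self) -> list[tuple[str, np.ndarray]]:
        """Contiguous index blocks per chromosome, in stored order."""
        chroms = self.sites["chrom"].to_numpy()
        out = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], np.arange(start, i)))
                start = i
        return out

    def validate(self) -> None:
        if list(self.sites.columns[:2]) != ["chrom", "pos"]:
            raise CallsetError("sites must start with columns chrom, pos")
        if self.G.shape != (self.n_sites, self.n_samples):
            raise CallsetError("G shape does not match sites/samples")
        uncovered = [s for s in self.samples if s not in self.populations]
        if uncovered:
            raise CallsetError(f"samples missing from population map: {uncovered}")
        bad = ~np.isin(self.G, [MISSING, 0, 1, 2])
        if bad.any():
            raise CallsetError("dosages outside {-1, 0, 1, 2}")
        seen: set[str] = set()
        prev_chrom = None
        prev_pos = -1
        for chrom, pos in zip(self.sites["chrom"], self.sites["pos"]):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise CallsetError(f"chromosome {chrom} appears in two blocks: unsorted sites")
                seen.add(chrom)
                prev_chrom = chrom
                prev_pos = -1
            if pos <= prev_pos:
                raise CallsetError(f"positions not strictly increasing on {chrom} at {pos}")
            prev_pos = pos

    # -- transformations -----------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "CohortCallset":
        mask = np.asarray(mask, dtype=bool)
        return CohortCallset(
            samples=list(self.samples),
            populations=dict(self.populations),
            sites=self.sites.loc[mask].reset_index(drop=True),
            G=self.G[mask].copy(),
            polarized=self.polarized,
            callable_bp=dict(self.callable_bp) if self.callable_bp else None,
            provenance=dict(self.provenance),
            vcf_fields=self.vcf_fields.subset(mask) if self.vcf_fields else None,
        )

    def derived_counts(self, population: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site derived-allele count d and total called alleles n."""
        cols = self.pop_index(population) if population else np.arange(self.n_samples)
        g = self.G[:, cols]
        called = g != MISSING
        d = np.where(called, g, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return d, n


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_population_table(source) -> dict[str, str]:
    """sample -> population map from a dict, DataFrame or 2-column TSV."""
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", comment=None, dtype=str)
        if df.columns[0].startswith("#"):
            df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    df.columns = [c.lower() for c in df.columns]
    if not {"sample", "population"} <= set(df.columns):
        raise CallsetError("population table needs columns 'sample' and 'population'")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path, sample_pop_table) -> CohortCallset:
    """Load biallelic SNPs from a VCF into a :class:`CohortCallset`.

    Multi-allelic and non-SNP records are skipped (counted in provenance);
    indel records feed the indel-proximity filter via ``vcf_fields.indels``.
    Dosages count ALT alleles until :func:`polarize_to_ancestral` is applied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    pops = read_population_table(sample_pop_table)
    unknown = [s for s in samples if s not in pops]
    if unknown:
        raise CallsetError(f"VCF samples absent from population table: {unknown}")

    chroms, poss, refs, alts = [], [], [], []
    gts, quals, dps, ads, aas, anns = [], [], [], [], [], []
    indels: dict[str, list[tuple[int, int]]] = {}
    n_skipped = 0
    for v in vcf:
        if v.is_indel:
            span = (v.POS, v.POS + max(len(v.REF) - 1, 0))
            indels.setdefault(v.CHROM, []).append(span)
            n_skipped += 1
            continue
        if (not v.is_snp) or len(v.ALT) != 1:
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        dps.append(np.full(len(samples), np.nan) if dp is None
                   else np.where(dp[:, 0] < 0, np.nan, dp[:, 0]).astype(float))
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        ads.append(np.full(len(samples), np.nan) if ad is None
                   else np.where(ad[:, 0] < 0, np.nan, ad[:, 0]).astype(float))
        aas.append(v.INFO.get("AA"))
        ann = v.INFO.get("ANN")
        anns.append(impact_from_ann(ann) if ann else None)

    sites = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
                          "ref": refs, "alt": alts})
    G = (np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8))
    fields = VcfFields(
        qual=np.asarray(quals, dtype=float),
        depth=np.vstack(dps) if dps else None,
        ref_depth=np.vstack(ads) if ads else None,
        aa=np.asarray(aas, dtype=object),
        ann_impact=np.asarray(anns, dtype=object),
        indels={c: np.asarray(v, dtype=np.int64) for c, v in indels.items()},
    )
    cs = CohortCallset(samples=samples, populations={s: pops[s] for s in samples},
                       sites=sites, G=G.astype(np.int8),
                       provenance={"records_skipped_non_biallelic_snp": n_skipped},
                       vcf_fields=fields)
    cs.validate()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    return cs


def impact_from_ann(ann_value: str) -> str | None:
    """Impact category (2nd pipe field) of the first annotation in an ANN string."""
    first = str(ann_value).split(",")[0].split("|")
    return first[2] if len(first) > 2 else None


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize_to_ancestral(callset: CohortCallset, outgroup_alleles) -> CohortCallset:
    """Re-orient dosages so they count derived alleles relative to an outgroup.

    ``outgroup_alleles`` may be a mapping ``(chrom, pos) -> base``, a DataFrame
    with columns (chrom, pos, allele), a path to such a TSV, or the string
    ``"AA"`` to use the INFO/AA field captured at read time.  Per site: if the
    outgroup base equals REF, dosages are unchanged; if it equals ALT, REF/ALT
    are swapped and dosage d becomes 2 - d; if it matches neither (or is
    absent) the site is dropped and counted.
    """
    og = _outgroup_series(callset, outgroup_alleles)
    ref = callset.sites["ref"].to_numpy()
    alt = callset.sites["alt"].to_numpy()
    is_ref = og == ref
    is_alt = og == alt
    keep = is_ref | is_alt
    n_dropped = int((~keep).sum())

    out = callset.subset_sites(keep)
    flip = is_alt[keep]
    g = out.G
    flipped = g[flip]
    m = flipped == MISSING
    flipped = (2 - flipped).astype(np.int8)
    flipped[m] = MISSING
    g[flip] = flipped
    new_ref = np.where(flip, alt[keep], ref[keep])
    new_alt = np.where(flip, ref[keep], alt[keep])
    out.sites = out.sites.assign(ref=new_ref, alt=new_alt)
    out.polarized = True
    out.provenance["polarize_dropped"] = n_dropped
    out.provenance["polarize_flipped"] = int(flip.sum())
    if n_dropped:
        log.info("polarize: dropped %d sites with outgroup matching neither allele", n_dropped)
    return out


def _outgroup_series(callset: CohortCallset, source) -> np.ndarray:
    key = pd.MultiIndex.from_frame(callset.sites[["chrom", "pos"]])
    if isinstance(source, str) and source.upper() == "AA":
        if callset.vcf_fields is None or callset.vcf_fields.aa is None:
            raise CallsetError("no INFO/AA field available for polarization")
        return np.asarray([a if a is not None else "" for a in callset.vcf_fields.aa],
                          dtype=object)
    if isinstance(source, Mapping):
        return np.asarray([source.get((c, p), "") for c, p in
                           zip(callset.sites["chrom"], callset.sites["pos"])], dtype=object)
    if isinstance(source, (str, Path)):
        source = pd.read_csv(source, sep="\t", comment="#", header=None,
                             names=["chrom", "pos", "allele"], dtype={"chrom": str})
    if isinstance(source, pd.Series):
        ser = source
    else:
        df = source.copy()
        df.columns = [c.lower() for c in df.columns]
        ser = df.set_index(["chrom", "pos"])["allele"]
    aligned = ser.reindex(key)
    return aligned.fillna("").to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Site- and genotype-level filter thresholds.

    Defaults follow common museum-cohort resequencing practice: QUAL >= 30,
    SNPs within 5 bp of indels removed, per-genotype depth within [mean/3,
    2*mean], heterozygote allelic balance (REF reads / depth) within
    (0.2, 0.8).  Any threshold set to ``None`` disables that filter.
    """

    min_qual: float | None = 30.0
    min_depth_frac: float | None = 1.0 / 3.0
    max_depth_mult: float | None = 2.0
    indel_pad_bp: int = 5
    ab_low: float | None = 0.2
    ab_high: float | None = 0.8
    mask_beds: list = field(default_factory=list)
    excluded_scaffolds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ab_low is not None and self.ab_high is not None \
                and not (0.0 <= self.ab_low < self.ab_high <= 1.0):
            raise CallsetError("require 0 <= ab_low < ab_high <= 1")
        if self.indel_pad_bp < 0:
            raise CallsetError("indel_pad_bp must be >= 0")


def read_bed(path) -> pd.DataFrame:
    """First three BED columns (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    return df


def _in_bed(sites: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, sub in bed.groupby("chrom"):
        sel = sites["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        iv = sub.sort_values("start")[["start", "end"]].to_numpy()
        pos0 = sites.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        k = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = (k >= 0) & (pos0 < iv[np.clip(k, 0, None), 1])
        hit[np.where(sel)[0]] = ok
    return hit


def _near_indel(sites: pd.DataFrame, indels: dict[str, np.ndarray], pad: int) -> np.ndarray:
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, spans in indels.items():
        sel = sites["chrom"].to_numpy() == chrom
        if not sel.any() or len(spans) == 0:
            continue
        lo = spans[:, 0] - pad
        hi = spans[:, 1] + pad
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        hi = np.maximum.accumulate(hi)
        pos = sites.loc[sel, "pos"].to_numpy()
        k = np.searchsorted(lo, pos, side="right") - 1
        ok = (k >= 0) & (pos <= hi[np.clip(k, 0, None)])
        hit[np.where(sel)[0]] = ok
    return hit


def apply_site_filters(callset: CohortCallset, spec: FilterSpec,
                       fields: VcfFields | None = None) -> CohortCallset:
    """Apply the full site/genotype filter stack, recording per-filter drops.

    Site-level: excluded scaffolds, BED masks, QUAL, indel proximity.
    Genotype-level (set to missing, so a single bad sample does not delete a
    site before the complete-case restriction): depth outside
    [min_depth_frac * mean, max_depth_mult * mean] per sample; heterozygotes
    whose REF-read fraction falls outside (ab_low, ab_high).
    """
    fields = fields if fields is not None else callset.vcf_fields
    prov: dict[str, int] = {}
    keep = np.ones(callset.n_sites, dtype=bool)

    if spec.excluded_scaffolds:
        drop = callset.sites["chrom"].isin(spec.excluded_scaffolds).to_numpy()
        prov["dropped_scaffold"] = int(drop.sum())
        keep &= ~drop
    for bed in spec.mask_beds:
        bed_df = bed if isinstance(bed, pd.DataFrame) else read_bed(bed)
        drop = _in_bed(callset.sites, bed_df) & keep
        prov["dropped_mask"] = prov.get("dropped_mask", 0) + int(drop.sum())
        keep &= ~drop
    if spec.min_qual is not None:
        if fields is None or fields.qual is None:
            raise CallsetError("QUAL filter enabled but no QUAL field available")
        drop = ~(fields.qual >= spec.min_qual) & keep  # nan fails
        prov["dropped_qual"] = int(drop.sum())
        keep &= ~drop
    if spec.indel_pad_bp and fields is not None and fields.indels:
        drop = _near_indel(callset.sites, fields.indels, spec.indel_pad_bp) & keep
        prov["dropped_indel_pad"] = int(drop.sum())
        keep &= ~drop

    out = callset.subset_sites(keep)
    f = out.vcf_fields if fields is callset.vcf_fields else fields.subset(keep)

    if spec.min_depth_frac is not None or spec.max_depth_mult is not None:
        if f is None or f.depth is None:
            raise CallsetError("depth filter enabled but no DP field available")
        with np.errstate(invalid="ignore"):
            mean_dp = np.nanmean(f.depth, axis=0)
        bad = np.zeros_like(out.G, dtype=bool)
        if spec.min_depth_frac is not None:
            bad |= f.depth < spec.min_depth_frac * mean_dp
        if spec.max_depth_mult is not None:
            bad |= f.depth > spec.max_depth_mult * mean_dp
        bad &= out.G != MISSING
        prov["genotypes_masked_depth"] = int(bad.sum())
        out.G[bad] = MISSING
    if spec.ab_low is not None and f is not None and f.depth is not None \
            and f.ref_depth is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = f.ref_depth / f.depth
        het = out.G == 1
        bad = het & ((ab <= spec.ab_low) | (ab >= spec.ab_high))
        bad &= ~np.isnan(ab)
        prov["genotypes_masked_balance"] = int(bad.sum())
        out.G[bad] = MISSING

    out.provenance.update(prov)
    return out


def restrict_complete_cases(callset: CohortCallset) -> CohortCallset:
    """Keep only sites genotyped in every sample (the complete-case callset)."""
    keep = (callset.G != MISSING).all(axis=1)
    out = callset.subset_sites(keep)
    out.provenance["dropped_incomplete"] = int((~keep).sum())
    if out.n_sites == 0 and callset.n_sites > 0:
        log.warning("restrict_complete_cases: no site is genotyped in all samples")
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def load_annotations(gerp_source=None, impact_source=None) -> pd.DataFrame:
    """Join per-site conservation scores and impact categories.

    ``gerp_source``: TSV/DataFrame with columns (chrom, pos, gerp); positions
    1-based.  ``impact_source``: TSV/DataFrame with columns (chrom, pos,
    impact) or a VCF path whose ANN INFO field carries the impact.  Returns a
    DataFrame indexed by (chrom, pos) with columns ``gerp`` and ``impact``.
    Duplicate coordinates are an error.
    """
    def _table(src, value_names):
        if src is None:
            return None
        if isinstance(src, pd.DataFrame):
            df = src.copy()
        else:
            df = pd.read_csv(src, sep="\t", comment=None)
            df = df.rename(columns={df.columns[0]: str(df.columns[0]).lstrip("#")})
        df.columns = [str(c).lower() for c in df.columns]
        for cand in value_names:
            if cand in df.columns:
                df = df.rename(columns={cand: value_names[0]})
                break
        need = {"chrom", "pos", value_names[0]}
        if not need <= set(df.columns):
            raise CallsetError(f"annotation table needs columns {sorted(need)}")
        df["chrom"] = df["chrom"].astype(str)
        df = df.set_index(["chrom", "pos"])
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()[:5]
            raise CallsetError(f"duplicate annotation rows at {dups}")
        return df[[value_names[0]]]

    gerp = _table(gerp_source, ["gerp", "score"])
    if isinstance(impact_source, (str, Path)) and str(impact_source).endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        rows = [(v.CHROM, v.POS, impact_from_ann(v.INFO.get("ANN") or ""))
                for v in VCF(str(impact_source))]
        impact_source = pd.DataFrame(rows, columns=["chrom", "pos", "impact"])
    impact = _table(impact_source, ["impact", "category"])

    if gerp is None and impact is None:
        raise CallsetError("provide at least one of gerp_source / impact_source")
    if gerp is None:
        out = impact.assign(gerp=np.nan)[["gerp", "impact"]]
    elif impact is None:
        out = gerp.assign(impact=None)[["gerp", "impact"]]
    else:
        out = gerp.join(impact, how="outer")
    return out


def annotate_sites(callset: CohortCallset, annotations: pd.DataFrame) -> pd.DataFrame:
    """Annotations aligned to callset site order; ``annotated`` flags coverage."""
    key = pd.MultiIndex.from_frame(callset.sites[["chrom", "pos"]])
    aligned = annotations.reindex(key)
    aligned = aligned.reset_index(drop=True)
    aligned["annotated"] = ~(aligned["gerp"].isna() & aligned["impact"].isna())
    return aligned


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_vcf(callset: CohortCallset, path, contig_lengths: Mapping[str, int] | None = None,
              qual: str = ".") -> None:
    """Write the callset as a minimal VCF v4.2 with the ancestral allele in INFO/AA."""
    lines = ["##fileformat=VCFv4.2",
             "##source=bottleload",
             '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(callset.samples))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    sites = callset.sites
    for i in range(callset.n_sites):
        row = sites.iloc[i]
        gts = "\t".join(gt_code[int(g)] for g in callset.G[i])
        lines.append(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{qual}\t.\t"
                     f"AA={row.ref}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Tab-separated output with a '#'-prefixed header line."""
    cols = "\t".join(str(c) for c in df.columns)
    body = df.to_csv(sep="\t", header=False, index=False)
    Path(path).write_text(f"#{cols}\n{body}")
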