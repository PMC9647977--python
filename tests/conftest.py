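"""Shared fixtures: hand-built callsets, toy VCF text, and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bottleload import CohortCallset, SimulationConfig, simulate_cohort


def make_callset(chrom, pos, G, samples=None, populations=None,
                 ref=None, alt=None, polarized=True) -> CohortCallset:
    """Build a small callset from parallel site arrays and a dosage matrix."""
    G = np.asarray(G, dtype=np.int8)
    n_sites, n_samples = G.shape
    samples = samples or [f"s{j}" for j in range(n_samples)]
    populations = populations or {s: "pop" for s in samples}
    sites = pd.DataFrame({
        "chrom": list(chrom) if not isinstance(chrom, str) else [chrom] * n_sites,
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": ref if ref is not None else ["A"] * n_sites,
        "alt": alt if alt is not None else ["G"] * n_sites,
    })
    cs = CohortCallset(samples=list(samples), populations=dict(populations),
                       sites=sites, G=G, polarized=polarized)
    cs.validate()
    return cs


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tG\t50\t.\tAA=A\tGT:DP:AD\t0/1:20:10,10\t1/1:22:0,22
chr1\t200\t.\tC\tT\t25\t.\tAA=T\tGT:DP:AD\t0/0:18:18,0\t0/1:20:10,10
chr1\t300\t.\tG\tGTT\t60\t.\t.\tGT:DP:AD\t0/1:20:10,10\t0/0:21:21,0
chr1\t303\t.\tT\tA\t60\t.\tAA=T\tGT:DP:AD\t0/1:19:9,10\t0/0:20:20,0
chr1\t400\t.\tA\tC,G\t60\t.\tAA=A\tGT:DP:AD\t1/2:20:0,10,10\t0/0:20:20,0,0
chr1\t500\t.\tT\tC\t60\t.\tAA=C\tGT:DP:AD\t./.:.:.\t0/1:20:4,16
chr2\t150\t.\tG\tA\t60\t.\tAA=T\tGT:DP:AD\t0/1:20:10,10\t1/1:20:0,20
chr2\t250\t.\tC\tA\t60\t.\tAA=C\tGT:DP:AD\t0/1:20:3,17\t0/1:20:10,10
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture()
def toy_pops():
    return {"s1": "popA", "s2": "popB"}


def neutral_config(seed: int) -> SimulationConfig:
    """Default demography with selection switched off in every class."""
    from bottleload.scenarios import neutral_crash_config

    return neutral_crash_config(seed)


@pytest.fixture(scope="session")
def neutral_replicates():
    """Twenty neutral-drift replicates of the default crash-and-split demography."""
    out = []
    for seed in range(20):
        cfg = neutral_config(seed)
        callset, ann, truth = simulate_cohort(cfg)
        out.append((cfg, callset, ann, truth))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """One small selected cohort reused by analysis-level tests."""
    cfg = SimulationConfig(seed=7, n_chromosomes=4, chrom_length_bp=200_000,
                           n_standing_sites=1200)
    callset, ann, truth = simulate_cohort(cfg)
    return cfg, callset, ann, truth
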