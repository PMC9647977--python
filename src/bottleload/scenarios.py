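"""Canonical simulation scenarios used for validation experiments.

Two fixed study conditions recur across the test-bench:

* :func:`neutral_crash_config` — the default crash-to-pair-and-translocation
  demography with selection switched off in every effect class.  Under pure
  drift the expected per-individual derived-allele count is conserved across
  the timeline, while inbreeding (F_ROH) rises and heterozygosity falls in
  the post-crash populations.
* :func:`purging_config` — a single population of N = 50 evolved for 20
  generations under strong additive selection against the high class
  (s = -0.5, h = 0.5), sampled before and after.  Selection drives high-class
  derived frequencies down, so R_xy(descendant, ancestral) for HIGH-impact
  variants falls below 1.
"""

from __future__ import annotations

from .simulate import CLASSES, Epoch, Sample, SimulationConfig


def neutral_crash_config(seed: int) -> SimulationConfig:
    """Default demography, all selection coefficients zero (pure drift)."""
    return SimulationConfig(seed=seed,
                            s_by_class={c: 0.0 for c in CLASSES})


def purging_config(seed: int) -> SimulationConfig:
    """Strong additive selection against the high class in a small population."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=4,
        chrom_length_bp=250_000,
        n_standing_sites=1500,
        s_by_class={"neutral": 0.0, "low": 0.0, "moderate": 0.0, "high": -0.5},
        h_by_class={"neutral": 0.5, "low": 0.5, "moderate": 0.5, "high": 0.5},
        demography=[Epoch(1, 50), Sample("ancestral", 25),
                    Epoch(20, 50), Sample("descendant", 25)],
    )
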