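"""Forward diploid Wright-Fisher simulation of a near-extinction cohort.

The simulator produces a cohort with the statistical structure the downstream
load analysis assumes: "historical" individuals sampled from a large
pre-crash population, a crash to a single breeding pair, demographic
recovery, and a translocation split into two isolated modern populations.
Variant sites belong to effect classes (neutral / low / moderate / high),
each with its own selection coefficient ``s`` (negative = deleterious),
dominance ``h`` and conservation-score distribution, so GERP-style scores
correlate with deleteriousness by construction.

Standing variation is initialised from the neutral site-frequency spectrum
(P(count = i) proportional to 1/i) at the founding population size.  This
plays the role of the deep coalescent history that a forward simulation
cannot afford to burn in: with a realistic per-generation mutation rate the
variation segregating in the cohort is overwhelmingly old, and new mutations
over the simulated decades are a small perturbation — the regime in which
per-individual derived-allele counts are conserved in expectation under
neutral drift.

Selection is viability selection: an offspring survives with probability
equal to its fitness, multiplicative across sites (factors 1, 1 + hs,
1 + s for 0/1/2 derived copies).  Recombination is Poisson crossovers per
chromosome per meiosis with free assortment across chromosomes, which makes
chromosomes valid jack-knife units downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .callset import MISSING, CohortCallset, write_tsv, write_vcf

CLASSES = ("neutral", "low", "moderate", "high")
_IMPACT_BY_CLASS = {"neutral": "MODIFIER", "low": "LOW", "moderate": "MODERATE", "high": "HIGH"}
_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# demography stages
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    """Evolve for ``generations`` generations.

    ``size``: target diploid size (int), per-population dict, or None to keep
    current sizes.  ``ramp=True`` interpolates geometrically from the current
    size to ``size`` across the epoch (used for post-crash recovery growth).
    """

    generations: int
    size: int | dict | None = None
    ramp: bool = False


@dataclass
class BottleneckToPair:
    """Crash the (single) population to one randomly chosen breeding pair."""

    generations: int = 1


@dataclass
class Split:
    """Translocation: move individuals out to found a second population."""

    n_moved: int | None = None
    fraction: float | None = None
    source: str = "main"
    names: tuple[str, str] = ("popA", "popB")


@dataclass
class Sample:
    """Archive ``n`` randomly chosen individuals under ``label`` at this point."""

    label: str
    n: int
    population: str | None = None


def default_demography() -> list:
    """Desk-scale template mirroring a crash-to-pair-and-translocation history.

    40 generations at N=500 (pre-crash), historical museum sample, decline to
    N=50, crash to a single pair, geometric recovery to 60, translocation of
    20 founders, 15 generations of separation, then modern samples.
    """
    return [
        Epoch(40, 500),
        Sample("historical", 13),
        Epoch(10, 50),
        BottleneckToPair(),
        Epoch(10, 60, ramp=True),
        Split(n_moved=20, names=("popA", "popB")),
        Epoch(15, None),
        Sample("popA", 9, population="popA"),
        Sample("popB", 20, population="popB"),
    ]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator.

    Defaults give a 2 Mb genome on 8 chromosomes with ~3,000 standing variant
    sites, an avian-scale mutation rate, and mildly deleterious low/moderate
    classes plus a partially recessive high class — enough structure for
    bottleneck-driven inbreeding, load and purging signals to emerge at desk
    scale.
    """

    n_chromosomes: int = 8
    chrom_length_bp: int = 250_000
    mu: float = 2.3e-9
    rec_rate: float = 1e-6
    class_probs: dict = field(default_factory=lambda: {
        "neutral": 0.70, "low": 0.15, "moderate": 0.10, "high": 0.05})
    s_by_class: dict = field(default_factory=lambda: {
        "neutral": 0.0, "low": -0.005, "moderate": -0.02, "high": -0.10})
    h_by_class: dict = field(default_factory=lambda: {
        "neutral": 0.5, "low": 0.3, "moderate": 0.25, "high": 0.05})
    gerp_range_by_class: dict = field(default_factory=lambda: {
        "neutral": (-2.0, 1.0), "low": (1.0, 3.0),
        "moderate": (3.0, 5.88), "high": (5.88, 12.0)})
    n_standing_sites: int = 3000
    demography: list = field(default_factory=default_demography)
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_probs sum to {total}, expected 1")
        unknown = set(self.class_probs) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")
        if self.mu < 0 or self.rec_rate < 0:
            raise ConfigurationError("mu and rec_rate must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ConfigurationError("need at least one chromosome of positive length")
        for st in self.demography:
            if isinstance(st, Epoch) and isinstance(st.size, int) and st.size < 1:
                raise ConfigurationError("population sizes must be >= 1")
        if not (self.demography and isinstance(self.demography[0], Epoch)
                and isinstance(self.demography[0].size, int)):
            raise ConfigurationError("demography must start with an Epoch of explicit size")

    @property
    def genome_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demography"] = [_stage_to_dict(st) for st in self.demography]
        d["gerp_range_by_class"] = {k: list(v) for k, v in self.gerp_range_by_class.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "demography" in d:
            d["demography"] = [_stage_from_dict(s) for s in d["demography"]]
        if "gerp_range_by_class" in d:
            d["gerp_range_by_class"] = {k: tuple(v) for k, v in d["gerp_range_by_class"].items()}
        return cls(**d)


def _stage_to_dict(st) -> dict:
    d = asdict(st)
    d["type"] = type(st).__name__.lower()
    if isinstance(st, Split):
        d["names"] = list(st.names)
    return d


def _stage_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    cls = {"epoch": Epoch, "bottlenecktopair": BottleneckToPair,
           "split": Split, "sample": Sample}[kind]
    if cls is Split and "names" in d:
        d["names"] = tuple(d["names"])
    return cls(**d)


# ---------------------------------------------------------------------------
# site registry and effects
# ---------------------------------------------------------------------------

@dataclass
class SiteEffect:
    effect_class: str
    s: float
    h: float
    score: float


def draw_site_effect(class_probs: dict, rng: np.random.Generator,
                     s_by_class: dict | None = None, h_by_class: dict | None = None,
                     gerp_range_by_class: dict | None = None) -> SiteEffect:
    """Draw an effect class and its (s, h, conservation score) for a new site."""
    total = sum(class_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class_probs sum to {total}, expected 1")
    s_by_class = s_by_class or SimulationConfig().s_by_class
    h_by_class = h_by_class or SimulationConfig().h_by_class
    gerp_range_by_class = gerp_range_by_class or SimulationConfig().gerp_range_by_class
    names = [c for c in CLASSES if class_probs.get(c, 0.0) > 0]
    probs = np.array([class_probs[c] for c in names])
    cls = names[int(rng.choice(len(names), p=probs / probs.sum()))]
    lo, hi = gerp_range_by_class[cls]
    return SiteEffect(cls, float(s_by_class[cls]), float(h_by_class[cls]),
                      float(rng.uniform(lo, hi)))


class _Registry:
    """Append-only table of variant sites with vectorised attribute lookup."""

    def __init__(self, capacity: int = 1024):
        self._cap = max(capacity, 16)
        self.n = 0
        self.chrom = np.zeros(self._cap, dtype=np.int32)
        self.pos = np.zeros(self._cap, dtype=np.int64)
        self.cls = np.zeros(self._cap, dtype=np.int8)
        self.s = np.zeros(self._cap, dtype=np.float64)
        self.h = np.zeros(self._cap, dtype=np.float64)
        self.score = np.zeros(self._cap, dtype=np.float64)
        self.origin_gen = np.zeros(self._cap, dtype=np.int32)
        self.anc = np.zeros(self._cap, dtype=np.int8)
        self.der = np.zeros(self._cap, dtype=np.int8)
        self.sel = np.zeros(self._cap, dtype=bool)
        self.occupied: set[tuple[int, int]] = set()
        self.n_selected = 0

    def _grow(self) -> None:
        self._cap *= 2
        for name in ("chrom", "pos", "cls", "s", "h", "score", "origin_gen", "anc",
                     "der", "sel"):
            arr = getattr(self, name)
            new = np.zeros(self._cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add(self, chrom: int, pos: int, eff: SiteEffect, gen: int,
            rng: np.random.Generator) -> int:
        if self.n == self._cap:
            self._grow()
        i = self.n
        self.chrom[i] = chrom
        self.pos[i] = pos
        self.cls[i] = CLASSES.index(eff.effect_class)
        self.s[i] = eff.s
        self.h[i] = eff.h
        self.score[i] = eff.score
        self.origin_gen[i] = gen
        anc = int(rng.integers(4))
        der = (anc + 1 + int(rng.integers(3))) % 4
        self.anc[i] = anc
        self.der[i] = der
        self.occupied.add((chrom, pos))
        if eff.s != 0.0:
            self.sel[i] = True
            self.n_selected += 1
        self.n += 1
        return i


# ---------------------------------------------------------------------------
# truth output
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests: per-site effects and
    per-individual realized homozygosity."""

    sites: pd.DataFrame        # chrom pos effect_class s h gerp origin_gen
    individuals: pd.DataFrame  # sample population generation hom_fraction


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _gamete(ind, reg: _Registry, cfg: SimulationConfig, rng: np.random.Generator,
            gen: int) -> list:
    """One recombinant gamete (list of per-chromosome sorted site-id arrays)."""
    hap0, hap1, _w = ind
    L = cfg.chrom_length_bp
    n_c = cfg.n_chromosomes
    ks = rng.integers(0, 2, size=n_c)
    n_x = rng.poisson(cfg.rec_rate * L, size=n_c) if cfg.rec_rate > 0 \
        else np.zeros(n_c, dtype=np.int64)
    out = []
    for c in range(n_c):
        a = hap0[c] if ks[c] == 0 else hap1[c]
        if n_x[c] == 0:
            out.append(a)  # shared reference; haplotype arrays are immutable
            continue
        b = hap1[c] if ks[c] == 0 else hap0[c]
        breaks = np.sort(rng.integers(1, L + 1, size=n_x[c]))
        seg_a = np.searchsorted(breaks, reg.pos[a], side="right") % 2 == 0
        seg_b = np.searchsorted(breaks, reg.pos[b], side="right") % 2 == 1
        out.append(np.sort(np.concatenate([a[seg_a], b[seg_b]])))
    n_mut = int(rng.poisson(cfg.mu * L * n_c)) if cfg.mu > 0 else 0
    for _ in range(n_mut):
        c = int(rng.integers(n_c))
        pos = int(rng.integers(1, L + 1))
        while (c, pos) in reg.occupied:
            c = int(rng.integers(n_c))
            pos = int(rng.integers(1, L + 1))
        eff = draw_site_effect(cfg.class_probs, rng, cfg.s_by_class,
                               cfg.h_by_class, cfg.gerp_range_by_class)
        sid = reg.add(c, pos, eff, gen, rng)
        out[c] = np.sort(np.append(out[c], np.int64(sid)))
    return out


def _fitness(g1: list, g2: list, reg: _Registry) -> float:
    """Multiplicative viability: factors 1, 1+hs, 1+s for 0/1/2 derived copies."""
    if reg.n_selected == 0:
        return 1.0
    a = np.concatenate(g1)
    b = np.concatenate(g2)
    a = a[reg.sel[a]]
    b = b[reg.sel[b]]
    if len(a) == 0 and len(b) == 0:
        return 1.0
    hom = np.intersect1d(a, b, assume_unique=True)
    het = np.setxor1d(a, b, assume_unique=True)
    w = float(np.prod(1.0 + reg.s[hom]) * np.prod(1.0 + reg.h[het] * reg.s[het]))
    return max(w, 0.0)


def _next_generation(pop: list, n_target: int, reg: _Registry, cfg: SimulationConfig,
                     rng: np.random.Generator, gen: int, pop_name: str) -> list:
    """Offspring survive with probability w / max(parental w) (relative viability)."""
    if len(pop) == 0:
        raise SimulationError(f"population {pop_name} extinct entering generation {gen}")
    w_max = max(ind[2] for ind in pop)
    if w_max <= 0.0:
        raise SimulationError(
            f"population {pop_name} has all-zero fitness at generation {gen}")
    offspring = []
    attempts = 0
    max_attempts = max(2000, 200 * n_target)
    while len(offspring) < n_target:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"population {pop_name} failed to produce offspring at generation {gen}")
        if len(pop) == 1:
            i = j = 0  # forced selfing in a singleton population
        else:
            i = int(rng.integers(len(pop)))
            j = int(rng.integers(len(pop) - 1))
            if j >= i:
                j += 1
        g1 = _gamete(pop[i], reg, cfg, rng, gen)
        g2 = _gamete(pop[j], reg, cfg, rng, gen)
        w = _fitness(g1, g2, reg)
        if w >= w_max or rng.random() < w / w_max:
            offspring.append((g1, g2, w))
    return offspring


def _init_standing(cfg: SimulationConfig, reg: _Registry, rng: np.random.Generator,
                   n0: int) -> list:
    """Found the population with standing variation from the neutral 1/i SFS."""
    hap_ids: list[list[list[int]]] = [[[] for _ in range(cfg.n_chromosomes)]
                                      for _ in range(2 * n0)]
    if cfg.n_standing_sites > 0 and 2 * n0 >= 2:
        counts = np.arange(1, 2 * n0)
        sfs = (1.0 / counts)
        sfs /= sfs.sum()
        drawn = rng.choice(counts, size=cfg.n_standing_sites, p=sfs)
        for k in range(cfg.n_standing_sites):
            chrom = int(rng.integers(cfg.n_chromosomes))
            pos = int(rng.integers(1, cfg.chrom_length_bp + 1))
            while (chrom, pos) in reg.occupied:
                chrom = int(rng.integers(cfg.n_chromosomes))
                pos = int(rng.integers(1, cfg.chrom_length_bp + 1))
            eff = draw_site_effect(cfg.class_probs, rng, cfg.s_by_class,
                                   cfg.h_by_class, cfg.gerp_range_by_class)
            sid = reg.add(chrom, pos, eff, 0, rng)
            carriers = rng.permutation(2 * n0)[: int(drawn[k])]
            for hp in carriers:
                hap_ids[hp][chrom].append(sid)
    pop = []
    for k in range(n0):
        h0 = [np.sort(np.asarray(hap_ids[2 * k][c], dtype=np.int64))
              for c in range(cfg.n_chromosomes)]
        h1 = [np.sort(np.asarray(hap_ids[2 * k + 1][c], dtype=np.int64))
              for c in range(cfg.n_chromosomes)]
        pop.append((h0, h1, _fitness(h0, h1, reg)))
    return pop


def simulate_cohort(config: SimulationConfig):
    """Run the demography and emit (CohortCallset, annotations, TruthTable).

    The emitted callset contains every site carrying at least one derived
    allele among the sampled individuals, sorted by (chromosome, position),
    with dosages already counting derived alleles (the written VCF stores the
    ancestral base as REF and in INFO/AA).  Identical (config, seed) yields
    byte-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    reg = _Registry(capacity=max(cfg.n_standing_sites * 2, 1024))

    first = cfg.demography[0]
    n0 = first.size
    pops: dict[str, list] = {"main": _init_standing(cfg, reg, rng, n0)}
    gen = 0
    archived: list[tuple[str, int, tuple]] = []

    for stage in cfg.demography:
        if isinstance(stage, Epoch):
            cur_sizes = {name: len(p) for name, p in pops.items()}
            for t in range(stage.generations):
                gen += 1
                for name in list(pops):
                    if stage.size is None:
                        n_target = cur_sizes[name]
                    elif isinstance(stage.size, dict):
                        n_target = stage.size.get(name, cur_sizes[name])
                    elif stage.ramp:
                        start = cur_sizes[name]
                        frac = (t + 1) / stage.generations
                        n_target = max(1, round(start * (stage.size / start) ** frac))
                    else:
                        n_target = stage.size
                    pops[name] = _next_generation(pops[name], n_target, reg, cfg,
                                                  rng, gen, name)
        elif isinstance(stage, BottleneckToPair):
            if len(pops) != 1:
                raise ConfigurationError("bottleneck_to_pair requires a single population")
            name = next(iter(pops))
            pop = pops[name]
            if len(pop) < 2:
                raise SimulationError(
                    f"population {name} too small for a breeding pair at generation {gen}")
            idx = rng.choice(len(pop), size=2, replace=False)
            pops[name] = [pop[int(idx[0])], pop[int(idx[1])]]
            for _ in range(stage.generations):
                gen += 1
                pops[name] = _next_generation(pops[name], 2, reg, cfg, rng, gen, name)
        elif isinstance(stage, Split):
            if stage.source not in pops:
                raise ConfigurationError(f"split source {stage.source!r} does not exist")
            pop = pops.pop(stage.source)
            n_moved = stage.n_moved
            if n_moved is None:
                n_moved = int(round(stage.fraction * len(pop)))
            if not (0 < n_moved < len(pop)):
                raise ConfigurationError("split must move between 1 and size-1 individuals")
            moved_idx = set(int(i) for i in rng.choice(len(pop), size=n_moved, replace=False))
            stay, move = [], []
            for i, ind in enumerate(pop):
                (move if i in moved_idx else stay).append(ind)
            pops[stage.names[0]] = stay
            pops[stage.names[1]] = move
        elif isinstance(stage, Sample):
            pname = stage.population
            if pname is None:
                if len(pops) != 1:
                    raise ConfigurationError(
                        f"sample {stage.label!r} must name a population (several exist)")
                pname = next(iter(pops))
            if pname not in pops:
                raise ConfigurationError(f"sample references unknown population {pname!r}")
            pop = pops[pname]
            if stage.n > len(pop):
                raise ConfigurationError(
                    f"cannot sample {stage.n} from population {pname!r} of size {len(pop)}")
            idx = rng.choice(len(pop), size=stage.n, replace=False)
            for i in idx:
                archived.append((stage.label, gen, pop[int(i)]))
        else:
            raise ConfigurationError(f"unknown demography stage {stage!r}")

    return _emit(archived, reg, cfg, rng)


def _emit(archived, reg: _Registry, cfg: SimulationConfig, rng: np.random.Generator):
    n_reg = reg.n
    names, pops_of, gens_of = [], {}, []
    counters: dict[str, int] = {}
    G_full = np.zeros((n_reg, len(archived)), dtype=np.int8)
    for j, (label, gen, ind) in enumerate(archived):
        counters[label] = counters.get(label, 0) + 1
        name = f"{label}_{counters[label]:02d}"
        names.append(name)
        pops_of[name] = label
        gens_of.append(gen)
        ids = np.concatenate([arr for hap in ind[:2] for arr in hap]) if n_reg else \
            np.empty(0, dtype=np.int64)
        if len(ids):
            G_full[:, j] = np.bincount(ids, minlength=n_reg).astype(np.int8)

    keep = G_full.sum(axis=1) > 0 if n_reg else np.zeros(0, dtype=bool)
    idx = np.where(keep)[0]
    order = idx[np.lexsort((reg.pos[idx], reg.chrom[idx]))]

    chrom_names = np.array([f"chr{c + 1}" for c in range(cfg.n_chromosomes)])
    sites = pd.DataFrame({
        "chrom": chrom_names[reg.chrom[order]],
        "pos": reg.pos[order],
        "ref": _BASES[reg.anc[order]],
        "alt": _BASES[reg.der[order]],
    })
    G = G_full[order]

    het_frac = (G == 1).mean(axis=0) if len(order) else np.zeros(len(archived))
    truth = TruthTable(
        sites=pd.DataFrame({
            "chrom": chrom_names[reg.chrom[order]],
            "pos": reg.pos[order],
            "effect_class": [CLASSES[c] for c in reg.cls[order]],
            "s": reg.s[order],
            "h": reg.h[order],
            "gerp": reg.score[order],
            "origin_gen": reg.origin_gen[order],
        }),
        individuals=pd.DataFrame({
            "sample": names,
            "population": [pops_of[n] for n in names],
            "generation": gens_of,
            "hom_fraction": 1.0 - het_frac,
        }),
    )

    if cfg.genotype_missing_rate > 0:
        mask = rng.random(G.shape) < cfg.genotype_missing_rate
        G = G.copy()
        G[mask] = MISSING

    annotations = pd.DataFrame({
        "chrom": truth.sites["chrom"],
        "pos": truth.sites["pos"],
        "gerp": truth.sites["gerp"],
        "impact": [_IMPACT_BY_CLASS[c] for c in truth.sites["effect_class"]],
    })

    callset = CohortCallset(
        samples=names,
        populations=pops_of,
        sites=sites,
        G=G,
        polarized=True,
        callable_bp={n: float(cfg.genome_bp) for n in names},
        provenance={"simulated": True, "seed": cfg.seed, "n_registry_sites": int(n_reg)},
    )
    callset.validate()
    return callset, annotations, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(callset: CohortCallset, annotations: pd.DataFrame, truth: TruthTable,
                 config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write VCF + TSV artifacts (annotations, populations, truth, config)."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "populations": outdir / "populations.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_individuals": outdir / "truth_individuals.tsv",
        "config": outdir / "sim_config.yaml",
    }
    contigs = {f"chr{c + 1}": config.chrom_length_bp for c in range(config.n_chromosomes)}
    write_vcf(callset, paths["vcf"], contig_lengths=contigs)
    write_tsv(annotations, paths["annotations"])
    write_tsv(pd.DataFrame({"sample": callset.samples,
                            "population": [callset.populations[s] for s in callset.samples]}),
              paths["populations"])
    write_tsv(truth.sites, paths["truth_sites"])
    write_tsv(truth.individuals, paths["truth_individuals"])
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return paths
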