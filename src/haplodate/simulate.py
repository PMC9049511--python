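"""Forward Wright-Fisher simulator of breed formation.

Models the demography behind modern breed radiations: a founder pool of
standing variation (array-ascertained common SNPs), scheduled population
splits tens to a few hundred generations before sampling, optional
admixture pulses, and recombination on a genetic map. There are no new
mutations: on the ~35-160 year timescale being dated, array SNP variation
is entirely standing founder variation.

Each population is a pool of diploids stored as a ``(2N, n_markers)``
haplotype matrix. One generation of random mating draws two parents per
offspring (uniformly, with replacement) and transmits one recombinant
gamete per parent; crossover counts are Poisson on the chromosome's map
length with uniform placement in cM (no interference). A split copies the
parent pool into each child branch; a pulse at generation ``g`` redraws
each parent of the target population from the source with probability
``fraction``. Sampling at generation 0 is without replacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, HaplotypePanel, MarkerMap, make_sample_table

#: Physical scale of the emitted marker map: 1 cM corresponds to 1 Mb,
#: a conventional average for the dog genome.
BP_PER_CM = 1_000_000


@dataclass
class ChromSpec:
    """One chromosome: genetic length in cM and number of markers."""
    length_cm: float
    n_markers: int


@dataclass
class PopSpec:
    """A population branch.

    ``origin_gen`` is the generation (before sampling; generation 0 = the
    sampled generation) at which the branch splits off its parent; the
    root population has ``parent=None`` and no origin.
    """
    name: str
    parent: str | None = None
    origin_gen: int | None = None
    size: int | None = None        # diploids; defaults to founder_size


@dataclass
class Pulse:
    """Admixture pulse: at ``generation`` before sampling, each parent of
    ``target`` is drawn from ``source`` with probability ``fraction``."""
    source: str
    target: str
    generation: int
    fraction: float


@dataclass
class DemographyConfig:
    populations: list[PopSpec]
    chromosomes: list[ChromSpec] = field(
        default_factory=lambda: [ChromSpec(100.0, 5000), ChromSpec(100.0, 5000)])
    founder_size: int = 200
    founder_law: tuple = ("uniform", 0.05, 0.95)
    samples_per_pop: int = 10
    generation_time: float = 3.0
    burnin: int = 0                # extra root generations before the first split
    pulses: list[Pulse] = field(default_factory=list)
    clades: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosomes = [c if isinstance(c, ChromSpec) else ChromSpec(*c)
                            for c in self.chromosomes]
        self.populations = [p if isinstance(p, PopSpec) else PopSpec(**p)
                            for p in self.populations]
        self.pulses = [p if isinstance(p, Pulse) else Pulse(**p)
                       for p in self.pulses]
        self.validate()

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        roots = [p for p in self.populations if p.parent is None]
        if len(roots) != 1:
            raise ValueError("exactly one root population required")
        by_name = {p.name: p for p in self.populations}
        for p in self.populations:
            if p.parent is None:
                continue
            if p.parent not in by_name:
                raise ValueError(f"unknown parent {p.parent!r}")
            if p.origin_gen is None or p.origin_gen < 0:
                raise ValueError(f"population {p.name!r}: split time must be >= 0")
            gp = by_name[p.parent]
            if gp.parent is not None and p.origin_gen >= gp.origin_gen:
                raise ValueError(
                    f"population {p.name!r} splits at {p.origin_gen}, not nested "
                    f"inside parent {p.parent!r} (origin {gp.origin_gen})")
        for pu in self.pulses:
            if not 0.0 <= pu.fraction <= 1.0:
                raise ValueError("pulse fraction must be in [0, 1]")
            if pu.source not in by_name or pu.target not in by_name:
                raise ValueError("pulse source/target must be configured populations")
        for c in self.chromosomes:
            if c.n_markers < 2:
                raise ValueError("each chromosome needs >= 2 markers")
            if c.length_cm < 0:
                raise ValueError("chromosome length must be >= 0 cM")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")

    @property
    def root(self) -> PopSpec:
        return next(p for p in self.populations if p.parent is None)

    @property
    def leaves(self) -> list[PopSpec]:
        parents = {p.parent for p in self.populations if p.parent is not None}
        return [p for p in self.populations if p.name not in parents]

    def size_of(self, name: str) -> int:
        p = next(p for p in self.populations if p.name == name)
        return p.size if p.size is not None else self.founder_size

    def pair_split_gen(self, a: str, b: str) -> int:
        """Generations before sampling at which the lineages of leaf
        populations ``a`` and ``b`` diverge (origin of the children of
        their most recent common ancestral population)."""
        by_name = {p.name: p for p in self.populations}

        def path(n):
            out = [n]
            while by_name[n].parent is not None:
                n = by_name[n].parent
                out.append(n)
            return out

        pa, pb = path(a), path(b)
        common = set(pa) & set(pb)
        if not common:
            raise ValueError("populations share no ancestor")
        # first common ancestor along a's path
        mrca = next(n for n in pa if n in common)
        if mrca in (a, b):
            return 0
        child_a = pa[pa.index(mrca) - 1]
        return by_name[child_a].origin_gen


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulation."""
    split_generations: dict[tuple[str, str], int]
    split_years: dict[tuple[str, str], float]
    pulses: list[Pulse]
    founder_freqs: np.ndarray
    generation_time: float
    seed: int

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "generation_time": self.generation_time,
            "split_generations": {f"{a}|{b}": g
                                  for (a, b), g in self.split_generations.items()},
            "split_years": {f"{a}|{b}": y
                            for (a, b), y in self.split_years.items()},
            "pulses": [vars(p) for p in self.pulses],
            "founder_freqs": [round(float(f), 6) for f in self.founder_freqs],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _build_marker_map(chromosomes: list[ChromSpec]) -> MarkerMap:
    chroms, ids, bps, cms = [], [], [], []
    for k, c in enumerate(chromosomes, 1):
        cm = np.linspace(0.0, c.length_cm, c.n_markers)
        bp = np.round(cm * BP_PER_CM).astype(np.int64) + 1
        if len(np.unique(bp)) != len(bp):      # degenerate cM spacing: fall back to index grid
            bp = np.arange(1, c.n_markers + 1, dtype=np.int64) * 1000
        chroms += [str(k)] * c.n_markers
        ids += [f"chr{k}_m{j}" for j in range(c.n_markers)]
        bps.append(bp)
        cms.append(cm)
    n = len(chroms)
    return MarkerMap(chroms, ids, np.concatenate(bps), np.concatenate(cms),
                     np.array(["A"] * n, dtype=object),
                     np.array(["C"] * n, dtype=object))


def _founder_freqs(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = law[0]
    if name == "uniform":
        lo, hi = law[1], law[2]
        return rng.uniform(lo, hi, n)
    if name == "beta":
        a, b = law[1], law[2]
        return rng.beta(a, b, n)
    if name == "fixed":
        return np.full(n, float(law[1]))
    raise ValueError(f"unknown founder frequency law {name!r}")


class _Recombinator:
    """Draws recombinant gametes from a pool, per chromosome.

    Crossover counts are Poisson(map length in Morgans) per chromosome and
    gamete, with crossover positions uniform in cM. Markers of one
    chromosome occupy a contiguous column block, so the common
    few-crossover case reduces to block copies.
    """

    def __init__(self, markers: MarkerMap):
        self.blocks = []           # (col start, col end, cM offsets, Morgans)
        for idx in markers.chromosome_indices().values():
            a, b = int(idx[0]), int(idx[-1]) + 1
            if not np.array_equal(idx, np.arange(a, b)):
                raise ValueError("markers of a chromosome must be contiguous")
            cm = markers.cm[a:b]
            self.blocks.append((a, b, cm - cm[0], (cm[-1] - cm[0]) / 100.0))

    def gametes(self, pool: np.ndarray, parents: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
        """One gamete per entry of ``parents`` (indices into pool diploids)."""
        g = len(parents)
        out = np.empty((g, pool.shape[1]), dtype=np.int8)
        for a, b, cm, morgans in self.blocks:
            start = rng.integers(0, 2, g)
            # bulk copy of the starting haplotype for every gamete
            np.take(pool[:, a:b], 2 * parents + start, axis=0, out=out[:, a:b])
            n_cross = rng.poisson(morgans, g) if morgans > 0 else np.zeros(g, np.int64)
            for gi in np.flatnonzero(n_cross):
                pos = np.sort(rng.uniform(0.0, morgans * 100.0, n_cross[gi]))
                cuts = np.searchsorted(cm, pos, side="left")
                cuts = np.append(cuts, b - a)
                other = pool[2 * parents[gi] + (1 - start[gi]), a:b]
                # segments between odd/even cuts come from the other haplotype
                for k in range(0, len(cuts) - 1, 2):
                    lo, hi = cuts[k], cuts[k + 1]
                    if hi > lo:
                        out[gi, a + lo:a + hi] = other[lo:hi]
        return out


def _wf_generation(pool: np.ndarray, n_offspring: int, recomb: _Recombinator,
                   rng: np.random.Generator,
                   alt_pool: np.ndarray | None = None,
                   alt_fraction: float = 0.0) -> np.ndarray:
    """One generation of random mating; each parent may be redrawn from
    ``alt_pool`` (an admixture source) with probability ``alt_fraction``."""
    n_parents = pool.shape[0] // 2
    if n_parents < 2:
        raise ValueError("population size fell below 2 diploids")
    child = np.empty((2 * n_offspring, pool.shape[1]), dtype=np.int8)
    for slot in (0, 1):            # maternal / paternal gamete
        parents = rng.integers(0, n_parents, n_offspring)
        if alt_pool is not None and alt_fraction > 0:
            from_alt = rng.random(n_offspring) < alt_fraction
            alt_parents = rng.integers(0, alt_pool.shape[0] // 2, n_offspring)
            gam = recomb.gametes(pool, parents, rng)
            if from_alt.any():
                gam_alt = recomb.gametes(alt_pool, alt_parents[from_alt], rng)
                gam[from_alt] = gam_alt
        else:
            gam = recomb.gametes(pool, parents, rng)
        child[slot::2] = gam
    return child


@dataclass
class SimResult:
    panel: HaplotypePanel
    dataset: GenotypeDataset
    truth: SimTruth


def simulate(config: DemographyConfig) -> SimResult:
    """Run the configured demography; returns phased panel, diploid
    genotypes, and the truth ledger. Identical config+seed gives
    bit-identical output."""
    rng = np.random.default_rng(config.seed)
    markers = _build_marker_map(config.chromosomes)
    recomb = _Recombinator(markers)
    m = markers.n_markers

    freqs = _founder_freqs(config.founder_law, m, rng)
    root = config.root
    root_size = config.size_of(root.name)
    pools: dict[str, np.ndarray] = {
        root.name: (rng.random((2 * root_size, m)) < freqs[None, :]).astype(np.int8)
    }

    splits: dict[int, list[PopSpec]] = {}
    for p in config.populations:
        if p.parent is not None:
            splits.setdefault(p.origin_gen, []).append(p)
    oldest = max(splits) if splits else 0
    start_gen = oldest + config.burnin

    pulses_by_gen: dict[int, list[Pulse]] = {}
    for pu in config.pulses:
        pulses_by_gen.setdefault(pu.generation, []).append(pu)

    for gen in range(start_gen, 0, -1):
        # splits scheduled at this time: children copy the parent pool
        if gen in splits:
            for child in sorted(splits[gen], key=lambda p: p.name):
                pools[child.name] = pools[child.parent].copy()
            for child in splits[gen]:
                parents_still_needed = any(
                    q.parent == child.parent and q.origin_gen < gen
                    for q in config.populations if q.parent is not None)
                if not parents_still_needed and child.parent in pools:
                    del pools[child.parent]
        active_pulses = pulses_by_gen.get(gen, [])
        next_pools = {}
        for name in sorted(pools):
            size = config.size_of(name)
            alt_pool, alt_frac = None, 0.0
            for pu in active_pulses:
                if pu.target == name:
                    alt_pool, alt_frac = pools[pu.source], pu.fraction
            next_pools[name] = _wf_generation(pools[name], size, recomb, rng,
                                              alt_pool, alt_frac)
        pools = next_pools

    # degenerate split-at-sampling-time: branches copy the pool, no drift
    if 0 in splits:
        for child in sorted(splits[0], key=lambda p: p.name):
            pools[child.name] = pools[child.parent].copy()

    # sample leaves without replacement
    leaves = sorted(config.leaves, key=lambda p: config.populations.index(p))
    sids, breeds, clades = [], [], []
    hap_rows = []
    for leaf in leaves:
        pool = pools[leaf.name]
        n_ind = pool.shape[0] // 2
        k = config.samples_per_pop
        if k > n_ind:
            raise ValueError(f"cannot sample {k} from {n_ind} individuals in {leaf.name}")
        chosen = np.sort(rng.choice(n_ind, size=k, replace=False))
        for ci in chosen:
            hap_rows.append(pool[2 * ci])
            hap_rows.append(pool[2 * ci + 1])
        sids += [f"{leaf.name}_{i:03d}" for i in range(k)]
        breeds += [leaf.name] * k
        clade_map = config.clades or {}
        clades += [clade_map.get(leaf.name)] * k

    samples = make_sample_table(sids, breeds, clades)
    panel = HaplotypePanel(markers, samples, np.array(hap_rows, dtype=np.int8))
    dataset = panel.to_genotypes()

    split_gens, split_years = {}, {}
    names = [p.name for p in leaves]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g = config.pair_split_gen(names[i], names[j])
            split_gens[(names[i], names[j])] = g
            split_years[(names[i], names[j])] = g * config.generation_time
    truth = SimTruth(split_gens, split_years, list(config.pulses), freqs,
                     config.generation_time, config.seed)
    return SimResult(panel, dataset, truth)


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def two_population_config(split_gen: int, seed: int = 0, burnin: int = 100,
                          root_size: int = 500, **kw) -> DemographyConfig:
    """Founder pool splitting into populations A and B ``split_gen``
    generations before sampling.

    ``burnin`` generations of random mating in a root pool of
    ``root_size`` diploids precede the split, giving the ancestral pool
    realistic identity-by-descent structure: without it the founders are
    unrelated i.i.d. draws and nothing is shared across the split
    regardless of its age. The root is larger than the breed branches so
    that drift does not fix most markers before the radiation starts.
    """
    pops = [PopSpec("ANC", size=root_size),
            PopSpec("A", "ANC", split_gen), PopSpec("B", "ANC", split_gen)]
    return DemographyConfig(populations=pops, seed=seed, burnin=burnin, **kw)


def single_population_config(generations: int, seed: int = 0, **kw) -> DemographyConfig:
    """One population drifting for ``generations`` generations."""
    pops = [PopSpec("POP")]
    return DemographyConfig(populations=pops, burnin=generations, seed=seed, **kw)


def clade_config(n_clades: int = 3, breeds_per_clade: int = 3,
                 within_gen: int = 15, across_gen: int = 150,
                 seed: int = 0, burnin: int = 100, root_size: int = 500,
                 **kw) -> DemographyConfig:
    """Radiation of ``n_clades`` clades splitting ``across_gen`` generations
    ago, each then radiating into ``breeds_per_clade`` breeds
    ``within_gen`` generations ago. Breeds are named C<k>B<j> and the clade
    map is filled in. ``burnin`` pre-split root generations in a
    ``root_size`` pool give the ancestral pool its haplotype-sharing
    structure."""
    kw["burnin"] = burnin
    pops = [PopSpec("ANC", size=root_size)]
    clades = {}
    for k in range(1, n_clades + 1):
        pops.append(PopSpec(f"C{k}", "ANC", across_gen))
        for j in range(1, breeds_per_clade + 1):
            name = f"C{k}B{j}"
            pops.append(PopSpec(name, f"C{k}", within_gen))
            clades[name] = f"clade{k}"
    return DemographyConfig(populations=pops, clades=clades, seed=seed, **kw)


def make_calibration_panel(base_config: DemographyConfig,
                           split_times: list[int],
                           seed: int,
                           independent: bool = False,
                           ) -> list[tuple[str, float, HaplotypePanel]]:
    """Population pairs with known split times, for calibration fitting.

    Returns ``(pair_label, true_years, panel)`` tuples; ``true_years`` is
    generations x the base config's generation time.

    By default all pairs branch off one shared ancestral pool in a single
    simulation, the way real calibration breed pairs share one genomic
    background; this cancels the ancestral-pool realization noise that
    otherwise dominates the fitted line. ``independent=True`` instead runs
    one isolated two-population simulation per split time.
    """
    if len(split_times) < 2:
        raise ValueError("need at least two split times")
    if len(set(split_times)) != len(split_times):
        raise ValueError("split times must be distinct")
    root_size = base_config.size_of(base_config.root.name)
    common = dict(chromosomes=base_config.chromosomes,
                  founder_size=base_config.founder_size,
                  founder_law=base_config.founder_law,
                  samples_per_pop=base_config.samples_per_pop,
                  generation_time=base_config.generation_time,
                  burnin=base_config.burnin)
    out = []
    if independent:
        seeds = np.random.SeedSequence(seed).generate_state(len(split_times)) % (2 ** 31)
        for t, s in zip(split_times, seeds):
            cfg = DemographyConfig(
                populations=[PopSpec("ANC", size=root_size),
                             PopSpec(f"A{t}", "ANC", int(t)),
                             PopSpec(f"B{t}", "ANC", int(t))],
                seed=int(s), **common)
            res = simulate(cfg)
            out.append((f"A{t}-B{t}", t * base_config.generation_time, res.panel))
        return out

    pops = [PopSpec("ANC", size=root_size)]
    for t in split_times:
        pops.append(PopSpec(f"A{t}", "ANC", int(t)))
        pops.append(PopSpec(f"B{t}", "ANC", int(t)))
    cfg = DemographyConfig(populations=pops, seed=int(seed) % (2 ** 31), **common)
    res = simulate(cfg)
    breeds = res.panel.samples["breed"].to_numpy()
    for t in split_times:
        idx = np.flatnonzero((breeds == f"A{t}") | (breeds == f"B{t}"))
        out.append((f"A{t}-B{t}", t * base_config.generation_time,
                    res.panel.subset_samples(idx)))
    return out
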