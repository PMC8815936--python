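"""Forward-time diploid Wright-Fisher simulation with selection and linkage.

The population is a matrix of 2N haplotypes over the currently
segregating sites (infinite-sites, biallelic).  Each generation:

* parents are drawn proportional to multiplicative fitness (fecundity
  selection); with probability beta an offspring is selfed and takes
  both gametes from a single fitness-weighted parent;
* each gamete receives Poisson(total map length) crossovers placed
  uniformly on the Morgan scale (no interference) and Poisson(mu*L) new
  mutations at uniform bp positions (collisions redrawn);
* fixed and lost mutations are pruned (fixed counts retained).

Coordinates are 0-based half-open bp; map positions are in Morgans.
All randomness flows from a single numpy Generator seeded per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .selection import draw_effects, population_log_fitness

__all__ = ["Population", "HaplotypeSample", "MutationRecord", "SimulationResult",
           "initialize_population", "step_generation", "run_simulation"]


@dataclass(frozen=True)
class MutationRecord:
    id: int
    position_bp: int
    s: float
    h: float
    origin_generation: int


@dataclass
class Population:
    """2N haplotypes over segregating sites, plus the mutation registry.

    Column (site) order is arbitrary during the forward pass; samples are
    sorted by bp position when drawn.
    """

    generation: int
    haplotypes: np.ndarray          # (2N, S) uint8
    positions_bp: np.ndarray        # (S,) int64, sorted
    map_positions: np.ndarray       # (S,) float, Morgans
    s: np.ndarray                   # (S,) float
    h: np.ndarray                   # (S,) float
    origin_generation: np.ndarray   # (S,) int
    mutation_ids: np.ndarray        # (S,) int64
    next_mutation_id: int = 0
    n_fixed: int = 0
    parent_assignments: np.ndarray | None = None   # (N, 2) diploid parent indices
    family_size_counts: np.ndarray | None = None   # gametes contributed per parent

    @property
    def n_diploids(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def mutation_registry(self) -> list[MutationRecord]:
        return [MutationRecord(int(i), int(p), float(s), float(h), int(g))
                for i, p, s, h, g in zip(self.mutation_ids, self.positions_bp,
                                         self.s, self.h, self.origin_generation)]


@dataclass(frozen=True)
class HaplotypeSample:
    """n_h phased haplotypes over the sites segregating in the sample."""

    matrix: np.ndarray           # (n_h, S) uint8
    positions_bp: np.ndarray     # (S,) int64, sorted
    map_positions: np.ndarray    # (S,) Morgans
    sequence_length_bp: int
    chrom: str = "1"

    def __post_init__(self):
        counts = self.matrix.sum(axis=0)
        if self.matrix.size and (counts.min() == 0 or counts.max() == self.matrix.shape[0]):
            raise ValueError("sample contains a fixed or lost column")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, min_maf: float) -> "HaplotypeSample":
        keep = self.minor_allele_frequencies() >= min_maf
        return HaplotypeSample(self.matrix[:, keep], self.positions_bp[keep],
                               self.map_positions[keep], self.sequence_length_bp, self.chrom)

    def pi(self) -> float:
        """Unbiased per-site nucleotide diversity, averaged over the full sequence."""
        n = self.n_haplotypes
        p = self.allele_frequencies()
        return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1)) / self.sequence_length_bp)


@dataclass
class SimulationResult:
    sample: HaplotypeSample
    config: SimulationConfig
    census_per_generation: np.ndarray
    vk_per_generation: np.ndarray
    n_fixed: int
    diversity: dict = field(default_factory=dict)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def initialize_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Starting state: mutation-free, or at neutral mutation-drift equilibrium.

    Equilibrium initialization draws the number of segregating sites from
    Poisson(theta*L*H_{2N-1}) with theta = 4*N*mu, site frequencies from the
    neutral SFS (P(i) proportional to 1/i on i = 1..2N-1 copies), and assigns
    carrier haplotypes independently across sites (linkage equilibrium).
    All initial sites are neutral; under selection models the selected
    variants accumulate during the forward burn-in.
    """
    n0 = config.initial_census
    two_n = 2 * n0
    if config.burn_in == "full" or config.mutation_rate == 0.0:
        s_count = 0
    else:
        theta_l = 4.0 * n0 * config.mutation_rate * config.sequence_length_bp
        expected = theta_l * _harmonic(two_n - 1)
        if expected > config.max_init_sites:
            raise ValueError(
                f"expected {expected:.0f} segregating sites exceeds max_init_sites="
                f"{config.max_init_sites}; reduce theta*L or raise the cap")
        s_count = int(rng.poisson(expected))
    positions = _draw_unique_positions(s_count, config.sequence_length_bp,
                                       np.empty(0, dtype=np.int64), rng)
    positions.sort()
    haplotypes = np.zeros((two_n, s_count), dtype=np.uint8)
    if s_count:
        classes = np.arange(1, two_n)
        weights = 1.0 / classes
        copies = rng.choice(classes, size=s_count, p=weights / weights.sum())
        # exactly `copies` carriers per site, drawn uniformly without
        # replacement; carrier sets are independent across sites (LE)
        u = rng.random((s_count, two_n))
        kth = np.sort(u, axis=1)[np.arange(s_count), copies - 1]
        haplotypes = np.ascontiguousarray((u <= kth[:, None]).T.astype(np.uint8))
    map_pos = np.asarray(config.recombination_map.morgans_at(positions), dtype=float)
    return Population(
        generation=0,
        haplotypes=np.ascontiguousarray(haplotypes),
        positions_bp=positions,
        map_positions=map_pos,
        s=np.zeros(s_count),
        h=np.full(s_count, 0.5),
        origin_generation=np.zeros(s_count, dtype=np.int64),
        mutation_ids=np.arange(s_count, dtype=np.int64),
        next_mutation_id=s_count,
    )


def _draw_unique_positions(k: int, length: int, existing: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """k distinct bp positions avoiding `existing` (infinite sites)."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    existing_sorted = np.sort(existing)
    pos = rng.integers(0, length, size=k, dtype=np.int64)
    while True:
        if len(existing_sorted):
            idx = np.minimum(np.searchsorted(existing_sorted, pos), len(existing_sorted) - 1)
            bad = existing_sorted[idx] == pos
        else:
            bad = np.zeros(k, dtype=bool)
        # intra-batch duplicates: mark all but the first occurrence
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        dup = np.zeros(k, dtype=bool)
        dup[order[1:]] = sorted_pos[1:] == sorted_pos[:-1]
        bad |= dup
        if not bad.any():
            return pos
        pos[bad] = rng.integers(0, length, size=int(bad.sum()), dtype=np.int64)


def _fitness_probabilities(pop: Population) -> np.ndarray | None:
    """Parent-sampling probabilities; None means uniform (all w equal)."""
    sel = pop.s != 0.0
    if not sel.any():
        return None
    geno = (pop.haplotypes[0::2][:, sel].astype(np.int8)
            + pop.haplotypes[1::2][:, sel].astype(np.int8))
    logw = population_log_fitness(geno, pop.s[sel], pop.h[sel])
    logw = logw - logw.max()
    w = np.exp(logw)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise RuntimeError("population inviable: all fitness values are zero")
    return w / total


def step_generation(pop: Population, config: SimulationConfig,
                    rng: np.random.Generator, n_next: int | None = None) -> Population:
    """Advance the population one Wright-Fisher generation."""
    n_prev = pop.n_diploids
    if n_next is None:
        n_next = config.census_at(pop.generation + 1)
    probs = _fitness_probabilities(pop)
    beta = config.selfing_fraction

    # --- parent choice -------------------------------------------------
    def draw_parents(size):
        if probs is None:
            return rng.integers(0, n_prev, size=size)
        return rng.choice(n_prev, size=size, p=probs)

    parents = np.empty((n_next, 2), dtype=np.int64)
    parents[:, 0] = draw_parents(n_next)
    parents[:, 1] = draw_parents(n_next)
    if beta > 0:
        selfed = rng.random(n_next) < beta
        parents[selfed, 1] = parents[selfed, 0]

    # --- gametes: recombination ---------------------------------------
    gamete_parent = parents.reshape(-1)                      # (2 n_next,)
    total_m = config.recombination_map.total_morgans
    n_gametes = 2 * n_next
    start_hap = rng.integers(0, 2, size=n_gametes)
    n_co = rng.poisson(total_m, size=n_gametes) if total_m > 0 else np.zeros(n_gametes, dtype=np.int64)
    rows = 2 * gamete_parent + start_hap
    new_h = pop.haplotypes[rows]                             # copy; fixed below for recombinants
    recomb = np.nonzero(n_co > 0)[0]
    mp = pop.map_positions
    for g in recomb:
        cuts = np.sort(rng.random(n_co[g]) * total_m)
        parity = (np.searchsorted(cuts, mp, side="right") % 2).astype(bool)
        a = pop.haplotypes[2 * gamete_parent[g] + start_hap[g]]
        b = pop.haplotypes[2 * gamete_parent[g] + 1 - start_hap[g]]
        new_h[g] = np.where(parity, b, a)

    # --- prune fixed/lost among inherited sites ------------------------
    counts = new_h.sum(axis=0)
    fixed = counts == n_gametes
    keep = (counts > 0) & ~fixed
    n_fixed = pop.n_fixed + int(fixed.sum())
    new_h = new_h[:, keep]
    kept_pos = pop.positions_bp[keep]
    kept_map = pop.map_positions[keep]
    kept_s = pop.s[keep]
    kept_hh = pop.h[keep]
    kept_orig = pop.origin_generation[keep]
    kept_ids = pop.mutation_ids[keep]

    # --- new mutations (appended; column order is arbitrary) ------------
    mu_l = config.mutation_rate * config.sequence_length_bp
    n_mut = rng.poisson(mu_l, size=n_gametes) if mu_l > 0 else np.zeros(n_gametes, dtype=np.int64)
    k = int(n_mut.sum())
    if k:
        mut_pos = _draw_unique_positions(k, config.sequence_length_bp, kept_pos, rng)
        mut_s, mut_h = draw_effects(config.dfe, k, rng)
        carriers = np.repeat(np.arange(n_gametes), n_mut)
        mut_cols = np.zeros((n_gametes, k), dtype=np.uint8)
        mut_cols[carriers, np.arange(k)] = 1
        new_h = np.concatenate([new_h, mut_cols], axis=1)
        kept_pos = np.concatenate([kept_pos, mut_pos])
        mut_map = np.asarray(config.recombination_map.morgans_at(mut_pos), dtype=float)
        kept_map = np.concatenate([kept_map, mut_map])
        kept_s = np.concatenate([kept_s, mut_s])
        kept_hh = np.concatenate([kept_hh, mut_h])
        kept_orig = np.concatenate([kept_orig,
                                    np.full(k, pop.generation + 1, dtype=np.int64)])
        kept_ids = np.concatenate([kept_ids,
                                   pop.next_mutation_id + np.arange(k, dtype=np.int64)])

    family = np.bincount(gamete_parent, minlength=n_prev)
    return Population(
        generation=pop.generation + 1,
        haplotypes=new_h,
        positions_bp=kept_pos,
        map_positions=kept_map,
        s=kept_s,
        h=kept_hh,
        origin_generation=kept_orig,
        mutation_ids=kept_ids,
        next_mutation_id=pop.next_mutation_id + k,
        n_fixed=n_fixed,
        parent_assignments=parents,
        family_size_counts=family,
    )


def sample_haplotypes(pop: Population, n_diploids: int, rng: np.random.Generator,
                      sequence_length_bp: int, chrom: str = "1") -> HaplotypeSample:
    """Sample n diploids (2n haplotypes) without replacement."""
    if n_diploids > pop.n_diploids:
        raise ValueError(f"sample_size {n_diploids} exceeds census {pop.n_diploids}")
    chosen = rng.choice(pop.n_diploids, size=n_diploids, replace=False)
    rows = np.sort(np.concatenate([2 * chosen, 2 * chosen + 1]))
    mat = pop.haplotypes[rows]
    counts = mat.sum(axis=0)
    seg = np.nonzero((counts > 0) & (counts < 2 * n_diploids))[0]
    seg = seg[np.argsort(pop.positions_bp[seg], kind="stable")]
    return HaplotypeSample(np.ascontiguousarray(mat[:, seg]), pop.positions_bp[seg],
                           pop.map_positions[seg], sequence_length_bp, chrom)


def run_simulation(config: SimulationConfig, rng: np.random.Generator | None = None,
                   chrom: str = "1") -> SimulationResult:
    """Run a full scenario and sample at the final generation."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, rng)
    census = np.empty(config.n_generations + 1, dtype=np.int64)
    vk = np.full(config.n_generations + 1, np.nan)
    census[0] = pop.n_diploids
    for g in range(1, config.n_generations + 1):
        pop = step_generation(pop, config, rng, config.census_at(g))
        census[g] = pop.n_diploids
        vk[g] = float(np.var(pop.family_size_counts))
    sample = sample_haplotypes(pop, config.sample_size, rng,
                               config.sequence_length_bp, chrom)
    diversity = {
        "pi_sample": sample.pi(),
        "segregating_sites_sample": sample.n_sites,
        "segregating_sites_population": pop.n_sites,
    }
    return SimulationResult(sample=sample, config=config,
                            census_per_generation=census,
                            vk_per_generation=vk, n_fixed=pop.n_fixed,
                            diversity=diversity)
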