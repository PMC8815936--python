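"""Simulation scenario configuration and population-genetic rescaling."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .maps import RecombinationMap
from .selection import DFEConfig

__all__ = ["SimulationConfig", "rescale_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """One forward-simulation scenario.

    `census_trajectory` lists (generation_index, N) change points; the
    census is piecewise constant from each index on, starting at index 0.
    `burn_in` selects the starting state: ``equilibrium_init`` draws
    segregating sites from the neutral mutation-drift SFS at linkage
    equilibrium, ``full`` starts mutation-free.
    """

    census_trajectory: tuple
    sequence_length_bp: int
    mutation_rate: float
    recombination_map: RecombinationMap
    dfe: DFEConfig = field(default_factory=DFEConfig)
    selfing_fraction: float = 0.0
    n_generations: int = 0
    burn_in: str = "equilibrium_init"
    sample_size: int = 50
    seed: int = 0
    rescale_factor: float = 1.0
    max_init_sites: int = 500_000

    def __post_init__(self):
        traj = tuple((int(g), int(n)) for g, n in self.census_trajectory)
        object.__setattr__(self, "census_trajectory", traj)
        gens = [g for g, _ in traj]
        if not traj or gens[0] != 0:
            raise ValueError("census_trajectory must start at generation 0")
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("census trajectory generations must be strictly increasing")
        if any(n < 2 for _, n in traj):
            raise ValueError("census sizes must be >= 2")
        if gens[-1] > self.n_generations:
            raise ValueError("census trajectory references a generation beyond n_generations")
        if self.mutation_rate < 0 or not np.isfinite(self.mutation_rate * self.sequence_length_bp):
            raise ValueError("mutation rate must be >= 0 and mu*L finite")
        if not 0.0 <= self.selfing_fraction <= 1.0:
            raise ValueError("selfing_fraction must be in [0, 1]")
        if self.sequence_length_bp != self.recombination_map.length_bp:
            raise ValueError("recombination map length must equal sequence_length_bp")
        if self.burn_in not in ("equilibrium_init", "full"):
            raise ValueError("burn_in must be 'equilibrium_init' or 'full'")
        if self.rescale_factor <= 0:
            raise ValueError("rescale_factor must be positive")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")

    def census_at(self, generation: int) -> int:
        n = self.census_trajectory[0][1]
        for g, size in self.census_trajectory:
            if generation >= g:
                n = size
            else:
                break
        return n

    @property
    def initial_census(self) -> int:
        return self.census_trajectory[0][1]

    @property
    def final_census(self) -> int:
        return self.census_at(self.n_generations)


def rescale_config(config: SimulationConfig, q: float) -> SimulationConfig:
    """Rescale a scenario by Q, preserving N*mu, N*(map length) and N*s.

    Census sizes and generation counts shrink by Q; the mutation rate, map
    rates and selection coefficients grow by Q.  Standard desk-scaling of
    large scenarios; Q = 1 is the identity.
    """
    if q < 1:
        raise ValueError("Q must be >= 1")
    if q == 1:
        return config
    traj = tuple((int(round(g / q)), int(round(n / q))) for g, n in config.census_trajectory)
    if any(n < 20 for _, n in traj):
        raise ValueError("rescaled census below 20 diploids; choose a smaller Q")
    mu = config.mutation_rate * q
    if mu > 1:
        raise ValueError("rescaled mutation rate exceeds 1")
    m = config.recombination_map
    rmap = RecombinationMap(m.segment_starts_bp, m.rates_cm_per_mb * q, m.length_bp)
    dfe = config.dfe
    if dfe.p_selected > 0:
        dfe = replace(dfe, gamma_mean_abs_s=dfe.gamma_mean_abs_s * q, fixed_s=dfe.fixed_s * q)
    return replace(
        config,
        census_trajectory=traj,
        mutation_rate=mu,
        recombination_map=rmap,
        dfe=dfe,
        n_generations=int(round(config.n_generations / q)),
        rescale_factor=config.rescale_factor * q,
    )
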