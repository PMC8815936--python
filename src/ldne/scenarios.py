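"""Canonical desk-scale study scenarios.

These are the configurations the analysis drivers, the test suite and
the acceptance script all share, so every consumer measures the same
conditions:

* ``constant_size_config`` — census 1000, ~2 Mb, equilibrium-initialized
  and run 600 further generations (LD at the shallowest c window used,
  0.0025, equilibrates on the 1/(2c) = 200-generation timescale, so 600
  generations of forward burn-in suffice after the linkage-equilibrium
  start).  The map rate is chosen so pair distances cover
  c in [0.0025, 0.025], the window over which bin estimates are averaged
  into a single Ne_LD.
* ``tight_linkage_config`` — a Q = 5 rescale of the extreme
  low-recombination scenario (census 1000, 100 Mb at 0.01 cM/Mb, i.e. a
  1 cM genome): census 200, total map 5 cM, per-gamete deleterious input
  0.25 and selection coefficients scaled by Q.  The sequence is shrunk
  to 1 Mb, which preserves the per-gamete totals that drive linked
  selection while keeping the SNP budget at desk scale.
* ``step_change_config`` — census 1000 dropping to 250 thirty
  generations before sampling, for the historical-trajectory check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .estimate import (LDBin, bin_pairs, historical_trajectory,
                       mean_ne_in_c_window, ne_from_bin, ne_from_pi, pairwise_r2)
from .maps import RecombinationMap
from .selection import DFEConfig
from .simulate import run_simulation

__all__ = ["constant_size_config", "tight_linkage_config", "step_change_config",
           "ne_estimates_for_run", "replicate_ne_estimates",
           "pooled_tight_linkage_ne", "trajectory_step_contrast",
           "C_WINDOW_LOW", "C_WINDOW_HIGH"]

# the c window whose bin estimates are averaged into one Ne_LD
C_WINDOW_LOW = 0.0025
C_WINDOW_HIGH = 0.0250


def constant_size_config(model: str = "neutral", seed: int = 0,
                         census: int = 1000,
                         rr_cm_per_mb: float | None = None,
                         selfing_fraction: float = 0.0) -> SimulationConfig:
    """Constant census, ~equilibrium scenario (desk scale).

    Default map rates: 1.25 cM/Mb for the neutral run (pairs reach
    c = 0.025 on 2 Mb) and 1 cM/Mb under selection models, matching the
    uniform-rate scenario the selection comparison is made at.
    """
    if rr_cm_per_mb is None:
        rr_cm_per_mb = 1.25 if model == "neutral" else 1.0
    length = 2_000_000
    return SimulationConfig(
        census_trajectory=((0, census),),
        sequence_length_bp=length,
        mutation_rate=2e-8,
        recombination_map=RecombinationMap.uniform(length, rr_cm_per_mb),
        dfe=DFEConfig.for_model(model),
        selfing_fraction=selfing_fraction,
        n_generations=600,
        sample_size=100,
        seed=seed,
    )


def tight_linkage_config(model: str = "neutral", seed: int = 0) -> SimulationConfig:
    """Q = 5 rescale of the 1 cM-genome scenario; shared total mutation
    rate so Ne_pi = pi/(4 mu) is comparable across models."""
    length = 1_000_000
    mu_total = 0.55 / length          # 0.30 neutral + 0.25 deleterious per gamete
    p_selected = 0.25 / 0.55
    if model == "neutral":
        dfe = DFEConfig()
    else:
        dfe = DFEConfig(model=model, p_selected=p_selected,
                        gamma_mean_abs_s=0.1)   # 0.02 * Q
    return SimulationConfig(
        census_trajectory=((0, 200),),
        sequence_length_bp=length,
        mutation_rate=mu_total,
        recombination_map=RecombinationMap.uniform(length, 5.0),
        dfe=dfe,
        n_generations=1600,   # 4 x 2N: linked-selection equilibration is slow
        sample_size=100,
        seed=seed,
        rescale_factor=5.0,
    )


def step_change_config(seed: int = 0) -> SimulationConfig:
    """Census 1000 for 600 generations, then 250 for the final 30."""
    length = 2_000_000
    return SimulationConfig(
        census_trajectory=((0, 1000), (600, 250)),
        sequence_length_bp=length,
        mutation_rate=2e-8,
        recombination_map=RecombinationMap.uniform(length, 10.0),
        n_generations=630,
        sample_size=100,
        seed=seed,
    )


def ne_estimates_for_run(config: SimulationConfig, maf_min: float = 0.05,
                         c_low: float = C_WINDOW_LOW,
                         c_high: float = C_WINDOW_HIGH) -> dict:
    """Run one replicate and estimate Ne_LD (c-window mean) and Ne_pi."""
    result = run_simulation(config)
    sample = result.sample.filter_maf(maf_min)
    pairs = pairwise_r2(sample)
    traj = historical_trajectory(bin_pairs(pairs), sample.n_haplotypes, phased=True)
    return {
        "seed": config.seed,
        "ne_ld": mean_ne_in_c_window(traj, c_low, c_high),
        "ne_pi": ne_from_pi(result.sample.pi(), config.mutation_rate),
        "pi": result.sample.pi(),
        "n_snps": sample.n_sites,
        "mean_vk": float(np.nanmean(result.vk_per_generation)),
    }


def replicate_ne_estimates(make_config, seeds) -> pd.DataFrame:
    """Replicate ne_estimates_for_run over seeds; `make_config(seed)`."""
    return pd.DataFrame([ne_estimates_for_run(make_config(int(s))) for s in seeds])


def pooled_tight_linkage_ne(model: str, seeds,
                            c_low: float = C_WINDOW_LOW,
                            c_high: float = C_WINDOW_HIGH) -> dict:
    """Tight-linkage comparison: pool SNP pairs across replicates (the
    per-replicate information content at a 5 cM map is low) and invert
    the pooled bin; Ne_pi is averaged across replicates."""
    cs, r2s, ne_pis = [], [], []
    n_h = None
    for seed in seeds:
        cfg = tight_linkage_config(model, int(seed))
        result = run_simulation(cfg)
        sample = result.sample.filter_maf(0.05)
        pairs = pairwise_r2(sample, c_min=c_low, c_max=c_high)
        cs.append(pairs.c)
        r2s.append(pairs.r2)
        n_h = sample.n_haplotypes
        ne_pis.append(ne_from_pi(result.sample.pi(), cfg.mutation_rate))
    c = np.concatenate(cs)
    r2 = np.concatenate(r2s)
    pooled = LDBin(c_low, c_high, len(c), float(c.mean()), float(r2.mean()))
    return {
        "model": model,
        "ne_ld": ne_from_bin(pooled, n_h, phased=True),
        "ne_pi": float(np.mean(ne_pis)),
        "n_pairs": len(c),
        "n_replicates": len(list(seeds)),
    }


def trajectory_step_contrast(seed: int, t_recent=(2.0, 15.0), t_old=(100.0, 250.0)) -> dict:
    """One step-demography replicate: mean Ne_LD in recent vs old t bins."""
    cfg = step_change_config(seed)
    result = run_simulation(cfg)
    sample = result.sample.filter_maf(0.05)
    traj = historical_trajectory(bin_pairs(pairwise_r2(sample)),
                                 sample.n_haplotypes, phased=True)
    def window_mean(lo, hi):
        sel = (traj.t >= lo) & (traj.t <= hi) & np.isfinite(traj.ne_hat)
        return float(traj.ne_hat[sel].mean()) if sel.any() else float("nan")
    return {
        "seed": seed,
        "ne_recent": window_mean(*t_recent),
        "ne_old": window_mean(*t_old),
        "trajectory": traj,
    }
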