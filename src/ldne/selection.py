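"""Distributions of fitness effects and multiplicative fitness.

Four mutation models are supported:

``neutral``
    every mutation has s = 0.
``bs`` (background selection)
    a fraction of new mutations is deleterious, with |s| drawn from a
    gamma distribution (default shape 0.2, mean 0.02) and additive gene
    action (h = 0.5); the rest are neutral.
``ss`` (selective sweeps)
    as ``bs`` but the selected fraction is advantageous (s > 0).
``od`` (overdominance)
    the selected fraction has a fixed s > 0 with dominance h > 1, i.e.
    heterozygote advantage.

Genotype fitness at one locus is 1, 1 + s h and 1 + s for the wild-type
homozygote, heterozygote and mutant homozygote; individual fitness is the
product over loci, floored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionModel", "DFEConfig", "draw_effects", "classify_new_mutation",
           "individual_fitness", "population_log_fitness"]

MODELS = ("neutral", "bs", "ss", "od")


class SelectionModel(str):
    """Model name; one of 'neutral', 'bs', 'ss', 'od'."""


@dataclass(frozen=True)
class DFEConfig:
    model: str = "neutral"
    p_selected: float = 0.0
    gamma_shape: float = 0.2
    gamma_mean_abs_s: float = 0.02
    fixed_s: float = 0.02
    fixed_h: float = 1.5

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown selection model {self.model!r}; expected one of {MODELS}")
        if not 0.0 <= self.p_selected <= 1.0:
            raise ValueError("p_selected must be in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_mean_abs_s <= 0:
            raise ValueError("gamma parameters must be positive")

    @classmethod
    def for_model(cls, model: str, **overrides) -> "DFEConfig":
        """Default parameterization of each mutation model."""
        defaults = {"neutral": 0.0, "bs": 0.05, "ss": 0.001, "od": 0.0001}
        if model not in defaults:
            raise ValueError(f"unknown selection model {model!r}")
        kw = {"model": model, "p_selected": defaults[model]}
        kw.update(overrides)
        return cls(**kw)


def draw_effects(dfe: DFEConfig, n: int, rng: np.random.Generator):
    """Draw (s, h) for `n` new mutations.  Vectorized.

    Gamma draws with s <= -1 (possible in the long tail at shape 0.2)
    are resampled so that 1 + s stays positive.
    """
    s = np.zeros(n)
    h = np.full(n, 0.5)
    if dfe.p_selected == 0.0 or n == 0:
        return s, h
    sel = rng.random(n) < dfe.p_selected
    k = int(sel.sum())
    if k == 0:
        return s, h
    if dfe.model == "bs":
        mag = _gamma_truncated(dfe, k, rng)
        s[sel] = -mag
    elif dfe.model == "ss":
        s[sel] = _gamma_truncated(dfe, k, rng, truncate=False)
    elif dfe.model == "od":
        s[sel] = dfe.fixed_s
        h[sel] = dfe.fixed_h
    else:  # neutral with p_selected > 0 is a contradiction
        raise ValueError("neutral model cannot have p_selected > 0")
    return s, h


def _gamma_truncated(dfe, k, rng, truncate=True):
    scale = dfe.gamma_mean_abs_s / dfe.gamma_shape
    mag = rng.gamma(dfe.gamma_shape, scale, size=k)
    if truncate:
        while True:
            bad = mag >= 1.0
            if not bad.any():
                break
            mag[bad] = rng.gamma(dfe.gamma_shape, scale, size=int(bad.sum()))
    return mag


def classify_new_mutation(dfe: DFEConfig, rng: np.random.Generator):
    """Single-mutation convenience wrapper around :func:`draw_effects`."""
    s, h = draw_effects(dfe, 1, rng)
    return float(s[0]), float(h[0])


def individual_fitness(hap1, hap2, s, h) -> float:
    """Multiplicative fitness of one diploid.

    `hap1`/`hap2` are 0/1 vectors over loci with effects `s` and
    dominance `h`.  Neutral loci (s = 0) contribute a factor of 1.
    """
    g = np.asarray(hap1, dtype=np.int8) + np.asarray(hap2, dtype=np.int8)
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    factors = np.ones_like(s)
    factors[g == 1] = 1.0 + s[g == 1] * h[g == 1]
    factors[g == 2] = 1.0 + s[g == 2]
    return float(max(np.prod(factors), 0.0))


def population_log_fitness(genotypes, s, h):
    """log-fitness for all individuals at the selected loci only.

    `genotypes` is an (N, k) dosage matrix over the k selected loci.
    Returns an N-vector of log w; -inf marks individuals driven to
    w <= 0 (possible only if some 1 + s h <= 0).
    """
    het = 1.0 + s * h
    hom = 1.0 + s
    if np.any(het <= 0) or np.any(hom <= 0):
        # fall back to the safe per-individual product with flooring
        n = genotypes.shape[0]
        out = np.empty(n)
        for i in range(n):
            g = genotypes[i]
            f = np.ones_like(s)
            f[g == 1] = het[g == 1]
            f[g == 2] = hom[g == 2]
            w = max(np.prod(f), 0.0)
            out[i] = np.log(w) if w > 0 else -np.inf
        return out
    lhet = np.log(het)
    lhom = np.log(hom)
    return (genotypes == 1) @ lhet + (genotypes == 2) @ lhom
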