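"""Effective population size estimators.

Three families:

* **LD-based** — squared allelic correlation r2 between SNP pairs, binned
  by recombination fraction c.  Each bin inverts the drift expectation
  E(r2) = 1/(alpha + 4 Ne c) + sample correction into an estimate of the
  ancestral Ne roughly t = 1/(2c) generations ago (Sved-type inversion
  with the Hayes c <-> time mapping).  Phased haplotype data uses the
  direct r2 with alpha = 1 and a 1/n_h correction; unphased genotypes use
  the Burrows-style composite correlation of dosages with alpha = 2 and a
  1/n correction.
* **Diversity-based** — Ne_pi = pi / (4 mu) at mutation-drift equilibrium.
* **Pedigree/analytic** — from the variance of family (gamete) sizes, and
  the closed form N/(1 + alpha), alpha = beta/(2 - beta), under partial
  self-fertilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import haldane_c
from .simulate import HaplotypeSample

__all__ = ["PairLD", "PairSet", "LDBin", "NeTrajectory", "RegionalNe",
           "pairwise_r2", "log_bins", "bin_pairs", "ne_from_bin",
           "historical_trajectory", "mean_ne_in_c_window", "regional_ne",
           "ne_from_pi", "ne_vk_analytic", "ne_vk_from_pedigree",
           "critical_sweep_c"]


@dataclass(frozen=True)
class PairLD:
    site_i: int
    site_j: int
    map_distance: float
    c: float
    r2: float


@dataclass(frozen=True)
class PairSet:
    """Columnar container of SNP-pair LD values."""

    site_i: np.ndarray
    site_j: np.ndarray
    c: np.ndarray
    r2: np.ndarray
    phased: bool
    n_haplotypes: int     # haplotypes if phased, else 2 * n diploids

    def __len__(self) -> int:
        return len(self.c)

    def __iter__(self):
        d = -0.5 * np.log1p(-2.0 * self.c)   # inverse Haldane, for reporting
        for i in range(len(self)):
            yield PairLD(int(self.site_i[i]), int(self.site_j[i]),
                         float(d[i]), float(self.c[i]), float(self.r2[i]))


@dataclass(frozen=True)
class LDBin:
    c_low: float
    c_high: float
    n_pairs: int
    mean_c: float
    mean_r2: float


def _r2_matrix(matrix: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all columns of a 0/1/2 matrix."""
    x = matrix.astype(float)
    x -= x.mean(axis=0)
    sd = np.sqrt((x ** 2).mean(axis=0))
    if np.any(sd == 0):
        raise ValueError("monomorphic site encountered; filter sites upstream")
    x /= sd
    r = (x.T @ x) / x.shape[0]
    return r ** 2


def pairwise_r2(sample: HaplotypeSample, phased: bool = True,
                c_min: float = 0.001, c_max: float = 0.5,
                max_pairs: int = 5_000_000,
                rng: np.random.Generator | None = None) -> PairSet:
    """All SNP-pair r2 values with recombination fraction in [c_min, c_max].

    With `phased=True`, r2 is the squared haplotype correlation
    (D^2 / (pA pa pB pb)); with `phased=False`, the squared composite
    (Burrows) correlation of genotype dosages.  c comes from the Morgan
    distance via the Haldane map function.  If more than `max_pairs`
    pairs qualify, a seeded uniform subsample is taken.
    """
    if sample.n_sites < 2:
        raise ValueError("need at least 2 segregating sites")
    if phased:
        mat = sample.matrix
        n_h = sample.n_haplotypes
    else:
        mat = sample.matrix[0::2].astype(np.int8) + sample.matrix[1::2].astype(np.int8)
        n_h = sample.n_haplotypes  # record haplotype count; correction uses n_h/2 diploids
    r2 = _r2_matrix(mat)
    d = np.abs(sample.map_positions[:, None] - sample.map_positions[None, :])
    c = haldane_c(d)
    iu, ju = np.triu_indices(sample.n_sites, k=1)
    cc = c[iu, ju]
    mask = (cc >= c_min) & (cc <= c_max) & (cc > 0)
    iu, ju, cc = iu[mask], ju[mask], cc[mask]
    rr = r2[iu, ju]
    if len(cc) > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        pick = rng.choice(len(cc), size=max_pairs, replace=False)
        iu, ju, cc, rr = iu[pick], ju[pick], cc[pick], rr[pick]
    return PairSet(iu, ju, cc, rr, phased, n_h)


def log_bins(c_min: float = 0.001, c_max: float = 0.5, n_bins: int = 30) -> np.ndarray:
    """Default logarithmic bin edges over the usable c range."""
    return np.geomspace(c_min, c_max, n_bins + 1)


def bin_pairs(pairs: PairSet, edges: np.ndarray | None = None,
              min_pairs: int = 100) -> list[LDBin]:
    """Aggregate pairs into c bins; bins under `min_pairs` are dropped."""
    if edges is None:
        edges = log_bins()
    idx = np.digitize(pairs.c, edges) - 1
    bins = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < min_pairs:
            continue
        bins.append(LDBin(float(edges[b]), float(edges[b + 1]), n,
                          float(pairs.c[sel].mean()), float(pairs.r2[sel].mean())))
    return bins


def ne_from_bin(ld_bin: LDBin, n_haplotypes: int, phased: bool = True) -> float:
    """Invert E(r2) = 1/(alpha + 4 Ne c) + correction for one bin.

    Returns NaN (an invalid-estimate flag, not an exception) when the
    corrected r2 is <= 0 or the inversion is non-finite; negative
    estimates are returned as-is so callers can apply exclusion rules.
    """
    if n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if phased:
        alpha, correction = 1.0, 1.0 / n_haplotypes
    else:
        alpha, correction = 2.0, 1.0 / (n_haplotypes // 2)
    r2_adj = ld_bin.mean_r2 - correction
    if r2_adj <= 0 or not np.isfinite(r2_adj):
        return float("nan")
    ne = (1.0 / r2_adj - alpha) / (4.0 * ld_bin.mean_c)
    return float(ne) if np.isfinite(ne) else float("nan")


@dataclass(frozen=True)
class NeTrajectory:
    """Historical Ne(t) from binned LD; t = 1/(2 mean_c) generations ago."""

    t: np.ndarray
    ne_hat: np.ndarray     # NaN marks invalid (flagged, not dropped)
    mean_c: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ne_hat": self.ne_hat,
                             "mean_c": self.mean_c, "n_pairs": self.n_pairs})


def historical_trajectory(bins: list[LDBin], n_haplotypes: int,
                          phased: bool = True) -> NeTrajectory:
    if not bins:
        raise ValueError("empty bin list")
    order = np.argsort([1.0 / (2.0 * b.mean_c) for b in bins])
    bins = [bins[i] for i in order]
    t = np.array([1.0 / (2.0 * b.mean_c) for b in bins])
    ne = np.array([ne_from_bin(b, n_haplotypes, phased) for b in bins])
    return NeTrajectory(t, ne,
                        np.array([b.mean_c for b in bins]),
                        np.array([b.n_pairs for b in bins], dtype=np.int64))


def mean_ne_in_c_window(traj: NeTrajectory, c_low: float = 0.0025,
                        c_high: float = 0.0250, weighted: bool = True) -> float:
    """Mean of valid bin estimates with mean c in [c_low, c_high].

    By default bins are weighted by their pair counts (roughly inverse
    variance), which keeps sparse small-c bins — the ones with the
    largest inversion bias — from dominating the average.
    """
    sel = (traj.mean_c >= c_low) & (traj.mean_c <= c_high) & np.isfinite(traj.ne_hat)
    if not sel.any():
        return float("nan")
    if weighted:
        return float(np.average(traj.ne_hat[sel], weights=traj.n_pairs[sel]))
    return float(traj.ne_hat[sel].mean())


@dataclass(frozen=True)
class RegionalNe:
    ne_hat: float          # NaN if insufficient pairs
    n_pairs: int
    mean_c: float
    sufficient: bool


def regional_ne(sample: HaplotypeSample, phased: bool = False,
                c_low: float = 1.0 / 100.0, c_high: float = 1.0 / 50.0,
                min_pairs: int = 250_000, max_pairs: int = 5_000_000,
                rng: np.random.Generator | None = None) -> RegionalNe:
    """Constant-size Ne for one genomic region from the pooled c in
    [1/100, 1/50] Morgans bin (unphased composite LD by default, matching
    genotype data of unknown phase)."""
    try:
        pairs = pairwise_r2(sample, phased=phased, c_min=c_low, c_max=c_high,
                            max_pairs=max_pairs, rng=rng)
    except ValueError:
        return RegionalNe(float("nan"), 0, float("nan"), False)
    n = len(pairs)
    if n < min_pairs:
        return RegionalNe(float("nan"), n, float("nan"), False)
    pooled = LDBin(c_low, c_high, n, float(pairs.c.mean()), float(pairs.r2.mean()))
    ne = ne_from_bin(pooled, pairs.n_haplotypes, phased)
    return RegionalNe(ne, n, pooled.mean_c, True)


# -- diversity and pedigree estimators ---------------------------------


def ne_from_pi(pi: float, mu: float) -> float:
    """Ne_pi = pi / (4 mu) at mutation-drift equilibrium."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (4.0 * mu)


def ne_vk_analytic(n: float, beta: float) -> float:
    """Ne from family-size variance under partial selfing:
    Ne = N / (1 + alpha) with alpha = beta / (2 - beta)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if n < 1:
        raise ValueError("N must be >= 1")
    alpha = beta / (2.0 - beta)
    return n / (1.0 + alpha)


def ne_vk_from_pedigree(family_gamete_counts, n: int) -> float:
    """Realized Ne from gamete counts k_i: Ne = (4N - 2)/(Vk + 2),
    the constant-size variance-effective size."""
    counts = np.asarray(family_gamete_counts)
    if counts.sum() != 2 * n:
        raise ValueError("gamete counts must sum to 2N")
    vk = float(np.var(counts))
    return (4.0 * n - 2.0) / (vk + 2.0)


def critical_sweep_c(s: float) -> float:
    """Recombination distance below which a sweep with homozygous advantage
    s generates LD between flanking neutral loci: c = 0.1 * s."""
    return 0.1 * s
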