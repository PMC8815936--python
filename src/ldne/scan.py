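"""Windowed genome scan: 2 cM regions, diversity statistics, regional
LD-based Ne, filtering rules and Spearman correlations.

The genome is partitioned into consecutive windows of equal *genetic*
length (2 cM by default) from the start of each chromosome's map;
trailing (telomeric) spans shorter than one window are dropped.  Within
each window the scan computes nucleotide diversity pi (denominator =
window bp length, monomorphic sites contribute zero), the proportion of
polymorphic sites P, mean SNP minor allele frequency, the mean
recombination rate, a regional constant-size Ne_LD from pairs at
c in [1/100, 1/50] Morgans, and window averages of annotation tracks.
Windows failing the pair-count or Ne-range rules are excluded before
correlation, with per-rule exclusion tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimate import regional_ne
from .maps import GenomeMap
from .simulate import HaplotypeSample

__all__ = ["GenomicWindow", "CorrelationResult", "partition_windows",
           "window_stats", "scan_windows", "filter_windows", "correlate",
           "correlation_matrix", "aggregate_track",
           "DIVERSITY_VARIABLES", "ANNOTATION_VARIABLES"]

logger = logging.getLogger(__name__)

DIVERSITY_VARIABLES = ("rr_mean", "b_mean", "P", "maf_mean", "lof_count",
                       "missense_count", "gene_density")
ANNOTATION_VARIABLES = ("b_mean", "lof_count", "missense_count", "gene_density")


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start_bp: int
    end_bp: int
    map_start: float       # Morgans
    map_end: float
    index: int


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n_windows: int
    reason: str | None = None   # set when rho is undefined


def partition_windows(genome_map: GenomeMap, window_morgans: float = 0.02) -> list[GenomicWindow]:
    """Consecutive equal-map-length windows per chromosome; trailing
    sub-window (telomeric) spans are dropped."""
    windows: list[GenomicWindow] = []
    idx = 0
    for chrom in genome_map:
        rmap = genome_map[chrom]
        n_win = int(np.floor(rmap.total_morgans / window_morgans + 1e-9))
        if n_win == 0:
            logger.info("chromosome %s map %.4f M shorter than one window; skipped",
                        chrom, rmap.total_morgans)
            continue
        edges_m = np.arange(n_win + 1) * window_morgans
        edges_bp = np.asarray([rmap.bp_at(m) for m in edges_m])
        for k in range(n_win):
            windows.append(GenomicWindow(chrom, int(round(edges_bp[k])),
                                         int(round(edges_bp[k + 1])),
                                         float(edges_m[k]), float(edges_m[k + 1]), idx))
            idx += 1
    return windows


def aggregate_track(windows: list[GenomicWindow], track: pd.DataFrame,
                    mode: str = "mean") -> np.ndarray:
    """Per-window value of a BED-like track (chrom, start, end, value).

    mode="mean": overlap-length-weighted mean of interval values.
    mode="midpoint_sum": sum of values of intervals whose midpoint falls
    in the window (the rule used for genes and variant counts).
    Windows with no overlapping interval get NaN (mean) or 0 (sums).
    """
    out = np.full(len(windows), np.nan if mode == "mean" else 0.0)
    for chrom, sub in track.groupby("chrom"):
        starts = sub["start"].to_numpy(float)
        ends = sub["end"].to_numpy(float)
        vals = sub["value"].to_numpy(float)
        mids = 0.5 * (starts + ends)
        for w in windows:
            if w.chrom != str(chrom):
                continue
            if mode == "midpoint_sum":
                sel = (mids >= w.start_bp) & (mids < w.end_bp)
                out[w.index] = vals[sel].sum()
            elif mode == "mean":
                ov = np.minimum(ends, w.end_bp) - np.maximum(starts, w.start_bp)
                sel = ov > 0
                if sel.any():
                    out[w.index] = np.average(vals[sel], weights=ov[sel])
            else:
                raise ValueError(f"unknown aggregation mode {mode!r}")
    return out


def window_stats(sample: HaplotypeSample, window: GenomicWindow,
                 maf_min: float = 0.05, min_pairs: int = 250_000,
                 phased: bool = False,
                 rng: np.random.Generator | None = None) -> dict:
    """Diversity statistics and regional Ne_LD for one window."""
    sel = (sample.positions_bp >= window.start_bp) & (sample.positions_bp < window.end_bp)
    length = window.end_bp - window.start_bp
    n_h = sample.n_haplotypes
    p = sample.matrix[:, sel].mean(axis=0)
    pi = float(np.sum(2.0 * p * (1.0 - p) * n_h / (n_h - 1)) / length)
    maf = np.minimum(p, 1 - p)
    span_m = window.map_end - window.map_start
    rr_mean = span_m * 100.0 / (length / 1e6)   # cM/Mb
    row = {
        "chrom": window.chrom, "start_bp": window.start_bp, "end_bp": window.end_bp,
        "window": window.index, "n_snps": int(sel.sum()),
        "pi": pi, "P": float(sel.sum() / length),
        "maf_mean": float(maf.mean()) if sel.any() else np.nan,
        "rr_mean": rr_mean,
    }
    if sel.sum() >= 2:
        sub = HaplotypeSample(sample.matrix[:, sel], sample.positions_bp[sel],
                              sample.map_positions[sel], sample.sequence_length_bp,
                              sample.chrom)
        if maf_min > 0:
            sub = sub.filter_maf(maf_min)
        if sub.n_sites >= 2:
            reg = regional_ne(sub, phased=phased, min_pairs=min_pairs, rng=rng)
            row["ne_ld"] = reg.ne_hat
            row["n_pairs_in_c_range"] = reg.n_pairs
        else:
            row["ne_ld"], row["n_pairs_in_c_range"] = np.nan, 0
    else:
        row["ne_ld"], row["n_pairs_in_c_range"] = np.nan, 0
    return row


def scan_windows(samples: dict[str, HaplotypeSample], windows: list[GenomicWindow],
                 tracks: dict[str, tuple[pd.DataFrame, str]] | None = None,
                 maf_min: float = 0.05, min_pairs: int = 250_000,
                 phased: bool = False,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Window statistics for a whole genome.

    `samples` maps chromosome -> HaplotypeSample; `tracks` maps column
    name -> (BED-like frame, aggregation mode).  A missing track over a
    window yields NaN there; the window is retained for the others.
    """
    rows = []
    for w in windows:
        if w.chrom not in samples:
            raise KeyError(f"no genotype data for chromosome {w.chrom}")
        rows.append(window_stats(samples[w.chrom], w, maf_min=maf_min,
                                 min_pairs=min_pairs, phased=phased, rng=rng))
    df = pd.DataFrame(rows)
    if tracks:
        for name, (frame, mode) in tracks.items():
            df[name] = aggregate_track(windows, frame, mode)
    return df


def filter_windows(stats: pd.DataFrame, min_pairs: int = 250_000,
                   ne_max: float = 100_000.0) -> tuple[pd.DataFrame, dict]:
    """Exclusion rules for regional estimates.

    Keeps windows with more than `min_pairs` SNP pairs in the c range and
    a valid Ne_LD in (0, ne_max].  Returns the kept frame and per-rule
    exclusion tallies (a window is tallied under the first rule it fails).
    """
    n_pairs = stats["n_pairs_in_c_range"].to_numpy(float)
    ne = stats["ne_ld"].to_numpy(float)
    fail_pairs = ~(n_pairs > min_pairs)
    bad_ne = ~fail_pairs & (~np.isfinite(ne) | (ne <= 0) | (ne > ne_max))
    keep = ~fail_pairs & ~bad_ne
    counts = {
        "total": len(stats),
        "excluded_insufficient_pairs": int(fail_pairs.sum()),
        "excluded_ne_out_of_range": int(bad_ne.sum()),
        "kept": int(keep.sum()),
    }
    logger.info("window filter: %s", counts)
    return stats.loc[keep].reset_index(drop=True), counts


def _spearman(x: np.ndarray, y: np.ndarray):
    """Spearman rho with average ranks; two-sided p from the
    t-approximation on n-2 degrees of freedom."""
    n = len(x)
    rho = float(sps.spearmanr(x, y).statistic)
    if not np.isfinite(rho):
        return rho, float("nan")
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(tstat), df=n - 2)
    return rho, float(p)


def correlate(stats: pd.DataFrame,
              variable_pairs: list[tuple[str, str]] | None = None,
              min_windows: int = 5) -> list[CorrelationResult]:
    """Spearman correlations over windows for each variable pair.

    Defaults to {pi, ne_ld} x the diversity/annotation variables.
    Constant variables yield an undefined rho with a reason, not an error.
    """
    if variable_pairs is None:
        variable_pairs = [(a, b) for a in ("pi", "ne_ld")
                          for b in DIVERSITY_VARIABLES if b in stats.columns]
    out = []
    for vx, vy in variable_pairs:
        sub = stats[[vx, vy]].dropna()
        n = len(sub)
        if n < min_windows:
            out.append(CorrelationResult(vx, vy, float("nan"), float("nan"), n,
                                         reason=f"only {n} windows with both variables"))
            continue
        x, y = sub[vx].to_numpy(float), sub[vy].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationResult(vx, vy, float("nan"), float("nan"), n,
                                         reason="constant variable"))
            continue
        rho, p = _spearman(x, y)
        out.append(CorrelationResult(vx, vy, rho, p, n))
    return out


def correlation_matrix(stats: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Full pairwise Spearman matrix over windows."""
    if variables is None:
        variables = [v for v in ("pi", "ne_ld", *DIVERSITY_VARIABLES) if v in stats.columns]
    k = len(variables)
    mat = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    for i in range(k):
        for j in range(i + 1, k):
            sub = stats[[variables[i], variables[j]]].dropna()
            if len(sub) >= 3 and np.ptp(sub.iloc[:, 0]) > 0 and np.ptp(sub.iloc[:, 1]) > 0:
                rho, _ = _spearman(sub.iloc[:, 0].to_numpy(float),
                                   sub.iloc[:, 1].to_numpy(float))
            else:
                rho = np.nan
            mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat
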