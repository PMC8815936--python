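"""Piecewise-constant recombination maps.

A :class:`RecombinationMap` describes crossover intensity along one
chromosome as a set of contiguous bp segments, each with a rate in
cM/Mb.  It converts between physical coordinates (bp, 0-based
half-open) and genetic map coordinates (Morgans), in both directions.
Zero-rate segments are allowed; the inverse mapping places any query
falling exactly on the flat stretch at its left edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RecombinationMap", "GenomeMap", "haldane_c"]

# 1 cM/Mb == 1e-8 Morgans per bp
_CM_PER_MB_TO_M_PER_BP = 1e-8


def haldane_c(d):
    """Map distance (Morgans) -> recombination fraction, Haldane map function.

    c = (1 - exp(-2 d)) / 2, exact when crossovers are Poisson without
    interference, which is how gametes are simulated here.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant crossover rates along [0, length_bp).

    Parameters
    ----------
    segment_starts_bp
        Sorted segment start positions; the first must be 0.
    rates_cm_per_mb
        One non-negative rate per segment, in cM/Mb.
    length_bp
        Chromosome length; the last segment ends here.
    """

    segment_starts_bp: np.ndarray
    rates_cm_per_mb: np.ndarray
    length_bp: int
    _cum_morgans: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        starts = np.asarray(self.segment_starts_bp, dtype=np.int64)
        rates = np.asarray(self.rates_cm_per_mb, dtype=float)
        if starts.ndim != 1 or rates.shape != starts.shape:
            raise ValueError("segment_starts_bp and rates_cm_per_mb must be 1-D and equal length")
        if len(starts) == 0 or starts[0] != 0:
            raise ValueError("first segment must start at 0")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("segment starts must be strictly increasing")
        if self.length_bp <= starts[-1]:
            raise ValueError("length_bp must exceed the last segment start")
        if np.any(rates < 0):
            raise ValueError("recombination rates must be >= 0")
        object.__setattr__(self, "segment_starts_bp", starts)
        object.__setattr__(self, "rates_cm_per_mb", rates)
        bounds = np.append(starts, self.length_bp)
        seg_m = np.diff(bounds) * rates * _CM_PER_MB_TO_M_PER_BP
        object.__setattr__(self, "_cum_morgans", np.concatenate([[0.0], np.cumsum(seg_m)]))

    # -- constructors ---------------------------------------------------

    @classmethod
    def uniform(cls, length_bp: int, rate_cm_per_mb: float) -> "RecombinationMap":
        return cls(np.array([0]), np.array([float(rate_cm_per_mb)]), length_bp)

    @classmethod
    def from_anchors(cls, positions_bp, cum_cm, length_bp: int | None = None) -> "RecombinationMap":
        """Build from (bp, cumulative cM) anchors, as published genetic maps.

        Between anchors the map is linear; before the first and after the
        last anchor the nearest segment's rate is extrapolated.
        """
        pos = np.asarray(positions_bp, dtype=np.int64)
        cum = np.asarray(cum_cm, dtype=float)
        if len(pos) < 2:
            raise ValueError("need at least two anchors")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(cum) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        rates = np.diff(cum) / (np.diff(pos) / 1e6)  # cM/Mb per inter-anchor segment
        if pos[0] > 0:
            starts = np.concatenate([[0], pos[:-1]])
            rates = np.concatenate([[rates[0]], rates])
        else:
            starts = pos[:-1]
        if length_bp is None:
            length_bp = int(pos[-1])
        if length_bp > pos[-1]:
            starts = np.append(starts, pos[-1])
            rates = np.append(rates, rates[-1])
        return cls(starts, rates, length_bp)

    # -- queries --------------------------------------------------------

    @property
    def total_morgans(self) -> float:
        return float(self._cum_morgans[-1])

    @property
    def mean_rate_cm_per_mb(self) -> float:
        return self.total_morgans * 100.0 / (self.length_bp / 1e6)

    def morgans_at(self, bp):
        """Cumulative map position (Morgans) at physical position(s) bp."""
        bp = np.asarray(bp, dtype=float)
        if np.any(bp < 0) or np.any(bp > self.length_bp):
            raise ValueError("bp outside [0, length_bp]")
        seg = np.clip(np.searchsorted(self.segment_starts_bp, bp, side="right") - 1, 0, None)
        offs = (bp - self.segment_starts_bp[seg]) * self.rates_cm_per_mb[seg] * _CM_PER_MB_TO_M_PER_BP
        return self._cum_morgans[seg] + offs

    def bp_at(self, morgans):
        """Inverse map: Morgans -> bp (left edge on zero-rate plateaus)."""
        m = np.atleast_1d(np.asarray(morgans, dtype=float))
        if np.any(m < 0) or np.any(m > self.total_morgans * (1 + 1e-12)):
            raise ValueError("map position outside [0, total_morgans]")
        m = np.minimum(m, self.total_morgans)
        seg = np.clip(np.searchsorted(self._cum_morgans, m, side="right") - 1, 0, len(self.rates_cm_per_mb) - 1)
        rate_m = self.rates_cm_per_mb[seg] * _CM_PER_MB_TO_M_PER_BP
        bounds = np.append(self.segment_starts_bp, self.length_bp)
        with np.errstate(divide="ignore", invalid="ignore"):
            offs = np.where(rate_m > 0, (m - self._cum_morgans[seg]) / rate_m, 0.0)
        out = np.minimum(bounds[seg] + offs, self.length_bp)
        return out if np.ndim(morgans) else float(out[0])

    def rate_at(self, bp):
        """Local rate (cM/Mb) at physical position(s)."""
        bp = np.asarray(bp, dtype=float)
        seg = np.clip(np.searchsorted(self.segment_starts_bp, bp, side="right") - 1, 0, None)
        return self.rates_cm_per_mb[seg]


class GenomeMap(dict):
    """Mapping of chromosome name -> :class:`RecombinationMap`."""

    @property
    def total_morgans(self) -> float:
        return sum(m.total_morgans for m in self.values())
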