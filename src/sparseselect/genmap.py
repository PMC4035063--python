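"""Recombination maps: uniform baseline and hotspot-structured maps.

Human recombination is concentrated in kilobase-scale hotspots over a weak
uniform background; coalescent simulators of array-era data (cosi and kin)
generate region-specific hotspot maps around a stated baseline rate.  The
model here is a simplified version of that scheme: hotspot centres follow a
Poisson process (default mean spacing 10 kb), each hotspot is 2 kb wide with
a heavy-tailed (lognormal) intensity, and a uniform background carries a
fixed fraction (default 10%) of the total map.  The map total is normalized
to exactly ``baseline * length``, so the region-average rate always equals
the configured baseline (population-average maps are used by every scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RecombinationMap", "uniform_map", "hotspot_map"]

_CM_PER_MB_TO_PER_BP = 1e-8


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map over [0, L) bp."""

    breaks_bp: np.ndarray  # (K+1,) increasing, breaks_bp[0] = 0, last = L
    rates_cM_per_Mb: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.breaks_bp = np.asarray(self.breaks_bp, dtype=np.float64)
        self.rates_cM_per_Mb = np.asarray(self.rates_cM_per_Mb, dtype=np.float64)
        if np.any(np.diff(self.breaks_bp) <= 0) or np.any(self.rates_cM_per_Mb < 0):
            raise ValueError("breaks must increase and rates be non-negative")
        widths = np.diff(self.breaks_bp)
        self._cum_cM = np.concatenate(
            [[0.0], np.cumsum(widths * self.rates_cM_per_Mb * 1e-6)]
        )

    @property
    def length_bp(self) -> float:
        return float(self.breaks_bp[-1])

    @property
    def total_cM(self) -> float:
        return float(self._cum_cM[-1])

    @property
    def total_morgans(self) -> float:
        """Expected crossovers per meiosis over the region."""
        return self.total_cM / 100.0

    def cM_at(self, positions_bp: np.ndarray) -> np.ndarray:
        """Cumulative genetic position (cM) at physical positions."""
        return np.interp(
            np.asarray(positions_bp, dtype=np.float64), self.breaks_bp, self._cum_cM
        )

    def sample_crossovers(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Crossover bp positions drawn proportional to local rate."""
        u = rng.uniform(0.0, self.total_cM, size=n)
        return np.interp(u, self._cum_cM, self.breaks_bp)

    def scaled(self, factor: float) -> "RecombinationMap":
        return RecombinationMap(self.breaks_bp.copy(), self.rates_cM_per_Mb * factor)

    def to_msprime(self):
        import msprime

        return msprime.RateMap(
            position=self.breaks_bp,
            rate=self.rates_cM_per_Mb * _CM_PER_MB_TO_PER_BP,
        )

    def to_table(self):
        """Genetic-map table (position_bp, rate_cM_per_Mb, map_cM)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "position_bp": self.breaks_bp[:-1].astype(np.int64),
                "rate_cM_per_Mb": self.rates_cM_per_Mb,
                "map_cM": self._cum_cM[:-1],
            }
        )


def uniform_map(length_bp: float, baseline_cM_per_Mb: float) -> RecombinationMap:
    return RecombinationMap(
        np.array([0.0, float(length_bp)]), np.array([baseline_cM_per_Mb])
    )


def hotspot_map(
    length_bp: float,
    baseline_cM_per_Mb: float,
    seed: int,
    mean_spacing_bp: float = 10_000.0,
    hotspot_width_bp: float = 2_000.0,
    background_fraction: float = 0.1,
    intensity_sigma: float = 1.5,
) -> RecombinationMap:
    """Random hotspot map with region-average rate = ``baseline_cM_per_Mb``.

    Falls back to a uniform map when the Poisson draw yields no hotspot or
    the baseline is zero.
    """
    if baseline_cM_per_Mb <= 0:
        return uniform_map(length_bp, max(baseline_cM_per_Mb, 0.0))
    rng = np.random.default_rng(seed)
    L = float(length_bp)
    n_spots = rng.poisson(L / mean_spacing_bp)
    if n_spots == 0:
        return uniform_map(L, baseline_cM_per_Mb)
    centres = np.sort(rng.uniform(0.0, L, size=n_spots))
    half = hotspot_width_bp / 2.0
    starts = np.clip(centres - half, 0.0, L)
    ends = np.clip(centres + half, 0.0, L)
    # merge overlapping hotspots
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    spans = np.array(merged)  # (k, 2)
    weights = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=len(spans))
    total_cM = baseline_cM_per_Mb * L * 1e-6
    hot_cM = (1.0 - background_fraction) * total_cM
    spot_cM = hot_cM * weights / weights.sum()
    bg_rate = background_fraction * total_cM / (L * 1e-6)

    breaks = [0.0]
    rates = []
    for (s, e), c in zip(spans, spot_cM):
        if s > breaks[-1]:
            breaks.append(s)
            rates.append(bg_rate)
        width_mb = (e - s) * 1e-6
        breaks.append(e)
        rates.append(bg_rate + c / width_mb)
    if breaks[-1] < L:
        breaks.append(L)
        rates.append(bg_rate)
    return RecombinationMap(np.array(breaks), np.array(rates))
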