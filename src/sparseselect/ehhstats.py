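"""Extended haplotype homozygosity statistics: EHH curves, iHS and XP-EHH.

EHH at a SNP ``x`` is the probability that two randomly drawn carriers of a
core allele are identical at every SNP between the focal site and ``x``
(combinatorially exact: ``sum_g C(n_g, 2) / C(n_core, 2)`` over groups ``g``
of identical stretches).  It equals 1 at the focal SNP for allele-defined
cores and is non-increasing moving away from it.

iHS integrates the EHH of the ancestral and derived cores over genetic
distance (trapezoid rule), truncating at the first SNP with EHH below 0.05
or at a physical gap above 2.5 Mb; trapezoids spanning a gap ``g`` between
20 kb and 200 kb are damped by ``20000 / g`` and larger (non-truncating)
gaps by 0.1, guarding against inflation over SNP deserts.  The raw statistic
``ln(iHH_ancestral / iHH_derived)`` is standardized within 20 derived-allele
frequency bins; long derived haplotypes (sweeps) push it negative.

XP-EHH contrasts a target against a reference population: on the SNPs the
two share within 1 Mb of the focal site, a boundary SNP with pooled
(two-population) EHH nearest to 0.04 (within [0.03, 0.05]) fixes a common
integration interval, and the raw statistic is the log-ratio of the two
populations' EHH integrals (in bp) over it.  Pooling for the boundary keeps
the statistic exactly antisymmetric under swapping the populations.

Candidate regions come from non-overlapping windows (1 Mb by default):
for iHS the proportion of SNPs with |standardized score| > 2, for XP-EHH
the window maximum, each thresholded at the top 1% of windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import ehh_fill
from .panel import HaplotypePanel

__all__ = [
    "EHHCurve",
    "EHHUndefinedError",
    "ehh",
    "ihs_raw",
    "ihs_scan",
    "ihs_standardize",
    "ihs_call_windows",
    "xpehh",
    "xpehh_scan",
    "xpehh_standardize",
    "xpehh_call_windows",
]


class EHHUndefinedError(ValueError):
    """Raised when a core has fewer than two carriers."""


@dataclass
class EHHCurve:
    """EHH at every SNP of a panel relative to one focal SNP."""

    focal: int
    allele_class: str  # "ancestral" | "derived" | "pooled"
    values: np.ndarray  # (M,)
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    n_carriers: int

    @property
    def left(self) -> np.ndarray:
        """Values from the focal SNP moving left (index 0 = focal)."""
        return self.values[: self.focal + 1][::-1]

    @property
    def right(self) -> np.ndarray:
        return self.values[self.focal :]


def _carrier_rows(panel: HaplotypePanel, focal: int, allele_class: str) -> np.ndarray:
    col = panel.alleles[:, focal]
    if allele_class == "derived":
        return np.nonzero(col == 1)[0]
    if allele_class == "ancestral":
        return np.nonzero(col == 0)[0]
    if allele_class == "pooled":
        return np.arange(panel.n_haplotypes)
    raise ValueError(f"unknown allele_class {allele_class!r}")


def ehh(panel: HaplotypePanel, focal: int, allele_class: str = "derived") -> EHHCurve:
    """Exact EHH decay curve for one core at ``focal``.

    For ``allele_class`` "ancestral"/"derived" the carriers share the focal
    allele and the curve starts at exactly 1; for "pooled" all haplotypes are
    carriers and the curve starts at the focal-site homozygosity (the core
    haplotype is the focal SNP itself).
    """
    rows = _carrier_rows(panel, focal, allele_class)
    if rows.size < 2:
        raise EHHUndefinedError(
            f"core {allele_class!r} at SNP {focal} has {rows.size} carrier(s)"
        )
    sub = np.ascontiguousarray(panel.alleles[rows])
    values = ehh_fill(sub, focal)
    return EHHCurve(
        focal=focal,
        allele_class=allele_class,
        values=values,
        positions_bp=panel.positions_bp,
        positions_cM=panel.positions_cM,
        n_carriers=int(rows.size),
    )


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

_EHH_CUTOFF = 0.05
_GAP_TRUNCATE_BP = 2_500_000
_GAP_SCALE_LO = 20_000
_GAP_SCALE_HI = 200_000


def _gap_factor(g: float) -> float:
    if g <= _GAP_SCALE_LO:
        return 1.0
    if g <= _GAP_SCALE_HI:
        return _GAP_SCALE_LO / g
    return 0.1


def _integrate_side(
    values: np.ndarray,
    bp: np.ndarray,
    cM: np.ndarray,
    focal: int,
    step: int,
    cutoff: float = _EHH_CUTOFF,
) -> float:
    """Trapezoid integral of EHH vs genetic distance on one side of focal."""
    area = 0.0
    j = focal
    while True:
        k = j + step
        if k < 0 or k >= values.size:
            break
        g = abs(float(bp[k] - bp[j]))
        if g > _GAP_TRUNCATE_BP:
            break
        d_cM = abs(float(cM[k] - cM[j]))
        area += 0.5 * (values[j] + values[k]) * d_cM * _gap_factor(g)
        if values[k] < cutoff:
            break
        j = k
    return area


def ihs_raw(panel: HaplotypePanel, focal: int) -> float:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one SNP.

    NaN signals an undefined statistic: a core with fewer than two carriers,
    or a zero integral on either side.
    """
    try:
        curve_a = ehh(panel, focal, "ancestral")
        curve_d = ehh(panel, focal, "derived")
    except EHHUndefinedError:
        return float("nan")
    bp, cM = panel.positions_bp, panel.positions_cM
    ihh = {}
    for name, curve in (("a", curve_a), ("d", curve_d)):
        left = _integrate_side(curve.values, bp, cM, focal, -1)
        right = _integrate_side(curve.values, bp, cM, focal, +1)
        ihh[name] = left + right
    if ihh["a"] <= 0.0 or ihh["d"] <= 0.0:
        return float("nan")
    return math.log(ihh["a"] / ihh["d"])


def ihs_scan(panel: HaplotypePanel, min_carriers: int = 2) -> pd.DataFrame:
    """Raw iHS at every SNP of a panel (NaN where undefined).

    Returns a score table with columns chrom, position_bp, daf, raw.
    """
    H = panel.n_haplotypes
    daf = panel.alleles.mean(axis=0)
    raws = np.full(panel.n_snps, np.nan)
    for j in range(panel.n_snps):
        n_der = int(round(daf[j] * H))
        if n_der < min_carriers or H - n_der < min_carriers:
            continue
        raws[j] = ihs_raw(panel, j)
    return pd.DataFrame(
        {
            "chrom": panel.chrom,
            "position_bp": panel.positions_bp,
            "daf": daf,
            "raw": raws,
        }
    )


def ihs_standardize(table: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Standardize raw iHS within equal-width derived-allele-frequency bins.

    Appends a ``std`` column; bins holding fewer than two defined scores, or
    with zero spread, yield NaN (flagged undefined).  Exactly idempotent.
    """
    defined = table["raw"].notna()
    if defined.sum() < n_bins:
        warnings.warn("fewer defined scores than bins; standardization is noisy")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(table["daf"].to_numpy(), edges[1:-1]), 0, n_bins - 1)
    std = np.full(len(table), np.nan)
    raw = table["raw"].to_numpy()
    for b in range(n_bins):
        mask = (bins == b) & np.isfinite(raw)
        if mask.sum() < 2:
            continue
        mu = raw[mask].mean()
        sd = raw[mask].std()
        if sd == 0:
            continue
        std[mask] = (raw[mask] - mu) / sd
    out = table.copy()
    out["std"] = std
    return out


def _window_index(pos: np.ndarray, window_bp: int) -> np.ndarray:
    return (pos - 1) // window_bp


def _top_windows(stats: pd.DataFrame, top_frac: float) -> pd.DataFrame:
    """Rank windows by 'stat' and flag the top fraction (ties included)."""
    n = len(stats)
    out = stats.copy()
    if n == 0:
        out["called"] = np.array([], dtype=bool)
        return out
    if n < 100:
        warnings.warn(f"only {n} windows; a top-1% cut is coarse at this scale")
    vals = out["stat"].to_numpy()
    if np.all(vals == vals[0]):  # degenerate: no window stands out
        out["called"] = False
        return out
    k = max(1, int(math.floor(top_frac * n)))
    threshold = np.sort(vals)[::-1][k - 1]
    out["called"] = vals >= threshold
    return out


def ihs_call_windows(
    table: pd.DataFrame,
    window_bp: int = 1_000_000,
    z_cut: float = 2.0,
    top_frac: float = 0.01,
) -> pd.DataFrame:
    """Windowed iHS calling: proportion of SNPs with |std| > ``z_cut``.

    SNPs are grouped into non-overlapping windows; windows without any
    defined standardized score are excluded; the top ``top_frac`` of windows
    by proportion (ties at the cutoff included) are flagged ``called``.
    Windows whose proportion is zero are never called.
    """
    t = table[np.isfinite(table["std"])].copy()
    t["win"] = _window_index(t["position_bp"].to_numpy(), window_bp)
    rows = []
    for (chrom, win), grp in t.groupby(["chrom", "win"], sort=True):
        prop = float((np.abs(grp["std"]) > z_cut).mean())
        rows.append(
            dict(
                chrom=chrom,
                start_bp=int(win * window_bp + 1),
                end_bp=int((win + 1) * window_bp),
                n_snps=len(grp),
                stat=prop,
            )
        )
    wins = _top_windows(pd.DataFrame(rows), top_frac)
    if len(wins):
        wins.loc[wins["stat"] <= 0.0, "called"] = False
    return wins


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

_XP_BAND = (0.03, 0.05)
_XP_TARGET_EHH = 0.04


def _shared_columns(
    target: HaplotypePanel, ref: HaplotypePanel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shared, it, ir = np.intersect1d(
        target.positions_bp, ref.positions_bp, return_indices=True
    )
    return shared, it, ir


def _integrate_between(values: np.ndarray, bp: np.ndarray, a: int, b: int) -> float:
    """Plain trapezoid integral (in bp) of EHH between SNP indices a and b."""
    lo, hi = (a, b) if a <= b else (b, a)
    v, x = values[lo : hi + 1], bp[lo : hi + 1].astype(np.float64)
    return float(np.trapezoid(v, x))


def xpehh(
    target: HaplotypePanel,
    ref: HaplotypePanel,
    focal_bp: int,
    radius_bp: int = 1_000_000,
) -> float:
    """Raw XP-EHH at the SNP at ``focal_bp`` (must be shared by both panels).

    NaN signals an undefined statistic: no shared SNP with pooled EHH inside
    the [0.03, 0.05] boundary band, or a zero integral.  Positive values
    indicate longer haplotypes (stronger recent selection) in the target.
    """
    shared, it, ir = _shared_columns(target, ref)
    keep = np.abs(shared - focal_bp) <= radius_bp
    shared, it, ir = shared[keep], it[keep], ir[keep]
    hits = np.nonzero(shared == focal_bp)[0]
    if hits.size == 0:
        raise ValueError("focal_bp is not a shared SNP")
    focal = int(hits[0])
    sub_t = np.ascontiguousarray(target.alleles[:, it])
    sub_r = np.ascontiguousarray(ref.alleles[:, ir])
    pooled = np.concatenate([sub_t, sub_r], axis=0)
    ehh_pooled = ehh_fill(pooled, focal)
    band = np.nonzero((ehh_pooled >= _XP_BAND[0]) & (ehh_pooled <= _XP_BAND[1]))[0]
    band = band[band != focal]
    if band.size == 0:
        return float("nan")
    dev = np.abs(ehh_pooled[band] - _XP_TARGET_EHH)
    dist = np.abs(shared[band] - focal_bp)
    order = np.lexsort((band, dist, dev))  # nearest to 0.04, then closest, then left
    boundary = int(band[order[0]])
    ehh_t = ehh_fill(sub_t, focal)
    ehh_r = ehh_fill(sub_r, focal)
    i_t = _integrate_between(ehh_t, shared, focal, boundary)
    i_r = _integrate_between(ehh_r, shared, focal, boundary)
    if i_t <= 0.0 or i_r <= 0.0:
        return float("nan")
    return math.log(i_t / i_r)


def xpehh_scan(
    target: HaplotypePanel, ref: HaplotypePanel, radius_bp: int = 1_000_000
) -> pd.DataFrame:
    """Raw XP-EHH at every shared SNP; columns chrom, position_bp, raw."""
    shared, _, _ = _shared_columns(target, ref)
    raws = np.array([xpehh(target, ref, int(p), radius_bp) for p in shared])
    return pd.DataFrame(
        {"chrom": target.chrom, "position_bp": shared, "raw": raws}
    )


def xpehh_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide standardization to zero mean, unit variance (std column)."""
    raw = table["raw"].to_numpy()
    ok = np.isfinite(raw)
    out = table.copy()
    std = np.full(len(table), np.nan)
    if ok.sum() >= 2 and raw[ok].std() > 0:
        std[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std()
    out["std"] = std
    return out


def xpehh_call_windows(
    table: pd.DataFrame, window_bp: int = 1_000_000, top_frac: float = 0.01
) -> pd.DataFrame:
    """Windowed XP-EHH calling on window maxima of the standardized score."""
    t = table[np.isfinite(table["std"])].copy()
    t["win"] = _window_index(t["position_bp"].to_numpy(), window_bp)
    rows = []
    for (chrom, win), grp in t.groupby(["chrom", "win"], sort=True):
        rows.append(
            dict(
                chrom=chrom,
                start_bp=int(win * window_bp + 1),
                end_bp=int((win + 1) * window_bp),
                n_snps=len(grp),
                stat=float(grp["std"].max()),
            )
        )
    return _top_windows(pd.DataFrame(rows), top_frac)
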