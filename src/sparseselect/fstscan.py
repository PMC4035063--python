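"""Two-population Fst and the sliding-window differentiation scan.

Per SNP the unbiased variance-components (ANOVA, theta-type) estimator is
computed from haploid allele counts: with populations of ``n_i`` haplotypes
and allele frequencies ``p_i``,

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
    n_c = (n_tot - sum_i n_i^2 / n_tot) / (r - 1)
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

with ``r = 2`` populations.  The estimator is unbiased around zero under
identical allele frequencies (so single-SNP values may be negative) and
equals 1 at a fixed difference.  SNPs monomorphic across both populations
are undefined and excluded.

The window scan slides 500-kb windows in 250-kb steps; a window's statistic
is the mean of its three largest per-SNP Fst values, windows with fewer
than five SNPs are dropped, and windows in the top 1% (ties included) are
called.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = ["fst_per_snp", "fst_table", "fst_windows"]


def fst_per_snp(
    count1: np.ndarray, n1: int, count2: np.ndarray, n2: int
) -> np.ndarray:
    """Variance-components Fst per SNP from derived-allele counts.

    Parameters are the derived-allele count arrays and haplotype sample
    sizes of the two populations.  Returns NaN where both populations are
    monomorphic for the same allele (zero denominator).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 haplotypes per population")
    p1 = np.asarray(count1, dtype=np.float64) / n1
    p2 = np.asarray(count2, dtype=np.float64) / n2
    n_tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_tot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    nc = n_tot - (n1 * n1 + n2 * n2) / n_tot
    denom = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, (msp - msg) / denom, np.nan)
    return theta


def fst_table(target: HaplotypePanel, ref: HaplotypePanel) -> pd.DataFrame:
    """Per-SNP Fst on the SNPs shared by two panels.

    Columns: chrom, position_bp, count1, count2, fst (NaN = undefined).
    """
    shared, it, ir = np.intersect1d(
        target.positions_bp, ref.positions_bp, return_indices=True
    )
    c1 = target.alleles[:, it].sum(axis=0)
    c2 = ref.alleles[:, ir].sum(axis=0)
    fst = fst_per_snp(c1, target.n_haplotypes, c2, ref.n_haplotypes)
    return pd.DataFrame(
        {
            "chrom": target.chrom,
            "position_bp": shared,
            "count1": c1,
            "count2": c2,
            "fst": fst,
        }
    )


def fst_windows(
    table: pd.DataFrame,
    window_bp: int = 500_000,
    step_bp: int | None = None,
    min_snps: int = 5,
    top_k: int = 3,
    top_frac: float = 0.01,
) -> pd.DataFrame:
    """Sliding-window Fst statistic: mean of the ``top_k`` largest values.

    Windows slide in half-window steps by default; windows with fewer than
    ``min_snps`` defined Fst values are excluded before thresholding, and the
    top ``top_frac`` of surviving windows (ties included) are ``called``.
    """
    if step_bp is None:
        step_bp = window_bp // 2
    t = table[np.isfinite(table["fst"])]
    rows = []
    for chrom, grp in t.groupby("chrom", sort=True):
        pos = grp["position_bp"].to_numpy()
        vals = grp["fst"].to_numpy()
        if pos.size == 0:
            continue
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            mask = (pos >= start) & (pos <= end)
            n = int(mask.sum())
            if n >= min_snps:
                top = np.sort(vals[mask])[::-1][:top_k]
                rows.append(
                    dict(
                        chrom=chrom,
                        start_bp=start,
                        end_bp=end,
                        n_snps=n,
                        stat=float(top.mean()),
                    )
                )
            start += step_bp
    wins = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "stat"])
    n = len(wins)
    if n == 0:
        warnings.warn("no window passed the SNP-count filter")
        wins["called"] = np.array([], dtype=bool)
        return wins
    if n < 100:
        warnings.warn(f"only {n} windows; a top-1% cut is coarse at this scale")
    vals = wins["stat"].to_numpy()
    if np.all(vals == vals[0]):
        wins["called"] = False
        return wins
    k = max(1, int(math.floor(top_frac * n)))
    threshold = np.sort(vals)[::-1][k - 1]
    wins["called"] = vals >= threshold
    return wins
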