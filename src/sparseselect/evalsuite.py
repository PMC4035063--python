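"""Evaluation machinery: phasing accuracy, detection power, cross-density
consistency and signal-sharing population clustering.

* Switch-error rate: per individual, the number of flips of parental
  orientation between consecutive heterozygous sites divided by
  (heterozygote count - 1); a wholesale swap of the two haplotypes is not an
  error.  Population rate = unweighted mean over individuals with >= 2 hets.
* Power at a false-discovery threshold: the fraction of selected-region
  scores strictly below the 1st percentile (linear-interpolation quantile)
  of the null-region score distribution — smaller scores are stronger here.
* Region overlap: Table-style consistency counting, where a region in one
  call set overlaps the other if they share at least one bp.
* Population clustering: Pearson correlation of binary region-indicator
  vectors, distance 1 - r, Ward minimum-variance linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import ehhstats, fstscan
from .haplops import (
    DEFAULT_FREQ_GRID,
    NullDistributions,
    PanelBlocks,
    SelectionRegion,
    genome_candidates,
    region_best_score,
    scan,
)
from .panel import DiploidPhasing, HaplotypePanel

__all__ = [
    "PowerResult",
    "ClusterResult",
    "switch_error_rate",
    "estimate_power",
    "region_overlap",
    "cluster_populations",
    "build_null_distributions",
    "region_scores",
    "haplops_power",
    "thin_panel_pair",
    "density_consistency_experiment",
]


# ---------------------------------------------------------------------------
# switch error
# ---------------------------------------------------------------------------


def switch_error_rate(
    truth_panel: HaplotypePanel,
    truth_phasing: DiploidPhasing,
    inferred_panel: HaplotypePanel,
    inferred_phasing: DiploidPhasing,
) -> tuple[np.ndarray, float]:
    """Per-individual switch-error rates and their unweighted mean.

    Both phasings must describe the same individuals with identical
    genotypes (checked site by site).  Individuals with fewer than two
    heterozygous sites carry no phase information and are skipped (NaN).
    """
    if truth_phasing.n_individuals != inferred_phasing.n_individuals:
        raise ValueError("phasings describe different numbers of individuals")
    g_truth = truth_phasing.genotypes(truth_panel)
    g_inf = inferred_phasing.genotypes(inferred_panel)
    if g_truth.shape != g_inf.shape:
        raise ValueError("genotype matrices differ in shape")
    if not np.array_equal(g_truth, g_inf):
        ind, site = np.argwhere(g_truth != g_inf)[0]
        raise ValueError(
            f"genotype mismatch at individual {ind}, SNP index {site}"
        )
    rates = np.full(truth_phasing.n_individuals, np.nan)
    for k, ((t1, _t2), (s1, _s2)) in enumerate(
        zip(truth_phasing.pairing, inferred_phasing.pairing)
    ):
        hets = np.nonzero(g_truth[k] == 1)[0]
        if hets.size < 2:
            continue
        # orientation at each het: does inferred haplotype 1 match truth 1?
        orient = truth_panel.alleles[t1, hets] == inferred_panel.alleles[s1, hets]
        flips = int(np.sum(orient[1:] != orient[:-1]))
        rates[k] = flips / (hets.size - 1)
    mean = float(np.nanmean(rates)) if np.any(np.isfinite(rates)) else float("nan")
    return rates, mean


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


@dataclass
class PowerResult:
    """Detection power of a score against an empirical null at a fixed FDR."""

    frequency: float | None
    n_selected: int
    n_null: int
    threshold: float
    power: float
    fdr: float = 0.01


def estimate_power(
    selected_scores: np.ndarray,
    null_scores: np.ndarray,
    fdr: float = 0.01,
    frequency: float | None = None,
) -> PowerResult:
    """Fraction of selected scores strictly below the null's ``fdr`` quantile.

    The threshold is the lower-tail empirical percentile of the null scores
    (linear interpolation between order statistics).  Requires >= 100 null
    scores for the 1st percentile to be meaningful.
    """
    null_scores = np.asarray(null_scores, dtype=np.float64)
    selected_scores = np.asarray(selected_scores, dtype=np.float64)
    if null_scores.size < 100:
        raise ValueError(f"need >= 100 null scores, got {null_scores.size}")
    finite_null = null_scores[np.isfinite(null_scores)]
    threshold = float(np.percentile(finite_null, 100.0 * fdr))
    ok = np.isfinite(selected_scores)
    power = float(np.mean(selected_scores[ok] < threshold)) if ok.any() else 0.0
    # non-finite (unscoreable) selected regions count as misses
    power *= ok.sum() / selected_scores.size
    return PowerResult(
        frequency=frequency,
        n_selected=int(selected_scores.size),
        n_null=int(null_scores.size),
        threshold=threshold,
        power=power,
        fdr=fdr,
    )


# ---------------------------------------------------------------------------
# region overlap (cross-density consistency)
# ---------------------------------------------------------------------------


def _as_intervals(regions) -> list[tuple[str, int, int]]:
    if isinstance(regions, pd.DataFrame):
        if "called" in regions.columns:
            regions = regions[regions["called"]]
        return [
            (str(r.chrom), int(r.start_bp), int(r.end_bp))
            for r in regions.itertuples()
        ]
    out = []
    for r in regions:
        if isinstance(r, SelectionRegion):
            out.append((r.chrom, r.start_bp, r.end_bp))
        else:
            chrom, s, e = r
            out.append((str(chrom), int(s), int(e)))
    return out


def region_overlap(regions_a, regions_b) -> tuple[int, int, int]:
    """(|A|, |B|, number of B regions sharing >= 1 bp with any A region).

    Each B region is counted at most once even if it spans several A regions.
    """
    A = _as_intervals(regions_a)
    B = _as_intervals(regions_b)
    n_hit = 0
    for chrom_b, s_b, e_b in B:
        for chrom_a, s_a, e_a in A:
            if chrom_a == chrom_b and s_b <= e_a and s_a <= e_b:
                n_hit += 1
                break
    return len(A), len(B), n_hit


# ---------------------------------------------------------------------------
# signal-sharing clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: list[str]
    correlation: np.ndarray
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    excluded: list[str] = field(default_factory=list)


def _newick(node, labels: list[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        length = parent_dist - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:.6g}"

    root = node
    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


def cluster_populations(
    indicator: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
) -> ClusterResult:
    """Ward clustering of populations by shared selection signals.

    ``indicator`` is a populations x regions binary membership matrix.
    Pearson correlations across the region vectors give distances
    ``1 - r``; Ward's minimum-variance linkage is applied to them (on the
    usual squared-Euclidean embedding).  Populations with zero-variance
    indicator rows have no defined correlation and are excluded (flagged).
    """
    if isinstance(indicator, pd.DataFrame):
        labels = list(indicator.index.astype(str)) if labels is None else labels
        mat = indicator.to_numpy(dtype=float)
    else:
        mat = np.asarray(indicator, dtype=float)
        labels = labels or [f"pop{i}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D indicator matrix with >= 2 populations")
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError("indicator entries must be 0/1")
    variances = mat.var(axis=1)
    excluded = [labels[i] for i in np.nonzero(variances == 0)[0]]
    keep = np.nonzero(variances > 0)[0]
    if keep.size < 2:
        raise ValueError("fewer than two populations with variable indicators")
    sub = mat[keep]
    kept_labels = [labels[i] for i in keep]
    corr = np.corrcoef(sub)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    order = [kept_labels[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)
    return ClusterResult(
        labels=kept_labels,
        correlation=corr,
        linkage=Z,
        leaf_order=order,
        newick=_newick(tree, kept_labels),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# long-haplotype power pipeline
# ---------------------------------------------------------------------------


def build_null_distributions(
    null_panels: list[HaplotypePanel],
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID,
    blocks_list: list[PanelBlocks] | None = None,
) -> dict[float, NullDistributions]:
    """Pool candidates of matched neutral regions into per-frequency nulls."""
    if blocks_list is None:
        blocks_list = [PanelBlocks(p) for p in null_panels]
    return {
        f: genome_candidates(null_panels, f, blocks_list, keep_candidates=False)
        for f in freq_grid
    }


def region_scores(
    panels: list[HaplotypePanel],
    nulls: dict[float, NullDistributions],
) -> np.ndarray:
    """Best (minimum) candidate score of each region against pooled nulls."""
    return np.array([region_best_score(PanelBlocks(p), nulls) for p in panels])


def haplops_power(
    selected_panels: list[HaplotypePanel],
    null_panels: list[HaplotypePanel],
    fdr: float = 0.01,
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID,
    frequency: float | None = None,
) -> PowerResult:
    """Power of the long-haplotype scan on simulated regions.

    Every region (selected and null alike) is summarized by the minimum
    score of its candidates over the frequency grid, scored against the
    pooled null candidate set; the detection threshold is the ``fdr``-quantile
    of the null region scores.
    """
    null_blocks = [PanelBlocks(p) for p in null_panels]
    nulls = build_null_distributions(null_panels, freq_grid, null_blocks)
    null_scores = np.array([region_best_score(b, nulls) for b in null_blocks])
    sel_scores = region_scores(selected_panels, nulls)
    return estimate_power(sel_scores, null_scores, fdr=fdr, frequency=frequency)


# ---------------------------------------------------------------------------
# cross-density consistency experiment
# ---------------------------------------------------------------------------


def thin_panel_pair(
    target: HaplotypePanel,
    ref: HaplotypePanel,
    keep_fraction: float,
    seed: int,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Thin a two-population pair to the same SNP subset (shared positions)."""
    from .simdata import thin_uniform

    thin_t = thin_uniform(target, keep_fraction, seed=seed)
    idx = np.searchsorted(ref.positions_bp, thin_t.positions_bp)
    return thin_t, ref.subset_snps(idx)


def merge_intervals(
    intervals: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union of intervals sharing >= 1 bp (or abutting) on one chromosome."""
    out: list[list] = []
    for chrom, s, e in sorted(_as_intervals(intervals)):
        if out and out[-1][0] == chrom and s <= out[-1][2] + 1:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([chrom, s, e])
    return [tuple(iv) for iv in out]


def _called_intervals(windows: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Called windows collapsed into distinct regions (Table-style counting)."""
    return merge_intervals(_as_intervals(windows))


def density_consistency_experiment(
    region_pairs: list[tuple[HaplotypePanel, HaplotypePanel]],
    thin_fraction: float,
    seed: int = 0,
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID,
    window_bp: int = 1_000_000,
    fst_window_bp: int = 500_000,
    top_frac: float = 0.01,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Run all four scans at full and thinned density; count consistent calls.

    ``region_pairs`` are (target, reference) panels on distinct chromosome
    labels (one per region).  Returns a table with one row per method:
    ``n_full``, ``n_thin`` and ``n_overlap`` (thinned-density calls sharing
    >= 1 bp with a full-density call).
    """
    rng = np.random.default_rng(seed)

    def run_all(pairs):
        targets = [t for t, _ in pairs]
        out = {}
        out["haplops"] = scan(targets, freq_grid=freq_grid)
        ihs_tabs = []
        xp_tabs = []
        fst_tabs = []
        for t, r in pairs:
            tab = ehhstats.ihs_scan(t)
            ihs_tabs.append(tab)
            xp_tabs.append(ehhstats.xpehh_scan(t, r))
            fst_tabs.append(fstscan.fst_table(t, r))
        ihs_all = ehhstats.ihs_standardize(pd.concat(ihs_tabs, ignore_index=True))
        out["ihs"] = ehhstats.ihs_call_windows(
            ihs_all, window_bp=window_bp, top_frac=top_frac
        )
        xp_all = ehhstats.xpehh_standardize(pd.concat(xp_tabs, ignore_index=True))
        out["xpehh"] = ehhstats.xpehh_call_windows(
            xp_all, window_bp=window_bp, top_frac=top_frac
        )
        out["fst"] = fstscan.fst_windows(
            pd.concat(fst_tabs, ignore_index=True),
            window_bp=fst_window_bp,
            min_snps=min_snps,
            top_frac=top_frac,
        )
        return out

    full = run_all(region_pairs)
    thinned_pairs = [
        thin_panel_pair(t, r, thin_fraction, seed=int(rng.integers(2**31 - 1)))
        for t, r in region_pairs
    ]
    thin = run_all(thinned_pairs)

    rows = []
    for method in ("haplops", "ihs", "xpehh", "fst"):
        full_calls = (
            full[method]
            if isinstance(full[method], list)
            else _called_intervals(full[method])
        )
        thin_calls = (
            thin[method]
            if isinstance(thin[method], list)
            else _called_intervals(thin[method])
        )
        n_full, n_thin, n_over = region_overlap(full_calls, thin_calls)
        rows.append(
            dict(method=method, n_full=n_full, n_thin=n_thin, n_overlap=n_over)
        )
    return pd.DataFrame(rows)
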