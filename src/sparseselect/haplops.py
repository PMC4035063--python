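"""Long-haplotype positive-selection scan.

The scan asks, at each core haplotype frequency ``f`` on a grid (default
0.05 .. 0.95, step 0.05), whether a region harbours an *uncharacteristically
long* haplotype carried intact by at least a fraction ``f`` of the sample.
Evidence for a candidate haplotype is summarized by two genome-wide
empirical p-values — the proportion of same-frequency candidates anywhere in
the genome spanning at least as much genetic distance (cM), and at least as
many SNPs — whose product times the genome-wide candidate count is the
score.  Scores below 0.05 are called selected; at each locus the highest
frequency with a significant haplotype estimates the advantageous-allele
frequency.  The score is not a p-value and can exceed 1.

Candidate generation is an exhaustive search: every maximal
(interval, allele-string) pair whose carrier count stays at or above
``f * H`` is enumerated exactly (via incremental partition refinement in a
compiled kernel), so small-panel brute force reproduces the candidate set
verbatim.  :func:`longest_haplotype_at` additionally offers the greedy
seed-and-grow view of the same object, used by :func:`stacked_profile` to
draw frequency-stacked haplotype profiles around a locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import enumerate_maximal_blocks
from .panel import HaplotypePanel

__all__ = [
    "CandidateHaplotype",
    "NullDistributions",
    "SelectionRegion",
    "PanelBlocks",
    "DEFAULT_FREQ_GRID",
    "SCORE_THRESHOLD",
    "carrier_threshold",
    "enumerate_blocks",
    "maximal_candidates",
    "longest_haplotype_at",
    "genome_candidates",
    "haplops_score",
    "score_candidates",
    "region_best_score",
    "scan",
    "stacked_profile",
]

DEFAULT_FREQ_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 20)
)
SCORE_THRESHOLD = 0.05


def carrier_threshold(f: float, n_haplotypes: int) -> int:
    """Minimum carrier count for core frequency ``f``: smallest integer
    ``c`` with ``c / H >= f`` (so duplicating every haplotype leaves the
    candidate set unchanged)."""
    return max(1, int(math.ceil(f * n_haplotypes - 1e-9)))


@dataclass
class CandidateHaplotype:
    """A maximal core-haplotype: an allele string over a SNP interval carried
    intact by ``carrier_count`` haplotypes."""

    chrom: str
    snp_index_start: int
    snp_index_end: int  # inclusive
    allele_string: np.ndarray
    carrier_count: int
    core_frequency: float  # carrier_count / H
    span_cM: float
    snp_count: int
    start_bp: int
    end_bp: int

    def overlaps_bp(self, start_bp: int, end_bp: int) -> bool:
        return self.start_bp <= end_bp and start_bp <= self.end_bp


class PanelBlocks:
    """All maximal blocks of one panel, queryable at any frequency.

    One compiled enumeration serves the whole frequency grid: each block is
    maximal exactly for carrier thresholds ``climit < c <= size``.
    """

    def __init__(self, panel: HaplotypePanel):
        self.panel = panel
        raw = enumerate_maximal_blocks(panel.alleles)
        self.start = raw[:, 0]
        self.end = raw[:, 1]
        self.size = raw[:, 2]
        self.climit = raw[:, 3]
        self.rep = raw[:, 4]
        self.span_cM = panel.positions_cM[self.end] - panel.positions_cM[self.start]
        self.snp_count = self.end - self.start + 1
        self.start_bp = panel.positions_bp[self.start]
        self.end_bp = panel.positions_bp[self.end]

    def __len__(self) -> int:
        return self.start.shape[0]

    def indices_at(self, f: float) -> np.ndarray:
        c = carrier_threshold(f, self.panel.n_haplotypes)
        return np.nonzero((self.climit < c) & (c <= self.size))[0]

    def candidate(self, i: int) -> CandidateHaplotype:
        p = self.panel
        s, e = int(self.start[i]), int(self.end[i])
        return CandidateHaplotype(
            chrom=p.chrom,
            snp_index_start=s,
            snp_index_end=e,
            allele_string=p.alleles[int(self.rep[i]), s : e + 1].copy(),
            carrier_count=int(self.size[i]),
            core_frequency=float(self.size[i] / p.n_haplotypes),
            span_cM=float(self.span_cM[i]),
            snp_count=int(self.snp_count[i]),
            start_bp=int(self.start_bp[i]),
            end_bp=int(self.end_bp[i]),
        )


def enumerate_blocks(panel: HaplotypePanel) -> PanelBlocks:
    return PanelBlocks(panel)


def maximal_candidates(
    panel: HaplotypePanel, f: float, blocks: PanelBlocks | None = None
) -> list[CandidateHaplotype]:
    """All maximal candidate haplotypes of ``panel`` at core frequency ``f``."""
    blocks = blocks if blocks is not None else PanelBlocks(panel)
    return [blocks.candidate(int(i)) for i in blocks.indices_at(f)]


# ---------------------------------------------------------------------------
# greedy single-seed view
# ---------------------------------------------------------------------------


def longest_haplotype_at(
    panel: HaplotypePanel, seed_snp: int, f: float
) -> CandidateHaplotype | None:
    """Grow a maximal haplotype bidirectionally from one seed SNP.

    Starting from the commoner allele at ``seed_snp``, repeatedly extend the
    side whose majority allele loses the fewest carriers (ties extend left,
    allele ties keep the ancestral allele) while the carrier fraction stays
    at or above ``f``.  Returns ``None`` when the seed allele itself is rarer
    than ``f``.
    """
    a = panel.alleles
    H, M = a.shape
    if not (0 <= seed_snp < M):
        raise IndexError("seed_snp out of range")
    c = carrier_threshold(f, H)
    col = a[:, seed_snp]
    n1 = int(col.sum())
    commoner = 1 if n1 * 2 >= H else 0
    carriers = np.nonzero(col == commoner)[0]
    if carriers.size < c:
        return None
    left = right = seed_snp
    while True:
        best = None  # (lost, side, col_index, allele, kept_mask)
        for side, j in (("L", left - 1), ("R", right + 1)):
            if j < 0 or j >= M:
                continue
            vals = a[carriers, j]
            n_der = int(vals.sum())
            n_anc = carriers.size - n_der
            allele = 0 if n_anc >= n_der else 1
            kept = max(n_anc, n_der)
            if kept < c:
                continue
            lost = carriers.size - kept
            # prefer fewest carriers lost; tie -> left
            if best is None or lost < best[0] or (lost == best[0] and side == "L" and best[1] == "R"):
                best = (lost, side, j, allele, vals == allele)
        if best is None:
            break
        _, side, j, allele, keep_mask = best
        carriers = carriers[keep_mask]
        if side == "L":
            left = j
        else:
            right = j
    return CandidateHaplotype(
        chrom=panel.chrom,
        snp_index_start=left,
        snp_index_end=right,
        allele_string=a[carriers[0], left : right + 1].copy(),
        carrier_count=int(carriers.size),
        core_frequency=float(carriers.size / H),
        span_cM=float(panel.positions_cM[right] - panel.positions_cM[left]),
        snp_count=right - left + 1,
        start_bp=int(panel.positions_bp[left]),
        end_bp=int(panel.positions_bp[right]),
    )


# ---------------------------------------------------------------------------
# genome-wide null distributions and the score
# ---------------------------------------------------------------------------


@dataclass
class NullDistributions:
    """Genome-wide span/SNP-count distributions at one core frequency."""

    frequency: float
    spans_cM: np.ndarray  # sorted ascending
    snp_counts: np.ndarray  # sorted ascending
    n_total: int
    flagged_empty: bool = False
    candidates: list[CandidateHaplotype] = field(default_factory=list, repr=False)


def genome_candidates(
    panels: list[HaplotypePanel],
    f: float,
    blocks_list: list[PanelBlocks] | None = None,
    keep_candidates: bool = True,
) -> NullDistributions:
    """Pool maximal candidates at frequency ``f`` across a set of regions.

    The pooled span and SNP-count lists are the empirical null against which
    individual candidates are scored; ``n_total`` is the genome-wide
    candidate count.  An empty pool (no allele anywhere at frequency >= f)
    is returned flagged rather than raising.
    """
    if not panels:
        raise ValueError("need at least one panel")
    if blocks_list is None:
        blocks_list = [PanelBlocks(p) for p in panels]
    spans: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    cands: list[CandidateHaplotype] = []
    for blocks in blocks_list:
        idx = blocks.indices_at(f)
        spans.append(blocks.span_cM[idx])
        counts.append(blocks.snp_count[idx])
        if keep_candidates:
            cands.extend(blocks.candidate(int(i)) for i in idx)
    spans_all = np.sort(np.concatenate(spans)) if spans else np.zeros(0)
    counts_all = np.sort(np.concatenate(counts)) if counts else np.zeros(0, np.int64)
    n = int(spans_all.size)
    return NullDistributions(
        frequency=f,
        spans_cM=spans_all,
        snp_counts=counts_all,
        n_total=n,
        flagged_empty=(n == 0),
        candidates=cands,
    )


def _empirical_counts(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """# pool values >= x (inclusive rank), clipped to >= 1 so p is never 0."""
    ge = sorted_vals.size - np.searchsorted(sorted_vals, x, side="left")
    return np.maximum(ge, 1)


def score_candidates(
    spans_cM: np.ndarray, snp_counts: np.ndarray, null: NullDistributions
) -> np.ndarray:
    """Vectorized scores for arrays of candidate spans / SNP counts."""
    if null.flagged_empty:
        raise ValueError("empty null distribution")
    n = null.n_total
    c1 = _empirical_counts(null.spans_cM, np.asarray(spans_cM, dtype=np.float64))
    c2 = _empirical_counts(null.snp_counts, np.asarray(snp_counts, dtype=np.float64))
    # (c1/n) * (c2/n) * n
    return c1.astype(np.float64) * c2 / n


def haplops_score(candidate: CandidateHaplotype, null: NullDistributions) -> float:
    """Score = p_cM * p_snp * N_total (empirical inclusive-rank p-values)."""
    return float(
        score_candidates(
            np.array([candidate.span_cM]), np.array([candidate.snp_count]), null
        )[0]
    )


def region_best_score(
    blocks: PanelBlocks, nulls: dict[float, NullDistributions]
) -> float:
    """Minimum score of any candidate of one region over the frequency grid.

    This is the per-region summary used by the power study: the strongest
    evidence the scan finds anywhere in the region at any core frequency.
    Returns ``inf`` if the region has no scoreable candidate.
    """
    best = math.inf
    for f, null in nulls.items():
        if null.flagged_empty:
            continue
        idx = blocks.indices_at(f)
        if idx.size == 0:
            continue
        s = score_candidates(blocks.span_cM[idx], blocks.snp_count[idx], null)
        m = float(s.min())
        if m < best:
            best = m
    return best


# ---------------------------------------------------------------------------
# the scan proper
# ---------------------------------------------------------------------------


@dataclass
class SelectionRegion:
    """A called selection region: merged significant haplotypes at one locus."""

    chrom: str
    start_bp: int
    end_bp: int
    inferred_daf: float  # highest core frequency with a significant haplotype
    best_score: float
    population_label: str = ""
    contributing: list[tuple[float, float, CandidateHaplotype]] = field(
        default_factory=list, repr=False
    )  # (frequency, score, candidate)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def scan(
    panels: list[HaplotypePanel],
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID,
    score_threshold: float = SCORE_THRESHOLD,
    nulls: dict[float, NullDistributions] | None = None,
    population_label: str = "",
) -> list[SelectionRegion]:
    """Scan a set of regions ("the genome") for selection signals.

    Candidates at every grid frequency are scored against genome-wide null
    distributions (built from ``panels`` themselves unless ``nulls`` is
    supplied, e.g. from matched neutral simulations).  Significant
    haplotypes (score < ``score_threshold``) that overlap by at least one bp
    on the same chromosome are merged into one region whose inferred
    advantageous-allele frequency is the highest significant core frequency
    and whose bounds are the union of the merged spans.
    """
    blocks_list = [PanelBlocks(p) for p in panels]
    if nulls is None:
        nulls = {
            f: genome_candidates(panels, f, blocks_list, keep_candidates=False)
            for f in freq_grid
        }
    hits: list[tuple[str, int, int, float, float, CandidateHaplotype]] = []
    for blocks in blocks_list:
        for f in freq_grid:
            null = nulls.get(f)
            if null is None or null.flagged_empty:
                continue
            idx = blocks.indices_at(f)
            if idx.size == 0:
                continue
            scores = score_candidates(
                blocks.span_cM[idx], blocks.snp_count[idx], null
            )
            for k in np.nonzero(scores < score_threshold)[0]:
                i = int(idx[k])
                cand = blocks.candidate(i)
                hits.append(
                    (cand.chrom, cand.start_bp, cand.end_bp, f, float(scores[k]), cand)
                )
    # merge overlapping significant haplotypes per chromosome
    regions: list[SelectionRegion] = []
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    current: SelectionRegion | None = None
    for chrom, s_bp, e_bp, f, sc, cand in hits:
        if (
            current is not None
            and current.chrom == chrom
            and s_bp <= current.end_bp  # >= 1 bp overlap
        ):
            current.end_bp = max(current.end_bp, e_bp)
            current.inferred_daf = max(current.inferred_daf, f)
            current.best_score = min(current.best_score, sc)
            current.contributing.append((f, sc, cand))
        else:
            current = SelectionRegion(
                chrom=chrom,
                start_bp=s_bp,
                end_bp=e_bp,
                inferred_daf=f,
                best_score=sc,
                population_label=population_label,
                contributing=[(f, sc, cand)],
            )
            regions.append(current)
    return regions


def stacked_profile(
    panel: HaplotypePanel,
    locus_bp: int,
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID,
    blocks: PanelBlocks | None = None,
):
    """Longest haplotype overlapping ``locus_bp`` at each grid frequency.

    Returns a pandas DataFrame with one row per frequency (span_cM,
    snp_count, bounds, carrier count; NaN row where no haplotype at that
    frequency covers the locus).  The visual signature of a sweep at
    frequency ``p`` is a sharp drop in span just above ``f = p``.
    """
    import pandas as pd

    if not (panel.positions_bp[0] <= locus_bp <= panel.positions_bp[-1]):
        raise ValueError("locus outside the panel's span")
    blocks = blocks if blocks is not None else PanelBlocks(panel)
    rows = []
    for f in freq_grid:
        idx = blocks.indices_at(f)
        if idx.size:
            over = idx[
                (blocks.start_bp[idx] <= locus_bp) & (blocks.end_bp[idx] >= locus_bp)
            ]
        else:
            over = idx
        if over.size == 0:
            rows.append(
                dict(frequency=f, span_cM=np.nan, snp_count=0, start_bp=-1,
                     end_bp=-1, carrier_count=0)
            )
            continue
        order = np.lexsort(
            (blocks.start_bp[over], -blocks.snp_count[over], -blocks.span_cM[over])
        )
        i = int(over[order[0]])
        rows.append(
            dict(
                frequency=f,
                span_cM=float(blocks.span_cM[i]),
                snp_count=int(blocks.snp_count[i]),
                start_bp=int(blocks.start_bp[i]),
                end_bp=int(blocks.end_bp[i]),
                carrier_count=int(blocks.size[i]),
            )
        )
    return pd.DataFrame(rows)
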