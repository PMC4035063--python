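"""Haplotype similarity index: shared versus convergent selection.

When the same locus is called selected in ``K`` populations, the selected
haplotype forms are compared at their common set of ``L`` SNPs.  The
``K x K`` similarity matrix holds scaled Manhattan similarities
``M(i, j) = 1 - l / L`` (``l`` = discordant sites), ones on the diagonal.
The haplotype similarity index (HSI) is the fraction of variance captured
by the leading eigencomponent of ``M``: ``lambda_1 / K`` (the trace of a
similarity matrix with unit diagonal is exactly ``K``).  HSI is 1 exactly
when all forms are identical; a high index (>= 0.98) indicates a single
ancestral mutation shared across populations, a low one (<= 0.90) indicates
independent (convergent) selection events on different backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplops import CandidateHaplotype
from .panel import HaplotypePanel

__all__ = [
    "SimilarityMatrix",
    "build_similarity",
    "hsi",
    "classify_origin",
    "extract_form",
    "shared_forms",
]

HSI_SHARED_MIN = 0.98
HSI_CONVERGENT_MAX = 0.90


@dataclass
class SimilarityMatrix:
    """Scaled-Manhattan similarity between K selected haplotype forms."""

    labels: list[str]
    matrix: np.ndarray  # (K, K), symmetric, unit diagonal
    n_shared_snps: int
    discordant: np.ndarray  # (K, K) integer discordant-site counts


def build_similarity(
    forms: dict[str, np.ndarray] | list[tuple[str, np.ndarray]],
) -> SimilarityMatrix:
    """Similarity matrix from K allele strings over one shared SNP set.

    ``forms`` maps population label -> 0/1 allele vector; all vectors must
    share the same length L >= 1.  Discordance counts are exact integers.
    """
    items = list(forms.items()) if isinstance(forms, dict) else list(forms)
    if len(items) < 2:
        raise ValueError("need at least two haplotype forms")
    labels = [lab for lab, _ in items]
    arrs = [np.asarray(v, dtype=np.int64).ravel() for _, v in items]
    L = arrs[0].size
    if L < 1:
        raise ValueError("forms must cover at least one SNP")
    if any(a.size != L for a in arrs):
        raise ValueError("all haplotype forms must have the same length")
    K = len(arrs)
    stacked = np.stack(arrs)
    diff = (stacked[:, None, :] != stacked[None, :, :]).sum(axis=2)
    M = 1.0 - diff / L
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(
        labels=labels, matrix=M, n_shared_snps=L, discordant=diff
    )


def hsi(matrix: SimilarityMatrix | np.ndarray) -> float:
    """Variance explained by the first eigencomponent: ``lambda_1 / K``."""
    M = matrix.matrix if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix)
    eigvals = np.linalg.eigvalsh(M)
    return float(eigvals[-1] / M.shape[0])


def classify_origin(hsi_value: float) -> str:
    """"shared" (>= 0.98), "convergent" (<= 0.90), else "indeterminate"."""
    if not (0.0 < hsi_value <= 1.0 + 1e-12):
        raise ValueError("HSI must lie in (0, 1]")
    if hsi_value >= HSI_SHARED_MIN:
        return "shared"
    if hsi_value <= HSI_CONVERGENT_MAX:
        return "convergent"
    return "indeterminate"


# ---------------------------------------------------------------------------
# extracting comparable forms from scan output
# ---------------------------------------------------------------------------


def extract_form(
    panel: HaplotypePanel, candidate: CandidateHaplotype
) -> tuple[np.ndarray, np.ndarray]:
    """(positions_bp, alleles) of a candidate haplotype's allele string."""
    s, e = candidate.snp_index_start, candidate.snp_index_end
    return panel.positions_bp[s : e + 1].copy(), candidate.allele_string.copy()


def shared_forms(
    forms_by_pop: dict[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Restrict per-population (positions, alleles) forms to the SNPs common
    to all of them within the bp overlap of their intervals.

    This is the alignment step before :func:`build_similarity` when the
    selected intervals differ in extent across populations.
    """
    if len(forms_by_pop) < 2:
        raise ValueError("need at least two populations")
    lo = max(int(pos.min()) for pos, _ in forms_by_pop.values())
    hi = min(int(pos.max()) for pos, _ in forms_by_pop.values())
    if lo > hi:
        raise ValueError("selected intervals do not overlap in bp")
    common: np.ndarray | None = None
    for pos, _ in forms_by_pop.values():
        inside = pos[(pos >= lo) & (pos <= hi)]
        common = inside if common is None else np.intersect1d(common, inside)
    if common is None or common.size == 0:
        raise ValueError("no SNP shared by all forms in the overlap")
    out = {}
    for lab, (pos, alleles) in forms_by_pop.items():
        idx = np.searchsorted(pos, common)
        out[lab] = np.asarray(alleles)[idx]
    return out
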