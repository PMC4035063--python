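"""Core in-memory containers for phased haplotype data.

A :class:`HaplotypePanel` is the universal input of every statistic in this
package: an ``H x M`` matrix of 0/1 alleles (0 = ancestral, 1 = derived) over
``M`` SNPs with physical (bp, 1-based) and genetic (cM) coordinates, plus a
population label per haplotype.  ``H`` is always twice the number of diploid
individuals; a :class:`DiploidPhasing` records which haplotype rows pair up
into individuals, which is what switch-error evaluation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypePanel", "DiploidPhasing", "PanelError"]


class PanelError(ValueError):
    """Raised when haplotype data violates a structural invariant."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with physical and genetic coordinates.

    Parameters
    ----------
    alleles
        ``(H, M)`` array of 0/1; 0 = ancestral, 1 = derived.
    positions_bp
        ``(M,)`` strictly increasing 1-based physical positions.
    positions_cM
        ``(M,)`` non-decreasing genetic positions in centimorgans.
    chrom
        Chromosome / region label.
    population_of_haplotype
        ``(H,)`` population label per haplotype row.
    focal_snp_index
        Column index of the selected (focal) site, if any.
    allow_fixed
        Permit monomorphic columns (e.g. a swept focal site at fixation).
    """

    alleles: np.ndarray
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    chrom: str = "1"
    population_of_haplotype: np.ndarray | None = None
    focal_snp_index: int | None = None
    allow_fixed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cM = np.asarray(self.positions_cM, dtype=np.float64)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D (H, M) matrix")
        H, M = self.alleles.shape
        if self.positions_bp.shape != (M,) or self.positions_cM.shape != (M,):
            raise PanelError("positions must have one entry per SNP column")
        if M > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise PanelError("positions_bp must be strictly increasing")
        if M > 1 and not np.all(np.diff(self.positions_cM) >= -1e-12):
            raise PanelError("positions_cM must be non-decreasing")
        if np.any((self.alleles != 0) & (self.alleles != 1)):
            raise PanelError("alleles must be biallelic 0/1")
        if H % 2 != 0:
            raise PanelError("haplotype count H must be even (2 per individual)")
        if self.population_of_haplotype is None:
            self.population_of_haplotype = np.array(["pop0"] * H, dtype=object)
        else:
            self.population_of_haplotype = np.asarray(
                self.population_of_haplotype, dtype=object
            )
            if self.population_of_haplotype.shape != (H,):
                raise PanelError("population_of_haplotype must have one label per row")
        if not self.allow_fixed and M > 0:
            daf = self.alleles.mean(axis=0)
            mono = (daf == 0.0) | (daf == 1.0)
            if self.focal_snp_index is not None:
                mono[self.focal_snp_index] = False
            if np.any(mono):
                raise PanelError(
                    f"{int(mono.sum())} monomorphic column(s); pass allow_fixed=True "
                    "if intentional"
                )
        if self.focal_snp_index is not None and not (0 <= self.focal_snp_index < M):
            raise PanelError("focal_snp_index out of range")

    # -- basic queries -----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    def derived_allele_frequency(self, snp_index: int | None = None) -> float | np.ndarray:
        if snp_index is None:
            return self.alleles.mean(axis=0)
        return float(self.alleles[:, snp_index].mean())

    def subset_snps(self, keep: np.ndarray) -> "HaplotypePanel":
        """Column subset (sorted indices); focal index remapped or dropped."""
        keep = np.asarray(keep, dtype=np.int64)
        if keep.size and np.any(np.diff(keep) <= 0):
            raise PanelError("keep indices must be strictly increasing")
        focal = None
        if self.focal_snp_index is not None:
            hits = np.nonzero(keep == self.focal_snp_index)[0]
            focal = int(hits[0]) if hits.size else None
        return HaplotypePanel(
            alleles=self.alleles[:, keep],
            positions_bp=self.positions_bp[keep],
            positions_cM=self.positions_cM[keep],
            chrom=self.chrom,
            population_of_haplotype=self.population_of_haplotype.copy(),
            focal_snp_index=focal,
            allow_fixed=True,
            metadata=dict(self.metadata),
        )

    def subset_haplotypes(self, rows: np.ndarray) -> "HaplotypePanel":
        rows = np.asarray(rows, dtype=np.int64)
        return HaplotypePanel(
            alleles=self.alleles[rows, :],
            positions_bp=self.positions_bp.copy(),
            positions_cM=self.positions_cM.copy(),
            chrom=self.chrom,
            population_of_haplotype=self.population_of_haplotype[rows],
            focal_snp_index=self.focal_snp_index,
            allow_fixed=True,
            metadata=dict(self.metadata),
        )

    def population(self, label: str) -> "HaplotypePanel":
        rows = np.nonzero(self.population_of_haplotype == label)[0]
        if rows.size == 0:
            raise PanelError(f"no haplotypes labelled {label!r}")
        return self.subset_haplotypes(rows)

    def equals(self, other: "HaplotypePanel") -> bool:
        return (
            self.alleles.shape == other.alleles.shape
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions_bp, other.positions_bp)
            and np.allclose(self.positions_cM, other.positions_cM)
            and self.chrom == other.chrom
            and np.array_equal(self.population_of_haplotype, other.population_of_haplotype)
        )


@dataclass
class DiploidPhasing:
    """Pairing of haplotype rows into diploid individuals.

    ``pairing[k] = (i, j)`` means rows ``i`` and ``j`` of the panel are the
    two haplotypes of individual ``k``.  Every row index must appear exactly
    once across all pairs.
    """

    pairing: list[tuple[int, int]]

    def __post_init__(self) -> None:
        flat = [i for pair in self.pairing for i in pair]
        if len(flat) != len(set(flat)):
            raise PanelError("each haplotype index must appear in exactly one pair")

    @property
    def n_individuals(self) -> int:
        return len(self.pairing)

    @classmethod
    def consecutive(cls, n_haplotypes: int) -> "DiploidPhasing":
        """Rows (0,1), (2,3), ... — the layout simulators and HAPS files use."""
        if n_haplotypes % 2:
            raise PanelError("need an even number of haplotypes")
        return cls([(2 * k, 2 * k + 1) for k in range(n_haplotypes // 2)])

    def genotypes(self, panel: HaplotypePanel) -> np.ndarray:
        """(n_individuals, M) genotype dosage matrix (0/1/2)."""
        a = panel.alleles
        return np.stack([a[i].astype(np.int16) + a[j] for i, j in self.pairing])
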