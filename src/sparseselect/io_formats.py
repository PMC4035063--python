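"""File formats: Oxford HAPS/SAMPLE, phased VCF, genetic maps, population
maps, BED/TSV region output and JSON run metadata.

Internal coordinates are 1-based inclusive bp; BED output converts to
0-based half-open.  Allele coding is 0 = ancestral / 1 = derived throughout:
HAPS files are taken at face value (first allele = ancestral), VCF REF is
treated as ancestral unless an ``AA`` INFO tag is present and the caller
opts into it.  Missing genotypes are rejected — every downstream statistic
assumes complete haplotypes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DiploidPhasing, HaplotypePanel, PanelError

__all__ = [
    "FormatError",
    "RunConfig",
    "read_haps",
    "write_haps",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "interpolate_genetic_map",
    "read_population_map",
    "write_population_map",
    "regions_to_bed",
    "regions_to_tsv",
    "write_run_metadata",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Oxford HAPS / SAMPLE
# ---------------------------------------------------------------------------


def write_haps(
    panel: HaplotypePanel,
    haps_path: str | Path,
    sample_path: str | Path,
    phasing: DiploidPhasing | None = None,
) -> None:
    """Write a panel as Oxford HAPS + SAMPLE (alleles A=ancestral, G=derived).

    Haplotype columns follow ``phasing`` pair order (consecutive pairs by
    default); the SAMPLE file carries the population label of each
    individual (taken from its first haplotype).
    """
    phasing = phasing or DiploidPhasing.consecutive(panel.n_haplotypes)
    order = [i for pair in phasing.pairing for i in pair]
    a = panel.alleles[order]
    with open(haps_path, "w") as fh:
        for j in range(panel.n_snps):
            cols = [
                str(panel.chrom),
                f"snp{j}",
                str(int(panel.positions_bp[j])),
                "A",
                "G",
            ] + [str(int(v)) for v in a[:, j]]
            fh.write(" ".join(cols) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing population\n0 0 0 D\n")
        for k, (i1, _i2) in enumerate(phasing.pairing):
            pop = panel.population_of_haplotype[i1]
            fh.write(f"ind{k} ind{k} 0 {pop}\n")


def read_haps(
    haps_path: str | Path,
    sample_path: str | Path,
    recombination_rate_cM_per_Mb: float = 1.0,
    genetic_map: pd.DataFrame | None = None,
) -> tuple[HaplotypePanel, DiploidPhasing]:
    """Read Oxford HAPS + SAMPLE into a panel and its diploid pairing.

    Genetic positions come from ``genetic_map`` if given, else from a
    uniform baseline rate.  Raises :class:`FormatError` (with the line
    number) on ragged rows, non-0/1 alleles, or unsorted / duplicated
    positions.
    """
    ids: list[str] = []
    pops: list[str] = []
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError("SAMPLE file must have 2 header lines and >= 1 individual")
    has_pop = len(lines[0]) >= 4
    for row in lines[2:]:
        ids.append(row[0])
        pops.append(row[3] if has_pop and len(row) >= 4 else "pop0")

    n_ind = len(ids)
    rows: list[list[int]] = []
    positions: list[int] = []
    chrom = None
    width = None
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
                if width != 5 + 2 * n_ind:
                    raise FormatError(
                        f"line 1: expected {5 + 2 * n_ind} columns for "
                        f"{n_ind} individuals, got {width}"
                    )
            elif len(parts) != width:
                raise FormatError(f"line {lineno}: ragged row ({len(parts)} columns)")
            chrom = chrom or parts[0]
            pos = int(parts[2])
            if positions and pos <= positions[-1]:
                raise FormatError(
                    f"line {lineno}: position {pos} not strictly increasing"
                )
            positions.append(pos)
            try:
                alleles = [int(v) for v in parts[5:]]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer allele") from exc
            if any(v not in (0, 1) for v in alleles):
                raise FormatError(f"line {lineno}: alleles must be 0/1 (no missing)")
            rows.append(alleles)
    if not rows:
        raise FormatError("empty HAPS file")
    alleles = np.array(rows, dtype=np.uint8).T  # (H, M)
    bp = np.array(positions, dtype=np.int64)
    if genetic_map is not None:
        cM = interpolate_genetic_map(genetic_map, bp)
    else:
        cM = bp * 1e-6 * recombination_rate_cM_per_Mb
    pop_per_hap = np.array([p for p in pops for _ in range(2)], dtype=object)
    panel = HaplotypePanel(
        alleles=alleles,
        positions_bp=bp,
        positions_cM=cM,
        chrom=str(chrom),
        population_of_haplotype=pop_per_hap,
        allow_fixed=True,
    )
    return panel, DiploidPhasing.consecutive(panel.n_haplotypes)


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------


def write_phased_vcf(
    panel: HaplotypePanel,
    path: str | Path,
    phasing: DiploidPhasing | None = None,
) -> None:
    """Write a minimal phased VCF 4.2 (REF=A ancestral, ALT=G derived, AA tag)."""
    phasing = phasing or DiploidPhasing.consecutive(panel.n_haplotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        samples = "\t".join(f"ind{k}" for k in range(phasing.n_individuals))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n"
        )
        a = panel.alleles
        for j in range(panel.n_snps):
            gts = "\t".join(
                f"{a[i1, j]}|{a[i2, j]}" for i1, i2 in phasing.pairing
            )
            fh.write(
                f"{panel.chrom}\t{int(panel.positions_bp[j])}\tsnp{j}\tA\tG\t.\t"
                f"PASS\tAA=A\tGT\t{gts}\n"
            )


def read_phased_vcf(
    path: str | Path,
    ancestral_policy: str = "ref",
    recombination_rate_cM_per_Mb: float = 1.0,
    genetic_map: pd.DataFrame | None = None,
) -> tuple[HaplotypePanel, DiploidPhasing]:
    """Read a phased biallelic VCF into a panel.

    ``ancestral_policy`` is "ref" (REF = ancestral) or "use-AA" (flip the
    0/1 coding at sites whose ``AA`` INFO tag names the ALT allele).
    Unphased ("/") or missing genotypes raise :class:`FormatError`.
    """
    from cyvcf2 import VCF

    if ancestral_policy not in ("ref", "use-AA"):
        raise ValueError("ancestral_policy must be 'ref' or 'use-AA'")
    vcf = VCF(str(path))
    cols: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"{rec.CHROM}:{rec.POS}: non-biallelic record")
        chrom = chrom or rec.CHROM
        g = np.array(rec.genotypes)  # (n_ind, 3): a, b, phased flag
        if np.any(g[:, 2] == 0):
            raise FormatError(f"{rec.CHROM}:{rec.POS}: unphased genotype")
        if np.any(g[:, :2] < 0):
            raise FormatError(f"{rec.CHROM}:{rec.POS}: missing genotype")
        hap = g[:, :2].reshape(-1).astype(np.uint8)
        if ancestral_policy == "use-AA":
            aa = rec.INFO.get("AA")
            if aa is not None and str(aa).upper() == str(rec.ALT[0]).upper():
                hap = (1 - hap).astype(np.uint8)
        cols.append(hap)
        positions.append(rec.POS)
    if not cols:
        raise FormatError("VCF contains no variant records")
    alleles = np.stack(cols, axis=1)
    bp = np.array(positions, dtype=np.int64)
    if np.any(np.diff(bp) <= 0):
        raise FormatError("VCF positions not strictly increasing")
    if genetic_map is not None:
        cM = interpolate_genetic_map(genetic_map, bp)
    else:
        cM = bp * 1e-6 * recombination_rate_cM_per_Mb
    panel = HaplotypePanel(
        alleles=alleles,
        positions_bp=bp,
        positions_cM=cM,
        chrom=str(chrom),
        allow_fixed=True,
    )
    return panel, DiploidPhasing.consecutive(panel.n_haplotypes)


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["position_bp", "rate_cM_per_Mb", "map_cM"]


def write_genetic_map(map_table: pd.DataFrame, path: str | Path) -> None:
    map_table.to_csv(path, sep=" ", index=False, columns=_MAP_COLUMNS)


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Three-column whitespace table: position_bp, rate (cM/Mb), map (cM)."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise FormatError("genetic map needs 3 columns (bp, rate, cM)")
    df.columns = _MAP_COLUMNS[: df.shape[1]]
    if np.any(np.diff(df["position_bp"]) <= 0) or np.any(np.diff(df["map_cM"]) < 0):
        raise FormatError("genetic map must be monotone in bp and cM")
    return df


def interpolate_genetic_map(
    map_table: pd.DataFrame, positions_bp: np.ndarray
) -> np.ndarray:
    """Linear interpolation of cM at given bp; terminal-rate extrapolation."""
    bp = np.asarray(map_table["position_bp"], dtype=np.float64)
    cM = np.asarray(map_table["map_cM"], dtype=np.float64)
    rate = np.asarray(map_table["rate_cM_per_Mb"], dtype=np.float64)
    x = np.asarray(positions_bp, dtype=np.float64)
    out = np.interp(x, bp, cM)
    below = x < bp[0]
    above = x > bp[-1]
    out[below] = cM[0] - (bp[0] - x[below]) * rate[0] * 1e-6
    out[above] = cM[-1] + (x[above] - bp[-1]) * rate[-1] * 1e-6
    return out


# ---------------------------------------------------------------------------
# population maps and region output
# ---------------------------------------------------------------------------


def write_population_map(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for k in range(panel.n_individuals):
            fh.write(f"ind{k}\t{panel.population_of_haplotype[2 * k]}\n")


def read_population_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("population map needs 2 columns (sample_id, population)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def regions_to_bed(regions, path: str | Path) -> None:
    """Write called regions as BED (0-based half-open)."""
    from .evalsuite import _as_intervals

    with open(path, "w") as fh:
        for chrom, start, end in _as_intervals(regions):
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def regions_to_tsv(regions, path: str | Path) -> None:
    """Write scan regions with score and inferred frequency as TSV."""
    rows = []
    for r in regions:
        rows.append(
            dict(
                chrom=r.chrom,
                start_bp=r.start_bp,
                end_bp=r.end_bp,
                inferred_daf=r.inferred_daf,
                best_score=r.best_score,
                population=r.population_label,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration / metadata
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    input_haps: str = ""
    input_sample: str = ""
    genetic_map: str = ""
    population_map: str = ""
    freq_grid: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 20))
    score_threshold: float = 0.05
    window_bp: int = 1_000_000
    fst_window_bp: int = 500_000
    top_frac: float = 0.01
    fdr: float = 0.01
    seed: int = 0
    output_prefix: str = "sparseselect"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(0.0 < f < 1.0 for f in self.freq_grid):
            raise ValueError("freq_grid values must lie strictly in (0, 1)")
        for name in ("score_threshold", "top_frac", "fdr"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.window_bp <= 0 or self.fst_window_bp <= 0:
            raise ValueError("window sizes must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["freq_grid"] = list(self.freq_grid)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        try:
            payload = json.loads(str(source))
        except json.JSONDecodeError:
            payload = json.loads(Path(source).read_text())
        payload["freq_grid"] = tuple(payload.get("freq_grid", ()))
        return cls(**payload)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_metadata(
    path: str | Path, config: RunConfig, input_paths: list[str | Path] | None = None
) -> None:
    """JSON sidecar: configuration, seed, library versions, input checksums."""
    import numba
    import scipy

    meta = {
        "config": json.loads(config.to_json()),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "numba": numba.__version__,
        },
        "input_checksums": {
            str(p): _sha256(p) for p in (input_paths or []) if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
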