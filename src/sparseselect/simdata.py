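"""Synthetic haplotype panels under neutrality and positive selection.

The generator emulates the classic power-study design for haplotype-based
selection scans on array-density data: 100-kb regions with an additive
advantageous mutation (selection coefficient ``s = 0.01``) introduced at the
region midpoint in a population of effective size ``Ne = 17,469``, mutation
rate ``3e-8`` per bp per generation and a uniform ``1 cM/Mb`` recombination
map, conditioned on the present-day derived allele frequency of the selected
site.  Neutral regions come from the standard coalescent with identical
parameters.

Forward simulation at ``Ne ~ 17,000`` is not desk-scale, so the sweep engine
uses the usual population-size rescaling: population ``Ne/Q`` with ``s``,
``mu`` and ``r`` multiplied by ``Q`` (default 50), which preserves the
population-scaled products ``Ne*s``, ``Ne*mu*L`` and ``Ne*r*L``.  The
starting population is an equilibrium sample drawn from the neutral
coalescent at the rescaled parameters; the advantageous mutation is then
injected on one haplotype and the discrete Wright-Fisher process (genic
selection, Poisson crossovers, infinite-sites mutation) is run until the
population derived-allele frequency first reaches the target, with rejection
conditioning on the *sample* frequency landing within +/-0.05 of the target.

Density manipulation mirrors array ascertainment: :func:`thin_to_count` /
:func:`thin_uniform` drop SNPs uniformly at random (always retaining the
focal site), and :func:`thin_by_template` keeps, for each position of a
template marker list, the nearest panel SNP.  :func:`inject_switches`
introduces phasing switch errors with a per-heterozygote probability, giving
ground truth for switch-error evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import msprime
import numpy as np

from .genmap import RecombinationMap, hotspot_map, uniform_map
from .panel import DiploidPhasing, HaplotypePanel, PanelError

__all__ = [
    "SweepConfig",
    "SweepLostError",
    "simulate_sweep",
    "simulate_neutral",
    "simulate_population_pair",
    "thin_uniform",
    "thin_to_count",
    "thin_by_template",
    "ascertain_array",
    "expected_common_sites",
    "inject_switches",
    "force_switches",
    "watterson_expectation",
]

_CM_PER_MB_TO_PER_BP = 1e-8  # 1 cM/Mb = 1e-8 crossover probability per bp per generation


class SweepLostError(RuntimeError):
    """The advantageous allele failed to condition within the retry cap."""


@dataclass(frozen=True)
class SweepConfig:
    """All simulation parameters for one region.

    ``effective_size`` counts diploids and may be fractional after rescaling
    (the engine rounds the haplotype count to the nearest even integer).
    ``recombination_rate`` is the baseline genetic-map rate in cM/Mb.
    """

    effective_size: float = 17469.0
    selection_coefficient: float = 0.01
    mutation_rate: float = 3e-8
    recombination_rate: float = 1.0
    region_length: int = 100_000
    sample_size: int = 120
    target_daf: float = 0.9
    rescale_factor: float = 50.0
    seed: int = 0
    map_model: str = "hotspot"  # "hotspot" (cosi-style) or "uniform"

    def __post_init__(self) -> None:
        if self.effective_size <= 0:
            raise ValueError("effective_size must be positive")
        if not (0.0 < self.selection_coefficient < 1.0):
            raise ValueError("selection_coefficient must be in (0, 1)")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if self.sample_size < 4 or self.sample_size % 2:
            raise ValueError("sample_size must be even and >= 4")
        if not (0.0 < self.target_daf <= 1.0):
            raise ValueError("target_daf must be in (0, 1]")
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")
        if self.map_model not in ("hotspot", "uniform"):
            raise ValueError("map_model must be 'hotspot' or 'uniform'")

    def rescaled(self) -> "SweepConfig":
        """Equivalent configuration at population size Ne/Q.

        Leaves ``Ne*s``, ``Ne*mu*L`` and ``Ne*r*L`` exactly unchanged.
        """
        Q = self.rescale_factor
        return replace(
            self,
            effective_size=self.effective_size / Q,
            selection_coefficient=self.selection_coefficient * Q,
            mutation_rate=self.mutation_rate * Q,
            recombination_rate=self.recombination_rate * Q,
            rescale_factor=1.0,
        )

    @property
    def recombination_per_bp(self) -> float:
        return self.recombination_rate * _CM_PER_MB_TO_PER_BP


def watterson_expectation(config: SweepConfig) -> tuple[float, float]:
    """Expected number and SD of segregating sites under neutrality.

    ``E[S] = theta * a_n`` and ``Var[S] = theta * a_n + theta^2 * b_n`` with
    ``theta = 4 * Ne * mu * L`` and ``a_n``, ``b_n`` the harmonic sums over
    ``1 .. n-1``.
    """
    n = config.sample_size
    theta = 4.0 * config.effective_size * config.mutation_rate * config.region_length
    i = np.arange(1, n)
    a_n = float(np.sum(1.0 / i))
    b_n = float(np.sum(1.0 / i**2))
    mean = theta * a_n
    sd = math.sqrt(theta * a_n + theta**2 * b_n)
    return mean, sd


# ---------------------------------------------------------------------------
# coalescent building blocks
# ---------------------------------------------------------------------------


def region_map(config: SweepConfig, map_seed: int) -> RecombinationMap:
    """The region's natural-scale recombination map (hotspot or uniform)."""
    if config.map_model == "uniform" or config.recombination_rate == 0:
        return uniform_map(config.region_length, config.recombination_rate)
    return hotspot_map(config.region_length, config.recombination_rate, map_seed)


def _coalescent_haplotypes(
    n_haplotypes: int,
    config: SweepConfig,
    rec_map: RecombinationMap,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral equilibrium haplotypes: (alleles (n, S) uint8, float positions).

    ``rec_map`` must already be on the same (possibly rescaled) scale as
    ``config``.
    """
    # ploidy=1 with population_size = 2*Ne reproduces the diploid-Ne coalescent
    ts = msprime.sim_ancestry(
        samples=n_haplotypes,
        ploidy=1,
        population_size=2.0 * config.effective_size,
        recombination_rate=rec_map.to_msprime(),
        random_seed=max(1, seed),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=max(1, seed) + 1,
    )
    if ts.num_sites == 0:
        return (
            np.zeros((n_haplotypes, 0), dtype=np.uint8),
            np.zeros(0, dtype=np.float64),
        )
    geno = ts.genotype_matrix().T.astype(np.uint8)
    geno[geno > 1] = 1  # collapse any back-mutation states to derived
    pos = np.array([s.position for s in ts.sites()], dtype=np.float64)
    return np.ascontiguousarray(geno), pos


def _finalize_panel(
    alleles: np.ndarray,
    pos: np.ndarray,
    config: SweepConfig,
    rec_map: RecombinationMap,
    focal_pos: float | None,
    chrom: str,
    metadata: dict,
) -> HaplotypePanel:
    """Float positions -> unique 1-based bp; drop sample-monomorphic sites."""
    H, M = alleles.shape
    bp = np.floor(pos).astype(np.int64) + 1
    focal_idx = None
    if focal_pos is not None:
        hits = np.nonzero(pos == focal_pos)[0]
        focal_idx = int(hits[0]) if hits.size else None

    daf = alleles.mean(axis=0) if M else np.zeros(0)
    keep = (daf > 0.0) & (daf < 1.0)
    if focal_idx is not None and daf[focal_idx] > 0.0:
        keep[focal_idx] = True
    # resolve bp collisions: keep the first site at each bp, but never drop focal
    order_keep = np.nonzero(keep)[0]
    seen: dict[int, int] = {}
    final: list[int] = []
    for idx in order_keep:
        b = int(bp[idx])
        if b in seen:
            if focal_idx is not None and idx == focal_idx:
                final[final.index(seen[b])] = idx
                seen[b] = idx
            continue
        seen[b] = idx
        final.append(idx)
    final_arr = np.array(final, dtype=np.int64)
    new_focal = None
    if focal_idx is not None:
        hits = np.nonzero(final_arr == focal_idx)[0]
        new_focal = int(hits[0]) if hits.size else None
    bp_final = bp[final_arr]
    cM = rec_map.cM_at(bp_final)
    return HaplotypePanel(
        alleles=alleles[:, final_arr],
        positions_bp=bp_final,
        positions_cM=cM,
        chrom=chrom,
        focal_snp_index=new_focal,
        allow_fixed=True,
        metadata=metadata,
    )


def simulate_neutral(config: SweepConfig, chrom: str = "1") -> HaplotypePanel:
    """A neutral-coalescent panel of ``sample_size`` haplotypes.

    The selection coefficient in ``config`` is ignored.  Reproducible given
    ``config.seed``; the segregating-site count follows Watterson's
    expectation for ``theta = 4*Ne*mu*L``.
    """
    rec_map = region_map(config, map_seed=config.seed + 977)
    alleles, pos = _coalescent_haplotypes(
        config.sample_size, config, rec_map, config.seed
    )
    return _finalize_panel(
        alleles,
        pos,
        config,
        rec_map,
        focal_pos=None,
        chrom=chrom,
        metadata={"mode": "neutral", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher machinery (operates on the rescaled population)
# ---------------------------------------------------------------------------


class _Population:
    """Mutable forward-time population: (N2, S) uint8 matrix + float positions."""

    def __init__(self, alleles: np.ndarray, pos: np.ndarray):
        self.alleles = alleles
        self.pos = pos

    def copy(self) -> "_Population":
        return _Population(self.alleles.copy(), self.pos.copy())

    @property
    def size(self) -> int:
        return self.alleles.shape[0]

    def col_of(self, position: float) -> int:
        j = int(np.searchsorted(self.pos, position))
        if j >= len(self.pos) or self.pos[j] != position:
            raise KeyError(position)
        return j

    def frequency(self, position: float) -> float:
        try:
            j = self.col_of(position)
        except KeyError:
            return 0.0
        return float(self.alleles[:, j].mean())

    def insert_site(self, position: float, carrier: int | None) -> None:
        j = int(np.searchsorted(self.pos, position))
        col = np.zeros((self.size, 1), dtype=np.uint8)
        if carrier is not None:
            col[carrier, 0] = 1
        self.alleles = np.concatenate(
            [self.alleles[:, :j], col, self.alleles[:, j:]], axis=1
        )
        self.pos = np.insert(self.pos, j, position)


def _wf_generation(
    pops: list[_Population],
    fitness_site: float | None,
    s: float,
    mu_bp: float,
    rec_map: RecombinationMap,
    L: float,
    rng: np.random.Generator,
    selected_pop: int = 0,
) -> None:
    """Advance all demes one generation in lockstep (shared column ledger).

    Selection (``1 + s`` per derived copy at ``fitness_site``) acts only in
    ``pops[selected_pop]``.  New mutations are inserted as columns into every
    deme (zero elsewhere) so the demes keep identical position lists.
    """
    new_positions: list[float] = []
    new_carriers: list[tuple[int, int]] = []  # (deme, haplotype)

    for d, pop in enumerate(pops):
        N2 = pop.size
        if fitness_site is not None and d == selected_pop:
            try:
                j = pop.col_of(fitness_site)
                w = 1.0 + s * pop.alleles[:, j].astype(np.float64)
            except KeyError:
                w = np.ones(N2)
        else:
            w = np.ones(N2)
        prob = w / w.sum()
        pa = rng.choice(N2, size=N2, p=prob)
        pb = rng.choice(N2, size=N2, p=prob)
        child = pop.alleles[pa]
        n_x = rng.poisson(rec_map.total_morgans, size=N2)
        for h in np.nonzero(n_x > 0)[0]:
            cuts = np.sort(rec_map.sample_crossovers(rng, int(n_x[h])))
            take_b = (np.searchsorted(cuts, pop.pos, side="right") % 2) == 1
            child[h, take_b] = pop.alleles[pb[h], take_b]
        pop.alleles = child
        n_mut = rng.poisson(mu_bp * L * N2)
        for _ in range(n_mut):
            new_positions.append(float(rng.uniform(0.0, L)))
            new_carriers.append((d, int(rng.integers(0, N2))))

    if new_positions:
        newpos = np.asarray(new_positions, dtype=np.float64)
        order = np.argsort(newpos, kind="stable")
        newpos = newpos[order]
        for d, pop in enumerate(pops):
            cols = np.zeros((pop.size, newpos.size), dtype=np.uint8)
            for slot, k in enumerate(order):
                deme, hap = new_carriers[k]
                if deme == d:
                    cols[hap, slot] = 1
            pos_all = np.concatenate([pop.pos, newpos])
            merged = np.argsort(pos_all, kind="stable")
            pop.alleles = np.ascontiguousarray(
                np.concatenate([pop.alleles, cols], axis=1)[:, merged]
            )
            pop.pos = pos_all[merged]


def _prune(pops: list[_Population], protect: float | None) -> None:
    """Drop columns lost or fixed in *every* deme (keeping ``protect``)."""
    counts = [pop.alleles.sum(axis=0) for pop in pops]
    lost = np.ones(len(pops[0].pos), dtype=bool)
    fixed = np.ones(len(pops[0].pos), dtype=bool)
    for pop, c in zip(pops, counts):
        lost &= c == 0
        fixed &= c == pop.size
    drop = lost | fixed
    if protect is not None:
        j = int(np.searchsorted(pops[0].pos, protect))
        if j < len(pops[0].pos) and pops[0].pos[j] == protect:
            drop[j] = False
    if drop.any():
        keep = ~drop
        for pop in pops:
            pop.alleles = np.ascontiguousarray(pop.alleles[:, keep])
            pop.pos = pop.pos[keep]


def _even_haplotype_count(effective_size: float) -> int:
    n2 = int(round(2.0 * effective_size))
    return n2 + (n2 % 2)


_MAX_ATTEMPTS = 500
_MAX_GENERATIONS = 5000
_SAMPLE_REDRAWS = 30
_DAF_TOLERANCE = 0.05


def _run_sweep_forward(
    init: _Population,
    rc: SweepConfig,
    rec_map: RecombinationMap,
    target_daf: float,
    rng: np.random.Generator,
    companion: _Population | None = None,
) -> tuple[_Population, _Population | None, float, int] | None:
    """One conditioning attempt; returns (target pop, companion, focal_pos, gens)."""
    L = float(rc.region_length)
    focal_pos = L / 2.0
    pop = init.copy()
    pops = [pop]
    if companion is not None:
        pops.append(companion.copy())
    carrier = int(rng.integers(0, pop.size))
    for p in pops:
        p.insert_site(focal_pos, carrier if p is pop else None)

    gens = 0
    while gens < _MAX_GENERATIONS:
        _wf_generation(
            pops,
            fitness_site=focal_pos,
            s=rc.selection_coefficient,
            mu_bp=rc.mutation_rate,
            rec_map=rec_map,
            L=L,
            rng=rng,
        )
        gens += 1
        freq = pop.frequency(focal_pos)
        if freq == 0.0:
            return None  # lost
        if target_daf >= 1.0:
            if freq == 1.0:
                break
        elif freq >= target_daf:
            break
        if gens % 10 == 0:
            _prune(pops, protect=focal_pos)
    else:
        return None
    _prune(pops, protect=focal_pos)
    comp = pops[1] if companion is not None else None
    return pop, comp, focal_pos, gens


def _sample_rows(
    pop: _Population, n: int, rng: np.random.Generator
) -> np.ndarray:
    return np.sort(rng.choice(pop.size, size=n, replace=False))


def simulate_sweep(config: SweepConfig, chrom: str = "1") -> HaplotypePanel:
    """Simulate a region carrying a selective sweep conditioned on ``target_daf``.

    Returns a panel whose ``focal_snp_index`` marks the advantageous mutation,
    with sample derived-allele frequency within +/-0.05 of the target.

    Raises
    ------
    SweepLostError
        If conditioning fails ``500`` attempts in a row (e.g. an implausible
        parameter combination).
    """
    rng = np.random.default_rng(config.seed)
    rc = config.rescaled()
    n2 = _even_haplotype_count(rc.effective_size)
    if n2 < config.sample_size:
        raise ValueError(
            "rescaled population smaller than the requested sample; lower "
            "rescale_factor"
        )
    nat_map = region_map(config, map_seed=config.seed + 977)
    rc_map = nat_map.scaled(config.rescale_factor)
    init_seed = int(rng.integers(1, 2**31 - 1))
    alleles, pos = _coalescent_haplotypes(n2, rc, rc_map, init_seed)
    init = _Population(alleles, pos)

    for attempt in range(1, _MAX_ATTEMPTS + 1):
        result = _run_sweep_forward(init, rc, rc_map, config.target_daf, rng)
        if result is None:
            continue
        pop, _, focal_pos, gens = result
        focal_col = pop.col_of(focal_pos)
        for _ in range(_SAMPLE_REDRAWS):
            rows = _sample_rows(pop, config.sample_size, rng)
            daf = float(pop.alleles[rows, focal_col].mean())
            if abs(daf - config.target_daf) <= _DAF_TOLERANCE:
                return _finalize_panel(
                    pop.alleles[rows],
                    pop.pos,
                    config,
                    nat_map,
                    focal_pos=focal_pos,
                    chrom=chrom,
                    metadata={
                        "mode": "sweep",
                        "seed": config.seed,
                        "attempts": attempt,
                        "generations_rescaled": gens,
                        "sample_daf": daf,
                    },
                )
    raise SweepLostError(
        f"sweep conditioning failed after {_MAX_ATTEMPTS} attempts "
        f"(target_daf={config.target_daf})"
    )


def simulate_population_pair(
    config: SweepConfig,
    sweep: bool = True,
    divergence_generations: int = 50,
    chrom: str = "1",
    labels: tuple[str, str] = ("target", "reference"),
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Two demes split from one equilibrium population, sweep in the target only.

    Both demes descend from a single rescaled-coalescent population and then
    evolve independently: the target under selection at the region midpoint
    (if ``sweep``) until the conditioning frequency is reached, the reference
    neutrally for the same number of generations.  Without a sweep both demes
    drift for ``divergence_generations`` (rescaled) generations.  The two
    returned panels share one SNP list (sites monomorphic across the combined
    sample are dropped), which is what cross-population statistics consume.
    """
    rng = np.random.default_rng(config.seed)
    rc = config.rescaled()
    n2 = _even_haplotype_count(rc.effective_size)
    if n2 < config.sample_size:
        raise ValueError("rescaled population smaller than the requested sample")
    nat_map = region_map(config, map_seed=config.seed + 977)
    rc_map = nat_map.scaled(config.rescale_factor)
    init_seed = int(rng.integers(1, 2**31 - 1))
    alleles, pos = _coalescent_haplotypes(n2, rc, rc_map, init_seed)
    init = _Population(alleles, pos)

    if sweep:
        for attempt in range(1, _MAX_ATTEMPTS + 1):
            result = _run_sweep_forward(
                init, rc, rc_map, config.target_daf, rng, companion=init
            )
            if result is None:
                continue
            tpop, rpop, focal_pos, gens = result
            focal_col = tpop.col_of(focal_pos)
            rows_t = _sample_rows(tpop, config.sample_size, rng)
            daf = float(tpop.alleles[rows_t, focal_col].mean())
            if abs(daf - config.target_daf) > _DAF_TOLERANCE:
                continue
            rows_r = _sample_rows(rpop, config.sample_size, rng)
            break
        else:
            raise SweepLostError(
                f"paired sweep conditioning failed after {_MAX_ATTEMPTS} attempts"
            )
    else:
        tpop = init.copy()
        rpop = init.copy()
        pops = [tpop, rpop]
        for g in range(divergence_generations):
            _wf_generation(
                pops,
                fitness_site=None,
                s=0.0,
                mu_bp=rc.mutation_rate,
                rec_map=rc_map,
                L=float(rc.region_length),
                rng=rng,
            )
            if (g + 1) % 10 == 0:
                _prune(pops, protect=None)
        _prune(pops, protect=None)
        focal_pos = None
        rows_t = _sample_rows(tpop, config.sample_size, rng)
        rows_r = _sample_rows(rpop, config.sample_size, rng)

    # joint finalization on the shared column set
    combined = np.concatenate([tpop.alleles[rows_t], rpop.alleles[rows_r]], axis=0)
    panel_all = _finalize_panel(
        combined,
        tpop.pos,
        config,
        nat_map,
        focal_pos=focal_pos,
        chrom=chrom,
        metadata={"mode": "pair", "sweep": sweep, "seed": config.seed},
    )
    n = config.sample_size
    labels_arr = np.array([labels[0]] * n + [labels[1]] * n, dtype=object)
    panel_all.population_of_haplotype = labels_arr
    target_panel = panel_all.subset_haplotypes(np.arange(n))
    ref_panel = panel_all.subset_haplotypes(np.arange(n, 2 * n))
    target_panel.metadata["role"] = labels[0]
    ref_panel.metadata["role"] = labels[1]
    ref_panel.focal_snp_index = panel_all.focal_snp_index
    return target_panel, ref_panel


# ---------------------------------------------------------------------------
# density manipulation
# ---------------------------------------------------------------------------


def _keep_with_focal(
    panel: HaplotypePanel, k: int, rng: np.random.Generator
) -> np.ndarray:
    M = panel.n_snps
    chosen = rng.choice(M, size=k, replace=False)
    if panel.focal_snp_index is not None and panel.focal_snp_index not in chosen:
        chosen[rng.integers(0, k)] = panel.focal_snp_index
    return np.sort(np.unique(chosen))


def thin_uniform(
    panel: HaplotypePanel, keep_fraction: float, seed: int = 0, min_snps: int = 2
) -> HaplotypePanel:
    """Keep ``round(keep_fraction * M)`` SNPs uniformly at random.

    The focal SNP, if present, is always retained.  Positions of the result
    are a subset of the input's, in the original order.  By default thinning
    below two SNPs is an error; pipelines that must represent marker-poor
    regions (e.g. swept regions on a fixed array) may pass ``min_snps=0``.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return panel.subset_snps(np.arange(panel.n_snps))
    k = int(round(keep_fraction * panel.n_snps))
    if k < min_snps:
        raise PanelError(
            f"thinning to {k} SNP(s) leaves too little data (need >= {min_snps})"
        )
    rng = np.random.default_rng(seed)
    if k == 0:
        out = panel.subset_snps(np.zeros(0, dtype=np.int64))
    else:
        out = panel.subset_snps(_keep_with_focal(panel, k, rng))
    out.metadata["thinned_fraction"] = keep_fraction
    return out


def thin_to_count(panel: HaplotypePanel, n_target: int, seed: int = 0) -> HaplotypePanel:
    """Thin to exactly ``n_target`` SNPs (or all, if fewer are available)."""
    if n_target < 2:
        raise PanelError("n_target must be >= 2")
    if n_target >= panel.n_snps:
        return panel.subset_snps(np.arange(panel.n_snps))
    rng = np.random.default_rng(seed)
    out = panel.subset_snps(_keep_with_focal(panel, n_target, rng))
    out.metadata["thinned_to"] = n_target
    return out


def expected_common_sites(config: SweepConfig, maf_min: float = 0.05) -> float:
    """Expected neutral segregating sites with sample MAF >= ``maf_min``.

    From the standard neutral site-frequency spectrum: ``theta * sum 1/i``
    over derived counts ``i`` with ``maf_min <= i/n <= 1 - maf_min``.
    """
    n = config.sample_size
    theta = 4.0 * config.effective_size * config.mutation_rate * config.region_length
    lo = int(math.ceil(maf_min * n))
    i = np.arange(max(lo, 1), n - max(lo, 1) + 1)
    return float(theta * np.sum(1.0 / i))


def ascertain_array(
    panel: HaplotypePanel,
    config: SweepConfig,
    markers_per_region: float = 200.0,
    maf_min: float = 0.05,
    seed: int = 0,
) -> HaplotypePanel:
    """Emulate a fixed genotyping-array marker set over a simulated region.

    Array panels (HapMap2-like, ~200 markers per 100 kb) type common SNPs at
    a density fixed genome-wide, not per region.  This keeps each site with
    sample MAF >= ``maf_min`` with probability
    ``markers_per_region / E[neutral common sites]`` (the expectation from
    the neutral frequency spectrum, so neutral regions average
    ``markers_per_region`` markers).  Regions with reduced diversity — a
    selective sweep's footprint — therefore carry proportionally fewer
    markers, and a region at fixation may carry almost none; the fixed focal
    site itself is monomorphic and is never typed.
    """
    daf = panel.alleles.mean(axis=0) if panel.n_snps else np.zeros(0)
    maf = np.minimum(daf, 1.0 - daf)
    common = np.nonzero(maf >= maf_min)[0]
    frac = min(1.0, markers_per_region / expected_common_sites(config, maf_min))
    rng = np.random.default_rng(seed)
    k = int(round(frac * common.size))
    chosen = np.sort(rng.choice(common, size=k, replace=False)) if k else common[:0]
    out = panel.subset_snps(chosen)
    out.metadata["array_maf_min"] = maf_min
    out.metadata["array_fraction"] = frac
    return out


def thin_by_template(
    panel: HaplotypePanel, template_positions: np.ndarray
) -> HaplotypePanel:
    """Keep, for each template position, the nearest panel SNP by bp.

    Exact matches are kept as-is; otherwise the closest panel position wins,
    with ties broken toward the lower coordinate.  A panel SNP mapped to by
    several template positions is emitted once.
    """
    template = np.asarray(template_positions, dtype=np.int64)
    if template.size == 0:
        raise PanelError("template_positions must be non-empty")
    if np.any(np.diff(template) < 0):
        raise PanelError("template_positions must be sorted")
    bp = panel.positions_bp
    idx_right = np.searchsorted(bp, template)
    chosen = np.empty(template.size, dtype=np.int64)
    for t, (pos, ir) in enumerate(zip(template, idx_right)):
        if ir < bp.size and bp[ir] == pos:
            chosen[t] = ir
            continue
        lo = ir - 1
        hi = ir
        if lo < 0:
            chosen[t] = hi
        elif hi >= bp.size:
            chosen[t] = lo
        else:
            d_lo = pos - bp[lo]
            d_hi = bp[hi] - pos
            chosen[t] = lo if d_lo <= d_hi else hi  # tie -> lower coordinate
    keep = np.unique(chosen)
    return panel.subset_snps(keep)


# ---------------------------------------------------------------------------
# phasing switch errors
# ---------------------------------------------------------------------------


def _switch_individual(
    alleles: np.ndarray, i1: int, i2: int, flip_from: np.ndarray
) -> None:
    """Swap the two rows from each flip point onward (applied cumulatively)."""
    state = np.zeros(alleles.shape[1], dtype=bool)
    for site in flip_from:
        state[site:] ^= True
    cols = np.nonzero(state)[0]
    if cols.size:
        tmp = alleles[i1, cols].copy()
        alleles[i1, cols] = alleles[i2, cols]
        alleles[i2, cols] = tmp


def force_switches(
    panel: HaplotypePanel,
    phasing: DiploidPhasing,
    switches: dict[int, list[int]],
) -> tuple[HaplotypePanel, DiploidPhasing]:
    """Deterministically flip phase at given heterozygote ordinals.

    ``switches[k] = [o1, o2, ...]`` flips individual ``k``'s orientation
    starting at its ``o``-th heterozygous site (0-based ordinal, must be
    >= 1: the first het anchors the orientation).
    """
    alleles = panel.alleles.copy()
    for ind, ordinals in switches.items():
        i1, i2 = phasing.pairing[ind]
        hets = np.nonzero(panel.alleles[i1] != panel.alleles[i2])[0]
        flip_sites = []
        for o in ordinals:
            if not (1 <= o < hets.size):
                raise ValueError(f"het ordinal {o} out of range for individual {ind}")
            flip_sites.append(hets[o])
        _switch_individual(alleles, i1, i2, np.asarray(flip_sites))
    out = HaplotypePanel(
        alleles=alleles,
        positions_bp=panel.positions_bp.copy(),
        positions_cM=panel.positions_cM.copy(),
        chrom=panel.chrom,
        population_of_haplotype=panel.population_of_haplotype.copy(),
        focal_snp_index=panel.focal_snp_index,
        allow_fixed=True,
        metadata=dict(panel.metadata),
    )
    return out, phasing


def inject_switches(
    phasing: DiploidPhasing,
    panel: HaplotypePanel,
    switch_rate: float,
    seed: int = 0,
) -> tuple[HaplotypePanel, DiploidPhasing]:
    """Introduce phasing switch errors at a per-heterozygote rate.

    At every heterozygous site after an individual's first, the
    maternal/paternal assignment flips from that site onward with probability
    ``switch_rate``.  Genotypes are untouched.
    """
    if not (0.0 <= switch_rate <= 1.0):
        raise ValueError("switch_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    for i1, i2 in phasing.pairing:
        hets = np.nonzero(panel.alleles[i1] != panel.alleles[i2])[0]
        if hets.size < 2:
            continue
        flips = hets[1:][rng.random(hets.size - 1) < switch_rate]
        if flips.size:
            _switch_individual(alleles, i1, i2, flips)
    out = HaplotypePanel(
        alleles=alleles,
        positions_bp=panel.positions_bp.copy(),
        positions_cM=panel.positions_cM.copy(),
        chrom=panel.chrom,
        population_of_haplotype=panel.population_of_haplotype.copy(),
        focal_snp_index=panel.focal_snp_index,
        allow_fixed=True,
        metadata={**panel.metadata, "switch_rate": switch_rate, "switch_seed": seed},
    )
    return out, phasing
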