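import numpy as np
import pytest

from conftest import make_panel
from oracles import brute_force_candidates, brute_force_score
from sparseselect.haplops import (
    DEFAULT_FREQ_GRID,
    NullDistributions,
    PanelBlocks,
    carrier_threshold,
    genome_candidates,
    haplops_score,
    longest_haplotype_at,
    maximal_candidates,
    scan,
    stacked_profile,
)
from sparseselect.simdata import SweepConfig, simulate_sweep, thin_to_count


def _candidate_set(panel, f):
    blocks = PanelBlocks(panel)
    out = set()
    for i in blocks.indices_at(f):
        s, e = int(blocks.start[i]), int(blocks.end[i])
        out.add(
            (s, e, tuple(panel.alleles[int(blocks.rep[i]), s : e + 1]),
             int(blocks.size[i]))
        )
    return out


class TestEnumeration:
    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.7])
    def test_matches_brute_force_on_random_panels(self, random_panels, f):
        for panel in random_panels:
            assert _candidate_set(panel, f) == brute_force_candidates(
                panel.alleles, f
            )

    def test_identical_panel_single_candidate(self, toy_identical_panel):
        cands = maximal_candidates(toy_identical_panel, 0.5)
        assert len(cands) == 1
        c = cands[0]
        assert (c.snp_index_start, c.snp_index_end) == (0, 5)
        assert c.carrier_count == 8

    def test_no_candidate_above_max_frequency(self):
        # max allele frequency 0.6 -> empty at f = 0.95, flagged
        a = np.array([[1, 1]] * 6 + [[0, 0]] * 4, dtype=np.uint8)
        null = genome_candidates([make_panel(a)], 0.95)
        assert null.flagged_empty and null.n_total == 0

    def test_duplicating_haplotypes_leaves_candidates_unchanged(self, random_panels):
        for panel in random_panels[:5]:
            doubled = make_panel(np.vstack([panel.alleles, panel.alleles]))
            for f in (0.25, 0.5):
                expected = {
                    (s, e, st, 2 * k) for (s, e, st, k) in _candidate_set(panel, f)
                }
                assert _candidate_set(doubled, f) == expected


class TestGreedyGrowth:
    def test_identical_panel_spans_whole_region(self, toy_identical_panel):
        c = longest_haplotype_at(toy_identical_panel, 3, 0.5)
        assert (c.snp_index_start, c.snp_index_end) == (0, 5)
        assert c.carrier_count == 8

    def test_frequency_above_seed_allele_returns_none(self):
        a = np.array([[1, 0]] * 3 + [[0, 1]] * 7, dtype=np.uint8)
        assert longest_haplotype_at(make_panel(a), 0, 0.8) is None

    def test_result_is_maximal_member_of_exhaustive_set(self, random_panels):
        for panel in random_panels[:10]:
            for f in (0.3, 0.5):
                c = longest_haplotype_at(panel, panel.n_snps // 2, f)
                if c is None:
                    continue
                oracle = brute_force_candidates(panel.alleles, f)
                key = (
                    c.snp_index_start,
                    c.snp_index_end,
                    tuple(c.allele_string),
                    c.carrier_count,
                )
                assert key in oracle

    def test_span_monotone_non_increasing_in_frequency(self, random_panels):
        for panel in random_panels[:10]:
            seed = panel.n_snps // 2
            prev = None
            for f in (0.2, 0.4, 0.6, 0.8):
                c = longest_haplotype_at(panel, seed, f)
                span = -1.0 if c is None else c.span_cM
                if prev is not None:
                    assert span <= prev + 1e-12
                prev = span


class TestScore:
    def _null(self, spans, counts):
        return NullDistributions(
            frequency=0.5,
            spans_cM=np.sort(np.asarray(spans, float)),
            snp_counts=np.sort(np.asarray(counts)),
            n_total=len(spans),
        )

    def _cand(self, span, n):
        from sparseselect.haplops import CandidateHaplotype

        return CandidateHaplotype(
            chrom="1", snp_index_start=0, snp_index_end=n - 1,
            allele_string=np.zeros(n, np.uint8), carrier_count=5,
            core_frequency=0.5, span_cM=span, snp_count=n, start_bp=1, end_bp=n,
        )

    def test_uniquely_longest_candidate(self):
        n = 10_000
        rng = np.random.default_rng(0)
        null = self._null(rng.uniform(0, 1, n), rng.integers(2, 50, n))
        c = self._cand(span=2.0, n=100)  # beyond every null value
        # candidate outside the pool: clipped inclusive rank 1/N on both axes
        assert haplops_score(c, null) == pytest.approx(n * (1 / n) ** 2)

    def test_rank_arithmetic_example(self):
        # p_cM = 0.001, p_snp = 0.002, N = 10,000 -> score 0.02 < 0.05
        n = 10_000
        spans = np.concatenate([np.zeros(n - 10), np.full(10, 5.0)])
        counts = np.concatenate([np.zeros(n - 20), np.full(20, 99)])
        null = self._null(spans, counts)
        c = self._cand(span=5.0, n=99)
        score = haplops_score(c, null)
        assert score == pytest.approx(0.001 * 0.002 * n)
        assert score < 0.05

    def test_median_candidate_not_significant(self):
        n = 10_000
        spans = np.arange(n, dtype=float)
        counts = np.arange(n)
        null = self._null(spans, counts)
        c = self._cand(span=float(n // 2), n=n // 2)
        score = haplops_score(c, null)
        assert score >= 1.0  # approx 0.25 * N

    def test_matches_naive_counting(self, random_panels):
        rng = np.random.default_rng(5)
        spans = rng.uniform(0, 0.1, 500)
        counts = rng.integers(1, 30, 500)
        null = self._null(spans, counts)
        for _ in range(20):
            c = self._cand(float(rng.uniform(0, 0.12)), int(rng.integers(1, 35)))
            assert haplops_score(c, null) == pytest.approx(
                brute_force_score(c.span_cM, c.snp_count, list(spans), list(counts))
            )

    def test_empty_null_rejected(self):
        null = NullDistributions(0.5, np.zeros(0), np.zeros(0), 0, flagged_empty=True)
        with pytest.raises(ValueError, match="empty null"):
            haplops_score(self._cand(1.0, 5), null)

    def test_scores_invariant_under_haplotype_duplication(self, random_panels):
        panel = random_panels[0]
        doubled = make_panel(np.vstack([panel.alleles, panel.alleles]))
        for f in (0.3, 0.6):
            n1 = genome_candidates([panel], f)
            n2 = genome_candidates([doubled], f)
            assert n1.n_total == n2.n_total
            assert np.allclose(np.sort(n1.spans_cM), np.sort(n2.spans_cM))
            assert np.array_equal(np.sort(n1.snp_counts), np.sort(n2.snp_counts))


class TestScan:
    def test_overlapping_significant_haplotypes_merge_to_highest_freq(self):
        # two panels; panel 0 carries a long shared haplotype at ~0.4 frequency
        rng = np.random.default_rng(9)
        H, M = 20, 30
        noise = rng.integers(0, 2, size=(H, M)).astype(np.uint8)
        core = rng.integers(0, 2, M).astype(np.uint8)
        noise[:8] = core  # 8/20 = 0.4 carriers of one long haplotype
        p0 = make_panel(noise, spacing_bp=1000)
        panels = [p0] + [
            make_panel(rng.integers(0, 2, size=(H, M)), spacing_bp=1000)
            for _ in range(30)
        ]
        for i, p in enumerate(panels):
            p.chrom = f"c{i}"
        regions = scan(panels, freq_grid=(0.3, 0.4))
        hit = [r for r in regions if r.chrom == "c0"]
        assert len(hit) == 1
        assert hit[0].inferred_daf == 0.4
        fs = {f for f, _, _ in hit[0].contributing}
        assert fs == {0.3, 0.4}

    def test_neutral_genome_call_rate_bounded(self, neutral_batch):
        """Score < 0.05 admits ~0.05*(1 - ln(0.05/N_f)) extreme candidates per
        frequency stratum (~0.5 at these pool sizes), so a 19-step grid on a
        neutral genome should flag well under half of 30 loci."""
        panels = [thin_to_count(p, 120, seed=i) for i, p in enumerate(neutral_batch)]
        regions = scan(panels)
        assert len(regions) <= len(panels) // 2

    def test_planted_sweep_recovered(self, sweep_batch, neutral_batch):
        sweeps = [thin_to_count(p, 200, seed=3) for p in sweep_batch[:3]]
        neutrals = [thin_to_count(p, 200, seed=4) for p in neutral_batch]
        regions = scan(sweeps + neutrals)
        called_chroms = {r.chrom for r in regions}
        assert sum(p.chrom in called_chroms for p in sweeps) >= 2


class TestStackedProfile:
    def test_identical_panel_full_span_at_all_frequencies(self, toy_identical_panel):
        prof = stacked_profile(toy_identical_panel, locus_bp=3000)
        assert (prof["snp_count"] == 6).all()

    def test_sweep_profile_drops_above_sweep_frequency(self):
        p = simulate_sweep(SweepConfig(seed=33, target_daf=0.5))
        p = thin_to_count(p, 200, seed=1)
        prof = stacked_profile(p, int(p.positions_bp[p.focal_snp_index]))
        spans = prof.set_index("frequency")["span_cM"].fillna(0.0)
        low = spans[spans.index <= 0.45].mean()
        high = spans[spans.index >= 0.65].mean()
        assert low > 2 * high

    def test_locus_outside_panel_rejected(self, toy_identical_panel):
        with pytest.raises(ValueError, match="outside"):
            stacked_profile(toy_identical_panel, locus_bp=10**9)

    def test_frequency_above_max_carriers_gives_empty_row(self):
        a = np.array([[1, 1]] * 5 + [[0, 0]] * 5, dtype=np.uint8)
        prof = stacked_profile(make_panel(a), locus_bp=1000, freq_grid=(0.9,))
        assert prof.iloc[0]["snp_count"] == 0


def test_carrier_threshold_scale_invariance():
    for f in DEFAULT_FREQ_GRID:
        for H in (10, 20, 40, 120):
            c = carrier_threshold(f, H)
            assert (c - 1) / H < f <= c / H + 1e-12
            assert carrier_threshold(f, 2 * H) == pytest.approx(2 * f * H, abs=1)
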