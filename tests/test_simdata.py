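import numpy as np
import pytest

from conftest import make_panel
from sparseselect.ehhstats import ehh
from sparseselect.evalsuite import switch_error_rate
from sparseselect.panel import DiploidPhasing, PanelError
from sparseselect.simdata import (
    SweepConfig,
    force_switches,
    inject_switches,
    simulate_neutral,
    simulate_population_pair,
    simulate_sweep,
    thin_by_template,
    thin_to_count,
    thin_uniform,
    watterson_expectation,
)


class TestSweepConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(effective_size=-1),
            dict(selection_coefficient=0.0),
            dict(selection_coefficient=1.0),
            dict(mutation_rate=-1e-9),
            dict(recombination_rate=-0.1),
            dict(region_length=0),
            dict(sample_size=5),
            dict(sample_size=2),
            dict(target_daf=0.0),
            dict(target_daf=1.2),
            dict(rescale_factor=0.5),
        ],
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            SweepConfig(**kw)

    def test_rescaling_preserves_population_products(self):
        cfg = SweepConfig()
        rc = cfg.rescaled()
        L = cfg.region_length
        for a, b in [
            (cfg.effective_size * cfg.selection_coefficient,
             rc.effective_size * rc.selection_coefficient),
            (cfg.effective_size * cfg.mutation_rate * L,
             rc.effective_size * rc.mutation_rate * L),
            (cfg.effective_size * cfg.recombination_per_bp * L,
             rc.effective_size * rc.recombination_per_bp * L),
        ]:
            assert abs(a - b) <= 1e-9 * abs(a)


class TestNeutral:
    def test_segregating_sites_follow_watterson(self):
        cfg = SweepConfig(seed=11)
        mean, sd = watterson_expectation(cfg)
        counts = [simulate_neutral(SweepConfig(seed=11 + k)).n_snps for k in range(5)]
        assert abs(np.mean(counts) - mean) < 3 * sd / np.sqrt(len(counts))

    def test_zero_mutation_rate_gives_no_sites(self):
        p = simulate_neutral(SweepConfig(mutation_rate=0.0, seed=1))
        assert p.n_snps == 0

    def test_same_seed_is_deterministic(self):
        a = simulate_neutral(SweepConfig(seed=5))
        b = simulate_neutral(SweepConfig(seed=5))
        assert a.equals(b)

    def test_sfs_is_decreasing_in_expectation(self):
        counts = np.zeros(3)
        for k in range(6):
            p = simulate_neutral(SweepConfig(seed=300 + k))
            dac = p.alleles.sum(axis=0)
            counts += [np.sum(dac == 1), np.sum(dac == 2), np.sum(dac == 3)]
        assert counts[0] > counts[1] > counts[2]

    def test_rescaling_invariance_of_diversity(self):
        # neutral summaries agree between (Ne, mu) and (Ne/Q, Q*mu)
        base = dict(region_length=20_000, sample_size=40)
        s_a, s_b = [], []
        for k in range(200):
            s_a.append(simulate_neutral(SweepConfig(seed=700 + k, **base)).n_snps)
            cfg = SweepConfig(seed=900 + k, **base).rescaled()
            s_b.append(simulate_neutral(cfg).n_snps)
        se = np.sqrt(np.var(s_a) / 200 + np.var(s_b) / 200)
        assert abs(np.mean(s_a) - np.mean(s_b)) < 4 * se


class TestSweep:
    def test_focal_frequency_near_target(self, sweep_batch):
        for p in sweep_batch[:10]:
            daf = p.derived_allele_frequency(p.focal_snp_index)
            assert abs(daf - 0.9) <= 0.05

    def test_mean_daf_over_replicates_at_half(self):
        dafs = []
        for k in range(50):
            p = simulate_sweep(SweepConfig(seed=800 + k, target_daf=0.5))
            dafs.append(p.derived_allele_frequency(p.focal_snp_index))
        assert 0.45 <= np.mean(dafs) <= 0.55

    def test_fixation_conditioning(self):
        p = simulate_sweep(SweepConfig(seed=3, target_daf=1.0))
        assert p.derived_allele_frequency(p.focal_snp_index) == 1.0

    def test_deterministic_given_seed(self):
        a = simulate_sweep(SweepConfig(seed=17))
        b = simulate_sweep(SweepConfig(seed=17))
        assert a.equals(b)

    def test_sweep_lengthens_derived_haplotypes(self, sweep_batch, neutral_batch):
        """EHH ~50 kb from the focal SNP is higher among sweep-derived carriers
        than around matched-frequency alleles in neutral data."""

        def ehh_at_50kb(panel, focal):
            curve = ehh(panel, focal, "derived")
            target = panel.positions_bp[focal] + 50_000
            j = int(np.argmin(np.abs(panel.positions_bp - target)))
            return curve.values[j]

        sweep_vals = [ehh_at_50kb(p, p.focal_snp_index) for p in sweep_batch]
        neut_vals = []
        for p in neutral_batch:
            daf = p.derived_allele_frequency()
            # most common derived allele in the left half, mimicking a focal SNP
            j = int(np.argmax(np.where(np.arange(p.n_snps) < p.n_snps // 2, daf, -1)))
            neut_vals.append(ehh_at_50kb(p, j))
        assert np.mean(sweep_vals) > np.mean(neut_vals)

    def test_fewer_segregating_sites_than_neutral(self, sweep_batch, neutral_batch):
        assert np.mean([p.n_snps for p in sweep_batch]) < np.mean(
            [p.n_snps for p in neutral_batch]
        )


class TestPopulationPair:
    def test_sweep_only_in_target(self):
        t, r = simulate_population_pair(SweepConfig(seed=21), sweep=True)
        assert t.derived_allele_frequency(t.focal_snp_index) >= 0.85
        assert r.derived_allele_frequency(r.focal_snp_index) == 0.0
        assert np.array_equal(t.positions_bp, r.positions_bp)

    def test_neutral_pair_shares_positions(self):
        t, r = simulate_population_pair(SweepConfig(seed=22), sweep=False)
        assert np.array_equal(t.positions_bp, r.positions_bp)
        assert t.focal_snp_index is None


class TestThinning:
    def test_fraction_one_is_identity(self, neutral_batch):
        p = neutral_batch[0]
        assert thin_uniform(p, 1.0, seed=1).equals(p)

    def test_thinned_positions_are_ordered_subset(self, neutral_batch):
        p = neutral_batch[0]
        q = thin_uniform(p, 0.05, seed=2)
        assert q.n_snps == round(0.05 * p.n_snps)
        assert np.all(np.isin(q.positions_bp, p.positions_bp))
        assert np.all(np.diff(q.positions_bp) > 0)

    def test_focal_always_retained(self, sweep_batch):
        p = sweep_batch[0]
        for seed in range(10):
            q = thin_uniform(p, 0.05, seed=seed)
            assert q.focal_snp_index is not None
            assert (
                q.positions_bp[q.focal_snp_index]
                == p.positions_bp[p.focal_snp_index]
            )

    def test_two_half_thinnings_match_one_quarter(self, neutral_batch):
        p = thin_to_count(neutral_batch[0], 200, seed=0)
        twice = thin_uniform(thin_uniform(p, 0.5, seed=1), 0.5, seed=2)
        once = thin_uniform(p, 0.25, seed=3)
        assert twice.n_snps == once.n_snps == 50

    def test_overthinning_rejected(self):
        p = make_panel(np.array([[0, 1, 0], [1, 0, 1]]))
        with pytest.raises(PanelError):
            thin_uniform(p, 0.1, seed=0)

    def test_template_exact_subset(self):
        p = make_panel(np.random.default_rng(0).integers(0, 2, (4, 10)), spacing_bp=100)
        template = p.positions_bp[[1, 4, 7]]
        q = thin_by_template(p, template)
        assert q.positions_bp.tolist() == template.tolist()

    def test_template_nearest_with_tie_to_lower(self):
        p = make_panel(np.random.default_rng(1).integers(0, 2, (4, 2)), spacing_bp=1)
        p.positions_bp = np.array([4900, 5200])
        q = thin_by_template(p, np.array([5000]))
        assert q.positions_bp.tolist() == [4900]
        # exact tie: 5050 is equidistant from 4900+150 -> pick lower
        p.positions_bp = np.array([5000, 5100])
        q = thin_by_template(p, np.array([5050]))
        assert q.positions_bp.tolist() == [5000]

    def test_template_duplicate_mapping_deduped(self):
        p = make_panel(np.random.default_rng(2).integers(0, 2, (4, 2)), spacing_bp=10_000)
        q = thin_by_template(p, np.array([9_990, 10_010, 10_020]))
        assert q.n_snps == 1

    def test_empty_template_rejected(self, neutral_batch):
        with pytest.raises(PanelError):
            thin_by_template(neutral_batch[0], np.array([], dtype=int))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    seed=st.integers(0, 2**31 - 1),
    frac=st.floats(0.05, 1.0),
    m=st.integers(40, 120),
)
def test_thinning_never_reorders_or_invents_positions(seed, frac, m):
    rng = np.random.default_rng(seed)
    panel = make_panel(rng.integers(0, 2, size=(8, m)))
    k = round(frac * m)
    if k < 2:
        return
    out = thin_uniform(panel, frac, seed=seed)
    assert out.n_snps == k
    assert np.all(np.isin(out.positions_bp, panel.positions_bp))
    assert np.all(np.diff(out.positions_bp) > 0)


class TestSwitchInjection:
    def test_zero_rate_is_identity(self, phased_pair):
        panel, phasing = phased_pair
        out, _ = inject_switches(phasing, panel, 0.0, seed=1)
        assert np.array_equal(out.alleles, panel.alleles)

    def test_genotypes_preserved_at_any_rate(self, phased_pair):
        panel, phasing = phased_pair
        out, _ = inject_switches(phasing, panel, 0.7, seed=3)
        assert np.array_equal(phasing.genotypes(out), phasing.genotypes(panel))

    def test_rate_one_alternates_every_het(self, phased_pair):
        panel, phasing = phased_pair
        out, _ = inject_switches(phasing, panel, 1.0, seed=2)
        _, mean = switch_error_rate(panel, phasing, out, phasing)
        assert mean == 1.0

    def test_single_forced_switch_rate(self, phased_pair):
        panel, phasing = phased_pair
        # individual 0 has 8 hets; one switch -> 1/7
        out, _ = force_switches(panel, phasing, {0: [3]})
        rates, _ = switch_error_rate(panel, phasing, out, phasing)
        assert rates[0] == pytest.approx(1 / 7)
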