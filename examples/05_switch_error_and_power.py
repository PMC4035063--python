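"""Phasing switch error, and a miniature density/power experiment.

Switch errors (flips of parental phase between consecutive heterozygotes)
are injected at a known rate and recovered by the metric.  Then a small
version of the power study: sweep detection at 1% FDR before and after
thinning marker density 20-fold (run scripts/acceptance.py for the
full-size version).
"""

import numpy as np

from sparseselect import (
    DiploidPhasing,
    SweepConfig,
    ascertain_array,
    inject_switches,
    simulate_neutral,
    simulate_sweep,
    switch_error_rate,
    thin_uniform,
)
from sparseselect.evalsuite import build_null_distributions, estimate_power, region_scores

panel = simulate_neutral(SweepConfig(seed=11))
phasing = DiploidPhasing.consecutive(panel.n_haplotypes)
noisy, _ = inject_switches(phasing, panel, switch_rate=0.10, seed=3)
rates, mean = switch_error_rate(panel, phasing, noisy, phasing)
print(f"injected per-het switch rate 0.10 -> measured mean switch error {mean:.3f}")

n = 100  # miniature replicate count; the acceptance script uses 200
sweeps, nulls = [], []
for k in range(n):
    cs = SweepConfig(seed=20_000 + k, target_daf=0.9)
    cn = SweepConfig(seed=30_000 + k)
    sweeps.append(ascertain_array(simulate_sweep(cs, chrom=f"s{k}"), cs, 200, seed=k))
    nulls.append(ascertain_array(simulate_neutral(cn, chrom=f"n{k}"), cn, 200, seed=k))

for label, frac in (("array density (~200/100kb)", 1.0), ("1/20 density (~10/100kb)", 0.05)):
    sw = [thin_uniform(p, frac, seed=k, min_snps=0) for k, p in enumerate(sweeps)] if frac < 1 else sweeps
    nu = [thin_uniform(p, frac, seed=k, min_snps=0) for k, p in enumerate(nulls)] if frac < 1 else nulls
    dists = build_null_distributions(nu)
    res = estimate_power(region_scores(sw, dists), region_scores(nu, dists), fdr=0.05)
    print(f"{label}: power {res.power:.2f} at 5% FDR ({n}+{n} replicates)")
# Power collapses with density: sparse panels keep too few markers on the
# swept haplotype to make it genome-wide exceptional.
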