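"""The three classical scans on a two-population pair with one sweep.

Target and reference demes split from a common ancestral population; the
target then sweeps at the region midpoint (DAF ~0.8).  iHS (within the
target) goes negative at the swept site, XP-EHH (target vs reference) goes
positive, and windowed Fst rises around it.
"""

import numpy as np

from sparseselect import SweepConfig, simulate_population_pair
from sparseselect.ehhstats import ihs_scan, ihs_standardize, xpehh_scan
from sparseselect.fstscan import fst_table, fst_windows

cfg = SweepConfig(seed=42, target_daf=0.8)
target, ref = simulate_population_pair(cfg, sweep=True)
focal_bp = int(target.positions_bp[target.focal_snp_index])
print(f"pair simulated: {target.n_snps} shared SNPs, sweep at {focal_bp} bp")

ihs = ihs_standardize(ihs_scan(target))
print(f"mean raw iHS across the swept region: {np.nanmean(ihs['raw']):+.2f} "
      "(negative = derived-allele haplotypes longer than ancestral ones)")

xp = xpehh_scan(target, ref)
near = np.abs(xp["position_bp"] - focal_bp) < 10_000
print(f"mean raw XP-EHH near the focal SNP: {np.nanmean(xp['raw'][near]):+.2f} "
      f"(region mean {np.nanmean(xp['raw']):+.2f}; positive = longer in target)")

fst = fst_table(target, ref)
wins = fst_windows(fst, window_bp=50_000)
top = wins.sort_values("stat", ascending=False).iloc[0]
print(f"top Fst window: {int(top.start_bp)}-{int(top.end_bp)} bp, "
      f"stat {top.stat:.2f} (mean of 3 largest per-SNP Fst)")
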