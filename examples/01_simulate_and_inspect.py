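"""Simulate a selective sweep and a matched neutral region, then reduce both
to an array-like marker set.

The sweep carries an additive advantageous mutation (s = 0.01) introduced at
the midpoint of a 100-kb region in a population of Ne = 17,469 diploids,
conditioned so the sampled derived allele frequency is ~0.9.  Note the
sweep's diversity footprint: fewer segregating sites, and fewer common
(array-typable) markers, than the neutral region.
"""

from sparseselect import SweepConfig, ascertain_array, simulate_neutral, simulate_sweep

cfg_sweep = SweepConfig(seed=7, target_daf=0.9)
cfg_null = SweepConfig(seed=8)

sweep = simulate_sweep(cfg_sweep)
null = simulate_neutral(cfg_null)

print(f"sweep region : {sweep.n_snps} segregating sites, "
      f"focal DAF = {sweep.derived_allele_frequency(sweep.focal_snp_index):.3f}, "
      f"conditioned in {sweep.metadata['attempts']} attempt(s)")
print(f"neutral region: {null.n_snps} segregating sites")

sweep_array = ascertain_array(sweep, cfg_sweep, markers_per_region=200, seed=1)
null_array = ascertain_array(null, cfg_null, markers_per_region=200, seed=2)
print(f"array markers : sweep {sweep_array.n_snps}, neutral {null_array.n_snps} "
      "(common-SNP ascertainment at fixed genome-wide density)")
# The deficit of markers inside the sweep is itself part of the selection
# footprint an array sees.
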