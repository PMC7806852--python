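"""Simulate a small male cohort with known truth labels.

Builds a 4,000-probe chrX map, draws 20 normal males plus one mosaic gain
and one Klinefelter (XXY) sample, and prints the raw LRR offset that the
mixed-sex cluster reference induces — the quantity the baseline correction
exists to remove.
"""

import numpy as np

from xmosaic import CohortConfig, build_probe_map, simulate_cohort

probes = build_probe_map(4000, n_y_probes=60, seed=7)
config = CohortConfig(
    counts={"XY_NORMAL": 20, "X_MOSAIC_GAIN": 1, "XXY_FULL_HET": 1},
    cell_fraction_range=(0.20, 0.20),
)
samples, truth = simulate_cohort(config, probes, seed=1)

print(f"cohort: {len(samples)} samples x {len(probes)} probes")
print(truth["karyotype"].value_counts().to_string())

normal = samples[0]
raw_offset = np.median(normal.lrr[probes.is_nonpar_x])
print(f"\nraw hemizygous LRR offset of a normal male: {raw_offset:+.3f}")
print(f"expected from an even-sex cluster mix:      {np.log2(1 / 1.5):+.3f}")
# A normal male's single X reads against a half-female reference (1.5 copies),
# so raw LRR sits near -0.585 instead of 0 -- hence the male-specific baseline.
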