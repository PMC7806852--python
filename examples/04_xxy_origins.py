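"""Classify the molecular origin of constitutional XXY from BAF architecture.

Simulates the three origin patterns — chromosome-wide heterozygosity
(heterodisomy), block-wise heterozygosity (partial heterodisomy after
recombination), and none (isodisomy) — and recovers each label from the
fraction of the hemizygous X span covered by heterozygous blocks.
"""

from xmosaic import (
    SampleProfile,
    build_probe_map,
    call_het_probes,
    classify_xxy_origin,
    segment_het_blocks,
    simulate_sample,
)

probes = build_probe_map(6000, n_y_probes=0, seed=5)
span = probes.nonpar_span()

cases = [
    ("XXY_FULL_HET", {}),
    ("XXY_PARTIAL_HET", {"het_blocks": [(25_000_000, 60_000_000), (100_000_000, 130_000_000)]}),
    ("XXY_ISODISOMY", {}),
]
for karyotype, kwargs in cases:
    prof = SampleProfile(karyotype, karyotype, **kwargs)
    sample = simulate_sample(prof, probes, seed=6)
    mask = call_het_probes(sample.baf, probes)
    blocks = segment_het_blocks(mask, probes)
    origin, frac = classify_xxy_origin(blocks, span)
    print(f"{karyotype:16s} -> {origin:22s} "
          f"(het blocks: {len(blocks)}, covered fraction {frac:.3f})")
# Covered fraction >= 0.80 reads as full heterodisomy, <= 0.05 as isodisomy,
# anything between as partial heterodisomy.
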