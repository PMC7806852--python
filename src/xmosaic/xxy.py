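"""Molecular-origin classification of constitutional XXY from BAF architecture.

A 47,XXY genome shows its origin in where the two X copies carry different
alleles.  Heterozygosity across the whole chromosome points to a paternal
meiosis-I error (X and Y co-segregating) or a maternal MI error without
recombination: the two X copies come from different homologs
(heterodisomy).  Heterozygosity confined to blocks — the footprint of
ancestral recombination — points to maternal MI/MII errors after crossover
(partial heterodisomy).  No heterozygosity outside PAR/XTR means the two
copies are identical (isodisomy): a maternal MII error without
recombination, or a post-zygotic mitotic duplication.

On a male array the only expected heterozygous probes are in PAR1/PAR2 and
the XTR, so those regions are excluded before measuring het coverage.  The
quantitative cutoffs (>= 80% of the hemizygous span covered = full
heterodisomy, <= 5% = isodisomy) operationalise what is a visual BAF-plot
judgement in practice, and are configuration knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .regions import ProbeMap

BAND_DEFAULT = 0.15
MIN_BLOCK_PROBES_DEFAULT = 25
MAX_GAP_BP_DEFAULT = 2_000_000
FULL_CUT_DEFAULT = 0.80
NONE_CUT_DEFAULT = 0.05

XXY_ORIGINS = ("FULL_HETERODISOMY", "PARTIAL_HETERODISOMY", "ISODISOMY")

# mechanistic annotation attached to each label (metadata only; parental
# origin is not resolved — each pattern admits more than one mechanism)
ORIGIN_MECHANISM = {
    "FULL_HETERODISOMY": "paternal MI error, or maternal MI error without recombination",
    "PARTIAL_HETERODISOMY": "maternal MI/MII nondisjunction after recombination",
    "ISODISOMY": "maternal MII error without recombination, or early mitotic error",
}


@dataclass
class HetBlock:
    """A run of heterozygous NONPAR probes (bp-inclusive endpoints)."""

    start_pos: int
    end_pos: int
    n_het_probes: int
    het_density: float

    def __post_init__(self) -> None:
        if self.end_pos < self.start_pos:
            raise InputError("het block with end before start")

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def call_het_probes(baf: np.ndarray, probes: ProbeMap, band: float = BAND_DEFAULT) -> np.ndarray:
    """Boolean mask of heterozygous probes: |BAF - 0.5| <= band, NONPAR X only.

    PAR1/PAR2/XTR probes are always False — male heterozygosity there is
    expected and carries no origin information.
    """
    baf = np.asarray(baf, dtype=float)
    if len(baf) != len(probes):
        raise InputError("BAF vector not aligned to probe map")
    if not 0 < band < 0.5:
        raise InputError("band must lie in (0, 0.5)")
    with np.errstate(invalid="ignore"):
        mid = np.abs(baf - 0.5) <= band
    return mid & probes.is_nonpar_x & np.isfinite(baf)


def segment_het_blocks(
    mask: np.ndarray,
    probes: ProbeMap,
    min_block_probes: int = MIN_BLOCK_PROBES_DEFAULT,
    max_gap_bp: int = MAX_GAP_BP_DEFAULT,
) -> list[HetBlock]:
    """Group heterozygous probes into blocks, merging across gaps <= max_gap_bp.

    Gaps are measured in *informative* sequence: bp spanned by PAR1/PAR2/XTR
    do not count, since male heterozygosity there is uninformative and those
    regions would otherwise split any chromosome-wide block (the XTR alone
    is wider than the default gap).  Blocks with fewer than
    ``min_block_probes`` heterozygous probes are dropped as noise.  Density
    is het probes per informative (NONPAR) probe inside the block span.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(probes):
        raise InputError("mask not aligned to probe map")
    pos = probes.pos
    nonpar = probes.is_nonpar_x
    het_pos = pos[mask]
    if len(het_pos) == 0:
        return []
    nonpar_pos = pos[nonpar]

    excluded = sorted([probes.regions.par1, probes.regions.par2, probes.regions.xtr])

    def informative_coord(p: int) -> int:
        # position minus the excluded bp below it (het probes never lie inside)
        return p - sum(min(b, p) - a for a, b in excluded if a < p)

    eff = np.array([informative_coord(int(p)) for p in het_pos])
    runs: list[list[int]] = [[het_pos[0], het_pos[0], 1]]
    for p, e, e_prev in zip(het_pos[1:], eff[1:], eff[:-1]):
        if e - e_prev <= max_gap_bp:
            runs[-1][1] = p
            runs[-1][2] += 1
        else:
            runs.append([p, p, 1])
    blocks = []
    for a, b, n_het in runs:
        if n_het < min_block_probes:
            continue
        n_informative = int(np.count_nonzero((nonpar_pos >= a) & (nonpar_pos <= b)))
        blocks.append(
            HetBlock(
                start_pos=int(a),
                end_pos=int(b),
                n_het_probes=int(n_het),
                het_density=n_het / max(n_informative, 1),
            )
        )
    return blocks


def covered_fraction(blocks: list[HetBlock], nonpar_span: int) -> float:
    """Fraction of the hemizygous X span covered by het blocks."""
    if nonpar_span <= 0:
        raise InputError("nonpar_span must be positive")
    return sum(b.span_bp for b in blocks) / nonpar_span


def classify_xxy_origin(
    blocks: list[HetBlock],
    nonpar_span: int,
    full_cut: float = FULL_CUT_DEFAULT,
    none_cut: float = NONE_CUT_DEFAULT,
) -> tuple[str, float]:
    """Classify XXY origin from het-block coverage; returns (label, covered fraction)."""
    frac = covered_fraction(blocks, nonpar_span)
    if frac >= full_cut:
        return "FULL_HETERODISOMY", frac
    if frac <= none_cut:
        return "ISODISOMY", frac
    return "PARTIAL_HETERODISOMY", frac
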