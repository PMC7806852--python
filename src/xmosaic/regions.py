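"""Chromosome X/Y probe maps and sequence-class regions.

The male X chromosome is hemizygous except for the two pseudoautosomal
regions (PAR1, PAR2), which recombine with the Y, and the X-transposed
region (XTR, Xq21), which shares high sequence identity with Yq11.  On
genotyping arrays all three behave like diploid sequence in males, so the
probe map carries an explicit region flag used throughout the pipeline to
separate truly hemizygous probes from diploid-behaving ones.

Default coordinates are GRCh37 and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

# GRCh37 defaults; intervals are 1-based, half-open [start, end).
DEFAULT_CHROM_SPAN = (60_001, 155_270_560)
DEFAULT_PAR1 = (60_001, 2_699_520)
DEFAULT_PAR2 = (154_931_044, 155_260_560)
DEFAULT_XTR = (88_400_000, 92_000_000)
DEFAULT_Y_SPAN = (2_650_140, 28_000_000)

REGION_FLAGS = ("PAR1", "PAR2", "XTR", "NONPAR", "Y")


@dataclass(frozen=True)
class GenomeRegions:
    """Coordinate configuration for chrX sequence classes (1-based, half-open)."""

    chrom_span: tuple[int, int] = DEFAULT_CHROM_SPAN
    par1: tuple[int, int] = DEFAULT_PAR1
    par2: tuple[int, int] = DEFAULT_PAR2
    xtr: tuple[int, int] = DEFAULT_XTR
    y_span: tuple[int, int] = DEFAULT_Y_SPAN

    def __post_init__(self) -> None:
        for name in ("chrom_span", "par1", "par2", "xtr", "y_span"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} interval {lo, hi} is empty or inverted")
        lo, hi = self.chrom_span
        intervals = sorted([self.par1, self.xtr, self.par2])
        for a, b in intervals:
            if a < lo or b > hi + 1:
                raise ConfigurationError(f"region [{a}, {b}) outside chromosome span {self.chrom_span}")
        for (_, b1), (a2, _) in zip(intervals, intervals[1:]):
            if a2 < b1:
                raise ConfigurationError("PAR1/PAR2/XTR intervals overlap")

    def flag_positions(self, pos: np.ndarray) -> np.ndarray:
        """Region flag for each 1-based chrX position."""
        flags = np.full(len(pos), "NONPAR", dtype=object)
        for name, (a, b) in (("PAR1", self.par1), ("PAR2", self.par2), ("XTR", self.xtr)):
            flags[(pos >= a) & (pos < b)] = name
        return flags


@dataclass
class ProbeMap:
    """Ordered array probes on chrX (plus a small chrY set).

    Wraps a DataFrame with columns ``probe_id, chrom, pos, region_flag,
    b_freq``; X probes first (sorted by position), then Y probes.  ``b_freq``
    is the population B-allele frequency used by the simulator.
    """

    table: pd.DataFrame
    regions: GenomeRegions = field(default_factory=GenomeRegions)

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos", "region_flag"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"probe map missing columns: {sorted(missing)}")
        if "b_freq" not in self.table.columns:
            rng = np.random.default_rng(0)
            self.table = self.table.assign(b_freq=rng.uniform(0.05, 0.95, len(self.table)))
        bad = ~self.table["region_flag"].isin(REGION_FLAGS)
        if bad.any():
            raise InputError(f"unknown region flags: {sorted(self.table.loc[bad, 'region_flag'].unique())}")
        for chrom in ("X", "Y"):
            pos = self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise InputError(f"chr{chrom} probe positions are not strictly increasing")
        expected = self.regions.flag_positions(self.x_pos)
        got = self.table.loc[self.is_x, "region_flag"].to_numpy()
        if not np.array_equal(expected, got):
            raise InputError("region flags disagree with configured region coordinates")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def region_flag(self) -> np.ndarray:
        return self.table["region_flag"].to_numpy()

    @property
    def b_freq(self) -> np.ndarray:
        return self.table["b_freq"].to_numpy()

    @property
    def is_x(self) -> np.ndarray:
        return (self.table["chrom"] == "X").to_numpy()

    @property
    def is_y(self) -> np.ndarray:
        return (self.table["chrom"] == "Y").to_numpy()

    @property
    def is_nonpar_x(self) -> np.ndarray:
        """Hemizygous chrX probes: outside PAR1/PAR2/XTR."""
        return self.is_x & (self.region_flag == "NONPAR")

    @property
    def is_diploid_like(self) -> np.ndarray:
        """PAR1/PAR2/XTR probes, diploid-behaving in males."""
        return np.isin(self.region_flag, ("PAR1", "PAR2", "XTR"))

    @property
    def x_pos(self) -> np.ndarray:
        return self.table.loc[self.is_x, "pos"].to_numpy()

    @property
    def n_x(self) -> int:
        return int(self.is_x.sum())

    @property
    def n_y(self) -> int:
        return int(self.is_y.sum())

    def nonpar_span(self) -> int:
        """Inclusive bp span covered by hemizygous (NONPAR) X probes."""
        pos = self.table.loc[self.is_nonpar_x, "pos"].to_numpy()
        if len(pos) == 0:
            raise InputError("probe map has no NONPAR X probes")
        return int(pos[-1] - pos[0] + 1)


def _unique_positions(rng: np.random.Generator, n: int, span: tuple[int, int]) -> np.ndarray:
    lo, hi = span
    if hi - lo < n:
        raise ConfigurationError(f"span {span} too small for {n} distinct positions")
    pos = np.unique(rng.integers(lo, hi, size=n))
    while len(pos) < n:  # collisions are rare at genomic scale
        extra = rng.integers(lo, hi, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def build_probe_map(
    n_probes: int,
    *,
    regions: GenomeRegions | None = None,
    n_y_probes: int = 100,
    seed: int = 0,
) -> ProbeMap:
    """Draw a synthetic probe map: uniform positions across chrX plus chrY probes.

    Deterministic for a fixed seed.  Region flags follow the configured
    PAR1/PAR2/XTR coordinates; per-probe B-allele frequencies are drawn
    Uniform(0.05, 0.95).
    """
    if n_probes < 1:
        raise ConfigurationError("n_probes must be >= 1")
    if n_y_probes < 0:
        raise ConfigurationError("n_y_probes must be >= 0")
    regions = regions or GenomeRegions()
    rng = np.random.default_rng(seed)
    x_pos = _unique_positions(rng, n_probes, regions.chrom_span)
    rows = [
        pd.DataFrame(
            {
                "probe_id": [f"X_{i:06d}" for i in range(n_probes)],
                "chrom": "X",
                "pos": x_pos,
                "region_flag": regions.flag_positions(x_pos),
            }
        )
    ]
    if n_y_probes:
        y_pos = _unique_positions(rng, n_y_probes, regions.y_span)
        rows.append(
            pd.DataFrame(
                {
                    "probe_id": [f"Y_{i:06d}" for i in range(n_y_probes)],
                    "chrom": "Y",
                    "pos": y_pos,
                    "region_flag": "Y",
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["b_freq"] = rng.uniform(0.05, 0.95, len(table))
    return ProbeMap(table, regions=regions)
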