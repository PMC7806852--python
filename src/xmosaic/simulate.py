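"""Synthetic UK-Biobank-style array data for the male X chromosome.

The generator produces per-probe LRR/BAF vectors with known truth labels so
the whole detection pipeline is testable without access-controlled cohort
data.  The intensity model:

* LRR is ``compression * log2(c / c_ref) + Normal(0, lrr_noise_sd)`` where
  ``c`` is the sample's copy number at the probe and ``c_ref`` the copy
  number implied by the genotyping-cluster reference.  Because real cluster
  files pool male and female intensities, the hemizygous male reference is
  ``c_ref = 1 + female_weight`` — a normal male probe reads a *negative*
  raw LRR (e.g. log2(1/1.5) = -0.585 at an even sex mix), which is exactly
  the offset the baseline-correction stage removes.
* PAR1/PAR2/XTR probes behave as diploid sequence in males (c = c_ref = 2),
  so their raw offset is ~0.
* Mosaic events change copy number only in a fraction ``f`` of cells:
  a gain reads ``c = 1 + f`` over the event region, a loss ``c = 1 - f``.
  Constitutional XXY carries c = 2 on the whole chromosome in every cell.
* BAF encodes genotype: hemizygous probes cluster at 0/1; diploid-behaving
  probes add heterozygotes near 0.5 at rate 2q(1-q); the three XXY origin
  architectures differ in where the two X copies carry different alleles
  (everywhere / inside ancestral recombination blocks / nowhere).
* chrY probes are simulated against a male-only reference (c_ref = 1);
  a Y gain doubles their dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import SampleIntensity
from .errors import ConfigurationError
from .regions import ProbeMap

KARYOTYPES = (
    "XY_NORMAL",
    "X_MOSAIC_GAIN",
    "X_MOSAIC_LOSS",
    "XXY_FULL_HET",
    "XXY_PARTIAL_HET",
    "XXY_ISODISOMY",
)
MOSAIC_KARYOTYPES = ("X_MOSAIC_GAIN", "X_MOSAIC_LOSS")
XXY_KARYOTYPES = ("XXY_FULL_HET", "XXY_PARTIAL_HET", "XXY_ISODISOMY")


@dataclass(frozen=True)
class ClusterMixModel:
    """Sex composition and saturation of the genotyping-cluster reference.

    ``female_weight`` is the fraction of females pooled into the cluster
    file; the hemizygous reference copy number is
    ``c_ref = (1 - w) * 1 + w * 2 = 1 + w``.  ``compression`` < 1 emulates
    array intensity saturation shrinking log-ratios toward 0.
    """

    female_weight: float = 0.5
    compression: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_weight <= 1.0:
            raise ConfigurationError("female_weight must lie in [0, 1]")
        if not 0.0 < self.compression <= 1.0:
            raise ConfigurationError("compression must lie in (0, 1]")

    @property
    def c_ref_hemizygous(self) -> float:
        return 1.0 + self.female_weight


@dataclass
class SampleProfile:
    """Ground-truth state of one simulated male sample."""

    sample_id: str
    karyotype: str
    cell_fraction: float | None = None
    event_region: tuple[int, int] | None = None  # half-open bp; None = whole chromosome
    het_blocks: list[tuple[int, int]] | None = None
    y_dosage: str = "NORMAL"
    lrr_noise_sd: float = 0.2
    age: int = 55

    def __post_init__(self) -> None:
        if self.karyotype not in KARYOTYPES:
            raise ConfigurationError(f"unknown karyotype {self.karyotype!r}")
        mosaic = self.karyotype in MOSAIC_KARYOTYPES
        if mosaic:
            if self.cell_fraction is None or not 0.0 <= self.cell_fraction <= 1.0:
                raise ConfigurationError(f"{self.sample_id}: mosaic state needs cell_fraction in [0, 1]")
        elif self.cell_fraction is not None:
            raise ConfigurationError(f"{self.sample_id}: cell_fraction only applies to mosaic states")
        if self.karyotype == "XXY_PARTIAL_HET":
            if not self.het_blocks:
                raise ConfigurationError(f"{self.sample_id}: XXY_PARTIAL_HET needs nonempty het_blocks")
        elif self.het_blocks:
            raise ConfigurationError(f"{self.sample_id}: het_blocks only apply to XXY_PARTIAL_HET")
        if self.y_dosage not in ("NORMAL", "GAIN"):
            raise ConfigurationError(f"{self.sample_id}: y_dosage must be NORMAL or GAIN")
        if self.lrr_noise_sd < 0:
            raise ConfigurationError(f"{self.sample_id}: lrr_noise_sd must be >= 0")


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for a, b in intervals:
        mask |= (pos >= a) & (pos < b)
    return mask


def simulate_sample(
    profile: SampleProfile,
    probes: ProbeMap,
    mix: ClusterMixModel = ClusterMixModel(),
    seed: int = 0,
    *,
    baf_noise_sd: float = 0.03,
) -> SampleIntensity:
    """Simulate raw (uncorrected) LRR and BAF for one male sample."""
    if baf_noise_sd < 0:
        raise ConfigurationError("baf_noise_sd must be >= 0")
    span = probes.regions.chrom_span
    if profile.event_region is not None:
        a, b = profile.event_region
        if not (span[0] <= a < b <= span[1] + 1):
            raise ConfigurationError(f"{profile.sample_id}: event_region outside chromosome span")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(probes)
    pos = probes.pos
    nonpar = probes.is_nonpar_x
    diploid = probes.is_diploid_like
    y = probes.is_y
    q = probes.b_freq

    # --- copy number and reference ---
    c = np.ones(n)
    c_ref = np.full(n, mix.c_ref_hemizygous)
    c[diploid] = 2.0
    c_ref[diploid] = 2.0
    c_ref[y] = 1.0
    if profile.karyotype in XXY_KARYOTYPES:
        c[nonpar] = 2.0
    elif profile.karyotype in MOSAIC_KARYOTYPES:
        f = profile.cell_fraction
        if profile.event_region is None:
            affected = nonpar
        else:
            affected = nonpar & _in_intervals(pos, [profile.event_region])
        delta = f if profile.karyotype == "X_MOSAIC_GAIN" else -f
        c[affected] = 1.0 + delta
    if profile.y_dosage == "GAIN":
        c[y] = 2.0

    lrr = mix.compression * np.log2(c / c_ref)
    if profile.lrr_noise_sd > 0:
        lrr = lrr + rng.normal(0.0, profile.lrr_noise_sd, n)

    # --- genotypes -> BAF targets ---
    hap1 = rng.random(n) < q
    hap2_indep = rng.random(n) < q
    target = hap1.astype(float)  # hemizygous default: 0 or 1
    # diploid-behaving PAR/XTR: X copy + Y-homologous copy, independent alleles
    target[diploid] = (hap1[diploid] + hap2_indep[diploid].astype(float)) / 2.0
    if profile.karyotype in XXY_KARYOTYPES:
        if profile.karyotype == "XXY_FULL_HET":
            second = hap2_indep
        elif profile.karyotype == "XXY_ISODISOMY":
            second = hap1
        else:  # partial heterodisomy: independent alleles only inside het blocks
            in_block = _in_intervals(pos, profile.het_blocks)
            second = np.where(in_block, hap2_indep, hap1)
        target[nonpar] = (hap1[nonpar] + second[nonpar].astype(float)) / 2.0

    baf = target
    if baf_noise_sd > 0:
        baf = np.clip(target + rng.normal(0.0, baf_noise_sd, n), 0.0, 1.0)

    return SampleIntensity(sample_id=profile.sample_id, lrr=lrr, baf=baf, corrected=False)


@dataclass
class CohortConfig:
    """Composition and noise conditions of a simulated cohort.

    Defaults mirror the study conditions: ages uniform on 37–73, per-sample
    Gaussian LRR noise of SD 0.2 (comfortably under the 0.30 QC cutoff),
    mosaic gains at cellular fractions drawn from the observed 11–25% band,
    and whole-chromosome events unless ``segmental_prob`` is raised.
    """

    counts: dict[str, int] = field(default_factory=lambda: {"XY_NORMAL": 50})
    lrr_noise_sd: float = 0.2
    baf_noise_sd: float = 0.03
    cell_fraction_range: tuple[float, float] = (0.11, 0.25)
    age_range: tuple[int, int] = (37, 73)
    segmental_prob: float = 0.0
    segmental_span_range: tuple[int, int] = (10_000_000, 60_000_000)
    mix: ClusterMixModel = field(default_factory=ClusterMixModel)

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(KARYOTYPES)
        if unknown:
            raise ConfigurationError(f"unknown karyotypes in counts: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ConfigurationError("karyotype counts must be >= 0")
        if sum(self.counts.values()) < 2:
            raise ConfigurationError("cohort needs at least 2 samples (baseline requires multiple males)")
        if self.lrr_noise_sd < 0 or self.baf_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")


def _draw_het_blocks(
    rng: np.random.Generator, probes: ProbeMap, *, min_cov: float = 0.15, max_cov: float = 0.65
) -> list[tuple[int, int]]:
    """Random ancestral-recombination blocks covering 15–65% of the NONPAR span."""
    nonpar_pos = probes.table.loc[probes.is_nonpar_x, "pos"].to_numpy()
    lo, hi = int(nonpar_pos[0]), int(nonpar_pos[-1]) + 1
    span = hi - lo
    for _ in range(200):
        n_blocks = int(rng.integers(1, 4))
        cuts = np.sort(rng.integers(lo, hi, size=2 * n_blocks))
        blocks = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_blocks)]
        blocks = [(a, b) for a, b in blocks if b > a]
        cov = sum(b - a for a, b in blocks) / span
        if blocks and min_cov <= cov <= max_cov:
            return blocks
    # degenerate fallback: one mid-chromosome block at 40% coverage
    mid = (lo + hi) // 2
    w = int(0.2 * span)
    return [(mid - w, mid + w)]


def _draw_event_region(rng: np.random.Generator, config: CohortConfig, probes: ProbeMap) -> tuple[int, int] | None:
    if rng.random() >= config.segmental_prob:
        return None
    lo, hi = probes.regions.chrom_span
    span = int(rng.integers(*config.segmental_span_range))
    start = int(rng.integers(lo, max(lo + 1, hi - span)))
    return (start, min(start + span, hi + 1))


def draw_cohort_profiles(
    config: CohortConfig, probes: ProbeMap, seed: int = 0
) -> list[SampleProfile]:
    """Draw truth profiles for a cohort, deterministic under the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    profiles: list[SampleProfile] = []
    idx = 0
    for karyotype in KARYOTYPES:
        for _ in range(config.counts.get(karyotype, 0)):
            sample_id = f"S{idx:05d}"
            idx += 1
            kwargs: dict = {}
            if karyotype in MOSAIC_KARYOTYPES:
                kwargs["cell_fraction"] = float(rng.uniform(*config.cell_fraction_range))
                kwargs["event_region"] = _draw_event_region(rng, config, probes)
            if karyotype == "XXY_PARTIAL_HET":
                kwargs["het_blocks"] = _draw_het_blocks(rng, probes)
            profiles.append(
                SampleProfile(
                    sample_id=sample_id,
                    karyotype=karyotype,
                    lrr_noise_sd=config.lrr_noise_sd,
                    age=int(rng.integers(config.age_range[0], config.age_range[1] + 1)),
                    **kwargs,
                )
            )
    return profiles


def truth_table(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Machine-readable truth labels, one row per sample."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.sample_id,
                "karyotype": p.karyotype,
                "cell_fraction": p.cell_fraction if p.cell_fraction is not None else np.nan,
                "event_start": p.event_region[0] if p.event_region else -1,
                "event_end": p.event_region[1] if p.event_region else -1,
                "het_blocks": ";".join(f"{a}-{b}" for a, b in (p.het_blocks or [])),
                "y_dosage": p.y_dosage,
                "lrr_noise_sd": p.lrr_noise_sd,
                "age": p.age,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig, probes: ProbeMap, seed: int = 0
) -> tuple[list[SampleIntensity], pd.DataFrame]:
    """Simulate a cohort; returns (samples, truth table).  Deterministic under seed."""
    profiles = draw_cohort_profiles(config, probes, seed)
    child_seeds = np.random.SeedSequence([seed, 2]).generate_state(len(profiles))
    samples = [
        simulate_sample(p, probes, config.mix, int(s) % (2**31), baf_noise_sd=config.baf_noise_sd)
        for p, s in zip(profiles, child_seeds)
    ]
    return samples, truth_table(profiles)
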