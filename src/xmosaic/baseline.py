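"""Male-specific LRR baseline correction and per-sample QC.

Raw male chrX LRR from mixed-sex genotyping clusters sits well below zero:
the expected intensity is computed against a reference containing diploid
female X signal, so a hemizygous male probe reads log2(1 / c_ref) < 0.
Detection of dosage changes in males therefore first builds a per-probe
baseline — the median raw LRR of every probe across all male samples — and
subtracts it, centring normal male chrX at 0 so the usual mosaicism
thresholds apply.

Sample-level QC follows the array convention of excluding noisy samples:
a sample is dropped when the standard deviation of its corrected chrX LRR
is >= 0.30 (inclusive).  The SD uses the population formula (divisor n);
the inclusive cutoff, not the divisor, dominates boundary behaviour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .regions import ProbeMap

SD_CUTOFF_DEFAULT = 0.30


@dataclass(eq=False)  # identity semantics: probe vectors make field equality ill-defined
class SampleIntensity:
    """Per-probe LRR and BAF for one sample, aligned to a ProbeMap.

    ``corrected`` records whether ``lrr`` has had the male baseline
    subtracted.  ``lrr_sd`` and ``median_chrx_lrr`` are filled by QC.
    """

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    corrected: bool = False
    lrr_sd: float | None = None
    median_chrx_lrr: float | None = None

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise InputError(f"{self.sample_id}: LRR and BAF lengths differ")
        finite = self.baf[np.isfinite(self.baf)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise InputError(f"{self.sample_id}: BAF outside [0, 1]")


@dataclass
class BaselineVector:
    """Per-probe median raw LRR across all male samples."""

    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _check_alignment(samples: Sequence[SampleIntensity]) -> int:
    lengths = {len(s.lrr) for s in samples}
    if len(lengths) != 1:
        raise InputError(f"samples have misaligned probe vectors (lengths {sorted(lengths)})")
    return lengths.pop()


def compute_probe_baseline(samples: Sequence[SampleIntensity]) -> BaselineVector:
    """Median raw LRR per probe across samples (NaN-aware; even counts use the midpoint)."""
    samples = list(samples)
    if len(samples) < 2:
        raise InputError("baseline needs at least 2 male samples")
    _check_alignment(samples)
    stack = np.vstack([s.lrr for s in samples])
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(stack, axis=0)
    return BaselineVector(values=med, n_samples=len(samples))


def apply_baseline(sample: SampleIntensity, baseline: BaselineVector) -> SampleIntensity:
    """Subtract the male-specific baseline from a raw sample; BAF is untouched."""
    if len(sample.lrr) != len(baseline.values):
        raise InputError(
            f"{sample.sample_id}: probe vector length {len(sample.lrr)} "
            f"!= baseline length {len(baseline.values)}"
        )
    return dataclasses.replace(
        sample,
        lrr=sample.lrr - baseline.values,
        corrected=True,
        lrr_sd=None,
        median_chrx_lrr=None,
    )


def median_chrx_lrr(sample: SampleIntensity, probes: ProbeMap, *, include_par: bool = True) -> float:
    """Median corrected LRR over chrX probes.

    PAR/XTR probes are included by default ("all probes on the X
    chromosome"); set ``include_par=False`` to restrict to hemizygous
    sequence.  NaN probes are dropped.
    """
    mask = probes.is_x if include_par else probes.is_nonpar_x
    if not mask.any():
        raise InputError("probe map has no chrX probes")
    vals = sample.lrr[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise InputError(f"{sample.sample_id}: no finite chrX LRR values")
    return float(np.median(vals))


def chrx_lrr_sd(sample: SampleIntensity, probes: ProbeMap, *, include_par: bool = True) -> float:
    """Population SD (divisor n) of chrX LRR; NaN probes dropped."""
    mask = probes.is_x if include_par else probes.is_nonpar_x
    vals = sample.lrr[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise InputError(f"{sample.sample_id}: no finite chrX LRR values")
    return float(np.std(vals))


def annotate_qc_stats(
    sample: SampleIntensity, probes: ProbeMap, *, include_par: bool = True
) -> SampleIntensity:
    """Fill ``lrr_sd`` and ``median_chrx_lrr`` in place and return the sample."""
    sample.median_chrx_lrr = median_chrx_lrr(sample, probes, include_par=include_par)
    sample.lrr_sd = chrx_lrr_sd(sample, probes, include_par=include_par)
    return sample


def qc_filter(
    samples: Iterable[SampleIntensity],
    probes: ProbeMap,
    sd_cutoff: float = SD_CUTOFF_DEFAULT,
    *,
    include_par: bool = True,
) -> tuple[list[SampleIntensity], list[tuple[SampleIntensity, str]]]:
    """Partition samples into (kept, excluded-with-reason) by chrX LRR variability.

    Exclusion rule is inclusive at the boundary: SD >= sd_cutoff excludes.
    """
    if sd_cutoff <= 0:
        raise InputError("sd_cutoff must be > 0")
    samples = list(samples)
    if not samples:
        raise InputError("qc_filter received no samples")
    kept: list[SampleIntensity] = []
    excluded: list[tuple[SampleIntensity, str]] = []
    for s in samples:
        annotate_qc_stats(s, probes, include_par=include_par)
        if s.lrr_sd >= sd_cutoff:
            excluded.append((s, f"chrX LRR SD {s.lrr_sd:.4f} >= {sd_cutoff:g}"))
        else:
            kept.append(s)
    return kept, excluded
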