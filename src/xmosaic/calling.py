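"""Mosaic-event calling, cellular-fraction estimation and karyotype verdicts.

Segments surviving CBS are filtered with the standard array-mosaicism
thresholds for the male X: |median LRR| >= 0.15 (moderate) or >= 0.25
(high), at least 200 probes, and a genomic span of at least 2 Mb.  The
cellular fraction of a mosaic event follows from the hemizygous dosage
model: an event present in a fraction ``f`` of cells shifts average copy
number from 1 to 1 + f (gain) or 1 - f (loss), so

    gain:  f = 2**LRR - 1        loss:  f = 1 - 2**LRR

At the moderate threshold this gives f = 2**0.15 - 1 = 0.110, i.e. the ~11%
lower bound of detectable clones; at the high threshold f = 0.189.  (The
literature sometimes rounds the latter to "20% of leukocytes"; the exact
model value is reported here.)

A whole-chromosome median LRR >= 0.4 is not mosaic at all but constitutional
XXY (Klinefelter syndrome): every cell carries two X copies, so no cell
fraction is attached.  Y-probe dosage is checked for X-gain candidates to
confirm the sample is karyotypically male.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline import SampleIntensity
from .errors import InputError
from .regions import ProbeMap
from .segmentation import Segment

MODERATE_DEFAULT = 0.15
HIGH_DEFAULT = 0.25
MIN_PROBES_DEFAULT = 200
MIN_SPAN_DEFAULT = 2_000_000
XXY_CUT_DEFAULT = 0.4
Y_GAIN_CUT_DEFAULT = 0.3
Y_LOSS_CUT_DEFAULT = -0.5

CALL_CATEGORIES = (
    "NORMAL",
    "MOSAIC_GAIN_MODERATE",
    "MOSAIC_GAIN_HIGH",
    "MOSAIC_LOSS_MODERATE",
    "MOSAIC_LOSS_HIGH",
    "CONSTITUTIONAL_XXY",
)
Y_STATUSES = ("NORMAL_MALE", "Y_GAIN", "Y_LOSS", "UNKNOWN")


@dataclass
class CandidateEvent:
    """A retained segment tagged with direction and evidence tier."""

    segment: Segment
    direction: str  # "gain" | "loss"
    tier: str  # "moderate" | "high"


@dataclass
class SampleCall:
    """Per-sample verdict of the detection pipeline."""

    sample_id: str
    call: str
    median_chrx_lrr: float
    events: list[CandidateEvent] = field(default_factory=list)
    cell_fraction: float | None = None
    y_status: str = "UNKNOWN"
    xxy_origin: str | None = None
    xxy_covered_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.call not in CALL_CATEGORIES:
            raise InputError(f"unknown call category {self.call!r}")
        mosaic = self.call.startswith("MOSAIC")
        if mosaic and self.cell_fraction is None:
            raise InputError(f"{self.sample_id}: mosaic call requires cell_fraction")
        if not mosaic and self.cell_fraction is not None:
            raise InputError(f"{self.sample_id}: cell_fraction only attaches to mosaic calls")
        if (self.xxy_origin is not None) and self.call != "CONSTITUTIONAL_XXY":
            raise InputError(f"{self.sample_id}: xxy_origin only attaches to CONSTITUTIONAL_XXY")


def filter_candidate_segments(
    segments: list[Segment],
    moderate: float = MODERATE_DEFAULT,
    high: float = HIGH_DEFAULT,
    min_probes: int = MIN_PROBES_DEFAULT,
    min_span: int = MIN_SPAN_DEFAULT,
) -> list[CandidateEvent]:
    """Retain segments passing the event thresholds; all comparisons inclusive.

    Retention: |median LRR| >= moderate AND n_probes >= min_probes AND
    span >= min_span.  Retained events are tagged high when
    |median LRR| >= high; the sign of the median sets gain vs loss.
    """
    if moderate <= 0 or high <= 0 or min_probes < 1:
        raise InputError("thresholds must be positive and min_probes >= 1")
    events: list[CandidateEvent] = []
    for seg in segments:
        if not np.isfinite(seg.median_lrr):
            continue
        if abs(seg.median_lrr) < moderate:
            continue
        if seg.n_probes < min_probes or seg.span_bp < min_span:
            continue
        events.append(
            CandidateEvent(
                segment=seg,
                direction="gain" if seg.median_lrr > 0 else "loss",
                tier="high" if abs(seg.median_lrr) >= high else "moderate",
            )
        )
    return events


def estimate_cell_fraction(median_lrr: float, direction: str) -> float:
    """Fraction of cells carrying the event, from the hemizygous dosage model."""
    if direction == "gain":
        if median_lrr < 0:
            raise InputError("gain requires median_lrr >= 0")
        f = 2.0**median_lrr - 1.0
    elif direction == "loss":
        if median_lrr > 0:
            raise InputError("loss requires median_lrr <= 0")
        f = 1.0 - 2.0**median_lrr
    else:
        raise InputError(f"direction must be 'gain' or 'loss', got {direction!r}")
    return float(np.clip(f, 0.0, 1.0))


def check_y_dosage(
    sample: SampleIntensity,
    probes: ProbeMap,
    gain_cut: float = Y_GAIN_CUT_DEFAULT,
    loss_cut: float = Y_LOSS_CUT_DEFAULT,
) -> str:
    """Classify Y dosage from the median corrected Y-probe LRR."""
    y = probes.is_y
    if not y.any():
        import warnings

        warnings.warn("probe map has no Y probes; Y dosage unknown")
        return "UNKNOWN"
    vals = sample.lrr[y]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return "UNKNOWN"
    med = float(np.median(vals))
    if med >= gain_cut:
        return "Y_GAIN"
    if med <= loss_cut:
        return "Y_LOSS"
    return "NORMAL_MALE"


def classify_sample(
    sample_id: str,
    median_chrx_lrr: float,
    events: list[CandidateEvent],
    y_status: str = "UNKNOWN",
    xxy_cut: float = XXY_CUT_DEFAULT,
) -> SampleCall:
    """Combine whole-chromosome dosage and retained events into a verdict.

    Priority: whole-chromosome median >= xxy_cut is constitutional XXY;
    otherwise the highest-tier retained event (widest within the tier) sets
    the call, with the cellular fraction estimated from the widest retained
    event; no events means NORMAL.
    """
    if median_chrx_lrr >= xxy_cut:
        return SampleCall(
            sample_id=sample_id,
            call="CONSTITUTIONAL_XXY",
            median_chrx_lrr=median_chrx_lrr,
            events=list(events),
            y_status=y_status,
        )
    if not events:
        return SampleCall(
            sample_id=sample_id, call="NORMAL", median_chrx_lrr=median_chrx_lrr, y_status=y_status
        )
    tier = "high" if any(e.tier == "high" for e in events) else "moderate"
    top = max((e for e in events if e.tier == tier), key=lambda e: e.segment.span_bp)
    widest = max(events, key=lambda e: e.segment.span_bp)
    call = f"MOSAIC_{top.direction.upper()}_{tier.upper()}"
    return SampleCall(
        sample_id=sample_id,
        call=call,
        median_chrx_lrr=median_chrx_lrr,
        events=list(events),
        cell_fraction=estimate_cell_fraction(widest.segment.median_lrr, widest.direction),
        y_status=y_status,
    )
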