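"""End-to-end detection pipeline and its configuration.

Stage order matches the array-mosaicism workflow for the male X:
baseline -> QC -> outlier smoothing -> CBS -> undo-splits -> event
filtering -> calling (with Y-dosage verification) -> XXY origin
classification.  Both the raw and the undo-splits segmentations are kept;
the undo-splits result is primary, since the pass exists to remove
change-points driven by local trends.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import baseline as bl
from . import calling, io, segmentation, xxy
from .baseline import SampleIntensity
from .errors import ConfigurationError, InputError
from .regions import GenomeRegions, ProbeMap
from .segmentation import Segment
from .xxy import HetBlock


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the detection pipeline, with defaults."""

    # QC
    sd_cutoff: float = bl.SD_CUTOFF_DEFAULT
    include_par: bool = True
    # smoothing + CBS
    smooth_window: int = segmentation.SMOOTH_WINDOW_DEFAULT
    clip_sd: float = segmentation.CLIP_SD_DEFAULT
    alpha: float = segmentation.ALPHA_DEFAULT
    n_perm: int = segmentation.N_PERM_DEFAULT
    undo_sd: float = segmentation.UNDO_SD_DEFAULT
    kmax: int = segmentation.KMAX_DEFAULT
    full_scan_max: int = segmentation.FULL_SCAN_MAX_DEFAULT
    # event thresholds
    moderate: float = calling.MODERATE_DEFAULT
    high: float = calling.HIGH_DEFAULT
    min_probes: int = calling.MIN_PROBES_DEFAULT
    min_span: int = calling.MIN_SPAN_DEFAULT
    xxy_cut: float = calling.XXY_CUT_DEFAULT
    y_gain_cut: float = calling.Y_GAIN_CUT_DEFAULT
    y_loss_cut: float = calling.Y_LOSS_CUT_DEFAULT
    # XXY origin
    het_band: float = xxy.BAND_DEFAULT
    min_block_probes: int = xxy.MIN_BLOCK_PROBES_DEFAULT
    max_gap_bp: int = xxy.MAX_GAP_BP_DEFAULT
    full_cut: float = xxy.FULL_CUT_DEFAULT
    none_cut: float = xxy.NONE_CUT_DEFAULT
    # randomness
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    """Everything the pipeline derived for one QC-passing sample."""

    sample: SampleIntensity
    smoothed_x_lrr: np.ndarray
    segments_raw: list[Segment]
    segments: list[Segment]  # undo-splits result (primary)
    call: calling.SampleCall
    het_blocks: list[HetBlock] = field(default_factory=list)


@dataclass
class DetectionResult:
    probes: ProbeMap
    baseline: bl.BaselineVector
    results: list[SampleResult]
    excluded: list[tuple[SampleIntensity, str]]

    @property
    def calls(self) -> list[calling.SampleCall]:
        return [r.call for r in self.results]


def detect_sample(
    sample: SampleIntensity,
    probes: ProbeMap,
    config: PipelineConfig,
    seed: int,
) -> SampleResult:
    """Run smoothing, CBS, filtering and classification on one corrected sample."""
    if not sample.corrected:
        raise InputError(f"{sample.sample_id}: baseline correction must run before detection")
    is_x = probes.is_x
    lrr_x = sample.lrr[is_x]
    pos_x = probes.x_pos
    smoothed = segmentation.smooth_outliers(lrr_x, config.smooth_window, config.clip_sd)
    segs_raw = segmentation.cbs_segment(
        smoothed,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seed,
        sample_id=sample.sample_id,
        kmax=config.kmax,
        full_scan_max=config.full_scan_max,
    )
    segs_raw = segmentation.segment_stats(segs_raw, smoothed, pos_x)
    segs = segmentation.undo_splits(segs_raw, smoothed, config.undo_sd)
    segs = segmentation.segment_stats(segs, smoothed, pos_x)
    events = calling.filter_candidate_segments(
        segs, config.moderate, config.high, config.min_probes, config.min_span
    )
    y_status = calling.check_y_dosage(sample, probes, config.y_gain_cut, config.y_loss_cut)
    if sample.median_chrx_lrr is None:
        bl.annotate_qc_stats(sample, probes, include_par=config.include_par)
    call = calling.classify_sample(
        sample.sample_id, sample.median_chrx_lrr, events, y_status, config.xxy_cut
    )
    blocks: list[HetBlock] = []
    if call.call == "CONSTITUTIONAL_XXY":
        mask = xxy.call_het_probes(sample.baf, probes, config.het_band)
        blocks = xxy.segment_het_blocks(mask, probes, config.min_block_probes, config.max_gap_bp)
        origin, frac = xxy.classify_xxy_origin(
            blocks, probes.nonpar_span(), config.full_cut, config.none_cut
        )
        call.xxy_origin = origin
        call.xxy_covered_fraction = frac
    return SampleResult(
        sample=sample,
        smoothed_x_lrr=smoothed,
        segments_raw=segs_raw,
        segments=segs,
        call=call,
        het_blocks=blocks,
    )


def detect_cohort(
    raw_samples: Sequence[SampleIntensity],
    probes: ProbeMap,
    config: PipelineConfig | None = None,
) -> DetectionResult:
    """Full pipeline on a cohort of raw samples."""
    config = config or PipelineConfig()
    raw_samples = list(raw_samples)
    if not raw_samples:
        raise InputError("no samples to analyse")
    baseline = bl.compute_probe_baseline(raw_samples)
    corrected = [bl.apply_baseline(s, baseline) for s in raw_samples]
    kept, excluded = qc = bl.qc_filter(
        corrected, probes, config.sd_cutoff, include_par=config.include_par
    )
    seeds = np.random.SeedSequence([config.seed, 3]).generate_state(max(len(kept), 1))
    results = [
        detect_sample(s, probes, config, int(seeds[i]) % (2**31)) for i, s in enumerate(kept)
    ]
    return DetectionResult(probes=probes, baseline=baseline, results=results, excluded=excluded)


def write_outputs(result: DetectionResult, out_dir: str | Path, config: PipelineConfig) -> dict[str, Path]:
    """Write calls / QC / events / segments / het-block tables plus a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kept = [r.sample for r in result.results]
    paths = {
        "calls": io.write_frame(io.calls_frame(result.calls), out / "calls.tsv"),
        "qc": io.write_frame(
            io.qc_frame(kept, result.excluded, len(result.probes)), out / "qc.tsv"
        ),
        "events": io.write_frame(
            io.events_bed_frame([e for r in result.results for e in r.call.events]),
            out / "events.bed",
        ),
        "segments": io.write_frame(
            io.segments_bed_frame([s for r in result.results for s in r.segments]),
            out / "segments.bed",
        ),
        "segments_raw": io.write_frame(
            io.segments_bed_frame([s for r in result.results for s in r.segments_raw]),
            out / "segments_raw.bed",
        ),
        "het_blocks": io.write_frame(
            io.het_blocks_bed_frame(
                {r.sample.sample_id: r.het_blocks for r in result.results if r.het_blocks}
            ),
            out / "het_blocks.bed",
        ),
    }
    log = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_samples": len(result.results) + len(result.excluded),
        "n_qc_excluded": len(result.excluded),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    paths["run_log"] = log_path
    return paths


def run_detect(
    probes_path: str | Path,
    intensities_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    regions: GenomeRegions | None = None,
) -> DetectionResult:
    """File-driven entry point: read inputs, run the pipeline, write outputs."""
    config = config or PipelineConfig()
    probes = io.read_probe_map(probes_path, regions=regions)
    samples = io.read_intensities(intensities_path, probes)
    result = detect_cohort(samples, probes, config)
    write_outputs(result, out_dir, config)
    return result
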