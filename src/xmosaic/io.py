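"""Plain-text readers and writers for the pipeline's tabular formats.

Formats (TSV; gzip-compressed variants accepted by extension):

* probe map      — probe_id, chrom, pos, region_flag, b_freq
* intensities    — long format: sample_id, probe_id, chrom, pos, LRR, BAF
* truth table    — one row per simulated sample
* QC table       — sample_id, n_probes, median_chrx_lrr, lrr_sd, qc_pass, reason
* calls table    — one verdict row per sample
* events / blocks — BED-like: chrom, start (0-based half-open), end, ...
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import SampleIntensity
from .calling import CandidateEvent, SampleCall
from .errors import InputError
from .regions import GenomeRegions, ProbeMap
from .segmentation import Segment
from .xxy import HetBlock

FLOAT_FMT = "%.6g"


def write_probe_map(probes: ProbeMap, path: str | Path) -> Path:
    path = Path(path)
    probes.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_probe_map(path: str | Path, regions: GenomeRegions | None = None) -> ProbeMap:
    table = pd.read_csv(path, sep="\t")
    return ProbeMap(table, regions=regions or GenomeRegions())


def write_intensities(
    samples: Iterable[SampleIntensity], probes: ProbeMap, path: str | Path
) -> Path:
    path = Path(path)
    frames = []
    base = probes.table[["probe_id", "chrom", "pos"]]
    for s in samples:
        if len(s.lrr) != len(probes):
            raise InputError(f"{s.sample_id}: intensity vector not aligned to probe map")
        frames.append(base.assign(sample_id=s.sample_id, LRR=s.lrr, BAF=s.baf))
    long = pd.concat(frames, ignore_index=True)
    long = long[["sample_id", "probe_id", "chrom", "pos", "LRR", "BAF"]]
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_intensities(path: str | Path, probes: ProbeMap) -> list[SampleIntensity]:
    """Read long-format intensities and align each sample to the probe map order."""
    long = pd.read_csv(path, sep="\t")
    required = {"sample_id", "probe_id", "LRR", "BAF"}
    missing = required - set(long.columns)
    if missing:
        raise InputError(f"intensity file missing columns: {sorted(missing)}")
    if long.empty:
        raise InputError("intensity file contains no rows")
    order = pd.Series(np.arange(len(probes)), index=probes.table["probe_id"])
    samples = []
    for sample_id, grp in long.groupby("sample_id", sort=True):
        if len(grp) != len(probes) or not set(grp["probe_id"]) == set(order.index):
            raise InputError(f"{sample_id}: probes do not match the probe map")
        grp = grp.set_index("probe_id").loc[probes.table["probe_id"]]
        samples.append(
            SampleIntensity(
                sample_id=str(sample_id),
                lrr=grp["LRR"].to_numpy(),
                baf=grp["BAF"].to_numpy(),
            )
        )
    return samples


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def qc_frame(
    kept: Sequence[SampleIntensity],
    excluded: Sequence[tuple[SampleIntensity, str]],
    n_probes: int,
) -> pd.DataFrame:
    rows = []
    for s in kept:
        rows.append((s.sample_id, n_probes, s.median_chrx_lrr, s.lrr_sd, True, ""))
    for s, reason in excluded:
        rows.append((s.sample_id, n_probes, s.median_chrx_lrr, s.lrr_sd, False, reason))
    df = pd.DataFrame(
        rows, columns=["sample_id", "n_probes", "median_chrx_lrr", "lrr_sd", "qc_pass", "reason"]
    )
    return df.sort_values("sample_id", ignore_index=True)


def calls_frame(calls: Sequence[SampleCall]) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda c: c.sample_id):
        widest = max((e.segment.span_bp for e in c.events), default=0)
        rows.append(
            {
                "sample_id": c.sample_id,
                "call": c.call,
                "median_chrx_lrr": c.median_chrx_lrr,
                "n_events": len(c.events),
                "widest_event_span": widest,
                "cell_fraction": c.cell_fraction if c.cell_fraction is not None else np.nan,
                "y_status": c.y_status,
                "xxy_origin": c.xxy_origin or "",
                "xxy_covered_fraction": (
                    c.xxy_covered_fraction if c.xxy_covered_fraction is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def events_bed_frame(events: Sequence[CandidateEvent]) -> pd.DataFrame:
    rows = [
        {
            "chrom": "X",
            "start": e.segment.start_pos - 1,  # BED: 0-based half-open
            "end": e.segment.end_pos,
            "sample_id": e.segment.sample_id,
            "n_probes": e.segment.n_probes,
            "median_lrr": e.segment.median_lrr,
            "direction": e.direction,
            "tier": e.tier,
        }
        for e in events
    ]
    cols = ["chrom", "start", "end", "sample_id", "n_probes", "median_lrr", "direction", "tier"]
    return pd.DataFrame(rows, columns=cols)


def segments_bed_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    rows = [
        {
            "chrom": "X",
            "start": s.start_pos - 1,
            "end": s.end_pos,
            "sample_id": s.sample_id,
            "n_probes": s.n_probes,
            "median_lrr": s.median_lrr,
        }
        for s in segments
    ]
    cols = ["chrom", "start", "end", "sample_id", "n_probes", "median_lrr"]
    return pd.DataFrame(rows, columns=cols)


def het_blocks_bed_frame(blocks_by_sample: dict[str, list[HetBlock]]) -> pd.DataFrame:
    rows = [
        {
            "chrom": "X",
            "start": b.start_pos - 1,
            "end": b.end_pos,
            "sample_id": sid,
            "n_het_probes": b.n_het_probes,
            "het_density": b.het_density,
        }
        for sid, blocks in sorted(blocks_by_sample.items())
        for b in blocks
    ]
    cols = ["chrom", "start", "end", "sample_id", "n_het_probes", "het_density"]
    return pd.DataFrame(rows, columns=cols)


def write_frame(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path
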