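"""Review figures: the age boxplot and per-sample LRR/BAF panels.

Flagged samples (retained events or constitutional XXY) each get a
two-panel review figure, mirroring the manual-review step of the detection
workflow; unflagged samples get none.  Figures are artifacts for a human
reviewer — assertions in tests only touch the underlying data arrays.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .baseline import SampleIntensity
from .pipeline import DetectionResult, SampleResult
from .regions import ProbeMap
from .segmentation import Segment

MODERATE_LINE = 0.15
XXY_LINE = 0.4


def plot_age_boxplot(
    calls: pd.DataFrame,
    out_path: str | Path,
    *,
    moderate: float = MODERATE_LINE,
    xxy_cut: float = XXY_LINE,
) -> Path | None:
    """Boxplots of corrected median chrX LRR per 1-year age bin.

    Horizontal references: +/-moderate (blue, mosaicism evidence) and
    xxy_cut (green, constitutional XXY).  ``calls`` needs columns
    ``median_chrx_lrr`` and ``age``; missing ages skip the plot.
    """
    if "age" not in calls.columns or calls["age"].isna().all():
        warnings.warn("no ages available; skipping age boxplot")
        return None
    df = calls.dropna(subset=["age", "median_chrx_lrr"]).copy()
    df["age"] = df["age"].astype(int)
    ages = sorted(df["age"].unique())
    groups = [df.loc[df["age"] == a, "median_chrx_lrr"].to_numpy() for a in ages]
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(ages)), 4))
    ax.boxplot(groups, positions=ages, widths=0.7, manage_ticks=False)
    for y in (moderate, -moderate):
        ax.axhline(y, color="tab:blue", lw=1)
    ax.axhline(xxy_cut, color="tab:green", lw=1)
    ax.set_xlabel("age at sample collection (years)")
    ax.set_ylabel("baseline-corrected median chrX LRR")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_sample_review(
    sample: SampleIntensity,
    segments: list[Segment],
    probes: ProbeMap,
    out_path: str | Path,
) -> Path:
    """Two-panel figure: corrected LRR with segment medians, and BAF with PAR/XTR shading."""
    is_x = probes.is_x
    pos = probes.x_pos / 1e6
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax1.plot(pos, sample.lrr[is_x], ".", ms=1, color="0.6")
    for s in segments:
        ax1.hlines(s.median_lrr, s.start_pos / 1e6, s.end_pos / 1e6, color="tab:red", lw=2)
    ax1.axhline(0, color="0.3", lw=0.5)
    ax1.set_ylabel("corrected LRR")
    ax1.set_title(sample.sample_id)
    ax2.plot(pos, sample.baf[is_x], ".", ms=1, color="0.4")
    for name, (a, b) in (
        ("PAR1", probes.regions.par1),
        ("XTR", probes.regions.xtr),
        ("PAR2", probes.regions.par2),
    ):
        ax2.axvspan(a / 1e6, b / 1e6, color="tab:orange", alpha=0.2)
        ax2.text((a + b) / 2e6, 1.04, name, ha="center", fontsize=7)
    ax2.set_ylim(-0.05, 1.1)
    ax2.set_ylabel("BAF")
    ax2.set_xlabel("chrX position (Mb)")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def is_flagged(result: SampleResult) -> bool:
    """A sample is flagged for review when it has retained events or is XXY."""
    return bool(result.call.events) or result.call.call == "CONSTITUTIONAL_XXY"


def plot_flagged_samples(result: DetectionResult, out_dir: str | Path) -> dict[str, Path]:
    """One review figure per flagged sample; none for unflagged samples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for r in result.results:
        if is_flagged(r):
            paths[r.sample.sample_id] = plot_sample_review(
                r.sample, r.segments, result.probes, out / f"review_{r.sample.sample_id}.png"
            )
    return paths
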