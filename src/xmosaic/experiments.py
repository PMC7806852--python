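"""Reusable simulation experiments that characterise the pipeline.

Each function simulates data under the study conditions (18,000-probe
chrX map, LRR noise SD 0.2, mosaic fractions in the detectable 11–30%
band), runs the relevant pipeline stage from scratch, and returns the
measured operating characteristics.  They back both the validation test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baseline as bl
from .calling import estimate_cell_fraction
from .pipeline import PipelineConfig, detect_sample
from .regions import ProbeMap, build_probe_map
from .segmentation import cbs_segment, max_arc_statistic, pooled_t_statistic
from .simulate import ClusterMixModel, SampleProfile, simulate_sample
from .xxy import call_het_probes, classify_xxy_origin, segment_het_blocks

N_PROBES_DEFAULT = 18_000
NOISE_SD_DEFAULT = 0.2


def _seed_of(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0]) % (2**31)


def study_probe_map(seed: int, n_probes: int = N_PROBES_DEFAULT, n_y_probes: int = 100) -> ProbeMap:
    return build_probe_map(n_probes, n_y_probes=n_y_probes, seed=_seed_of(seed, 101))


# ---------------------------------------------------------------------------
# baseline centering
# ---------------------------------------------------------------------------


def centering_residual(seed: int, n_samples: int = 41, n_probes: int = 3000) -> float:
    """Max |per-probe cross-sample median| of corrected LRR on a male cohort.

    Exactly 0 by the median-subtraction construction; returned as measured.
    """
    probes = study_probe_map(seed, n_probes, n_y_probes=50)
    samples = [
        simulate_sample(
            SampleProfile(f"N{i:03d}", "XY_NORMAL", lrr_noise_sd=NOISE_SD_DEFAULT),
            probes,
            seed=_seed_of(seed, 201, i),
        )
        for i in range(n_samples)
    ]
    baseline = bl.compute_probe_baseline(samples)
    corrected = np.vstack([bl.apply_baseline(s, baseline).lrr for s in samples])
    return float(np.max(np.abs(np.median(corrected, axis=0))))


# ---------------------------------------------------------------------------
# CBS operating characteristics
# ---------------------------------------------------------------------------


def brute_force_best_split(x: np.ndarray) -> tuple[int, int]:
    """Independent oracle: exhaustive pooled-t maximisation over all arcs (i, j]."""
    n = len(x)
    best = (-np.inf, 0, 0)
    for i in range(n - 1):
        for j in range(i + 1, n):  # arcs ending at n duplicate prefix splits
            t = abs(pooled_t_statistic(x, i, j))
            if t > best[0]:
                best = (t, i, j)
    return best[1], best[2]


def oracle_split_agreement(seed: int, n_trials: int = 100) -> float:
    """Fraction of short random vectors where the CBS split equals the oracle's."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 301]))
    hits = 0
    for _ in range(n_trials):
        n = int(rng.integers(4, 13))
        x = rng.normal(0.0, 1.0, n)
        i, j, _ = max_arc_statistic(x)
        hits += (i, j) == brute_force_best_split(x)
    return hits / n_trials


def type_one_single_segment_rate(
    seed: int,
    n_vectors: int = 100,
    n_probes: int = 2000,
    noise_sd: float = NOISE_SD_DEFAULT,
    alpha: float = 0.01,
) -> float:
    """Fraction of pure-noise vectors segmented into exactly one segment."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 401]))
    single = 0
    for v in range(n_vectors):
        x = rng.normal(0.0, noise_sd, n_probes)
        segs = cbs_segment(x, alpha=alpha, seed=_seed_of(seed, 402, v))
        single += len(segs) == 1
    return single / n_vectors


# ---------------------------------------------------------------------------
# cell-fraction recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    table: pd.DataFrame  # one row per replicate: f_true, f_hat, call

    @property
    def within_tolerance_rate(self) -> float:
        ok = (self.table["f_hat"] - self.table["f_true"]).abs() <= 0.02
        return float(ok.mean())

    @property
    def n_false_loss_or_xxy(self) -> int:
        bad = self.table["call"].str.contains("LOSS") | (self.table["call"] == "CONSTITUTIONAL_XXY")
        return int(bad.sum())

    @property
    def max_abs_error(self) -> float:
        return float((self.table["f_hat"] - self.table["f_true"]).abs().max())


def cell_fraction_recovery(
    seed: int,
    fractions: tuple[float, ...] = (0.12, 0.15, 0.20, 0.30),
    n_reps: int = 20,
    n_probes: int = N_PROBES_DEFAULT,
    noise_sd: float = NOISE_SD_DEFAULT,
    n_reference: int = 60,
) -> RecoveryResult:
    """Simulate whole-chromosome gains and re-estimate their cellular fraction.

    Each replicate sample joins a reference cohort of ``n_reference`` normal
    males for baseline construction (events are rare in any realistic male
    cohort, so the per-probe median is effectively event-free), then runs
    the full detection path: correction, smoothing, CBS, undo-splits,
    filtering and calling.
    """
    probes = study_probe_map(seed, n_probes)
    config = PipelineConfig(seed=_seed_of(seed, 501))
    normals = [
        simulate_sample(
            SampleProfile(f"N{i:03d}", "XY_NORMAL", lrr_noise_sd=noise_sd),
            probes,
            seed=_seed_of(seed, 502, i),
        )
        for i in range(n_reference)
    ]
    rows = []
    for fi, f in enumerate(fractions):
        for rep in range(n_reps):
            prof = SampleProfile(
                f"G_{fi}_{rep:02d}", "X_MOSAIC_GAIN", cell_fraction=f, lrr_noise_sd=noise_sd
            )
            sample = simulate_sample(prof, probes, seed=_seed_of(seed, 503, fi, rep))
            baseline = bl.compute_probe_baseline([*normals, sample])
            corrected = bl.apply_baseline(sample, baseline)
            bl.annotate_qc_stats(corrected, probes)
            res = detect_sample(corrected, probes, config, _seed_of(seed, 504, fi, rep))
            rows.append(
                {
                    "f_true": f,
                    "f_hat": res.call.cell_fraction if res.call.cell_fraction is not None else np.nan,
                    "call": res.call.call,
                }
            )
    return RecoveryResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# XXY origin confusion matrix
# ---------------------------------------------------------------------------

_XXY_TRUTH_TO_ORIGIN = {
    "XXY_FULL_HET": "FULL_HETERODISOMY",
    "XXY_PARTIAL_HET": "PARTIAL_HETERODISOMY",
    "XXY_ISODISOMY": "ISODISOMY",
}


def xxy_origin_confusion(
    seed: int,
    n_per_subtype: int = 30,
    n_probes: int = N_PROBES_DEFAULT,
    baf_noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Confusion matrix (truth x predicted) of XXY origin classification."""
    from .simulate import _draw_het_blocks  # deterministic block sampler

    probes = study_probe_map(seed, n_probes)
    span = probes.nonpar_span()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 601]))
    counts: dict[tuple[str, str], int] = {}
    for ki, (karyotype, truth_origin) in enumerate(_XXY_TRUTH_TO_ORIGIN.items()):
        for rep in range(n_per_subtype):
            blocks = _draw_het_blocks(rng, probes) if karyotype == "XXY_PARTIAL_HET" else None
            prof = SampleProfile(
                f"K_{karyotype}_{rep:02d}", karyotype, het_blocks=blocks, lrr_noise_sd=NOISE_SD_DEFAULT
            )
            s = simulate_sample(prof, probes, seed=_seed_of(seed, 602, ki, rep),
                                baf_noise_sd=baf_noise_sd)
            mask = call_het_probes(s.baf, probes)
            het_blocks = segment_het_blocks(mask, probes)
            origin, _ = classify_xxy_origin(het_blocks, span)
            counts[(truth_origin, origin)] = counts.get((truth_origin, origin), 0) + 1
    origins = list(_XXY_TRUTH_TO_ORIGIN.values())
    return pd.DataFrame(
        [[counts.get((t, p), 0) for p in origins] for t in origins],
        index=origins,
        columns=origins,
    )


def fraction_lrr_identity() -> float:
    """Cellular fraction (percent) implied by the moderate LRR threshold 0.15."""
    return 100.0 * estimate_cell_fraction(0.15, "gain")
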