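# Methods

## Intensity model and why a male-specific baseline exists

Array LRR is the log2 ratio of observed to expected probe intensity, a proxy
for copy-number dosage. When genotyping cluster files are built from males
and females together, the expected intensity at a hemizygous chrX probe
corresponds to a reference copy number

    c_ref = (1 − w)·1 + w·2 = 1 + w,

where `w` is the female fraction of the cluster reference. A normal male
(one X copy) therefore reads `log2(1 / (1 + w))` — about −0.585 at w = 0.5 —
instead of 0. PAR1, PAR2 and the XTR behave as diploid sequence in males
(two copies in both sample and reference), so their raw offset is ≈ 0.

The correction takes, per probe, the median raw LRR across all male samples
and subtracts it. Two consequences used as tests:

* the per-probe cross-sample median of corrected LRR is **exactly** zero
  (for an odd sample count the median is an order statistic, so the central
  sample's corrected value is 0.0 in floating point as well);
* the correction is idempotent — recomputing the baseline on corrected data
  gives the zero vector.

The baseline is computed **before** QC exclusion: the median is robust to
the few high-variability samples, and this keeps the corrected values of
excluded samples interpretable for review. In cohorts where events are not
rare the baseline median can absorb part of the event signal; with a
realistic event prevalence (a handful per thousand or fewer) the effect is
negligible, and the recovery experiment keeps one event sample per ~60
reference males for this reason.

## QC

Per sample, median and population SD (divisor n) of corrected LRR over all
chrX probes (PAR/XTR included by default; a switch restricts to hemizygous
probes). Samples with SD ≥ 0.30 are excluded; the boundary is inclusive, and
with a 0.30 cutoff the divisor convention is immaterial in practice. NaN
probes are dropped probe-wise from all medians and SDs.

## Segmentation

CBS treats each interval as a circle and compares every arc (i, j] against
its complement. The test statistic is the two-sample pooled-variance t. For
a fixed interval the pooled-t is a strictly increasing function of the
constant-variance form `Z = (mean_in − mean_out)/sqrt(1/k + 1/(n−k))`
(between-group sum-of-squares identity), so the implementation maximises |Z|
via cumulative sums — identical argmax, identical permutation distribution
of the maximum, O(n) per candidate arc length.

* **Candidate arcs.** Up to n = 1000 the scan over arc lengths is
  exhaustive. Above that it covers all lengths ≤ 100, their mirror near n,
  and a geometric grid between, followed by a deterministic greedy
  refinement of (i, j). The same statistic is applied to observed and
  permuted data, so the permutation test remains exact for the statistic
  actually used. Arcs ending at the interval boundary duplicate prefix
  splits and are canonicalised to them; ties break toward the shortest,
  earliest arc.
* **Significance.** Sequential permutation sampling: stop "not significant"
  after 10 permuted maxima reach the observed one (Besag–Clifford estimate
  c/m), stop "significant" when the add-one estimate (c+1)/(m+1) falls below
  α, cap at 10,000 permutations. α defaults to 0.01. Measured type-I
  behaviour on pure noise (SD 0.2, 2,000 probes) is reported by the
  acceptance script.
* **Smoothing.** Before CBS, points farther than 3 robust SDs from their
  5-probe rolling median are clamped to the band edge. The robust SD is the
  normal-consistent MAD of first differences divided by √2, which a step
  change inflates only marginally.
* **Undo splits.** After CBS, adjacent segments whose means differ by less
  than 3 × (robust noise SD) are merged iteratively, closest pair first,
  until stable. Both the raw and the undone segmentations are written; the
  undone one is primary, since the pass exists to remove change-points due
  to local trends. Intervals shorter than 4 probes are never tested further;
  constant intervals cannot split (their max statistic is 0).

## Event calling and cellular fraction

Segments are retained when |median LRR| ≥ 0.15 (tagged high at ≥ 0.25), with
≥ 200 probes and an inclusive genomic span (end − start + 1) ≥ 2 Mb; all
comparisons are inclusive. Against a 1-copy baseline, a clone in fraction
`f` of cells gives average copy number 1 ± f, hence

    gain: f = 2^LRR − 1,   loss: f = 1 − 2^LRR,   clipped to [0, 1].

The moderate threshold maps to f = 0.1096 ≈ 11%. At the high threshold the
model gives f = 0.189; descriptions that round this to "20% of leukocytes"
are approximations — the exact model value is reported. A whole-chromosome
median ≥ 0.4 is called constitutional XXY on the sample median (not on
segments: constitutional events are chromosome-wide by definition) and
carries no cellular fraction, because a constitutional event is not mosaic.
Y dosage uses the median corrected Y-probe LRR with cutoffs +0.3 / −0.5
(configurable; there is no established standard).

**Known bias.** With the default undo-splits strength, a whole-chromosome
event usually merges with the diploid-behaving PAR/XTR segments (their step,
≈ the event LRR itself, is below 3 noise SDs at noise 0.2). The ~4% of
probes with LRR ≈ 0 pull the segment median down slightly, giving a ≈ 0.5–1.5
percentage-point underestimate of `f` — visible in the recovery experiment
and within its 0.02 tolerance, but worth knowing. Raising probe density,
lowering `undo_sd`, or excluding PAR/XTR from the map removes it.

## XXY origin classification

Heterozygous probes are those with |BAF − 0.5| ≤ 0.15 outside PAR1/PAR2/XTR
(the band tolerates the three-cluster BAF geometry of a balanced disomy).
Runs of het probes are merged across gaps ≤ 2 Mb of **informative** sequence
— bp inside PAR/XTR do not count toward a gap, otherwise the 3.6 Mb XTR
would bisect every chromosome-wide block — and runs with < 25 het probes are
dropped as noise. With `frac` = total block span / hemizygous span:

| covered fraction | label                 | mechanism annotation (metadata)              |
|------------------|-----------------------|----------------------------------------------|
| ≥ 0.80           | FULL_HETERODISOMY     | paternal MI, or maternal MI w/o recombination |
| (0.05, 0.80)     | PARTIAL_HETERODISOMY  | maternal MI/MII after recombination           |
| ≤ 0.05           | ISODISOMY             | maternal MII w/o recombination, or mitotic    |

The 0.80/0.05 cutoffs operationalise what is in practice a visual BAF-plot
judgement; they are configuration knobs, and the mechanism column is
annotation only — parental origin is not resolved (isodisomy in particular
cannot be distinguished from a revertant constitutional origin without
additional data).

## What the generator does and does not emulate

Emulated: the mixed-sex cluster offset (female_weight, default 0.5 — real
cluster sex composition is rarely published, so the raw offset magnitude is
effectively a free parameter); diploid-behaving PAR1/PAR2/XTR (GRCh37
coordinates, configurable); mosaic gains/losses at a controlled cell
fraction over a region or the whole chromosome; the three XXY BAF
architectures; Y-probe dosage against a male-only reference; i.i.d. Gaussian
LRR noise (default SD 0.2, comfortably under the 0.30 QC cutoff); BAF from
per-probe population B-allele frequencies U(0.05, 0.95) with Gaussian noise
SD 0.03 clipped to [0, 1]; ages uniform on 37–73.

Not emulated: GC waves and other spatially correlated LRR noise, probe-level
variance heterogeneity, intensity saturation (a `compression` < 1 knob
exists but defaults to 1), genotype-calling artefacts, autosomes and female
X mosaicism. Passing tests therefore demonstrate correctness of the
*method* under its stated noise model, not performance on any particular
array product; correlated noise would mainly raise the CBS false-split rate
and the QC SD.

PAR/XTR probes are held at copy number 2 under every karyotype including
mosaic gains: the pipeline never uses PAR dosage, and diploid-like cluster
behaviour there is what arrays show in males.

## Problem sizes and determinism

The validation experiments use 18,000 chrX probes (typical array density),
noise SD 0.2, 20 replicates per cell fraction in {0.12, 0.15, 0.20, 0.30}
with a 60-male reference cohort, 100 pure-noise vectors of 2,000 probes for
type-I measurement, and 30 samples per XXY subtype. Every random draw
derives from a single seed via `numpy` `SeedSequence` spawning; reruns with
the same configuration are byte-identical, and the run log records the
configuration hash and seed needed to reproduce a run.

## Known limitations

* Cellular fractions below ~10% sit under the moderate LRR threshold and are
  not detectable by design; at f = 0.12 occasional replicates fall just
  below the threshold and are (correctly, per the rule) left uncalled.
* The sequential permutation scheme trades a slightly conservative/liberal
  edge near p ≈ α for large speedups; the measured type-I rate is the
  relevant check.
* Segment boundary placement on long vectors uses the grid + refinement
  scan; in rare noisy configurations a boundary may land a few probes off a
  local optimum (the undo-splits pass absorbs the resulting slivers).
* The XXY origin cutoffs are declared, not learned; samples near 0.05 or
  0.80 coverage deserve manual BAF review, which is what the review figures
  are for.
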