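# Methods

## Model and procedure

The package decides, per genome of a reference catalog, whether a
shotgun metagenomic sample contains that genome, using only the
positions at which reads map. The underlying model is the classic
random-fragmentation picture: if a genome is truly in the sample, read
start positions along it are well approximated by a homogeneous Poisson
point process. Two statistics probe deviations from that process in
complementary coverage regimes.

**Depth, coverage, breadth.** Per contig, depth is accumulated as a
difference array (+1 at each read start, −1 at start + read length,
prefix-summed). Reads overhanging a contig end are clamped to it rather
than rejected — such records occur with real mappers and clamping
preserves depth totals. Coverage C is the mean of the depth array over
all positions of the genome, so it is automatically consistent with
end-clamping; the shortcut Rn·Rl/Gl agrees exactly when no read
overhangs. Breadth Bo is the fraction of positions with depth ≥ 1,
computed from exact integer zero counts.

**BER.** Bo is divided by the expected breadth Be = 1 − e^(−0.883·C).
The 0.883 constant is an empirical correction to the ideal Poisson
exponent (Olm and colleagues fitted it on resequencing data); it is a
fixed constant of the method, not a tunable, and re-deriving it is out
of scope here. BER may legitimately exceed 1 (observed spread slightly
above the empirical expectation).

**FUG.** For each genome the contigs are joined, in catalog order, into
one concatenated coordinate system, and read starts are projected onto
it. Paired-end mates are split by their SAM pair flags into FIRST and
SECOND groups that are scored independently (the insert couples the two
mates of a fragment; splitting de-correlates the gap statistics).
Unpaired reads form a single group. Each group receives two sentinel
positions — 0 and Gl − round(mean read length) — so that reads confined
to one interior region produce large boundary gaps. With n the array
length including sentinels, Δ = round(Gl/n) (half-to-even; the
alternative half-up rule differs by ≤ 1 bp and is immaterial at the Δ
values where FUG is consulted), distances the successive differences of
the sorted array (zero distances from stacked reads included), and p_d
the fraction of distances equal to d:

    FUG = (Δ − Σ_{d≥Δ} p_d · (d − Δ)) / Δ

FUG ≤ 1 always, equals 1 exactly when no gap exceeds Δ, and can go
negative for extreme clustering. For uniform placements it converges to
the exponential-CDF value 1 − 1/e ≈ 0.632. At high coverage (small Δ)
the integer rounding of Δ is coarse relative to typical gaps and FUG
drifts; the decision rule therefore never consults it there. Sentinels
count toward n (and hence Δ and the distance count) but never toward
the detection limit: the limit is about evidence, sentinels are an
algorithmic artifice.

**Decision rule.** With defaults: a genome with zero reads is absent
(`no_reads`); fewer than `min_reads = 80` records is absent
(`below_detection_limit`; both mates of a pair count, and the limit
exists because the gap distribution of a smaller sample is too noisy
for FUG). Otherwise BER must exceed `ber_threshold = 0.8`; above
`coverage_switch = 0.1` that alone decides (`present_ber_only` /
`low_ber`), at or below it the FUG criterion is also required
(`present_ber_fug` / `low_fug`). The FUG criterion defaults to the
*mean* over defined mate groups exceeding `fug_threshold = 0.5`
(matching what the joint BER/FUG scatterplots threshold); an `all`
mode requires every defined group to clear it. A genome whose FUG is
undefined in every group (too few reads per group) at low coverage is
called absent with `low_fug`: FUG is required evidence in that regime.
Two documented presets: `cami_protocol` moves the coverage switch to 1
(the synthetic-community protocol), `relaxed` lowers the BER threshold
to 0.77 (a threshold-sweep optimum reported alongside the defaults).

**Abundance.** Rcn = Nr·10⁹/(Gl·Rtot). Rtot is taken as the total
number of mapped reads collected over the catalog; an alignment-only
workflow cannot see unsequenced/unmapped read totals, and the choice
affects all genomes by a common factor.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ber_threshold` | 0.8 | minimum BER (ratio, unitless) for presence |
| `fug_threshold` | 0.5 | minimum (mean) FUG in the low-coverage regime |
| `min_reads` | 80 | detection limit in alignment records |
| `coverage_switch` | 0.1 (×) | coverage above which BER alone decides |
| `fug_aggregation` | mean | mean-over-groups vs every-group thresholding |
| `min_group_size` | 2 | non-sentinel reads below which a group's FUG is undefined (formula degenerates) |
| `default_read_length` | 150 bp | fallback when a record stores no sequence |

Alignment handling: mate groups come from the SAM pair flags rather
than encounter order (deterministic under re-sorting); secondary and
supplementary alignments are included by default (`--primary-only` to
tighten); duplicate alignments of the same read name are *not*
deduplicated; read length is the stored query length (CIGAR is
ignored, so no reference-span arithmetic is attempted).

## The simulator

The synthetic-fixture module places reads, it does not sequence them:
start positions are drawn from a placement model and written directly
into valid coordinate-sorted SAM, with no base errors and no aligner in
the loop. This isolates the metrics — which consume mapping positions
only — from mapper behaviour, while still exercising the full
alignment-file code path. Defaults emulate common short-read
metagenome sequencing: 150 bp reads, paired ends with a 270 bp mean
insert (SD 30 bp, a typical Illumina spread); the second mate starts at
the first mate's position plus (insert − read length), truncated onto
the genome. Patterns:

* `uniform(coverage)` — i.i.d. uniform starts on [0, Gl − Rl]; read
  count n = round(C·Gl/Rl) (paired mode uses n/2 pairs). Truth default:
  present.
* `region_restricted(coverage, covered_fraction, n_regions)` — starts
  confined to disjoint intervals totalling `covered_fraction`·Gl (the
  genome is cut into equal slots and one interval is placed uniformly
  in each, guaranteeing disjointness). Coverage is still the
  genome-wide mean. Truth default: absent (the mismapping signature).
* `bimodal(base, spike, spike_fraction)` — superposition of a uniform
  layer and a region-restricted spike, yielding a two-mode per-base
  depth distribution. Truth default: absent, as an emulation of
  mismapping inflating an absent or misassembled genome; override the
  `present` field per genome when modelling a present genome with a
  contaminated region.

Randomness: one global scenario seed; each genome's stream is derived
from (seed, crc32(genome_id)), so results are reproducible and
independent of genome ordering. Identical spec + seed give
byte-identical FASTA/SAM/TSV output.

What the simulator does not model — sequencing errors, quality scores,
GC bias, insert-size outliers, chimeras, real mapper heuristics, and
abundance distributions over community members. Passing the end-to-end
suites therefore shows the metrics behave correctly on their *model*
(ideal placements and clean region-confined mismapping), not that any
particular real mapper/database combination achieves the same rates.

## Evaluation

TPR is computed over truly-present genomes, TNR over truly-absent ones,
balanced accuracy as their mean; a rate whose class is empty is
reported NA. Coverage-binned rates use half-open log2 bins
(0.00004·2^i, 0.00004·2^(i+1)] with a configurable maximum index
(default 21); observations outside the range are dropped with a
warning. The exclusive-low/inclusive-up orientation and the index
origin follow the operational description of the binned benchmark
plots, which index bins one differently in two places; the origin is
exposed as `i_min` for the other reading.

## Numerical choices and degenerate inputs

* Depth arrays are integer; no floating-point epsilon enters breadth.
* Δ uses Python's banker's rounding; FUG's tail penalty is computed as
  the mean of max(d − Δ, 0) over all distances, which is algebraically
  identical to the histogram form and exact in float64 for genomic
  magnitudes.
* A genome shorter than the mean read length cannot take sentinels and
  is a hard error; an empty mate group gets sentinels only (FUG then
  reflects pure boundary gaps) but is undefined below `min_group_size`
  non-sentinel reads.
* A genome with reads on no contig yields all-NA metrics, `no_reads`.
* Reports format floats at 6 significant digits with NA sentinels and
  sort genomes lexicographically; parallel (`--processes`) and serial
  runs produce byte-identical reports because results are re-keyed by
  genome id after the pool returns.

## Problem sizes used in the checks

The calibration script uses 10,000 placements on a 1 Mb genome for the
FUG convergence estimate (20 replicates) and ~133,000 reads at 20× on a
1 Mb genome for the self-identity BER — sizes at which both statistics
are deep into their asymptotic regime while a full run stays in
seconds. The end-to-end recovery suite uses twenty 50-genome
communities (30 kb–1.2 Mb genomes, 50–800 reads each) mixing the
BER-only and BER+FUG decision paths on both present and absent genomes.

## Known limitations

* The 80-read limit and the 0.8/0.5 thresholds are calibrated for
  species-level catalogs; distinguishing strains at high ANI would need
  tighter thresholds and is not attempted.
* FUG is undefined for genomes whose every mate group has fewer than
  two reads, and unreliable at very high coverage; the coverage switch
  handles the latter, the detection limit the former.
* Rcn is a within-sample, length-normalized proxy, not a
  compositionally-aware abundance estimate.
* CRAM input and alignment itself (running a mapper) are out of scope.
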