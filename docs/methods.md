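# Methods

## Calibrated ChIP-seq model

### Read preprocessing and two-genome partition

Reads are trimmed positionally: bases 1–10 are removed, bases beyond 200
are removed, and reads shorter than 50 bases after trimming are dropped
(defaults `head_trim=10`, `max_keep=200`, `min_len=50`; all three are
arguments). Any context-dependent trimming beyond this fixed rule is a
manual-QC judgement and is deliberately not automated.

Partitioning reproduces a sequential two-pass alignment: each read is
matched against the calibration genome first and only the leftovers against
the experimental genome, so a read present in both genomes is assigned to
the calibration class. The matching criterion is **exact full-length match
on either strand**, implemented with a per-length k-mer index of both
strands of each genome. This replaces a mismatch-tolerant end-to-end
aligner; exactness keeps desk-scale behaviour provable, and the synthetic
genomes are constructed so that exact matching is also complete (below).
Reads containing N never match. Multi-mapping within one genome counts the
read once — counts are per read, not per alignment. An ingestion path
(`load_alignment_counts`) accepts externally aligned SAM text instead,
counting primary records only, classed by whether their reference name is
in the calibration set.

### Occupancy ratio

From the four counts (Wc, Wx = WCE reads on the calibration/experimental
genome; IPc, IPx = the same for the IP):

    OR = (Wc · IPx) / (Wx · IPc)

oriented so that a higher experimental IP yield relative to the spike-in
raises occupancy. The opposite orientation is available via
`occupancy_ratio(..., invert=True)` for pipelines defining the ratio the
other way; the orientation used is always recorded in the result's
components. Any zero count makes the ratio undefined and raises an error
naming the empty class — no pseudo-counts.

### Track scaling and "per million reads"

Calibrated tracks are `depth × OR × 1e6 / total_reads`. The
normalizing `total_reads` is taken to be the experimental-genome-aligned IP
read count (IPx), because the depth track being scaled is built from
exactly those reads; a caller may pass any other library-size definition.

### Pileups, gap filling, coordinates

Pileups are dense 1-based inclusive vectors over [1, chromosome length];
depth at p counts reads whose interval [start, start+len−1] contains p, and
positions never covered are explicit zeros (`fill_gaps` densifies sparse
mpileup-style input and conserves total depth). BED input/output is 0-based
half-open; the converters are exact and tested. Reads extending outside the
chromosome are an error rather than being clipped.

### Meta-profiles

For each offset o in [−window, +window] (default window 60 kb) the profile
is the mean of depth(anchor+o) over anchors, where the anchor is the
midpoint of each CDEIII element (elements are ~25 bp; the midpoint gives a
symmetric window). Offsets falling outside a chromosome are excluded from
that chromosome's contribution and the mean divides by the number of
**contributing** anchors only; `n_contributing` is reported per offset so
the truncation is auditable. (Dividing always by the full chromosome count
is the main alternative; contributing-only was chosen because a truncated
window otherwise deflates edge offsets.) The averaged profile is then
calibrated by OR × 1e6 / total_reads.

### Occupancy change

Per chromosome, the ratio of the `after` to the `before` chromosome-median
calibrated value (medians over every base, zeros included; even-length
median = mean of the two central values). A zero before-median makes that
chromosome's ratio undefined (NaN, reported, excluded from the summary).
The genome-wide summary is the median of the defined per-chromosome ratios.

## Fitness model

Per passage, genotype ratio r = nonfluorescent/fluorescent events (zero
counts in either class abort with advice to sample more events — no
smoothing rule is imposed) and generations
g = log₁₀(events_t24/events_t0)/log₁₀ 2 from **total** mixed-culture
events. The regression abscissa is cumulative generations: the day-0
sample sits at G = 0 and each later passage adds its own interval g.
Relative fitness is the OLS slope of logₑ r on G, with the standard OLS
slope standard error. The fluorophore-only control slope is subtracted
from comparisons involving those strains; replicates are summarized by
mean and sample (n−1) standard deviation, warning below three replicates;
groups are compared by a two-sided Welch unequal-variance t-test with
Satterthwaite degrees of freedom. No multiple-testing correction is
applied (single pairwise comparisons).

## Cytology

Percent two-dot (precociously separated) cells per strain is
100·n_two_dot/n_scored. A 95% Wilson score interval is attached and a
two-sided Fisher exact test compares strains; both are extensions beyond
the raw proportions and are labelled as such in outputs.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is validated.

* **Genome pair.** Random i.i.d. A/C/G/T sequences, 2 chromosomes per
  species by default; the pair is redrawn until no subsequence of
  read-length occurs in both species on either strand (audited by k-mer
  set intersection; bounded redraws, failure raised). This eliminates
  cross-species ambiguity by construction so every sampled read has exact
  ground truth; ambiguous-read behaviour is instead tested with hand-built
  genomes sharing an embedded sequence. Default read length is 190 bases,
  echoing a typical single-end library; unit and acceptance fixtures use
  50 bases with 5–10 kb chromosomes to keep k-mer indexes small.
* **Experiment sampling.** WCE reads fall on the calibration genome with
  probability equal to the spike-in fraction (default fixtures use 0.1–0.4)
  and uniformly within each genome. IP reads sample experimental start
  positions proportionally to an occupancy landscape (baseline plus
  Gaussian peaks) and calibration positions uniformly, with the
  calibration share set by a free pull-down efficiency parameter `e`
  (the relative pull-down of the calibration species is not a measurable
  of the assay, so it is an explicit simulation parameter). The analytic
  truth `true_OR = mean landscape weight / e` is recorded **before**
  sampling; realized counts converge to it as read numbers grow. Reads
  are drawn from both strands with equal probability (libraries are
  unstranded) and carry their true origin, chromosome, start, and strand.
* **Competition series.** Expected logₑ r follows
  logₑ(init_ratio) + s·G; at each sampling the nonfluorescent count is a
  binomial draw of the event total (default 30,000 events, the typical
  per-sample cytometer count) with success probability r/(1+r). Event
  totals grow deterministically by `gens_per_passage` doublings (default
  log₂ 1000 ≈ 9.97, a 1:1000 daily dilution), so the generation formula
  recovers the abscissa exactly. Binomial-on-the-split with deterministic
  totals is the minimal noise model; it omits instrument gating noise and
  day-to-day growth-rate variation.
* **Cytology.** n_two_dot ~ Binomial(n_cells, p).

What passing tests therefore show: the estimators are unbiased and
correctly calibrated **under these idealized conditions** — no sequencing
errors, no PCR duplicates, no mapping ambiguity, no growth-phase or gating
artefacts. They do not certify performance on real libraries where those
features matter.

## Numerical choices and problem sizes

* Exact-match indexes are cached per (species, read length); lookups are
  O(1) per read.
* Pileup uses a difference-array cumulative sum; meta-profile uses
  vectorized window slices, checked exactly against an (anchor, offset)
  double loop.
* Validation sizes were chosen as the smallest at which the binomial
  counting noise is well inside the stated bands: OR recovery uses
  2×10⁵ reads per sample (count noise ≈ 0.5–1%, band ±5%), eviction
  recovery 6×10⁴ reads per sample over 10 seeds (band [0.45, 0.55]),
  fitness recovery 200 series of 4 passages at 30,000 events, and the
  Welch type-I rate 2,000 simulations of 3-vs-3 replicate groups.
* All generators take integer seeds and are byte-identical under a fixed
  seed; derived seeds are kept below 2³¹.

## Known limitations

* Exact full-length matching cannot ingest reads with sequencing errors;
  real data should enter through the SAM ingestion path after external
  alignment.
* The per-chromosome occupancy-change ratio is undefined on chromosomes
  with zero before-median; sparse real tracks may need binning first.
* Welch's test on 3-vs-3 replicate groups is slightly conservative; the
  observed null rejection rate sits near 4% rather than exactly 5%.
* BigWig output exists behind a feature flag but all tested I/O paths are
  plain text (FASTA, FASTQ, SAM, BED, bedGraph, wiggle, TSV).
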