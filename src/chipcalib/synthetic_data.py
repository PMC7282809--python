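"""Synthetic inputs with known ground truth.

Everything the downstream pipeline consumes can be generated here:
a two-species genome pair (experimental + spike-in calibration genome),
mixed IP/WCE read sets drawn from a known occupancy landscape with a
known true calibration ratio, competition-assay event series following
exponential log-ratio dynamics, and Bernoulli scored-cell tables.

The two genomes are built with disjoint read-length k-mer spectra so
that every sampled read has an unambiguous origin and the partition
step can be audited against exact ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenomePair",
    "Peak",
    "OccupancyLandscape",
    "uniform_landscape",
    "SimulatedRead",
    "ExperimentTruth",
    "SyntheticExperiment",
    "Passage",
    "CompetitionSeries",
    "CytologyRow",
    "CytologyTable",
    "gen_genome_pair",
    "sample_experiment",
    "gen_competition",
    "gen_cytology",
    "reverse_complement",
    "write_fixture_dir",
]

#: Default read length in bases; mirrors the typical single-end library
#: read length of the assay this generator emulates.
DEFAULT_READ_LENGTH = 190

#: Generations per 24 h passage implied by a 1:1000 dilution regime.
DEFAULT_GENS_PER_PASSAGE = math.log2(1000)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome pair
# ---------------------------------------------------------------------------


@dataclass
class GenomePair:
    """An experimental genome plus a spike-in calibration genome.

    Sequences are plain upper-case A/C/G/T strings keyed by chromosome
    name; names are unique across the two species.  ``read_length`` is
    the fragment length at which the cross-species k-mer disjointness
    invariant was audited.
    """

    experimental: dict[str, str]
    calibration: dict[str, str]
    read_length: int
    # per-(species, k) exact-match index, built lazily by read_partition
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        overlap = set(self.experimental) & set(self.calibration)
        if overlap:
            raise ValueError(f"chromosome names shared across species: {sorted(overlap)}")

    def chrom_lengths(self, species: str) -> dict[str, int]:
        genome = getattr(self, species)
        return {name: len(seq) for name, seq in genome.items()}

    def audit_disjoint(self, k: int | None = None) -> bool:
        """True iff no k-mer occurs in both species on either strand."""
        k = self.read_length if k is None else k
        cal = _kmer_set(self.calibration, k)
        exp = _kmer_set(self.experimental, k)
        return not (cal & exp)


def _kmer_set(genome: dict[str, str], k: int) -> set[str]:
    out: set[str] = set()
    for seq in genome.values():
        for strand in (seq, reverse_complement(seq)):
            out.update(strand[i : i + k] for i in range(len(strand) - k + 1))
    return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def gen_genome_pair(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 10_000,
    read_length: int = DEFAULT_READ_LENGTH,
    max_attempts: int = 20,
) -> GenomePair:
    """Generate a random genome pair with disjoint read-length k-mer spectra.

    Chromosomes are named ``exp_1..exp_n`` and ``cal_1..cal_n``.  The
    pair is redrawn (from the same seeded stream, hence deterministic)
    until the cross-species uniqueness audit passes; failure after
    ``max_attempts`` redraws raises rather than returning a bad pair.
    """
    if read_length < 20:
        raise ValueError(f"read_length must be >= 20, got {read_length}")
    if chrom_len < read_length:
        raise ValueError(
            f"chrom_len ({chrom_len}) must be >= read_length ({read_length})"
        )
    if n_chrom < 1:
        raise ValueError("need at least one chromosome per species")

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        experimental = {f"exp_{i + 1}": _random_seq(rng, chrom_len) for i in range(n_chrom)}
        calibration = {f"cal_{i + 1}": _random_seq(rng, chrom_len) for i in range(n_chrom)}
        pair = GenomePair(experimental, calibration, read_length)
        if pair.audit_disjoint():
            return pair
    raise RuntimeError(
        f"could not build a k-mer-disjoint genome pair in {max_attempts} attempts "
        f"(chrom_len={chrom_len}, read_length={read_length})"
    )


# ---------------------------------------------------------------------------
# Occupancy landscape and experiment sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A Gaussian occupancy peak: weight height*exp(-(p-center)^2/(2 width^2))."""

    center: int
    width: float
    height: float


@dataclass
class OccupancyLandscape:
    """Relative IP pull-down weight per experimental-genome start position.

    The weight at 1-based position p is ``baseline`` plus the sum of the
    chromosome's Gaussian peaks.  Weights must be non-negative with at
    least one positive weight per chromosome.
    """

    baseline: float
    peaks: dict[str, list[Peak]] = field(default_factory=dict)

    def weights(self, chrom: str, n_positions: int) -> np.ndarray:
        pos = np.arange(1, n_positions + 1, dtype=float)
        w = np.full(n_positions, float(self.baseline))
        for pk in self.peaks.get(chrom, []):
            w += pk.height * np.exp(-((pos - pk.center) ** 2) / (2.0 * pk.width**2))
        if (w < 0).any():
            raise ValueError(f"negative occupancy weight on {chrom}")
        return w

    def scaled(self, factor: float) -> "OccupancyLandscape":
        """The same landscape with every weight multiplied by ``factor``."""
        return OccupancyLandscape(
            baseline=self.baseline * factor,
            peaks={
                c: [Peak(p.center, p.width, p.height * factor) for p in pks]
                for c, pks in self.peaks.items()
            },
        )


def uniform_landscape(weight: float = 1.0) -> OccupancyLandscape:
    return OccupancyLandscape(baseline=weight)


@dataclass(frozen=True)
class SimulatedRead:
    """A sampled read with its true origin recorded."""

    id: str
    sequence: str
    sample: str  # "IP" | "WCE"
    origin: str  # "calibration" | "experimental"
    chrom: str
    start: int  # 1-based start of the covered interval
    strand: str  # "+" | "-"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ExperimentTruth:
    spike_fraction_wce: float
    ip_calibration_efficiency: float
    landscape: OccupancyLandscape
    true_or: float
    seed: int


@dataclass
class SyntheticExperiment:
    reads_ip: list[SimulatedRead]
    reads_wce: list[SimulatedRead]
    truth: ExperimentTruth


def _genome_start_table(genome: dict[str, str], read_len: int):
    """Chromosome names and valid 1-based start counts for reads of read_len."""
    names = list(genome)
    n_starts = np.array([len(genome[c]) - read_len + 1 for c in names])
    if (n_starts < 1).any():
        raise ValueError("a chromosome is shorter than the read length")
    return names, n_starts


def _draw_reads(
    rng: np.random.Generator,
    genome: dict[str, str],
    read_len: int,
    n: int,
    sample: str,
    origin: str,
    id_prefix: str,
    start_weights: np.ndarray | None = None,
) -> list[SimulatedRead]:
    """Draw n reads; start positions uniform or proportional to start_weights
    (a concatenated per-chromosome weight vector over valid starts)."""
    names, n_starts = _genome_start_table(genome, read_len)
    offsets = np.concatenate([[0], np.cumsum(n_starts)])
    total = offsets[-1]
    if start_weights is None:
        flat = rng.integers(0, total, size=n)
    else:
        p = start_weights / start_weights.sum()
        flat = rng.choice(total, size=n, p=p)
    strands = rng.integers(0, 2, size=n)
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    starts = flat - offsets[chrom_idx] + 1  # 1-based
    reads = []
    for i in range(n):
        c = names[chrom_idx[i]]
        s = int(starts[i])
        seq = genome[c][s - 1 : s - 1 + read_len]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(
            SimulatedRead(f"{id_prefix}_{i}", seq, sample, origin, c, s, strand)
        )
    return reads


def sample_experiment(
    pair: GenomePair,
    landscape: OccupancyLandscape,
    n_ip: int,
    n_wce: int,
    spike_fraction_wce: float,
    ip_calibration_efficiency: float,
    seed: int,
) -> SyntheticExperiment:
    """Sample a paired IP/WCE read experiment with analytic ground truth.

    Model: the whole-cell extract is a mixture with calibration-species
    mass fraction ``spike_fraction_wce``; WCE reads fall uniformly on
    either genome.  The IP samples experimental fragments with start
    probability proportional to the occupancy landscape and calibration
    fragments uniformly, their overall pull-down weight per unit mass
    set by ``ip_calibration_efficiency`` relative to a unit landscape
    weight.  The true occupancy ratio implied by these expectations,

        true_OR = E[Wc/Wx] analogue x E[IPx/IPc] analogue
                = mean landscape weight / ip_calibration_efficiency,

    is recorded before any read is drawn.
    """
    if not 0.0 < spike_fraction_wce < 1.0:
        raise ValueError("spike_fraction_wce must lie in (0, 1)")
    if n_ip <= 0 or n_wce <= 0:
        raise ValueError("n_ip and n_wce must be positive")
    if ip_calibration_efficiency <= 0:
        raise ValueError("ip_calibration_efficiency must be positive")

    read_len = pair.read_length
    exp_names, exp_starts = _genome_start_table(pair.experimental, read_len)
    w = np.concatenate(
        [landscape.weights(c, int(ns)) for c, ns in zip(exp_names, exp_starts)]
    )
    if w.sum() <= 0:
        raise ValueError("degenerate landscape: all weights are zero")

    mean_w = float(w.mean())
    f = spike_fraction_wce
    e = ip_calibration_efficiency
    # expected counts: E[Wc]/E[Wx] = f/(1-f); E[IPx]/E[IPc] = (1-f) mean_w / (f e)
    true_or = mean_w / e

    rng = np.random.default_rng(seed)

    n_wce_cal = int(rng.binomial(n_wce, f))
    wce = _draw_reads(rng, pair.calibration, read_len, n_wce_cal, "WCE", "calibration", "wce_c")
    wce += _draw_reads(
        rng, pair.experimental, read_len, n_wce - n_wce_cal, "WCE", "experimental", "wce_x"
    )

    p_ip_cal = (f * e) / (f * e + (1 - f) * mean_w)
    n_ip_cal = int(rng.binomial(n_ip, p_ip_cal))
    ip = _draw_reads(rng, pair.calibration, read_len, n_ip_cal, "IP", "calibration", "ip_c")
    ip += _draw_reads(
        rng, pair.experimental, read_len, n_ip - n_ip_cal, "IP", "experimental", "ip_x",
        start_weights=w,
    )

    truth = ExperimentTruth(f, e, landscape, true_or, seed)
    return SyntheticExperiment(reads_ip=ip, reads_wce=wce, truth=truth)


# ---------------------------------------------------------------------------
# Competition series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Passage:
    """One sampling point of a competition culture."""

    passage_index: int
    events_t0: int
    events_t24: int
    fluorescent: int
    nonfluorescent: int


@dataclass
class CompetitionSeries:
    passages: list[Passage]
    replicate_id: str = "rep1"
    truth_s: float | None = None


def gen_competition(
    s_true: float,
    init_ratio: float = 1.0,
    gens_per_passage: float = DEFAULT_GENS_PER_PASSAGE,
    n_passages: int = 4,
    events_per_sample: int = 30_000,
    seed: int = 0,
    replicate_id: str = "rep1",
) -> CompetitionSeries:
    """Simulate a fluorescent-vs-nonfluorescent competition series.

    The expected log genotype ratio follows
    ``loge r(G) = loge(init_ratio) + s_true * G`` with G the cumulative
    generations; at each sampling the nonfluorescent count is a binomial
    draw of ``events_per_sample`` events with success probability
    r/(1+r).  Total-event counts grow deterministically by
    ``gens_per_passage`` doublings per passage, so the generation
    formula recovers the abscissa exactly.  Passage 0 is the day-0
    sample (no growth interval).
    """
    if init_ratio <= 0:
        raise ValueError("init_ratio must be positive")
    if events_per_sample <= 0:
        raise ValueError("events_per_sample must be positive")
    if n_passages < 2:
        raise ValueError("need at least 2 passages for a regression")

    rng = np.random.default_rng(seed)
    passages = []
    for p in range(n_passages + 1):  # passage 0 = day-0 sample
        g_cum = p * gens_per_passage
        r = init_ratio * math.exp(s_true * g_cum)
        nonfluor = int(rng.binomial(events_per_sample, r / (1.0 + r)))
        fluor = events_per_sample - nonfluor
        if p == 0:
            t0 = t24 = events_per_sample
        else:
            t0 = events_per_sample
            t24 = int(round(events_per_sample * 2.0**gens_per_passage))
        passages.append(Passage(p, t0, t24, fluor, nonfluor))
    return CompetitionSeries(passages, replicate_id=replicate_id, truth_s=s_true)


# ---------------------------------------------------------------------------
# Cytology tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CytologyRow:
    strain: str
    n_scored: int
    n_two_dot: int

    def __post_init__(self) -> None:
        if self.n_scored <= 0:
            raise ValueError(f"{self.strain}: n_scored must be positive")
        if not 0 <= self.n_two_dot <= self.n_scored:
            raise ValueError(f"{self.strain}: n_two_dot outside [0, n_scored]")


@dataclass
class CytologyTable:
    rows: list[CytologyRow]


def gen_cytology(
    n_cells: int, p_two_dot: float, seed: int = 0, strain: str = "synthetic"
) -> CytologyTable:
    """Score ``n_cells`` Bernoulli(p_two_dot) cells into a one-row table."""
    if not 0.0 <= p_two_dot <= 1.0:
        raise ValueError("p_two_dot must lie in [0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    n_two = int(rng.binomial(n_cells, p_two_dot))
    return CytologyTable([CytologyRow(strain, n_cells, n_two)])


# ---------------------------------------------------------------------------
# Fixture writers (FASTA / FASTQ / BED / TSV / truth manifest)
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads, path: str | Path, quality: int = 30) -> None:
    """Write reads as FASTQ with a constant Phred-33 quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def write_bed_anchors(anchors, path: str | Path, element_halfwidth: int = 12) -> None:
    """Write anchor midpoints as 0-based half-open BED intervals."""
    with open(path, "w") as fh:
        for a in anchors:
            start0 = max(0, a.anchor - 1 - element_halfwidth)
            end0 = a.anchor + element_halfwidth
            fh.write(f"{a.chromosome}\t{start0}\t{end0}\tCDEIII\n")


def write_competition_tsv(series_list: list[CompetitionSeries], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "replicate": s.replicate_id,
            "passage": p.passage_index,
            "events_t0": p.events_t0,
            "events_t24": p.events_t24,
            "fluorescent": p.fluorescent,
            "nonfluorescent": p.nonfluorescent,
        }
        for s in series_list
        for p in s.passages
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cytology_tsv(table: CytologyTable, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"strain": r.strain, "n_scored": r.n_scored, "n_two_dot": r.n_two_dot}
        for r in table.rows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fixture_dir(exp: SyntheticExperiment, pair: GenomePair, outdir: str | Path) -> None:
    """Write a complete read-simulation fixture with its truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(pair.experimental, outdir / "experimental.fa")
    write_fasta(pair.calibration, outdir / "calibration.fa")
    write_fastq(exp.reads_ip, outdir / "reads_ip.fastq")
    write_fastq(exp.reads_wce, outdir / "reads_wce.fastq")
    t = exp.truth
    manifest = {
        "spike_fraction_wce": t.spike_fraction_wce,
        "ip_calibration_efficiency": t.ip_calibration_efficiency,
        "true_or": t.true_or,
        "seed": t.seed,
        "n_ip": len(exp.reads_ip),
        "n_wce": len(exp.reads_wce),
        "origin_counts": {
            "IP": {
                o: sum(1 for r in exp.reads_ip if r.origin == o)
                for o in ("calibration", "experimental")
            },
            "WCE": {
                o: sum(1 for r in exp.reads_wce if r.origin == o)
                for o in ("calibration", "experimental")
            },
        },
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
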