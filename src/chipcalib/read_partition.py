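"""Read preprocessing and two-genome partitioning.

Each read is trimmed by fixed positional rules and then assigned to the
calibration genome, the experimental genome, or neither, reproducing a
sequential two-genome alignment strategy: reads are matched against the
calibration (spike-in) genome first and only the leftovers against the
experimental genome, so a read present in both genomes counts as
calibration.  Matching is exact full-length on either strand; the four
resulting read counts (Wc, Wx, IPc, IPx) feed the occupancy ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .synthetic_data import GenomePair, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "PartitionResult",
    "trim_reads",
    "assign_read",
    "partition",
    "load_alignment_counts",
    "read_fastq",
    "write_counts_tsv",
]

CALIBRATION = "calibration"
EXPERIMENTAL = "experimental"
UNALIGNED = "unaligned"


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    sample: str = "IP"  # "IP" | "WCE"


@dataclass
class PartitionResult:
    """Per-read assignments and the four calibration counts.

    Wc/Wx are WCE reads aligned to the calibration / experimental
    genome; IPc/IPx the same for the IP sample.  Unaligned reads are
    tracked so the assignment classes partition each read set exactly.
    """

    ip_assignments: list[str] = field(default_factory=list)
    wce_assignments: list[str] = field(default_factory=list)
    Wc: int = 0
    Wx: int = 0
    IPc: int = 0
    IPx: int = 0
    W_unaligned: int = 0
    IP_unaligned: int = 0

    def check_conservation(self) -> None:
        assert self.Wc + self.Wx + self.W_unaligned == len(self.wce_assignments)
        assert self.IPc + self.IPx + self.IP_unaligned == len(self.ip_assignments)


def trim_reads(
    reads: Iterable[Read],
    head_trim: int = 10,
    max_keep: int = 200,
    min_len: int = 50,
) -> list[Read]:
    """Trim each read to bases head_trim+1..max_keep and drop short survivors.

    The kept subsequence is positions ``head_trim + 1`` through
    ``max_keep`` (1-based, inclusive) of the input read; reads whose
    trimmed length falls below ``min_len`` are removed.  Input order is
    preserved.
    """
    if head_trim < 0:
        raise ValueError("head_trim must be >= 0")
    if max_keep <= head_trim:
        raise ValueError("max_keep must exceed head_trim")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out = []
    for r in reads:
        trimmed = r.sequence[head_trim:max_keep]
        if len(trimmed) >= min_len:
            out.append(Read(r.id, trimmed, r.sample))
    return out


def _match_index(pair: GenomePair, species: str, k: int) -> frozenset[str]:
    """All length-k substrings of one species' genome, both strands (cached)."""
    key = (species, k)
    idx = pair._index.get(key)
    if idx is None:
        genome = getattr(pair, species)
        kmers: set[str] = set()
        for seq in genome.values():
            for strand in (seq, reverse_complement(seq)):
                kmers.update(strand[i : i + k] for i in range(len(strand) - k + 1))
        idx = frozenset(kmers)
        pair._index[key] = idx
    return idx


def _matches(pair: GenomePair, species: str, seq: str) -> bool:
    return seq in _match_index(pair, species, len(seq))


def assign_read(read: Read, pair: GenomePair) -> str:
    """Assign one read: calibration genome first, then experimental.

    A read matches a genome if its sequence occurs exactly, full length,
    on either strand.  Reads containing N never match.  A read present
    in both genomes is assigned ``calibration`` (sequential precedence).
    """
    seq = read.sequence
    if not seq:
        raise ValueError(f"read {read.id}: empty sequence")
    if "N" in seq:
        return UNALIGNED
    if _matches(pair, CALIBRATION, seq):
        return CALIBRATION
    if _matches(pair, EXPERIMENTAL, seq):
        return EXPERIMENTAL
    return UNALIGNED


def partition(
    ip_reads: Sequence[Read], wce_reads: Sequence[Read], pair: GenomePair
) -> PartitionResult:
    """Partition trimmed IP and WCE read sets and tally the four counts."""
    if not ip_reads or not wce_reads:
        raise ValueError("IP and WCE read sets must both be non-empty")
    res = PartitionResult()
    for r in ip_reads:
        a = assign_read(r, pair)
        res.ip_assignments.append(a)
        if a == CALIBRATION:
            res.IPc += 1
        elif a == EXPERIMENTAL:
            res.IPx += 1
        else:
            res.IP_unaligned += 1
    for r in wce_reads:
        a = assign_read(r, pair)
        res.wce_assignments.append(a)
        if a == CALIBRATION:
            res.Wc += 1
        elif a == EXPERIMENTAL:
            res.Wx += 1
        else:
            res.W_unaligned += 1
    res.check_conservation()
    return res


def _count_sam(path: str | Path, calibration_names: set[str]):
    """Counts (calibration, experimental, unaligned, skipped) from a SAM file."""
    import pysam

    n_cal = n_exp = n_un = n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        refs = set(sam.references)
        missing = calibration_names - refs
        if missing:
            raise ValueError(
                f"calibration reference name(s) not in {path} header: {sorted(missing)}"
            )
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            if rec.is_unmapped:
                n_un += 1
            elif rec.reference_name in calibration_names:
                n_cal += 1
            else:
                n_exp += 1
    if n_skipped:
        logger.info("%s: ignored %d secondary/supplementary records", path, n_skipped)
    return n_cal, n_exp, n_un


def load_alignment_counts(
    sam_ip: str | Path, sam_wce: str | Path, calibration_names: Iterable[str]
) -> PartitionResult:
    """Build a PartitionResult from externally aligned SAM files.

    Primary alignments only; a record mapped to a calibration-named
    reference counts toward Wc/IPc, to any other reference toward
    Wx/IPx, and unmapped records toward the unaligned class.
    """
    names = set(calibration_names)
    IPc, IPx, IPu = _count_sam(sam_ip, names)
    Wc, Wx, Wu = _count_sam(sam_wce, names)
    res = PartitionResult(
        ip_assignments=[CALIBRATION] * IPc + [EXPERIMENTAL] * IPx + [UNALIGNED] * IPu,
        wce_assignments=[CALIBRATION] * Wc + [EXPERIMENTAL] * Wx + [UNALIGNED] * Wu,
        Wc=Wc, Wx=Wx, IPc=IPc, IPx=IPx, W_unaligned=Wu, IP_unaligned=IPu,
    )
    res.check_conservation()
    return res


def read_fastq(path: str | Path, sample: str = "IP") -> list[Read]:
    from Bio import SeqIO

    return [
        Read(rec.id, str(rec.seq).upper(), sample)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_counts_tsv(result: PartitionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tcount\n")
        for name in ("Wc", "Wx", "IPc", "IPx", "W_unaligned", "IP_unaligned"):
            fh.write(f"{name}\t{getattr(result, name)}\n")
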