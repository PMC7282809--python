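"""Dense depth tracks, centromere-anchored meta-profiles, and occupancy change.

Pileups are dense 1-based per-base read-depth vectors; positions never
covered by a read are explicit zeros (gap filling), so medians and
profile averages see the whole chromosome.  Meta-profiles average the
depth at each offset within a window either side of the CDEIII
centromere anchors across chromosomes, then calibrate by OR and
million-read normalization.  Occupancy change compares chromosome
medians of calibrated tracks between two conditions.

Coordinate conventions: tracks and anchors are 1-based inclusive
internally; BED input/output is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .calibration import OccupancyRatio, ScaledTrack

__all__ = [
    "DepthTrack",
    "CentromereAnchor",
    "MetaProfile",
    "OccupancyChange",
    "pileup",
    "fill_gaps",
    "meta_profile",
    "chromosome_median",
    "occupancy_change",
    "read_bed_anchors",
    "read_depth_tsv",
    "write_depth_tsv",
    "write_meta_profile_tsv",
]


@dataclass
class DepthTrack:
    """Per-chromosome dense read depth, 1-based inclusive over [1, length]."""

    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            if len(arr) != self.chrom_lengths[chrom]:
                raise ValueError(
                    f"{chrom}: depth vector length {len(arr)} != "
                    f"chromosome length {self.chrom_lengths[chrom]}"
                )
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"{chrom}: negative depth")


@dataclass(frozen=True)
class CentromereAnchor:
    """CDEIII element midpoint, 1-based."""

    chromosome: str
    anchor: int


@dataclass
class MetaProfile:
    """Calibrated mean depth by offset from the anchors.

    ``mean_depth[i]`` is the mean over contributing anchors of the depth
    at anchor + offsets[i], scaled by OR * 1e6 / total_reads;
    ``n_contributing[i]`` records how many anchors supplied that offset
    (anchors whose window is truncated by a chromosome end contribute
    only the offsets that exist).
    """

    offsets: np.ndarray
    mean_depth: np.ndarray
    n_contributing: np.ndarray
    or_value: float
    total_reads: int


@dataclass
class OccupancyChange:
    """Per-chromosome after/before median ratios and their genome-wide median.

    Chromosomes whose before-median is zero have an undefined ratio,
    recorded as NaN and excluded from the genome-wide summary.
    """

    per_chromosome: dict[str, float]
    genome_wide: float


def pileup(assigned_reads: Iterable, chrom_lengths: Mapping[str, int]) -> DepthTrack:
    """Dense per-base depth from placed reads.

    Each read must carry ``chrom``, ``start`` (1-based) and ``length``
    attributes (or be a (chrom, start, length) tuple); depth at position
    p counts the reads whose interval [start, start+length-1] contains
    p.  Reads extending outside [1, chromosome length] are an error.
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    for r in assigned_reads:
        if isinstance(r, tuple):
            chrom, start, length = r
            rid = f"{chrom}:{start}"
        else:
            chrom, start, length = r.chrom, r.start, r.length
            rid = getattr(r, "id", f"{chrom}:{start}")
        if chrom not in diffs:
            raise ValueError(f"read {rid}: unknown chromosome {chrom}")
        end = start + length - 1
        if start < 1 or end > chrom_lengths[chrom]:
            raise ValueError(
                f"read {rid}: interval [{start}, {end}] outside "
                f"[1, {chrom_lengths[chrom]}] on {chrom}"
            )
        diffs[chrom][start - 1] += 1
        diffs[chrom][end] -= 1
    values = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return DepthTrack(values=values, chrom_lengths=dict(chrom_lengths))


def fill_gaps(sparse_depth: Mapping[int, int], chrom_length: int) -> np.ndarray:
    """Densify a sparse position -> depth map; unlisted positions get 0.

    Positions are 1-based; the result has length ``chrom_length`` and
    conserves the total depth of the input.
    """
    dense = np.zeros(chrom_length, dtype=np.int64)
    for pos, depth in sparse_depth.items():
        if not 1 <= pos <= chrom_length:
            raise ValueError(f"position {pos} outside [1, {chrom_length}]")
        dense[pos - 1] = depth
    return dense


def meta_profile(
    tracks: DepthTrack,
    anchors: Iterable[CentromereAnchor],
    window: int = 60_000,
    or_: OccupancyRatio | None = None,
    total_reads: int = 1_000_000,
) -> MetaProfile:
    """Average depth by offset from the anchors, then calibrate.

    For each offset o in [-window, +window] the raw profile is the mean
    of depth(anchor + o) over the anchors for which that position lies
    inside the chromosome; the mean divides by the number of
    contributing anchors only.  The calibrated profile multiplies by
    OR * 1e6 / total_reads.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchors supplied")
    width = 2 * window + 1
    total = np.zeros(width, dtype=float)
    count = np.zeros(width, dtype=np.int64)
    for a in anchors:
        if a.chromosome not in tracks.values:
            raise ValueError(f"anchor on missing chromosome {a.chromosome}")
        length = tracks.chrom_lengths[a.chromosome]
        if not 1 <= a.anchor <= length:
            raise ValueError(
                f"anchor {a.anchor} outside [1, {length}] on {a.chromosome}"
            )
        lo = max(1, a.anchor - window)
        hi = min(length, a.anchor + window)  # inclusive
        i0 = lo - (a.anchor - window)
        i1 = i0 + (hi - lo + 1)
        total[i0:i1] += tracks.values[a.chromosome][lo - 1 : hi]
        count[i0:i1] += 1
    or_value = 1.0 if or_ is None else or_.value
    factor = or_value * 1e6 / total_reads
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan) * factor
    return MetaProfile(
        offsets=np.arange(-window, window + 1),
        mean_depth=mean,
        n_contributing=count,
        or_value=or_value,
        total_reads=total_reads,
    )


def chromosome_median(track: ScaledTrack, chromosome: str) -> float:
    """Median calibrated value over every base of one chromosome (zeros included)."""
    if chromosome not in track.values:
        raise ValueError(f"chromosome {chromosome} not in track")
    return float(np.median(track.values[chromosome]))


def occupancy_change(before: ScaledTrack, after: ScaledTrack) -> OccupancyChange:
    """Per-chromosome after/before median ratio and its genome-wide median."""
    if set(before.values) != set(after.values):
        raise ValueError("before and after tracks cover different chromosomes")
    per_chrom: dict[str, float] = {}
    for chrom in before.values:
        m_before = chromosome_median(before, chrom)
        m_after = chromosome_median(after, chrom)
        per_chrom[chrom] = m_after / m_before if m_before > 0 else math.nan
    defined = [v for v in per_chrom.values() if not math.isnan(v)]
    genome_wide = float(np.median(defined)) if defined else math.nan
    return OccupancyChange(per_chromosome=per_chrom, genome_wide=genome_wide)


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------


def read_bed_anchors(path: str | Path) -> list[CentromereAnchor]:
    """Read CDEIII elements from BED (0-based half-open); anchor = midpoint."""
    anchors = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise ValueError(f"empty BED interval on {chrom}: [{start0}, {end0})")
            anchors.append(CentromereAnchor(chrom, (start0 + end0 + 1) // 2))
    return anchors


def read_depth_tsv(path: str | Path, chrom_lengths: Mapping[str, int]) -> DepthTrack:
    """Read sparse or dense (chrom, pos, depth) rows into a dense track."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"], comment="#")
    values = {}
    for chrom, length in chrom_lengths.items():
        sub = df[df["chrom"] == chrom]
        values[chrom] = fill_gaps(
            dict(zip(sub["pos"].astype(int), sub["depth"].astype(int))), length
        )
    return DepthTrack(values=values, chrom_lengths=dict(chrom_lengths))


def write_depth_tsv(track: DepthTrack, path: str | Path, sparse: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            for i, d in enumerate(arr, start=1):
                if sparse and d == 0:
                    continue
                fh.write(f"{chrom}\t{i}\t{d}\n")


def write_meta_profile_tsv(profile: MetaProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_calibrated_depth\tn_contributing\n")
        for o, m, n in zip(profile.offsets, profile.mean_depth, profile.n_contributing):
            fh.write(f"{o}\t{m:g}\t{n}\n")
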