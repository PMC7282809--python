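"""Occupancy-ratio calibration and track scaling.

The occupancy ratio (OR) converts raw IP read depth into a quantity
comparable across samples.  It is computed from the four partition
counts as

    OR = (Wc * IPx) / (Wx * IPc)

so that a higher experimental IP yield relative to the spike-in raises
occupancy; ``invert=True`` flips the orientation for pipelines that
define the ratio the other way round.  Calibrated tracks are the raw
per-base depth multiplied by OR and normalized to one million reads
(by the experimental-genome-aligned IP read count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .read_partition import PartitionResult

__all__ = [
    "OccupancyRatio",
    "ScaledTrack",
    "occupancy_ratio",
    "scale_track",
    "write_bedgraph",
    "write_wiggle",
    "write_bigwig",
]


@dataclass(frozen=True)
class OccupancyRatio:
    value: float
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("occupancy ratio must be positive")


def occupancy_ratio(counts: PartitionResult, invert: bool = False) -> OccupancyRatio:
    """OR = (Wc * IPx) / (Wx * IPc) from the four partition counts.

    All four counts must be positive; a zero count makes the ratio
    undefined and raises an error naming the empty class.
    """
    comp = {"Wc": counts.Wc, "Wx": counts.Wx, "IPc": counts.IPc, "IPx": counts.IPx}
    empty = [k for k, v in comp.items() if v <= 0]
    if empty:
        raise ValueError(
            f"occupancy ratio undefined: no reads in class(es) {', '.join(empty)}"
        )
    value = (counts.Wc * counts.IPx) / (counts.Wx * counts.IPc)
    if invert:
        value = 1.0 / value
    return OccupancyRatio(value=value, components=comp)


@dataclass
class ScaledTrack:
    """Calibrated occupancy per base: depth * OR * 1e6 / total_reads."""

    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    or_value: float
    total_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            if len(arr) != self.chrom_lengths[chrom]:
                raise ValueError(
                    f"{chrom}: track length {len(arr)} != declared "
                    f"chromosome length {self.chrom_lengths[chrom]}"
                )


def scale_track(depth, or_: OccupancyRatio, total_reads: int, sample_id: str = "") -> ScaledTrack:
    """Scale a DepthTrack by OR and normalize to one million reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    factor = or_.value * 1e6 / total_reads
    values = {}
    for chrom, arr in depth.values.items():
        if len(arr) != depth.chrom_lengths[chrom]:
            raise ValueError(
                f"{chrom}: depth length {len(arr)} != declared "
                f"chromosome length {depth.chrom_lengths[chrom]}"
            )
        values[chrom] = np.asarray(arr, dtype=float) * factor
    return ScaledTrack(
        values=values,
        chrom_lengths=dict(depth.chrom_lengths),
        or_value=or_.value,
        total_reads=total_reads,
        sample_id=sample_id,
    )


def _runs(arr: np.ndarray):
    """Run-length encode: yields (start_idx0, end_idx0_exclusive, value)."""
    n = len(arr)
    if n == 0:
        return
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), arr[s]


def write_bedgraph(track: ScaledTrack, path: str | Path, skip_zero: bool = True) -> None:
    """Write a track as run-length-merged bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in track.values:
            for s, e, v in _runs(track.values[chrom]):
                if skip_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_wiggle(track: ScaledTrack, path: str | Path) -> None:
    """Write a track as fixed-step wiggle (1-based, step 1)."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:g}" for v in arr))
            fh.write("\n")


def write_bigwig(track: ScaledTrack, path: str | Path) -> None:
    """Optional BigWig output; requires pyBigWig."""
    import pyBigWig  # deferred: binary output is feature-flagged

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(track.chrom_lengths.items()))
    for chrom, arr in track.values.items():
        starts, ends, vals = [], [], []
        for s, e, v in _runs(arr):
            starts.append(s)
            ends.append(e)
            vals.append(float(v))
        bw.addEntries([chrom] * len(starts), starts, ends=ends, values=vals)
    bw.close()
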