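"""Relative fitness from flow-cytometry competition series.

A competition culture mixes a test and a reference strain carrying
different fluorophores.  At each passage the genotype ratio is
r = nonfluorescent / fluorescent events, and the generations elapsed in
a growth interval are g = log10(events_t24 / events_t0) / log10(2).
Relative fitness is the ordinary-least-squares slope of loge r against
cumulative generations; fitness measured between isogenic strains
carrying different fluorophores is subtracted as a control, replicates
are summarized by mean and sample standard deviation, and groups are
compared by Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .synthetic_data import CompetitionSeries, Passage

__all__ = [
    "RatioPoint",
    "FitnessEstimate",
    "genotype_ratio",
    "generations",
    "fit_fitness",
    "correct_fitness",
    "summarize_replicates",
    "welch_test",
    "read_competition_tsv",
]


@dataclass(frozen=True)
class RatioPoint:
    g_cum: float
    log_ratio: float


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-generation relative fitness (regression slope) with its OLS stderr."""

    slope: float
    stderr: float
    n_points: int
    replicate_id: str = ""
    corrected: float | None = None


def genotype_ratio(nonfluorescent: int, fluorescent: int) -> float:
    """r = nonfluorescent / fluorescent.  Zero counts are an error."""
    if fluorescent <= 0 or nonfluorescent <= 0:
        raise ValueError(
            "genotype ratio needs positive counts in both classes "
            f"(got nonfluorescent={nonfluorescent}, fluorescent={fluorescent}); "
            "sample more events"
        )
    return nonfluorescent / fluorescent


def generations(events_t0: int, events_t24: int) -> float:
    """g = log10(events_t24 / events_t0) / log10(2)."""
    if events_t0 <= 0 or events_t24 <= 0:
        raise ValueError("event counts must be positive")
    if events_t24 < events_t0:
        raise ValueError(
            f"culture shrank (t24={events_t24} < t0={events_t0}); g undefined"
        )
    return math.log10(events_t24 / events_t0) / math.log10(2)


def ratio_points(series: CompetitionSeries) -> list[RatioPoint]:
    """(cumulative generations, loge r) per passage, in passage order.

    Cumulative generations sum each passage's growth-interval g starting
    from the second row; the first row (day-0 sample) sits at g = 0.
    """
    ordered = sorted(series.passages, key=lambda p: p.passage_index)
    points = []
    g_cum = 0.0
    for i, p in enumerate(ordered):
        if i > 0:
            g_cum += generations(p.events_t0, p.events_t24)
        r = genotype_ratio(p.nonfluorescent, p.fluorescent)
        points.append(RatioPoint(g_cum, math.log(r)))
    return points


def fit_fitness(series: CompetitionSeries) -> FitnessEstimate:
    """OLS slope of loge r versus cumulative generations."""
    points = ratio_points(series)
    if len(points) < 2:
        raise ValueError("need at least 2 passages to fit a slope")
    g = np.array([p.g_cum for p in points])
    if not (np.diff(g) > 0).all():
        raise ValueError("cumulative generations must be strictly increasing")
    y = np.array([p.log_ratio for p in points])
    fit = stats.linregress(g, y)
    stderr = 0.0 if math.isnan(fit.stderr) else float(fit.stderr)
    return FitnessEstimate(
        slope=float(fit.slope),
        stderr=stderr,
        n_points=len(points),
        replicate_id=series.replicate_id,
    )


def correct_fitness(raw: FitnessEstimate, fluorophore_control: FitnessEstimate) -> FitnessEstimate:
    """Subtract the fluorophore-only control slope from a raw estimate."""
    return replace(raw, corrected=raw.slope - fluorophore_control.slope)


def summarize_replicates(estimates: list[float]) -> dict:
    """Mean and sample standard deviation (n-1) over replicate slopes."""
    n = len(estimates)
    if n < 2:
        raise ValueError("need at least 2 replicate values")
    if n < 3:
        warnings.warn("fewer than 3 biological replicates", stacklevel=2)
    arr = np.asarray(estimates, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)), "n": n}


def welch_test(a: list[float], b: list[float]) -> dict:
    """Two-sided Welch unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def read_competition_tsv(path) -> list[CompetitionSeries]:
    """Read (replicate, passage, events_t0, events_t24, fluorescent,
    nonfluorescent) rows into one series per replicate."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for rep, sub in df.groupby("replicate", sort=True):
        passages = [
            Passage(
                int(r.passage), int(r.events_t0), int(r.events_t24),
                int(r.fluorescent), int(r.nonfluorescent),
            )
            for r in sub.itertuples()
        ]
        out.append(CompetitionSeries(passages, replicate_id=str(rep)))
    return out
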