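"""Precocious sister-chromatid separation proportions from scored cells.

Metaphase (securin-positive) cells are scored for one versus two GFP
dots at a marked locus; two dots indicate precocious loss of cohesion.
Each strain's percentage of two-dot cells is reported with a 95% Wilson
score interval, and strains can be compared with a two-sided Fisher
exact test (both uncertainty measures are extensions beyond the raw
proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synthetic_data import CytologyRow, CytologyTable

__all__ = ["SeparationResult", "percent_precocious", "compare_strains", "read_cytology_tsv"]


@dataclass(frozen=True)
class SeparationResult:
    strain: str
    percent_two_dot: float
    n_scored: int
    ci_low: float
    ci_high: float


def percent_precocious(table: CytologyTable) -> list[SeparationResult]:
    """Percent two-dot cells per strain with a 95% Wilson score interval."""
    results = []
    for row in table.rows:
        if row.n_scored <= 0:
            raise ValueError(f"{row.strain}: no cells scored")
        pct = 100.0 * row.n_two_dot / row.n_scored
        lo, hi = proportion_confint(row.n_two_dot, row.n_scored, alpha=0.05, method="wilson")
        results.append(
            SeparationResult(row.strain, pct, row.n_scored, 100.0 * lo, 100.0 * hi)
        )
    return results


def compare_strains(a: CytologyRow, b: CytologyRow) -> dict:
    """Difference in percent two-dot cells and a two-sided Fisher exact p."""
    delta = 100.0 * a.n_two_dot / a.n_scored - 100.0 * b.n_two_dot / b.n_scored
    table = [
        [a.n_two_dot, a.n_scored - a.n_two_dot],
        [b.n_two_dot, b.n_scored - b.n_two_dot],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"delta_percent": delta, "p": float(p)}


def read_cytology_tsv(path) -> CytologyTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    rows = [
        CytologyRow(str(r.strain), int(r.n_scored), int(r.n_two_dot))
        for r in df.itertuples()
    ]
    return CytologyTable(rows)
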