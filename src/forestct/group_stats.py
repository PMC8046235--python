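"""Group contrasts between conservation-translocation categories.

Two families of tests compare species recommended for reintroduction with
species recommended for benign introduction:

* a two-sided Mann–Whitney U test on the percentage of each species' range
  inside protected areas (the distributions are far from normal — many
  zeros, long right tail), and
* chi-square tests of independence on 2×2 tables crossing CT category with
  whether a conservation action (invasive-species control, habitat
  restoration) is recommended, with the standard expected-count assumption
  check (at least 80% of expected cells above 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .species_catalog import SpeciesRecord

#: Sample-size ceiling below which the Mann–Whitney p-value is computed by
#: exact enumeration (ties force the tie-corrected normal approximation).
_EXACT_LIMIT = 20


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method_notes: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class ContingencyTable2x2:
    """CT category (rows) × action recommended yes/no (columns)."""

    cells: np.ndarray  # shape (2, 2), nonnegative ints
    row_labels: tuple[str, str] = ("reintroduction", "benign_introduction")
    col_labels: tuple[str, str] = ("recommended", "not_recommended")

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.shape != (2, 2) or (self.cells < 0).any():
            raise ValueError("cells must be a 2x2 nonnegative integer table")

    @property
    def row_margins(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    @property
    def expected(self) -> np.ndarray:
        return np.outer(self.row_margins, self.col_margins) / self.total

    @classmethod
    def from_catalog(cls, records: Iterable[SpeciesRecord], action: str) -> "ContingencyTable2x2":
        """Cross CT category with whether ``action`` is recommended."""
        cells = np.zeros((2, 2), dtype=int)
        rows = {"reintroduction": 0, "benign_introduction": 1}
        for rec in records:
            i = rows.get(rec.ct_category)
            if i is None:
                continue
            j = 0 if action in rec.actions_recommended else 1
            cells[i, j] += 1
        return cls(cells=cells)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided") -> TestResult:
    """Two-sided Mann–Whitney U test with midranks for ties.

    The p-value is exact (full enumeration of rank arrangements) when the
    pooled sample is small (≤ 20) and tie-free; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used. The reported statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= _EXACT_LIMIT and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    note = ("exact enumeration" if exact
            else "normal approximation, tie-corrected variance, continuity correction")
    return TestResult(statistic=float(res.statistic), df=None,
                      p_value=float(res.pvalue), method_notes=note)


def chi_square_independence(table: ContingencyTable2x2,
                            continuity_correction: bool = True) -> TestResult:
    """Chi-square test of independence on a 2×2 table.

    With ``continuity_correction`` (the default, matching the R 2×2
    convention) the statistic is Σ (|O−E| − ½)² / E; without it the plain
    Pearson statistic. df = 1.
    """
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError("all margins must be positive")
    stat, p, df, _ = stats.chi2_contingency(table.cells, correction=continuity_correction)
    note = "Yates continuity correction" if continuity_correction else "no continuity correction"
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p), method_notes=note)


def check_chi_square_assumption(table: ContingencyTable2x2,
                                min_expected: float = 5.0,
                                min_fraction: float = 0.8) -> bool:
    """True when ≥ 80% of expected cell counts exceed 5."""
    expected = table.expected
    return float((expected > min_expected).mean()) >= min_fraction


def summarize_groups(catalog_frame: pd.DataFrame, metrics_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-CT-category habitat summary.

    Expects the flattened catalog frame (one row per species with
    ``ct_category`` and recommendation booleans) and a metrics frame with
    ``pct_protected``/``pct_restoration``. Returns one row per CT category:
    n, median/mean protected percentage, percent recommended for habitat
    restoration and for invasive-species control, percent island dwellers
    and percent of species with no restoration potential in their range.
    """
    joined = catalog_frame.merge(metrics_frame, on="species_id", how="inner")
    rows = []
    for category, grp in joined.groupby("ct_category", sort=True):
        rows.append({
            "ct_category": category,
            "n": len(grp),
            "median_pct_protected": float(grp["pct_protected"].median()),
            "mean_pct_protected": float(grp["pct_protected"].mean()),
            "pct_habitat_restoration_recommended":
                100.0 * float(grp["habitat_restoration_recommended"].mean()),
            "pct_invasive_control_recommended":
                100.0 * float(grp["invasive_control_recommended"].mean()),
            "pct_island_dwellers": 100.0 * float(grp["island_dweller"].mean()),
            "pct_no_restoration_potential":
                100.0 * float((grp["pct_restoration"] <= 0).mean()),
        })
    return pd.DataFrame(rows).set_index("ct_category")
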