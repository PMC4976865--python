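"""Inventory completeness per group x site via abundance-based sample coverage.

Sample coverage estimates the proportion of individuals in the assemblage
belonging to species already detected in the sample; it depends only on the
total number of records ``n`` and the numbers of singletons ``f1`` and
doubletons ``f2``:

    C_hat = 1 - (f1 / n) * [ (n - 1) * f1 / ((n - 1) * f1 + 2 * f2) ]

with C_hat = 1 when f1 = 0 (every species seen at least twice, so an
unseen individual almost surely belongs to a detected species). Reported as
a percentage with two decimals in the completeness table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .community import OccurrenceTable, normalize_label
from .errors import SmallSampleWarning, UndefinedValueWarning, UnknownSiteError

__all__ = [
    "AbundanceSummary",
    "CoverageEstimate",
    "summarize_abundance",
    "sample_coverage",
    "coverage_table",
    "write_coverage_csv",
]


class AbundanceSummary(NamedTuple):
    """Totals driving the coverage estimator for one group x site cell."""

    n: int   # total records over species
    f1: int  # species with exactly one record
    f2: int  # species with exactly two records

    @property
    def is_empty(self) -> bool:
        return self.n == 0


@dataclass(frozen=True)
class CoverageEstimate:
    coverage: float  # proportion in [0, 1] (NaN if undefined)

    @property
    def percent(self) -> float:
        """Coverage x 100, rounded to 2 decimals."""
        return round(self.coverage * 100.0, 2) if not math.isnan(self.coverage) else math.nan


def summarize_abundance(occ: OccurrenceTable, group: str, site: str) -> AbundanceSummary:
    """Tally n, f1, f2 from per-species record counts at one site.

    Species with zero records contribute nothing. An empty (group, site)
    cell returns the empty summary (n = 0); coverage on it is undefined.
    """
    sl = occ.group_slice(group)
    key = normalize_label(site)
    site_mask = sl["site"].map(normalize_label) == key
    if not site_mask.any():
        raise UnknownSiteError(site)
    counts = sl.loc[site_mask & (sl["records"] > 0), "records"]
    return AbundanceSummary(
        n=int(counts.sum()),
        f1=int((counts == 1).sum()),
        f2=int((counts == 2).sum()),
    )


def sample_coverage(s: AbundanceSummary) -> CoverageEstimate:
    """Abundance-based coverage estimate from (n, f1, f2).

    Edge cases: n = 0 is undefined (NaN with a warning); f1 = 0 gives
    exactly 1; n = 1 with f1 = 1 degenerates to 0 and triggers a
    small-sample warning.
    """
    n, f1, f2 = s
    if n == 0:
        warnings.warn(
            "sample coverage undefined for an empty sample",
            UndefinedValueWarning,
            stacklevel=2,
        )
        return CoverageEstimate(math.nan)
    if f1 == 0:
        return CoverageEstimate(1.0)
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        # only reachable at n = 1, f1 = 1: a single record of a single species
        warnings.warn(
            "coverage estimated from a single record; reported as 0",
            SmallSampleWarning,
            stacklevel=2,
        )
        return CoverageEstimate(0.0)
    return CoverageEstimate(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def coverage_table(
    occ: OccurrenceTable,
    groups: Iterable[str] | None = None,
    sites: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Completeness table: one row per group x site with S, R, f1, f2 and
    the completeness percentage."""
    rows = []
    for group in groups if groups is not None else occ.groups:
        sl = occ.group_slice(group)
        group_sites = sites if sites is not None else dict.fromkeys(sl["site"])
        for site in group_sites:
            s = summarize_abundance(occ, group, site)
            present = sl[(sl["site"].map(normalize_label) == normalize_label(site))
                         & (sl["records"] > 0)]
            est = sample_coverage(s) if not s.is_empty else CoverageEstimate(math.nan)
            rows.append(
                {
                    "group": group,
                    "site": site,
                    "S": int(len(present)),
                    "R": s.n,
                    "f1": s.f1,
                    "f2": s.f2,
                    "completeness_pct": est.percent,
                }
            )
    return pd.DataFrame(rows)


def write_coverage_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
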