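"""Partitioning of pairwise and multiple-site dissimilarity.

Total incidence-based dissimilarity between two communities is the Jaccard
complement

    beta_cc = (b + c) / (a + b + c)

with ``a`` shared elements, ``b`` exclusive to the first site and ``c``
exclusive to the second. It decomposes additively into a turnover
(replacement) component and a richness-difference component:

    beta_3    = 2 * min(b, c) / (a + b + c)
    beta_rich = |b - c|       / (a + b + c)
    beta_cc   = beta_3 + beta_rich          (exact in rational arithmetic)

Applied to species sets this is species-level dissimilarity; applied to the
pooled set of taxa at every Linnaean rank (species, genus, family, ...,
obtained with :func:`taxbeta.community.expand_taxa`) it measures
dissimilarity of the whole taxonomic structure, a surrogate for
phylogenetic beta diversity: shared higher taxa pull the value down even
when the species themselves differ.

Multiple-site summaries generalize the same partition to T sites. The
default "component-sum" variant sums the components a, b, c over all
T(T-1)/2 site pairs before forming the ratios, which preserves exact
additivity and reduces to the pairwise partition at T = 2; a "pair-mean"
alternate (arithmetic mean of pairwise values) is available for
sensitivity checks.

Undefined quantities (two empty communities, zero total dissimilarity in a
contribution split) propagate as NaN with a warning, never as zeros.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd

from .community import IncidenceMatrix, TaxonomyTable, expand_taxa
from .errors import UndefinedValueWarning, ValidationError

__all__ = [
    "PairComponents",
    "BetaPartition",
    "MultiSiteBeta",
    "pair_components",
    "partition",
    "taxonomic_partition",
    "pairwise_table",
    "multi_site",
    "contribution_percentages",
    "square_matrix",
    "write_pairwise_csv",
    "write_multisite_csv",
]

Level = Literal["species", "taxonomic"]
Variant = Literal["component-sum", "pair-mean"]


class PairComponents(NamedTuple):
    """Element counts for one unordered site pair: shared / first-only /
    second-only. At species level these are species counts; at taxonomic
    level, counts over taxa pooled across all ranks (Ta, Tb, Tc)."""

    a: int
    b: int
    c: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c


class BetaPartition(NamedTuple):
    """The additive triple (total, turnover, richness-difference)."""

    beta_cc: float
    beta_3: float
    beta_rich: float


_NAN_PARTITION = BetaPartition(math.nan, math.nan, math.nan)


@dataclass(frozen=True)
class MultiSiteBeta:
    """Multiple-site dissimilarity summary over T sites.

    ``contribution_turnover``/``contribution_rich`` are percentages of
    total dissimilarity (NaN when beta_cc = 0).
    """

    T: int
    beta_cc: float
    beta_3: float
    beta_rich: float
    contribution_turnover: float
    contribution_rich: float
    variant: Variant = "component-sum"

    @property
    def partition(self) -> BetaPartition:
        return BetaPartition(self.beta_cc, self.beta_3, self.beta_rich)


def pair_components(setA: Iterable, setB: Iterable) -> PairComponents:
    """Count shared and exclusive elements of two communities.

    Both sets empty yields (0, 0, 0); downstream :func:`partition` turns
    that into a NaN partition with a warning rather than failing.
    """
    A, B = frozenset(setA), frozenset(setB)
    return PairComponents(a=len(A & B), b=len(A - B), c=len(B - A))


def partition(components: PairComponents) -> BetaPartition:
    """Partition one pair's dissimilarity into turnover + richness difference.

    beta_cc = (b+c)/(a+b+c); beta_3 = 2*min(b,c)/(a+b+c);
    beta_rich = |b-c|/(a+b+c). Additivity beta_cc = beta_3 + beta_rich is
    exact. An all-zero component triple is undefined and returns NaNs with
    an :class:`UndefinedValueWarning`.
    """
    a, b, c = components
    if min(a, b, c) < 0:
        raise ValidationError(f"negative pair components: {components}")
    n = a + b + c
    if n == 0:
        warnings.warn(
            "dissimilarity undefined for a pair of empty communities",
            UndefinedValueWarning,
            stacklevel=2,
        )
        return _NAN_PARTITION
    return BetaPartition(
        beta_cc=(b + c) / n,
        beta_3=2 * min(b, c) / n,
        beta_rich=abs(b - c) / n,
    )


def taxonomic_partition(
    speciesA: Iterable[str],
    speciesB: Iterable[str],
    tax: TaxonomyTable,
) -> BetaPartition:
    """Partition dissimilarity of the full taxonomic structure of two sites.

    Each species set is expanded to the upward-closed set of (rank, name)
    pairs over every configured rank — species included — and the ordinary
    partition is applied to those pooled taxon sets, so the components are
    the shared/exclusive taxon counts Ta, Tb, Tc.
    """
    TA = expand_taxa(speciesA, tax)
    TB = expand_taxa(speciesB, tax)
    return partition(pair_components(TA, TB))


def _pair_sets(
    inc: IncidenceMatrix,
    level: Level,
    tax: TaxonomyTable | None,
) -> dict[str, frozenset]:
    """Per-site element sets at the requested level."""
    if level not in ("species", "taxonomic"):
        raise ValueError(f"unknown level {level!r}")
    if level == "taxonomic" and tax is None:
        raise ValidationError("taxonomic level requires a TaxonomyTable")
    out: dict[str, frozenset] = {}
    for site in inc.sites:
        sp = inc.site_species(site)
        out[site] = expand_taxa(sp, tax) if level == "taxonomic" else sp
    return out


def pairwise_table(
    inc: IncidenceMatrix,
    level: Level = "species",
    tax: TaxonomyTable | None = None,
) -> pd.DataFrame:
    """Partition every unordered site pair of an incidence matrix.

    Returns a long-format DataFrame with one row per pair and columns
    ``group, level, site_i, site_j, a, b, c, beta_cc, beta_3, beta_rich``
    (T(T-1)/2 rows, pairs in site order). Pairs involving a site with zero
    presences yield NaN values with a warning.
    """
    if len(inc.sites) < 2:
        raise ValidationError(f"need >= 2 sites, got {len(inc.sites)}")
    sets = _pair_sets(inc, level, tax)
    empty = set(inc.empty_sites)
    rows = []
    for si, sj in itertools.combinations(inc.sites, 2):
        if si in empty or sj in empty:
            warnings.warn(
                f"pair ({si}, {sj}) involves an empty site; value set to NaN",
                UndefinedValueWarning,
                stacklevel=2,
            )
            comp = PairComponents(0, 0, 0)
            part = _NAN_PARTITION
        else:
            comp = pair_components(sets[si], sets[sj])
            part = partition(comp)
        rows.append(
            {
                "group": inc.group,
                "level": level,
                "site_i": si,
                "site_j": sj,
                "a": comp.a,
                "b": comp.b,
                "c": comp.c,
                "beta_cc": part.beta_cc,
                "beta_3": part.beta_3,
                "beta_rich": part.beta_rich,
            }
        )
    return pd.DataFrame(rows)


def multi_site(
    inc: IncidenceMatrix,
    level: Level = "species",
    tax: TaxonomyTable | None = None,
    variant: Variant = "component-sum",
) -> MultiSiteBeta:
    """Summarize dissimilarity over all sites simultaneously.

    component-sum (default): beta_cc = sum(b+c)/sum(a+b+c) etc., sums over
    all defined site pairs — additive by construction and equal to the
    pairwise partition at T = 2. pair-mean: arithmetic mean of the pairwise
    values. Identical sites everywhere give beta_cc = 0 and NaN
    contributions with a warning.
    """
    if variant not in ("component-sum", "pair-mean"):
        raise ValueError(f"unknown multi-site variant {variant!r}")
    nonempty = [s for s in inc.sites if s not in set(inc.empty_sites)]
    if len(nonempty) < 2:
        raise ValidationError(
            f"multi-site dissimilarity needs >= 2 non-empty sites, got {len(nonempty)}"
        )
    table = pairwise_table(inc, level=level, tax=tax)
    defined = table.dropna(subset=["beta_cc"])
    T = len(nonempty)
    if variant == "component-sum":
        tot = int((defined["a"] + defined["b"] + defined["c"]).sum())
        bcc = float((defined["b"] + defined["c"]).sum() / tot)
        b3 = float((2 * np.minimum(defined["b"], defined["c"])).sum() / tot)
        brich = float((defined["b"] - defined["c"]).abs().sum() / tot)
    else:
        bcc = float(defined["beta_cc"].mean())
        b3 = float(defined["beta_3"].mean())
        brich = float(defined["beta_rich"].mean())
    if bcc > 0:
        pct_t, pct_r = 100.0 * b3 / bcc, 100.0 * brich / bcc
    else:
        warnings.warn(
            "all sites identical: contribution percentages undefined",
            UndefinedValueWarning,
            stacklevel=2,
        )
        pct_t = pct_r = math.nan
    return MultiSiteBeta(
        T=T,
        beta_cc=bcc,
        beta_3=b3,
        beta_rich=brich,
        contribution_turnover=pct_t,
        contribution_rich=pct_r,
        variant=variant,
    )


def contribution_percentages(msb: MultiSiteBeta | BetaPartition) -> tuple[float, float]:
    """Percent of total dissimilarity due to turnover vs richness difference.

    Sums to 100 (within floating rounding). Undefined when beta_cc = 0.
    """
    bcc, b3, brich = msb.beta_cc, msb.beta_3, msb.beta_rich
    if not bcc > 0:
        warnings.warn(
            "contribution percentages undefined for beta_cc = 0",
            UndefinedValueWarning,
            stacklevel=2,
        )
        return (math.nan, math.nan)
    return (100.0 * b3 / bcc, 100.0 * brich / bcc)


def square_matrix(table: pd.DataFrame, field: str = "beta_cc") -> pd.DataFrame:
    """Pivot a long pairwise table into a symmetric square matrix
    (zero diagonal) for ordination."""
    sites = list(dict.fromkeys(list(table["site_i"]) + list(table["site_j"])))
    mat = pd.DataFrame(0.0, index=sites, columns=sites)
    for row in table.itertuples(index=False):
        val = getattr(row, field)
        mat.at[row.site_i, row.site_j] = val
        mat.at[row.site_j, row.site_i] = val
    return mat


def write_pairwise_csv(table: pd.DataFrame, path) -> None:
    """Long-format pairwise writer: group, level, site_i, site_j and the
    three partition components at full precision."""
    cols = ["group", "level", "site_i", "site_j", "beta_cc", "beta_3", "beta_rich"]
    table[cols].to_csv(path, index=False)


def write_multisite_csv(results: Iterable[tuple[str, Level, MultiSiteBeta]], path) -> None:
    """Multi-site writer: one row per (group, level) summary."""
    rows = [
        {
            "group": g,
            "level": lv,
            "variant": m.variant,
            "T": m.T,
            "beta_cc": m.beta_cc,
            "beta_3": m.beta_3,
            "beta_rich": m.beta_rich,
            "pct_turnover": m.contribution_turnover,
            "pct_rich": m.contribution_rich,
        }
        for g, lv, m in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
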