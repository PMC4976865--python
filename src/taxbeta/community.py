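"""Data model and ingestion for multi-site occurrence records and taxonomies.

The analysis operates on three structures per faunal group:

* an :class:`OccurrenceTable` — one row per (group, species, site) with a
  record count;
* a :class:`TaxonomyTable` — an ordered list of Linnaean ranks
  (coarse -> fine, ending in ``species``) and each species' name at every
  rank, possibly ragged (blank cells where a rank does not apply to a
  lineage);
* an :class:`IncidenceMatrix` — the binary site x species presence matrix
  obtained by thresholding record counts at >= 1, the input to all
  dissimilarity computations.

Labels are compared after normalization (trimmed, internal whitespace
collapsed, case-folded) because spreadsheet-sourced names are dirty; the
original spelling of the first occurrence is preserved in outputs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptySiteWarning,
    SchemaError,
    UnassignedSpeciesError,
    UnknownGroupError,
    ValidationError,
)

__all__ = [
    "OccurrenceTable",
    "TaxonomyTable",
    "IncidenceMatrix",
    "TaxonSet",
    "normalize_label",
    "read_occurrences",
    "read_taxonomy",
    "xlsx_to_csv",
    "build_incidence",
    "expand_taxa",
]

_WS = re.compile(r"\s+")

OCCURRENCE_COLUMNS = ("group", "species", "site", "records")


def normalize_label(label: str) -> str:
    """Normalize a label for matching: trim, collapse whitespace, casefold."""
    return _WS.sub(" ", str(label).strip()).casefold()


@dataclass(frozen=True)
class OccurrenceTable:
    """Validated long-format occurrence records.

    ``data`` holds columns ``group, species, site, records`` with one row per
    (group, species, site) triple; ``records`` is a non-negative integer and
    rows with zero records are legal but contribute no presence.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"occurrence table missing columns: {missing}")
        if (df["records"] < 0).any():
            bad = df.loc[df["records"] < 0]
            raise ValidationError(
                f"negative record counts for {len(bad)} row(s), "
                f"first: {tuple(bad.iloc[0][['group', 'species', 'site']])}"
            )
        keys = pd.DataFrame(
            {
                "g": df["group"].map(normalize_label),
                "s": df["species"].map(normalize_label),
                "t": df["site"].map(normalize_label),
            }
        )
        dup_mask = keys.duplicated(keep=False)
        if dup_mask.any():
            trips = (
                df.loc[dup_mask, ["group", "species", "site"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise DuplicateRecordError(trips)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.data["site"]))

    def group_slice(self, group: str) -> pd.DataFrame:
        key = normalize_label(group)
        mask = self.data["group"].map(normalize_label) == key
        if not mask.any():
            raise UnknownGroupError(group)
        return self.data.loc[mask]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-group classification: ordered ranks and per-species assignments.

    ``ranks`` runs coarse -> fine and must end in ``species``.
    ``assignments`` has one column per rank; blank/NaN cells mean the rank is
    not applicable to that lineage and contribute no taxon.
    """

    group: str
    ranks: tuple[str, ...]
    assignments: pd.DataFrame
    _index: dict[str, tuple] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.ranks or normalize_label(self.ranks[-1]) != "species":
            raise SchemaError(
                f"rank list must end in 'species', got {list(self.ranks)}"
            )
        missing = [r for r in self.ranks if r not in self.assignments.columns]
        if missing:
            raise SchemaError(f"taxonomy table missing rank columns: {missing}")
        idx = {}
        for vals in self.assignments[list(self.ranks)].to_numpy(dtype=object):
            lineage = tuple(
                None if (v is None or pd.isna(v) or str(v).strip() == "") else str(v)
                for v in vals
            )
            if lineage[-1] is None:
                raise SchemaError("taxonomy row with blank species cell")
            idx[normalize_label(lineage[-1])] = lineage
        object.__setattr__(self, "_index", idx)

    def lineage(self, species: str) -> tuple:
        """Names at every rank for one species (None where blank)."""
        try:
            return self._index[normalize_label(species)]
        except KeyError:
            raise UnassignedSpeciesError([species], self.group) from None

    @property
    def species(self) -> list[str]:
        return list(self.assignments[self.ranks[-1]])

    def check_covers(self, species: Iterable[str]) -> None:
        """Raise if any species in the iterable lacks an assignment row."""
        missing = [s for s in species if normalize_label(s) not in self._index]
        if missing:
            raise UnassignedSpeciesError(missing, self.group)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary site x species presence matrix for one group.

    ``presence`` is a pandas DataFrame indexed by site with species columns,
    values in {0, 1}: 1 iff the species has >= 1 record at the site. Sites
    with no presences are retained and listed in ``empty_sites``.
    """

    group: str
    presence: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def empty_sites(self) -> list[str]:
        sums = self.presence.sum(axis=1)
        return list(sums.index[sums == 0])

    def site_species(self, site: str) -> frozenset[str]:
        """The species set observed at one site."""
        row = self.presence.loc[site]
        return frozenset(row.index[row > 0])

    def richness(self) -> pd.Series:
        """Species per site (the row sums; S in completeness tables)."""
        return self.presence.sum(axis=1).astype(int)


#: A set of (rank, name) pairs, upward-closed over the classification.
TaxonSet = frozenset


def read_occurrences(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> OccurrenceTable:
    """Read a delimited occurrence table and validate it.

    Parameters
    ----------
    path:
        CSV/TSV file with columns ``group, species, site, records`` (any
        order; names remappable through ``schema``).
    schema:
        Optional mapping from the canonical column names to the names used in
        the file, e.g. ``{"species": "Especie"}``.
    delimiter:
        Field separator; sniffed by pandas when omitted.

    Duplicated (group, species, site) triples are an error, never silently
    summed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    rename = {}
    for canonical in OCCURRENCE_COLUMNS:
        source = (schema or {}).get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)[list(OCCURRENCE_COLUMNS)].copy()
    try:
        df["records"] = pd.to_numeric(df["records"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-integer record counts in {path.name}: {exc}")
    return OccurrenceTable(df.reset_index(drop=True))


def xlsx_to_csv(
    xlsx_path: str | Path,
    csv_path: str | Path,
    sheet: int | str = 0,
) -> Path:
    """Thin conversion entry point: re-export an XLSX sheet as UTF-8 CSV."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    return csv_path


def read_taxonomy(path: str | Path, group: str) -> TaxonomyTable:
    """Read one group's taxonomy CSV.

    The header row gives the rank names, coarse -> fine, ending in
    ``species``; each subsequent row is one species' lineage. Blank cells
    denote ranks not applicable to that lineage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    ranks = tuple(df.columns)
    return TaxonomyTable(group=group, ranks=ranks, assignments=df)


def build_incidence(
    occ: OccurrenceTable,
    group: str,
    sites: Sequence[str] | None = None,
) -> IncidenceMatrix:
    """Derive the binary site x species matrix for one group.

    ``presence[i, j] = 1`` iff the (group, species j, site i) row has >= 1
    record. Sites with zero presences are retained and flagged with an
    :class:`EmptySiteWarning`. The result is invariant to the row order of
    the occurrence table. ``sites`` fixes the site universe (and row order);
    by default the sites observed for the group, in first-appearance order.
    """
    sl = occ.group_slice(group)
    site_order = list(sites) if sites is not None else list(dict.fromkeys(sl["site"]))
    present = sl[sl["records"] >= 1]
    species_order = sorted(dict.fromkeys(present["species"]), key=normalize_label)
    mat = pd.DataFrame(0, index=site_order, columns=species_order, dtype=int)
    for row in present.itertuples(index=False):
        if row.site in mat.index:
            mat.at[row.site, row.species] = 1
    inc = IncidenceMatrix(group=group, presence=mat)
    if inc.empty_sites:
        warnings.warn(
            f"group {group!r}: site(s) with zero presences: {inc.empty_sites}",
            EmptySiteWarning,
            stacklevel=2,
        )
    return inc


def expand_taxa(species_set: Iterable[str], tax: TaxonomyTable) -> TaxonSet:
    """Pool a species set with all its higher taxa.

    Returns the upward-closed set of ``(rank, name)`` pairs over every
    configured rank, species included. Blank rank cells contribute no
    member. Taxon identity is the (rank, name) pair, so identical names at
    different ranks stay distinct.
    """
    species = list(species_set)
    tax.check_covers(species)
    members: set[tuple[str, str]] = set()
    for sp in species:
        lineage = tax.lineage(sp)
        for rank, name in zip(tax.ranks, lineage):
            if name is None:
                continue
            members.add((rank, normalize_label(name)))
    return frozenset(members)
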