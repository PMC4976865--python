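"""Synthetic taxonomies and multi-site occurrence tables with known structure.

Every pipeline stage is testable against ground truth: a
:class:`CommunityDesign` fixes, per group, a shared species core present at
all sites plus per-site exclusive species, so the pairwise components
(a, b, c) — and hence every dissimilarity partition — are known by
construction and returned alongside the generated table.

Record counts for present species are i.i.d. draws from a geometric
distribution on {1, 2, ...}; its long right tail yields the skewed
rank-abundance shape of real survey data and guarantees singletons and
doubletons, which is what the coverage estimator consumes. The success
parameter p is the expected fraction of singleton species (E[f1] = S * p).

The ``hidalgo_like`` preset fabricates four vertebrate groups across six
ecoregion-style sites with ragged Linnaean hierarchies of 5-15 ranks and
per-site richness magnitudes typical of a state-level vertebrate survey.
Species and taxon names are synthetic labels, not real taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import OccurrenceTable, TaxonomyTable
from .errors import DesignError

__all__ = [
    "CommunityDesign",
    "generate_taxonomy",
    "generate_occurrences",
    "hidalgo_like",
    "two_site_contrast",
    "HIDALGO_SITES",
    "HIDALGO_RANKS",
]

#: Six ecoregion-style site labels for the bundled preset.
HIDALGO_SITES = (
    "Montane Forests",
    "Moist Forests",
    "Volcanic Belt",
    "Mexican Matorral",
    "Meseta Central",
    "Sierra Madre",
)

#: Rank lists per group, coarse -> fine; depth 5 to 15 levels.
HIDALGO_RANKS: dict[str, tuple[str, ...]] = {
    "amphibians": ("order", "family", "subfamily", "genus", "species"),
    "reptiles": (
        "subclass", "order", "suborder", "infraorder", "superfamily",
        "family", "subfamily", "genus", "species",
    ),
    "birds": (
        "subclass", "infraclass", "parvclass", "superdivision", "division",
        "subdivision", "infradivision", "superorder", "order", "suborder",
        "superfamily", "family", "subfamily", "genus", "species",
    ),
    "mammals": (
        "order", "suborder", "infraorder", "superfamily", "family",
        "subfamily", "tribe", "genus", "species",
    ),
}


@dataclass(frozen=True)
class CommunityDesign:
    """Controllable blueprint for one group's multi-site community.

    ``site_exclusive`` fixes each site's exclusive species count directly;
    when omitted it is derived from ``base_exclusive`` and
    ``turnover_bias``: bias 1 gives equal exclusive counts at every site
    (pure turnover, beta_rich = 0 for every pair), bias 0 grades them from
    0 to 2x the base (richness differences dominate).

    ``branching[i]`` is the (mean) number of children each rank-(i-1) taxon
    has at rank i, root children for i = 0; integer values give a
    deterministic balanced classification, fractional values draw counts
    from a shifted Poisson. ``ragged_drop`` blanks the named intermediate
    ranks with the given probability per lineage.

    ``abundance_geom_p`` in (0, 1) is the geometric parameter for record
    counts of present species (mean 1/p records; E[f1] = S * p).
    """

    group: str = "group1"
    n_sites: int = 6
    sites: tuple[str, ...] | None = None
    shared_core: int = 10
    site_exclusive: tuple[int, ...] | None = None
    base_exclusive: int = 8
    turnover_bias: float = 0.7
    ranks: tuple[str, ...] = ("family", "genus", "species")
    branching: tuple[float, ...] = (4, 3, 4)
    ragged_drop: Mapping[str, float] = field(default_factory=dict)
    abundance_geom_p: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise DesignError(f"need >= 2 sites, got {self.n_sites}")
        if self.shared_core < 0 or self.base_exclusive < 0:
            raise DesignError("species counts must be >= 0")
        if not 0 < self.abundance_geom_p < 1:
            raise DesignError("abundance parameter must lie in (0, 1)")
        if not 0 <= self.turnover_bias <= 1:
            raise DesignError("turnover_bias must lie in [0, 1]")
        if len(self.branching) != len(self.ranks):
            raise DesignError("branching must give one value per rank")
        if self.sites is not None and len(self.sites) != self.n_sites:
            raise DesignError("sites list length must equal n_sites")
        if self.site_exclusive is not None and len(self.site_exclusive) != self.n_sites:
            raise DesignError("site_exclusive length must equal n_sites")

    @property
    def site_labels(self) -> tuple[str, ...]:
        if self.sites is not None:
            return self.sites
        return tuple(f"site{i + 1}" for i in range(self.n_sites))

    @property
    def exclusive_counts(self) -> tuple[int, ...]:
        if self.site_exclusive is not None:
            return self.site_exclusive
        t, e, n = self.turnover_bias, self.base_exclusive, self.n_sites
        grades = np.linspace(0.0, 2.0, n) if n > 1 else np.array([1.0])
        return tuple(
            int(max(0, round(e * (t + (1 - t) * g)))) for g in grades
        )

    @property
    def n_species_needed(self) -> int:
        return self.shared_core + sum(self.exclusive_counts)

    def expected_components(self) -> pd.DataFrame:
        """Designed (a, b, c) for every unordered site pair — the ground
        truth the dissimilarity module must recover exactly."""
        labels, uniq = self.site_labels, self.exclusive_counts
        rows = []
        for i in range(self.n_sites):
            for j in range(i + 1, self.n_sites):
                rows.append(
                    {
                        "site_i": labels[i],
                        "site_j": labels[j],
                        "a": self.shared_core,
                        "b": uniq[i],
                        "c": uniq[j],
                    }
                )
        return pd.DataFrame(rows)


def _rank_prefix(rank: str) -> str:
    return rank[:3].capitalize()


def generate_taxonomy(design: CommunityDesign, rng: np.random.Generator | None = None) -> TaxonomyTable:
    """Random rooted classification with the designed branching.

    Deterministic given the design seed; with integer branching the shape
    itself is deterministic (e.g. branching (3, 2, 2) over
    (family, genus, species) gives exactly 3 families, 6 genera,
    12 species). Species labels are synthetic binomial-style strings built
    from the parent genus (or the group name when no genus rank exists).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(2)[0])
    ranks = design.ranks
    counters = {r: 0 for r in ranks}

    def n_children(mean: float) -> int:
        if float(mean).is_integer():
            return int(mean)
        return 1 + int(rng.poisson(max(mean - 1, 0.0)))

    lineages: list[dict[str, str]] = []

    def grow(level: int, lineage: dict[str, str]) -> None:
        rank = ranks[level]
        for _ in range(n_children(design.branching[level])):
            counters[rank] += 1
            if rank == ranks[-1]:
                parent = next(
                    (lineage[r] for r in reversed(ranks[:-1]) if r in lineage),
                    design.group,
                )
                name = f"{parent} sp{counters[rank]:04d}"
            else:
                name = f"{_rank_prefix(rank)}{counters[rank]:03d}"
            child = {**lineage, rank: name}
            if level == len(ranks) - 1:
                lineages.append(child)
            else:
                grow(level + 1, child)

    grow(0, {})
    if not lineages:
        raise DesignError("branching produced zero species")
    # blank ragged ranks after growth so dropping never orphans a species
    for lin in lineages:
        for rank, p in design.ragged_drop.items():
            if rank in lin and rank != ranks[-1] and rng.random() < p:
                del lin[rank]
    df = pd.DataFrame(
        [[lin.get(r, "") for r in ranks] for lin in lineages], columns=list(ranks)
    )
    return TaxonomyTable(group=design.group, ranks=ranks, assignments=df)


def generate_occurrences(
    design: CommunityDesign,
    tax: TaxonomyTable,
    rng: np.random.Generator | None = None,
) -> tuple[OccurrenceTable, pd.DataFrame]:
    """Realize the designed community as an occurrence table.

    Each site receives the shared core plus its exclusive species; record
    counts for every present (species, site) are geometric draws, so every
    designed presence has >= 1 record and the realized pairwise components
    equal the design exactly. Returns (occurrences, ground-truth
    components per pair).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(2)[1])
    pool = list(tax.species)
    if len(pool) < design.n_species_needed:
        raise DesignError(
            f"design needs {design.n_species_needed} species but taxonomy "
            f"provides only {len(pool)}"
        )
    order = rng.permutation(len(pool))
    picked = [pool[i] for i in order[: design.n_species_needed]]
    core = picked[: design.shared_core]
    rest = picked[design.shared_core:]
    labels = design.site_labels
    rows = []
    offset = 0
    for site, k in zip(labels, design.exclusive_counts):
        exclusives = rest[offset: offset + k]
        offset += k
        for sp in core + exclusives:
            rows.append(
                {
                    "group": design.group,
                    "species": sp,
                    "site": site,
                    "records": int(rng.geometric(design.abundance_geom_p)),
                }
            )
    occ = OccurrenceTable(pd.DataFrame(rows, columns=["group", "species", "site", "records"]))
    return occ, design.expected_components()


#: Preset designs: per-site richness magnitudes (core + exclusives) follow
#: the spread of a real state-level vertebrate survey across six
#: ecoregions; all names are synthetic.
_HIDALGO_DESIGNS: dict[str, dict] = {
    "amphibians": dict(
        shared_core=6,
        site_exclusive=(23, 15, 12, 7, 3, 22),
        branching=(3, 4, 1, 3, 3),
        ragged_drop={"subfamily": 0.4},
    ),
    "reptiles": dict(
        shared_core=20,
        site_exclusive=(46, 33, 10, 27, 16, 38),
        branching=(2, 2, 2, 2, 2, 2, 1, 2, 2),
        ragged_drop={"subfamily": 0.3, "superfamily": 0.5, "infraorder": 0.5},
    ),
    "birds": dict(
        shared_core=150,
        site_exclusive=(117, 67, 39, 61, 63, 159),
        branching=(2, 1, 1, 2, 1, 2, 1, 1, 2, 2, 1, 2, 2, 2, 3),
        ragged_drop={"subfamily": 0.4, "subdivision": 0.3, "parvclass": 0.3},
    ),
    "mammals": dict(
        shared_core=15,
        site_exclusive=(54, 17, 7, 33, 30, 32),
        branching=(2, 2, 2, 2, 2, 1, 2, 2, 2),
        ragged_drop={"tribe": 0.5, "subfamily": 0.3},
    ),
}


def hidalgo_like(
    seed: int = 0,
) -> tuple[OccurrenceTable, dict[str, TaxonomyTable], dict[str, CommunityDesign]]:
    """Bundled preset: 4 faunal groups x 6 sites with ragged hierarchies.

    Returns the combined occurrence table, one taxonomy per group, and the
    designs (whose :meth:`CommunityDesign.expected_components` give the
    ground truth per group). Deterministic given ``seed``.
    """
    children = np.random.SeedSequence(seed).spawn(len(_HIDALGO_DESIGNS))
    frames, taxonomies, designs = [], {}, {}
    for (group, kw), child in zip(_HIDALGO_DESIGNS.items(), children):
        sub = child.spawn(2)
        design = CommunityDesign(
            group=group,
            n_sites=len(HIDALGO_SITES),
            sites=HIDALGO_SITES,
            ranks=HIDALGO_RANKS[group],
            seed=int(child.generate_state(1)[0] % (2**31)),
            **kw,
        )
        tax = generate_taxonomy(design, rng=np.random.default_rng(sub[0]))
        occ, _ = generate_occurrences(design, tax, rng=np.random.default_rng(sub[1]))
        frames.append(occ.data)
        taxonomies[group] = tax
        designs[group] = design
    combined = OccurrenceTable(pd.concat(frames, ignore_index=True))
    return combined, taxonomies, designs


def two_site_contrast(
    case: Literal["shared-higher", "unshared-higher"],
) -> tuple[frozenset[str], frozenset[str], TaxonomyTable]:
    """Two hand-built two-site communities with identical species-level
    dissimilarity but contrasting taxonomic structure.

    Both cases hold 15 species of which 4 are shared, 6 exclusive to site A
    and 5 to site B (species beta_cc = 11/15). In ``"shared-higher"`` the
    15 species sit in 8 genera and 3 families all present at both sites, so
    only the 11 unshared species differentiate the sites taxonomically
    (beta_ccT = 11/26 ~ 0.423). In ``"unshared-higher"`` they sit in 9
    genera and 2 families with a single genus and family shared
    (beta_ccT = 20/26 ~ 0.769). All names are synthetic.
    """
    sp = [f"sp{i:02d}" for i in range(1, 16)]
    shared = sp[0:4]                  # sp01..sp04
    only_a = [sp[4], sp[6], sp[8], sp[10], sp[11], sp[13]]   # 6 species
    only_b = [sp[5], sp[7], sp[9], sp[12], sp[14]]           # 5 species
    if case == "shared-higher":
        # every genus and family spans both sites
        assignment = {
            "sp01": ("famA", "gen1"), "sp05": ("famA", "gen1"), "sp06": ("famA", "gen1"),
            "sp07": ("famA", "gen2"), "sp08": ("famA", "gen2"),
            "sp02": ("famA", "gen3"),
            "sp09": ("famB", "gen4"), "sp10": ("famB", "gen4"),
            "sp03": ("famB", "gen5"), "sp11": ("famB", "gen5"),
            "sp12": ("famB", "gen6"), "sp13": ("famB", "gen6"),
            "sp04": ("famC", "gen7"),
            "sp14": ("famC", "gen8"), "sp15": ("famC", "gen8"),
        }
    elif case == "unshared-higher":
        # the four shared species share one genus; everything else is
        # confined to a single site's side of the classification
        assignment = {
            "sp01": ("famA", "gen1"), "sp02": ("famA", "gen1"),
            "sp03": ("famA", "gen1"), "sp04": ("famA", "gen1"),
            # site-A-only genera, family B
            "sp05": ("famB", "gen2"), "sp07": ("famB", "gen2"),
            "sp09": ("famB", "gen3"),
            "sp11": ("famB", "gen4"),
            "sp12": ("famB", "gen5"), "sp14": ("famB", "gen5"),
            # site-B-only genera live in the shared family A
            "sp06": ("famA", "gen6"), "sp08": ("famA", "gen6"),
            "sp10": ("famA", "gen7"),
            "sp13": ("famA", "gen8"),
            "sp15": ("famA", "gen9"),
        }
    else:
        raise ValueError(f"unknown case {case!r}")
    df = pd.DataFrame(
        [(assignment[s][0], assignment[s][1], s) for s in sp],
        columns=["family", "genus", "species"],
    )
    tax = TaxonomyTable(group="contrast", ranks=("family", "genus", "species"), assignments=df)
    return frozenset(shared + only_a), frozenset(shared + only_b), tax


def write_preset_csvs(outdir, seed: int = 0) -> dict[str, str]:
    """Emit the preset as the same CSV dialects the ingestion module reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    occ, taxonomies, _ = hidalgo_like(seed)
    paths = {}
    occ_path = outdir / "occurrences.csv"
    occ.data.to_csv(occ_path, index=False)
    paths["occurrences"] = str(occ_path)
    for group, tax in taxonomies.items():
        p = outdir / f"taxonomy_{group}.csv"
        tax.assignments.to_csv(p, index=False)
        paths[f"taxonomy_{group}"] = str(p)
    return paths
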