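"""Ordination and cross-level correlation of dissimilarity tables.

Non-metric multidimensional scaling (NMDS) embeds the sites in two
dimensions so that the rank order of configuration distances matches the
rank order of the input dissimilarities as closely as possible; fit
quality is Kruskal stress-1 (0 = perfect monotone fit). The solver is
iterative stress majorization (SMACOF) alternating with
pool-adjacent-violators isotonic regression, restarted from several random
configurations and keeping the best; deterministic for a fixed seed.

Pearson correlation between species-level and taxonomic dissimilarity
treats the unordered site pairs as independent observations — the same
convention as classic distance-matrix scatter plots. That ignores the
non-independence of pairs sharing a site, so a permutation (Mantel-style)
p-value that permutes site identities jointly is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import MDS

from .dissimilarity import square_matrix
from .errors import UndefinedValueWarning, ValidationError

__all__ = [
    "NMDSResult",
    "CorrelationResult",
    "nmds",
    "correlate_levels",
    "write_nmds_csv",
    "write_correlations_csv",
]


@dataclass(frozen=True)
class NMDSResult:
    """2-D NMDS configuration. Coordinates are defined only up to rotation,
    reflection and translation; stress and inter-point distances are the
    invariant quantities."""

    coordinates: pd.DataFrame  # site x (axis1, axis2)
    stress: float              # Kruskal stress-1
    converged: bool
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float   # Pearson coefficient
    p: float   # two-sided probability
    n: int     # number of site pairs used


def _as_square(d, metric_field: str) -> pd.DataFrame:
    if isinstance(d, pd.DataFrame) and {"site_i", "site_j"}.issubset(d.columns):
        return square_matrix(d, metric_field)
    mat = pd.DataFrame(d)
    if mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"dissimilarity matrix not square: {mat.shape}")
    return mat


def nmds(
    d,
    metric_field: str = "beta_cc",
    dims: int = 2,
    seed: int = 0,
    restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NMDSResult:
    """Best-of-``restarts`` non-metric MDS of a dissimilarity matrix.

    ``d`` is either a long pairwise table (``site_i``/``site_j`` plus the
    ``metric_field`` column) or a square symmetric matrix. Missing entries
    are an error: impute or drop the offending sites first. Needs at least
    3 sites for a 2-D configuration; an all-zero (identical sites) matrix
    is degenerate and refused.
    """
    mat = _as_square(d, metric_field)
    if mat.isna().to_numpy().any():
        raise ValidationError(
            "dissimilarity matrix has missing entries; impute or exclude "
            "the affected sites before ordination"
        )
    arr = mat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValidationError("dissimilarity matrix is not symmetric")
    if len(mat) < dims + 1:
        raise ValidationError(
            f"NMDS in {dims} dimensions needs >= {dims + 1} sites, got {len(mat)}"
        )
    off_diag = arr[~np.eye(len(arr), dtype=bool)]
    if np.all(off_diag == 0):
        raise ValidationError(
            "all dissimilarities are zero: configuration is degenerate"
        )
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(arr)
    return NMDSResult(
        coordinates=pd.DataFrame(
            coords, index=mat.index, columns=[f"axis{i + 1}" for i in range(dims)]
        ),
        stress=float(model.stress_),
        converged=bool(model.n_iter_ < max_iter),
        seed=seed,
    )


def _pair_vector(table: pd.DataFrame, field: str) -> pd.Series:
    keyed = table.set_index(
        table.apply(lambda r: frozenset((r["site_i"], r["site_j"])), axis=1)
    )
    return keyed[field]


def correlate_levels(
    species_table: pd.DataFrame,
    taxo_table: pd.DataFrame,
    field: str = "beta_cc",
    permutations: int = 0,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation between species-level and taxonomic dissimilarity
    over the same unordered site pairs.

    Pairs missing at either level are dropped pairwise (count logged as a
    warning). The default p-value is the two-sided t transform on n - 2
    degrees of freedom; ``permutations > 0`` replaces it with a
    Mantel-style p obtained by permuting site identities of the taxonomic
    matrix.
    """
    x = _pair_vector(species_table, field)
    y = _pair_vector(taxo_table, field)
    if set(x.index) != set(y.index):
        raise ValidationError("tables cover different site pairs")
    y = y.reindex(x.index)
    keep = ~(x.isna() | y.isna())
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"dropped {dropped} pair(s) with missing values",
            UndefinedValueWarning,
            stacklevel=2,
        )
    xv, yv = x[keep].to_numpy(float), y[keep].to_numpy(float)
    n = len(xv)
    if n < 3:
        raise ValidationError(f"need >= 3 pairs for a correlation, got {n}")
    if np.std(xv) == 0 or np.std(yv) == 0:
        warnings.warn(
            "zero variance in a dissimilarity vector: r undefined",
            UndefinedValueWarning,
            stacklevel=2,
        )
        return CorrelationResult(math.nan, math.nan, n)
    r, p = sps.pearsonr(xv, yv)
    if permutations > 0:
        p = _mantel_p(species_table, taxo_table, field, float(r), permutations, seed)
    return CorrelationResult(float(r), float(p), n)


def _mantel_p(
    species_table: pd.DataFrame,
    taxo_table: pd.DataFrame,
    field: str,
    r_obs: float,
    permutations: int,
    seed: int,
) -> float:
    """Permute site labels of the taxonomic matrix jointly and count
    permuted |r| >= observed |r| (add-one permutation p)."""
    X = square_matrix(species_table, field).to_numpy(float)
    Y = square_matrix(taxo_table, field)
    Y = Y.loc[square_matrix(species_table, field).index,
              square_matrix(species_table, field).columns].to_numpy(float)
    iu = np.triu_indices(len(X), k=1)
    xv = X[iu]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(Y))
        yv = Y[np.ix_(perm, perm)][iu]
        if np.std(yv) == 0:
            continue
        rp = np.corrcoef(xv, yv)[0, 1]
        if abs(rp) >= abs(r_obs) - 1e-15:
            hits += 1
    return (hits + 1) / (permutations + 1)


def write_nmds_csv(result: NMDSResult, path) -> None:
    """Coordinates plus a trailing stress line."""
    with open(path, "w", encoding="utf-8") as fh:
        df = result.coordinates.reset_index(names="site")
        df.to_csv(fh, index=False)
        fh.write(f"# stress,{result.stress!r},converged,{result.converged},seed,{result.seed}\n")


def write_correlations_csv(rows: list[dict], path) -> None:
    """Correlation writer: group, field, r, p, n."""
    pd.DataFrame(rows, columns=["group", "field", "r", "p", "n"]).to_csv(path, index=False)
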