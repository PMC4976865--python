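"""End-to-end orchestration: coverage -> pairwise -> multi-site -> NMDS ->
correlations, with a machine-readable run manifest.

Per group the run writes:

* ``coverage.csv`` — completeness per site (S, R, f1, f2, percent);
* ``pairwise.csv`` — species and taxonomic partitions for every site pair;
* ``multisite.csv`` — multiple-site summaries with contribution percentages;
* ``nmds_<field>.csv`` — 2-D ordination of the taxonomic dissimilarity for
  each partition component;
* ``correlations.csv`` — species-vs-taxonomic Pearson r for each component;
* ``manifest.json`` — config, seed, package version, warning log.

Numbers in machine-readable outputs keep full precision; rounding (2
decimals) happens only in the presentation-layer coverage percent column.
Any stage failure aborts the run with a stage-tagged error and marks the
manifest invalid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .community import OccurrenceTable, TaxonomyTable, build_incidence, read_occurrences, read_taxonomy
from .coverage import coverage_table
from .dissimilarity import (
    multi_site,
    pairwise_table,
    write_multisite_csv,
)
from .errors import PipelineError
from .stats import correlate_levels, nmds, write_correlations_csv, write_nmds_csv
from .synthetic import hidalgo_like

__all__ = ["RunConfig", "run_all"]

_FIELDS = ("beta_cc", "beta_3", "beta_rich")


@dataclass
class RunConfig:
    """Configuration for one full analysis run.

    Either ``occurrences`` + ``taxonomies`` point at input CSVs, or
    ``preset = "simulate"`` generates the bundled synthetic communities.
    """

    occurrences: str | None = None
    taxonomies: Mapping[str, str] = dc_field(default_factory=dict)
    preset: str | None = None
    groups: Sequence[str] | None = None
    variant: str = "component-sum"
    nmds_restarts: int = 50
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    seed: int = 0
    outdir: str = "taxbeta_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _load_inputs(cfg: RunConfig):
    if cfg.preset == "simulate":
        occ, taxonomies, _ = hidalgo_like(cfg.seed)
        return occ, taxonomies
    if not cfg.occurrences:
        raise PipelineError("config", "either an occurrence file or preset='simulate' is required")
    occ = read_occurrences(cfg.occurrences)
    taxonomies = {g: read_taxonomy(p, g) for g, p in cfg.taxonomies.items()}
    return occ, taxonomies


def run_all(cfg: RunConfig) -> dict:
    """Run every stage for every requested group; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**asdict(cfg), "taxonomies": dict(cfg.taxonomies)},
        "seed": cfg.seed,
        "version": __version__,
        "warnings": [],
        "valid": False,
        "outputs": {},
    }

    manifest_path = outdir / "manifest.json"

    def _dump() -> None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        return _run_stages(cfg, outdir, manifest, _dump)
    except Exception:
        # partial outputs already on disk are flagged invalid
        manifest["valid"] = False
        _dump()
        raise


def _run_stages(cfg: RunConfig, outdir: Path, manifest: dict, dump) -> dict:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        occ, taxonomies = _load_inputs(cfg)
        groups = list(cfg.groups) if cfg.groups else occ.groups
        for g in groups:
            if g not in taxonomies:
                raise PipelineError("taxonomic", f"no taxonomy configured for group {g!r}")

        cov = coverage_table(occ, groups=groups)
        cov_path = outdir / "coverage.csv"
        cov.to_csv(cov_path, index=False)
        manifest["outputs"]["coverage"] = cov_path.name

        pairwise_frames, multisite_rows, corr_rows = [], [], []
        for g in groups:
            try:
                inc = build_incidence(occ, g)
                sp_tab = pairwise_table(inc, level="species")
                tx_tab = pairwise_table(inc, level="taxonomic", tax=taxonomies[g])
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage tagging
                raise PipelineError("pairwise", f"group {g!r}: {exc}") from exc
            pairwise_frames += [sp_tab, tx_tab]
            try:
                for level, tax in (("species", None), ("taxonomic", taxonomies[g])):
                    msb = multi_site(inc, level=level, tax=tax, variant=cfg.variant)
                    multisite_rows.append((g, level, msb))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("multi-site", f"group {g!r}: {exc}") from exc
            try:
                for fld in _FIELDS:
                    res = nmds(
                        tx_tab,
                        metric_field=fld,
                        seed=cfg.seed,
                        restarts=cfg.nmds_restarts,
                        max_iter=cfg.nmds_max_iter,
                        tol=cfg.nmds_tol,
                    )
                    write_nmds_csv(res, outdir / f"nmds_{g}_{fld}.csv")
                    manifest["outputs"][f"nmds_{g}_{fld}"] = f"nmds_{g}_{fld}.csv"
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("nmds", f"group {g!r}: {exc}") from exc
            try:
                for fld in _FIELDS:
                    cr = correlate_levels(sp_tab, tx_tab, field=fld)
                    corr_rows.append(
                        {"group": g, "field": fld, "r": cr.r, "p": cr.p, "n": cr.n}
                    )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("correlation", f"group {g!r}: {exc}") from exc

        pw = pd.concat(pairwise_frames, ignore_index=True)
        pw_path = outdir / "pairwise.csv"
        pw.to_csv(pw_path, index=False)
        manifest["outputs"]["pairwise"] = pw_path.name

        ms_path = outdir / "multisite.csv"
        write_multisite_csv(multisite_rows, ms_path)
        manifest["outputs"]["multisite"] = ms_path.name

        corr_path = outdir / "correlations.csv"
        write_correlations_csv(corr_rows, corr_path)
        manifest["outputs"]["correlations"] = corr_path.name

        manifest["warnings"] = sorted(
            {f"{w.category.__name__}: {w.message}" for w in caught}
        )
        manifest["warning_count"] = len(caught)

    manifest["valid"] = True
    dump()
    return manifest
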