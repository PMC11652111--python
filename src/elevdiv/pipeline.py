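"""End-to-end orchestration of one mountain's analysis, and cross-mountain
comparisons.

One mountain = one run = one output directory. A run consumes either real
input files (occurrence CSV, Newick tree, area table, synonym/alien lists)
or a synthetic scenario, and serializes every analysis surface as CSV/JSON:

    inputs/                    synthetic input files (synthetic runs only)
    cleaning_report.json
    belt_matrix.csv            wide belt x taxon 0/1 matrix
    belt_matrix_long.tsv
    alpha_diversity.csv        SR / PD / PE per belt
    beta_adjacent.csv          Jaccard + Cody between adjacent belts
    nri_profile.csv
    trends.csv                 richness~area, NRI~elevation, NRI~richness
    native_nonnative.json
    summary.csv
    manifest.json              config hash, seed, versions, decision flags

Runs are deterministic given config + seed (no timestamps are written), so
re-running a config must reproduce every output byte for byte.
Cross-mountain analyses consume completed runs; they never recompute a
mountain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .belts import BeltMatrix, assign_belts, attach_areas, build_grid
from .beta import adjacent_belt_profile, profile_to_frame
from .ingest import (
    clean_occurrences,
    read_alien_list,
    read_occurrences,
    read_synonym_table,
    read_taxonomy,
)
from .nri import NullModelConfig, nri_profile
from .phylodiv import faith_pd, load_tree, match_tree_matrix, phylogenetic_endemism
from .summaries import MountainSummary, cross_mountain_stats, summarize_mountain, summary_table
from .synthetic import ScenarioConfig, simulate_mountain, write_mountain
from .trends import (
    TrendFit,
    fit_gaussian,
    native_nonnative_correlation,
    nri_trend,
    peak_determinants,
    peak_elevation,
    richness_area_fit,
    trend_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "MountainRun", "run_mountain", "run_cross_mountain"]


@dataclass
class RunConfig:
    """Everything one mountain run depends on, incl. every decision flag."""

    mountain_id: str
    out_dir: str
    seed: int
    # file inputs (ignored when `synthetic` is set)
    occurrences_path: str | None = None
    tree_path: str | None = None
    areas_path: str | None = None
    synonyms_path: str | None = None
    taxonomy_path: str | None = None
    alien_list_path: str | None = None
    column_map: dict | None = None
    # synthetic input
    synthetic: ScenarioConfig | None = None
    # grid / decision flags (each mirrors a documented default)
    min_elev: float | None = None
    max_elev: float | None = None
    belt_width: float = 100.0
    anchor: float | None = None  # grid anchored at min_elev unless overridden
    occupancy_mode: str = "record"
    jaccard_convention: str = "unique_counts"
    cody_convention: str = "half"
    null_scheme: str = "pool_draw"
    n_reps: int = 1000
    include_root: bool = True
    drop_unresolved: bool = False
    keep_out_of_span: bool = False
    duplicate_rounding_m: float = 1.0
    peak_family: str = "quasipoisson"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw.get("synthetic"):
            raw["synthetic"] = ScenarioConfig(**raw["synthetic"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory in pipeline runs")
        if self.synthetic is None:
            for name in ("occurrences_path", "tree_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config missing {name} (and no synthetic scenario)")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            for name in ("areas_path", "synonyms_path", "taxonomy_path", "alien_list_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            if self.min_elev is None or self.max_elev is None:
                raise ValueError("min_elev/max_elev required for file-based runs")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class MountainRun:
    config: RunConfig
    matrix: BeltMatrix
    alpha: pd.DataFrame
    beta: pd.DataFrame
    nri: pd.DataFrame
    fits: list[TrendFit]
    native_nonnative: dict | None
    summary: MountainSummary
    peak_m: float
    out_dir: Path


STAGES = ("simulate", "clean", "belts", "alpha", "beta", "nri", "trends", "summary")


def run_mountain(config: RunConfig, stages: tuple[str, ...] = STAGES) -> MountainRun:
    """Run the per-mountain analysis and serialize every surface.

    ``stages`` truncates the pipeline after the last named stage (earlier
    stages always run, since each feeds the next); the full tuple is the
    default end-to-end run.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    last = max(STAGES.index(s) for s in stages)

    # --- inputs (synthetic runs emit their inputs, then re-read them) ---
    if config.synthetic is not None:
        scen = config.synthetic
        if scen.mountain_id != config.mountain_id:
            scen = dataclasses.replace(scen, mountain_id=config.mountain_id)
        sim = simulate_mountain(scen)
        paths = write_mountain(sim, out / "inputs")
        config = dataclasses.replace(
            config,
            occurrences_path=str(paths["occurrences"]),
            tree_path=str(paths["tree"]),
            areas_path=str(paths["areas"]),
            alien_list_path=str(paths["aliens"]),
            min_elev=scen.min_elev,
            max_elev=scen.max_elev,
        )
    if last < STAGES.index("clean"):
        return _finish(config, out, None, None, None, None, [], None, None, float("nan"))

    spans = {config.mountain_id: (config.min_elev, config.max_elev)}
    records = read_occurrences(config.occurrences_path, config.column_map, spans=spans)
    synonyms = read_synonym_table(config.synonyms_path) if config.synonyms_path else None
    taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    aliens = read_alien_list(config.alien_list_path) if config.alien_list_path else set()
    cleaned, report = clean_occurrences(
        records,
        synonyms,
        taxonomy,
        drop_unresolved=config.drop_unresolved,
        keep_out_of_span=config.keep_out_of_span,
    )
    (out / "cleaning_report.json").write_text(report.to_json())
    if last < STAGES.index("belts"):
        return _finish(config, out, None, None, None, None, [], None, None, float("nan"))

    # --- belts ---
    anchor = config.anchor if config.anchor is not None else config.min_elev
    grid = build_grid(config.mountain_id, anchor, config.max_elev, config.belt_width)
    matrix = assign_belts(cleaned, grid, mode=config.occupancy_mode,
                          keep_out_of_span=config.keep_out_of_span)
    if config.areas_path:
        areas = pd.read_csv(config.areas_path, comment="#")
        matrix = attach_areas(matrix, areas)
    matrix.to_wide_csv(out / "belt_matrix.csv")
    matrix.to_long_tsv(out / "belt_matrix_long.tsv")
    if last < STAGES.index("alpha"):
        return _finish(config, out, matrix, None, None, None, [], None, None, float("nan"))

    # --- alpha diversity: SR, PD, PE per belt ---
    tree = load_tree(config.tree_path)
    tree, matrix, match_report = match_tree_matrix(tree, matrix)
    pd_vals = []
    for i in range(grid.n_belts):
        taxa = matrix.belt_taxa(i)
        pd_vals.append(faith_pd(tree, taxa, include_root=config.include_root) if taxa else 0.0)
    pe = phylogenetic_endemism(tree, matrix)
    alpha = pd.DataFrame(
        {
            "mountain_id": config.mountain_id,
            "belt_lo": [lo for lo, _ in grid.belts],
            "belt_hi": [hi for _, hi in grid.belts],
            "midpoint": grid.midpoints,
            "SR": matrix.richness.to_numpy(),
            "PD": pd_vals,
            "PE": pe.to_numpy(),
        }
    )
    alpha.to_csv(out / "alpha_diversity.csv", index=False)
    peak = peak_elevation(pd.Series(alpha["SR"].to_numpy(), index=alpha["midpoint"]))
    if last < STAGES.index("beta"):
        return _finish(config, out, matrix, alpha, None, None, [], None, None, peak)

    # --- beta diversity between adjacent belts ---
    beta_df = profile_to_frame(
        adjacent_belt_profile(matrix, config.jaccard_convention, config.cody_convention)
    )
    beta_df.insert(0, "mountain_id", config.mountain_id)
    beta_df.to_csv(out / "beta_adjacent.csv", index=False)
    if last < STAGES.index("nri"):
        return _finish(config, out, matrix, alpha, beta_df, None, [], None, None, peak)

    # --- NRI profile ---
    null_cfg = NullModelConfig(n_reps=config.n_reps, scheme=config.null_scheme, seed=config.seed)
    nri_df = nri_profile(tree, matrix, null_cfg)
    nri_df.insert(0, "mountain_id", config.mountain_id)
    nri_df.to_csv(out / "nri_profile.csv", index=False)
    if last < STAGES.index("trends"):
        return _finish(config, out, matrix, alpha, beta_df, nri_df, [], None, None, peak)

    # --- trend fits ---
    fits: list[TrendFit] = []
    if matrix.belt_area_km2 is not None:
        fits.append(richness_area_fit(matrix))
    nn = None
    if aliens:
        nn = native_nonnative_correlation(matrix, aliens)
        (out / "native_nonnative.json").write_text(json.dumps(nn, indent=2, sort_keys=True))
    evaluable = nri_df[nri_df["evaluable"] & nri_df["nri"].notna()]
    if len(evaluable) >= 3:
        fits.append(nri_trend(nri_df))
        fits.append(
            fit_gaussian(
                evaluable["n_taxa"].to_numpy(dtype=float),
                evaluable["nri"].to_numpy(),
                response="NRI",
                predictor="SR",
            )
        )
    trend_table(fits, config.mountain_id).to_csv(out / "trends.csv", index=False)
    if last < STAGES.index("summary"):
        return _finish(config, out, matrix, alpha, beta_df, nri_df, fits, nn, None, peak)

    # --- taxonomic summary ---
    summary = summarize_mountain(cleaned, taxonomy, mountain_id=config.mountain_id)
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(out / "summary.csv", index=False)
    return _finish(config, out, matrix, alpha, beta_df, nri_df, fits, nn, summary, peak)


def _finish(config, out, matrix, alpha, beta_df, nri_df, fits, nn, summary, peak) -> MountainRun:
    _write_manifest(config, out)
    return MountainRun(config, matrix, alpha, beta_df, nri_df, fits, nn, summary, peak, out)


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "package": "elevdiv",
        "version": __version__,
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "decisions": {
            "synonym_resolution": "local table (no online name services)",
            "duplicate_definition": (
                f"identical (accepted_name, mountain, elevation rounded to "
                f"{config.duplicate_rounding_m:g} m)"
            ),
            "out_of_span": "kept" if config.keep_out_of_span else "flagged and excluded",
            "unresolved_names": "dropped" if config.drop_unresolved else "kept verbatim",
            "occupancy_mode": config.occupancy_mode,
            "belt_boundaries": "half-open [lo, hi); summit belt closed",
            "belt_label": "interval midpoint",
            "grid_anchor": config.anchor if config.anchor is not None else config.min_elev,
            "belt_width_m": config.belt_width,
            "pd_root": "included" if config.include_root else "excluded",
            "pe_range_unit": "occupied belts within the mountain",
            "zero_length_branches": "permitted, contribute 0",
            "jaccard_convention": config.jaccard_convention,
            "cody_convention": config.cody_convention,
            "empty_belts_in_beta": "skipped",
            "null_scheme": config.null_scheme,
            "null_pool": "all species recorded on the mountain",
            "null_sd": "sample (n-1)",
            "n_reps": config.n_reps,
            "glm_r2": "deviance pseudo-R2 (fitted-vs-observed r2 also emitted)",
            "nri_trend_family": "gaussian OLS",
            "peak_definition": "midpoint of the belt with maximal SR; ties -> lowest",
            "peak_family": config.peak_family,
            "multiple_testing": "none across peak predictors",
            "mean_rounding": "half-up to integer",
            "synthetic_tree": "pure-birth (Yule)",
            "synthetic_range_widths": "lognormal",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_cross_mountain(
    runs: list[MountainRun],
    attributes: pd.DataFrame,
    out_dir: str | Path | None = None,
    peak_family: str | None = None,
) -> dict:
    """Cross-mountain statistics, peak table and peak-determinant fits.

    Consumes >= 4 completed runs plus an attribute table (mountain_id,
    relative_elevation_m, longitude_deg, amt_c, ap_mm). Returns a dict with
    the summary table, per-mountain peaks and determinant fits; writes
    summary_table.csv / peaks.csv / peak_determinants.csv when ``out_dir``
    is given.
    """
    if len(runs) < 4:
        raise ValueError(f"cross-mountain analysis requires >= 4 runs, got {len(runs)}")
    summaries = [r.summary for r in runs if r.summary is not None]
    table = summary_table(summaries)
    stats = cross_mountain_stats(summaries)
    peaks = {r.config.mountain_id: r.peak_m for r in runs}
    family = peak_family or runs[0].config.peak_family
    fits = peak_determinants(peaks, attributes, family=family)
    peaks_df = pd.DataFrame(
        {"mountain_id": list(peaks), "peak_elevation_m": list(peaks.values())}
    )
    fits_df = trend_table(fits)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary_table.csv", index=False)
        peaks_df.to_csv(out / "peaks.csv", index=False)
        fits_df.to_csv(out / "peak_determinants.csv", index=False)
        (out / "cross_mountain_stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True)
        )
    return {"summary_table": table, "stats": stats, "peaks": peaks_df, "determinants": fits_df}
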