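"""Readers, writers, run configuration and the reproducibility manifest.

All artifacts are plain delimited text (CSV): marker matrices (rows =
lines, first columns line_id and family, then one column per marker),
plot-level phenotypes, square GRMs with an id header row and column, BLUE
tables, calibration splits and cross-validation results.  The run manifest
is JSON and records the configuration, input checksums, software version,
per-stage seeds and timings — enough to re-execute a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics import GenomicsError, Grm, MarkerMatrix
from .simulate import SimulationConfig

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_phenotypes",
    "write_phenotypes",
    "read_markers",
    "write_markers",
    "read_grm",
    "write_grm",
    "read_simulation_config",
    "stage_seeds",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["line_id", "family", "year", "location", "management",
                     "environment", "tester", "trial", "rep", "block",
                     "yield"]

_STAGES = ("simulate", "grm", "optimize", "crossval")


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds derived from one global seed.

    Stage k gets ``SeedSequence(seed).generate_state(len(stages))[k]``
    reduced below 2**31, so any stage can be rerun independently.
    """
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, state)}


# ---------------------------------------------------------------------------
# phenotypes


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} is missing columns: "
                         f"{missing}")
    bad_mgmt = sorted(set(df["management"]) - {"WW", "WS"})
    if bad_mgmt:
        raise ValueError(f"management must be WW or WS; found {bad_mgmt}")
    df["year"] = df["year"].astype(int)
    y = pd.to_numeric(df["yield"], errors="coerce")
    n_bad = int(y.isna().sum())
    if n_bad:
        rows = df.index[y.isna()][:5].tolist()
        logger.warning("dropping %d records with missing/non-numeric yield "
                       "(first rows: %s)", n_bad, rows)
    df = df[y.notna()].copy()
    df["yield"] = y[y.notna()]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# markers


def write_markers(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(path, index=False)


def read_markers(path) -> MarkerMatrix:
    df = pd.read_csv(path)
    for col in ("line_id", "family"):
        if col not in df.columns:
            raise ValueError(f"marker file {path} is missing column {col!r}")
    marker_ids = [c for c in df.columns if c not in ("line_id", "family")]
    values = df[marker_ids].to_numpy(float)
    # load-time imputation: missing calls to the column mean, rounded to 0/2
    if np.isnan(values).any():
        n_missing = int(np.isnan(values).sum())
        col_mean = np.nanmean(values, axis=0)
        fill = np.where(col_mean >= 1.0, 2.0, 0.0)
        idx = np.where(np.isnan(values))
        values[idx] = fill[idx[1]]
        logger.info("imputed %d missing marker calls to the rounded column "
                    "mean", n_missing)
    bad = ~np.isin(values, (0.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenomicsError(
            f"marker values must be 0 or 2; found {values[i, j]!r} at line "
            f"{df['line_id'].iloc[i]!r}, marker {marker_ids[j]!r}")
    return MarkerMatrix(
        line_ids=df["line_id"].tolist(),
        family_of=dict(zip(df["line_id"], df["family"])),
        values=values.astype(np.int8),
        marker_ids=marker_ids,
    )


# ---------------------------------------------------------------------------
# GRM


def write_grm(grm: Grm, path) -> None:
    pd.DataFrame(grm.values, index=grm.line_ids,
                 columns=grm.line_ids).to_csv(path)


def read_grm(path) -> Grm:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise GenomicsError(f"GRM {path}: row ids do not match column ids")
    return Grm(list(df.index), df.to_numpy(float))


# ---------------------------------------------------------------------------
# simulation config files (flat YAML)


def read_simulation_config(path, seed: int | None = None) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "envs_per_year" in raw:
        raw["envs_per_year"] = tuple(tuple(e) for e in raw["envs_per_year"])
    for key in ("true_Go", "residual_variances"):
        if key in raw and raw[key] is not None:
            raw[key] = np.asarray(raw[key], float)
    if seed is not None:
        raw["seed"] = seed
    return SimulationConfig(**raw)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Settings of a full pipeline run (validated before any computation)."""

    out_dir: str
    phenotypes: str | None = None
    markers: str | None = None
    historical_phenotypes: str | None = None
    simulate: bool = False
    simulation_config: str | None = None
    scheme: str = "cv2"
    grouping: str = "LM"
    structure: str = "FA"
    m: int | None = None
    augmentation: str = "none"
    n_repeats: int = 10
    lam: float = 0.5
    maf: float = 0.05
    n_select: int = 300
    tol: float = 1e-6
    max_iter: int = 200
    floor_frac: float = 1e-8
    epsilon: float = 1e-6
    min_family_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        from .model import GROUPING_SCHEMES
        if self.scheme.lower() not in ("cv1", "cv2"):
            raise ValueError(f"invalid scheme {self.scheme!r}")
        if self.grouping not in GROUPING_SCHEMES:
            raise ValueError(f"invalid grouping {self.grouping!r}")
        if self.structure not in ("US", "FA", "DIAG"):
            raise ValueError(f"invalid structure {self.structure!r}")
        if self.augmentation not in ("none", "all", "optimized"):
            raise ValueError(f"invalid augmentation {self.augmentation!r}")
        if not self.simulate and not (self.phenotypes and self.markers):
            raise ValueError("either simulate=True or provide phenotype "
                             "and marker files")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run, written at the end."""

    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path) -> None:
        payload = asdict(self)
        tmp = Path(path).with_suffix(".tmp")
        tmp.write_text(json.dumps(payload, indent=2, default=str))
        tmp.replace(path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """simulate (optional) -> GRM -> CDmean splits -> cross-validation.

    Writes every stage artifact under ``config.out_dir`` and a JSON manifest
    recording config, checksums, seeds, timings and convergence.  A stage
    failure is recorded in the manifest (partial completion) and re-raised.
    """
    from .evaluation import cdmean_splits, compute_blues, run_crossval
    from .genomics import compute_grm, filter_markers
    from .simulate import simulate_dataset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config=asdict(config), seeds=seeds)
    manifest_path = out / "manifest.json"
    stage = "setup"
    try:
        historical = None
        stage = "simulate"
        t0 = time.time()
        if config.simulate:
            if config.simulation_config:
                sim_cfg = read_simulation_config(config.simulation_config,
                                                 seed=seeds["simulate"])
            else:
                sim_cfg = SimulationConfig(seed=seeds["simulate"])
            dataset = simulate_dataset(sim_cfg)
            markers = dataset.marker_matrix
            phenotypes = dataset.phenotypes
            write_markers(markers, out / "markers.csv")
            write_phenotypes(phenotypes, out / "phenotypes.csv")
            dataset.true_genetic_values.to_csv(out / "true_values.csv")
        else:
            markers = read_markers(config.markers)
            phenotypes = read_phenotypes(config.phenotypes)
            manifest.input_checksums = {
                "markers": _sha256(config.markers),
                "phenotypes": _sha256(config.phenotypes),
            }
            if config.historical_phenotypes:
                historical = read_phenotypes(config.historical_phenotypes)
                manifest.input_checksums["historical_phenotypes"] = \
                    _sha256(config.historical_phenotypes)
        manifest.stage_seconds["simulate"] = round(time.time() - t0, 3)
        manifest.completed_stages.append("simulate")

        stage = "grm"
        t0 = time.time()
        kept = filter_markers(markers, config.maf)
        grm = compute_grm(kept)
        write_grm(grm, out / "grm.csv")
        manifest.stage_seconds["grm"] = round(time.time() - t0, 3)
        manifest.completed_stages.append("grm")

        stage = "optimize"
        t0 = time.time()
        from .evaluation import _classify_envs
        ww_envs, _ = _classify_envs(phenotypes)
        family_lines = {f: sorted(d["line_id"].unique())
                        for f, d in phenotypes.groupby("family")}
        splits = cdmean_splits(grm, family_lines, ww_envs, lam=config.lam)
        split_rows = []
        for fam, split in splits.items():
            for line, env in sorted(split.observed_ww.items()):
                split_rows.append({
                    "line_id": line, "family": fam, "ww_observed": env,
                    "ws_observed": line in split.ws_observed})
        pd.DataFrame(split_rows).to_csv(out / "cv2_splits.csv", index=False)
        manifest.stage_seconds["optimize"] = round(time.time() - t0, 3)
        manifest.completed_stages.append("optimize")

        stage = "crossval"
        t0 = time.time()
        blues = compute_blues(phenotypes)
        blues.to_csv(out / "blues.csv", index=False)
        result = run_crossval(
            phenotypes, grm, scheme=config.scheme, grouping=config.grouping,
            structure=config.structure, m=config.m,
            augmentation=config.augmentation, historical=historical,
            n_repeats=config.n_repeats, seed=seeds["crossval"],
            lam=config.lam, n_select=config.n_select,
            min_family_size=config.min_family_size, blues=blues,
            fit_options={"tol": config.tol, "max_iter": config.max_iter,
                         "floor_frac": config.floor_frac})
        result.records.to_csv(out / "accuracy.csv", index=False)
        result.mean_by_environment().to_csv(
            out / "accuracy_by_environment.csv", index=False)
        manifest.convergence["crossval"] = bool(
            result.records["converged"].all()) if len(result.records) else None
        manifest.stage_seconds["crossval"] = round(time.time() - t0, 3)
        manifest.completed_stages.append("crossval")
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
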