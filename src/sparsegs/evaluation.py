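"""Sparse-testing evaluation: BLUEs, masking schemes and prediction accuracy.

The study design evaluated here phenotypes every line somewhere but nowhere
completely and asks how well multi-environment GBLUP fills the grid:

* **CV1** masks whole bi-parental families: in each repeat a random half of
  the families is observed in the first well-watered (WW) environment and
  masked in the second, and vice versa; in the water-stress (WS) environment
  half of each WW-observed group of families is masked.  With twelve
  families this is the classic six-and-six WW split with three families
  from each group masked in WS.
* **CV2** splits every family across the WW environments by CDmean rank
  (the optimization module's CalibrationSplit); the plan is deterministic
  given the scores.

Validation targets are per-environment BLUEs of the testcross means
computed from the complete data (genotype fixed, trial/replicate/block
random); prediction accuracy is the Pearson correlation between masked
lines' GEBVs and their BLUEs, per family and environment, averaged over
families.  Because every nuisance factor and the residual are nested within
environment, the per-environment BLUE fits coincide with a combined
full-data analysis, so both schemes validate against the same table.

Masked phenotypes are removed from the training records before any model
fitting; they enter nothing but the validation correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomics import Grm, regularize_grm
from .model import MultiEnvGBLUP, EnvironmentGrouping
from .optimization import (avg_grm_select, cdmean_per_individual,
                           split_family_cv2)
from .reml import IIDTerm, MixedREML

__all__ = [
    "MaskPlan",
    "CvResult",
    "compute_blues",
    "make_cv1_masks",
    "make_cv2_masks",
    "cdmean_splits",
    "augment_with_historical",
    "run_crossval",
]

logger = logging.getLogger(__name__)


@dataclass
class MaskPlan:
    """Which (line, environment) cells are masked in one repeat."""

    scheme: str
    repeat: int
    masked: set  # of (line_id, environment)
    seed: int | None = None

    def is_masked(self, line_id: str, environment: str) -> bool:
        return (line_id, environment) in self.masked

    def training_records(self, phenotypes: pd.DataFrame) -> pd.DataFrame:
        """Complete records minus every masked line x environment cell."""
        key = list(zip(phenotypes["line_id"], phenotypes["environment"]))
        keep = [k not in self.masked for k in key]
        return phenotypes[keep].reset_index(drop=True)


@dataclass
class CvResult:
    """Tidy per-(repeat, family, environment) accuracies plus settings."""

    records: pd.DataFrame
    scheme: str
    grouping: str
    structure: str
    augmentation: str
    seed: int | None = None
    n_skipped_cells: int = 0

    def mean_by_environment(self) -> pd.DataFrame:
        """Mean accuracy across families, per environment and repeat,
        then averaged over repeats."""
        per_rep = (self.records.groupby(["environment", "repeat"])
                   ["accuracy"].mean().reset_index())
        return per_rep.groupby("environment")["accuracy"].mean().reset_index()

    def mean_accuracy(self) -> float:
        return float(self.mean_by_environment()["accuracy"].mean())


# ---------------------------------------------------------------------------
# stage-one BLUEs


def _nested_iid_terms(df: pd.DataFrame, names=("trial", "rep", "block")):
    keys = {
        "trial": df["trial"].astype(str),
        "rep": df["trial"].astype(str) + "|r" + df["rep"].astype(str),
        "block": (df["trial"].astype(str) + "|r" + df["rep"].astype(str)
                  + "|b" + df["block"].astype(str)),
    }
    terms = []
    for name in names:
        k = keys[name]
        cats = sorted(k.unique())
        if len(cats) < 2:
            logger.info("BLUE model: term %r has one level; dropped", name)
            continue
        pos = {c: i for i, c in enumerate(cats)}
        Z = sp.csr_matrix((np.ones(len(df)),
                           (np.arange(len(df)), k.map(pos).to_numpy())),
                          shape=(len(df), len(cats)))
        terms.append(IIDTerm(name, Z, cats))
    return terms


def compute_blues(phenotypes: pd.DataFrame, response: str = "yield",
                  tol: float = 1e-5, max_iter: int = 100) -> pd.DataFrame:
    """Per-environment BLUEs of the line testcross means from complete data.

    For each environment a cell-means model is fitted by REML with genotype
    fixed and trial, replicate and incomplete block random; the genotype
    solutions are the BLUEs.  Lines without plots in an environment get no
    BLUE there.  Returns a tidy frame (line_id, environment, blue).
    """
    out = []
    for env, df in phenotypes.groupby("environment"):
        df = df.reset_index(drop=True)
        lines = sorted(df["line_id"].unique())
        pos = {l: i for i, l in enumerate(lines)}
        X = sp.csr_matrix(
            (np.ones(len(df)),
             (np.arange(len(df)), df["line_id"].map(pos).to_numpy())),
            shape=(len(df), len(lines)))
        terms = _nested_iid_terms(df)
        engine = MixedREML(df[response].to_numpy(float), X, terms)
        state, status = engine.fit(tol=tol, max_iter=max_iter)
        if not status.converged:
            logger.warning("BLUE REML for %s stopped: %s", env,
                           status.message)
        alpha = state["sol"][:len(lines)]
        out.append(pd.DataFrame({"line_id": lines, "environment": env,
                                 "blue": alpha}))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# masking schemes


def _classify_envs(phenotypes: pd.DataFrame):
    env_mgmt = (phenotypes[["environment", "management"]]
                .drop_duplicates().set_index("environment")["management"])
    ww = sorted(env_mgmt[env_mgmt == "WW"].index)
    ws = sorted(env_mgmt[env_mgmt == "WS"].index)
    if len(ww) != 2:
        raise ValueError(f"sparse-testing schemes need exactly 2 WW "
                         f"environments; found {ww}")
    if not ws:
        raise ValueError("no WS environment found")
    return ww, ws


def make_cv1_masks(family_lines: dict, ww_envs, ws_envs, n_repeats: int = 10,
                   seed: int = 0) -> list:
    """CV1 plans: random family-level sparse testing, repeated.

    Each repeat: half of the families (extra one to the first group on odd
    counts) is observed in the first WW environment and masked in the
    second, the other half the reverse; within WS, floor(k/2) random
    families from each WW-observed group of size k are masked.
    """
    families = sorted(family_lines)
    if len(families) < 2:
        raise ValueError("CV1 needs at least 2 families")
    ww_envs = list(ww_envs)
    plans = []
    root = np.random.SeedSequence(seed)
    for rep, ss in enumerate(root.spawn(n_repeats)):
        rng = np.random.default_rng(ss)
        order = [families[i] for i in rng.permutation(len(families))]
        n_a = (len(order) + 1) // 2
        group_a, group_b = order[:n_a], order[n_a:]
        if len(order) % 2:
            logger.info("odd family count %d: extra family observed in %s",
                        len(order), ww_envs[0])
        masked = set()
        for fams, obs_env, mask_env in ((group_a, ww_envs[0], ww_envs[1]),
                                        (group_b, ww_envs[1], ww_envs[0])):
            for fam in fams:
                masked.update((l, mask_env) for l in family_lines[fam])
            k = len(fams) // 2
            picks = [fams[i] for i in rng.permutation(len(fams))[:k]]
            for fam in picks:
                for ws in ws_envs:
                    masked.update((l, ws) for l in family_lines[fam])
        plans.append(MaskPlan("CV1", rep, masked, seed))
    return plans


def cdmean_splits(grm: Grm, family_lines: dict, ww_envs, lam: float = 0.5,
                  epsilon: float = 1e-4) -> dict:
    """CDmean scores and CV2 splits for every family."""
    splits = {}
    for fam in sorted(family_lines):
        sub = regularize_grm(grm.submatrix(family_lines[fam]), epsilon)
        scores = cdmean_per_individual(sub, family=fam, lam=lam)
        splits[fam] = split_family_cv2(scores, ww_envs)
    return splits


def make_cv2_masks(splits: dict, ww_envs, ws_envs,
                   family_lines: dict | None = None) -> MaskPlan:
    """Single deterministic CV2 plan from per-family CalibrationSplits."""
    ww_envs = list(ww_envs)
    if family_lines is not None:
        missing = sorted(set(family_lines) - set(splits))
        if missing:
            raise ValueError(f"families without a CV2 split: {missing[:5]}")
    masked = set()
    for fam, split in splits.items():
        for line, obs_env in split.observed_ww.items():
            other = ww_envs[1] if obs_env == ww_envs[0] else ww_envs[0]
            masked.add((line, other))
            if line not in split.ws_observed:
                for ws in ws_envs:
                    masked.add((line, ws))
    return MaskPlan("CV2", 0, masked)


# ---------------------------------------------------------------------------
# historical augmentation


def augment_with_historical(current: pd.DataFrame,
                            historical: pd.DataFrame | None,
                            mode: str = "none", grm: Grm | None = None,
                            n_select: int = 300,
                            grouping: str | EnvironmentGrouping | None = None
                            ) -> pd.DataFrame:
    """Extend the training records with historical phenotypes.

    ``mode='all'`` appends every historical record; ``mode='optimized'``
    appends, for each current family, the Avg_GRM-selected ``n_select``
    historical lines' records (union over families).  Multi-year data
    require a multi-year grouping scheme.
    """
    if mode not in ("none", "all", "optimized"):
        raise ValueError("mode must be 'none', 'all' or 'optimized'")
    if mode == "none" or historical is None or historical.empty:
        return current.reset_index(drop=True)
    overlap = set(current["line_id"]) & set(historical["line_id"])
    if overlap:
        raise ValueError(f"current and historical line ids overlap: "
                         f"{sorted(overlap)[:5]}")
    if grouping is not None:
        g = grouping if isinstance(grouping, EnvironmentGrouping) \
            else EnvironmentGrouping(grouping)
        if not g.multi_year:
            raise ValueError(
                f"grouping {g.scheme!r} is single-year; historical "
                "augmentation needs one of LMY, MY, M_plus")
    if mode == "all":
        return pd.concat([current, historical], ignore_index=True)
    if grm is None:
        raise ValueError("mode='optimized' needs the joint GRM")
    pool = sorted(historical["line_id"].unique())
    chosen: set = set()
    for fam, fam_df in current.groupby("family"):
        members = sorted(fam_df["line_id"].unique())
        sel = avg_grm_select(grm.cross(pool, members), pool, family=fam,
                             n_select=n_select)
        chosen.update(sel.selected)
    picked = historical[historical["line_id"].isin(chosen)]
    return pd.concat([current, picked], ignore_index=True)


# ---------------------------------------------------------------------------
# the cross-validation loop


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def run_crossval(phenotypes: pd.DataFrame, grm: Grm, scheme: str = "cv2",
                 grouping: str = "LM", structure: str = "FA",
                 m: int | None = None, augmentation: str = "none",
                 historical: pd.DataFrame | None = None,
                 n_repeats: int = 10, seed: int = 0, lam: float = 0.5,
                 n_select: int = 300, min_family_size: int | None = None,
                 min_masked_lines: int = 3, blues: pd.DataFrame | None = None,
                 fit_options: dict | None = None) -> CvResult:
    """Run one sparse-testing evaluation end to end.

    Masks per the scheme, fits the multi-environment GBLUP on the observed
    records (optionally augmented with historical data), predicts GEBVs and
    correlates the masked lines' GEBVs with their full-data BLUEs per family
    and environment.  Cells with fewer than ``min_masked_lines`` masked
    lines are skipped.  Fully reproducible from (data, settings, seed).
    """
    scheme = scheme.lower()
    if scheme not in ("cv1", "cv2"):
        raise ValueError("scheme must be 'cv1' or 'cv2'")
    df = phenotypes.reset_index(drop=True)
    if min_family_size:
        sizes = df.groupby("family")["line_id"].nunique()
        small = sizes[sizes < min_family_size].index
        if len(small):
            logger.info("dropping %d families below size %d: %s",
                        len(small), min_family_size, list(small))
            df = df[~df["family"].isin(small)].reset_index(drop=True)

    ww_envs, ws_envs = _classify_envs(df)
    family_lines = {f: sorted(d["line_id"].unique())
                    for f, d in df.groupby("family")}
    if blues is None:
        blues = compute_blues(df)
    blue_lookup = blues.set_index(["line_id", "environment"])["blue"]

    if scheme == "cv1":
        plans = make_cv1_masks(family_lines, ww_envs, ws_envs,
                               n_repeats=n_repeats, seed=seed)
    else:
        splits = cdmean_splits(grm, family_lines, ww_envs, lam=lam)
        plans = [make_cv2_masks(splits, ww_envs, ws_envs, family_lines)]
        if n_repeats > 1:
            logger.info("CV2 is deterministic; running a single plan")

    g_obj = grouping if isinstance(grouping, EnvironmentGrouping) \
        else EnvironmentGrouping(grouping)
    env_triples = (df[["environment", "location", "management", "year"]]
                   .drop_duplicates().set_index("environment"))
    env_to_label = {e: g_obj.label(r["location"], r["management"], r["year"])
                    for e, r in env_triples.iterrows()}

    rows, skipped = [], 0
    options = dict(fit_options or {})
    for plan in plans:
        training = plan.training_records(df)
        training = augment_with_historical(training, historical,
                                           mode=augmentation, grm=grm,
                                           n_select=n_select,
                                           grouping=g_obj)
        model = MultiEnvGBLUP(training, grm, grouping=g_obj,
                              structure=structure, m=m)
        fit = model.fit(**options)
        gebv = fit.predict_gebv(force=True)
        for fam in sorted(family_lines):
            for env in ww_envs + ws_envs:
                lines = [l for l in family_lines[fam]
                         if plan.is_masked(l, env)
                         and (l, env) in blue_lookup.index]
                if len(lines) < min_masked_lines:
                    if any(plan.is_masked(l, env)
                           for l in family_lines[fam]):
                        skipped += 1
                        logger.debug("skipping %s x %s: %d masked lines",
                                     fam, env, len(lines))
                    continue
                acc = _pearson(
                    gebv.loc[lines, env_to_label[env]].to_numpy(),
                    blue_lookup.loc[[(l, env) for l in lines]].to_numpy())
                rows.append({"scheme": plan.scheme, "grouping": g_obj.scheme,
                             "structure": structure, "repeat": plan.repeat,
                             "family": fam, "environment": env,
                             "n_lines": len(lines), "accuracy": acc,
                             "converged": fit.converged})
    records = pd.DataFrame(rows)
    return CvResult(records, scheme=scheme, grouping=g_obj.scheme,
                    structure=structure, augmentation=augmentation,
                    seed=seed, n_skipped_cells=skipped)
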