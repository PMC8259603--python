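"""Multi-environment genomic BLUP with structured GxE covariance.

The model for plot-level testcross yields is

    y = 1 mu + X1 b_loc + Z1 u1 + Z2 u2 + Z3 u3 + Z4 u4 + Z5 u5 + e

with a fixed location effect, a genetic line x environment effect
u1 ~ N(0, Go (x) G), iid tester (u2), trial (u3), replicate-within-
environment/trial (u4) and incomplete-block-within-replicate (u5) effects,
and a heterogeneous diagonal residual (one variance per environment).
``Go`` may be unstructured (US), factor-analytic (FA, Go = Lambda Lambda' +
Psi) or diagonal (DIAG); environments are whatever an
:class:`EnvironmentGrouping` maps the raw (location, management, year)
triples onto.

Typical use::

    model = MultiEnvGBLUP.from_dataframe(pheno, grm, grouping="LM",
                                         structure="FA")
    res = model.fit()
    res.heritability()          # per-environment plot h2
    res.genetic_correlations()  # between-environment genetic correlations
    res.predict_gebv()          # GEBVs for every line in G, every environment
    print(res.summary())

Masked line x environment cells are handled by omitting their records: the
Kronecker covariance spans the full line x environment grid, so BLUPs of
unobserved cells borrow strength through G and Go.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .genomics import Grm, regularize_grm
from .reml import (DiagCovariance, FACovariance, IIDTerm, KroneckerTerm,
                   MixedREML, USCovariance)

__all__ = [
    "EnvironmentGrouping",
    "CovarianceSpec",
    "DesignMatrices",
    "MultiEnvGBLUP",
    "MultiEnvGBLUPResults",
    "build_design",
    "heritability",
    "genetic_correlations",
    "predict_gebv",
]

logger = logging.getLogger(__name__)

GROUPING_SCHEMES = ("LM", "M", "MY", "M_plus", "LMY")

REQUIRED_COLUMNS = ("line_id", "family", "year", "location", "management",
                    "environment", "tester", "trial", "rep", "block", "yield")

DEFAULT_RANDOM_TERMS = ("tester", "trial", "rep", "block")


class EnvironmentGrouping:
    """Maps raw (location, management, year) triples to analysis environments.

    Schemes: ``LM`` location x management and ``M`` management (single-year
    analyses); ``MY`` management x year, ``M_plus`` management pooled over
    years, and ``LMY`` location x management x year (multi-year analyses).
    """

    def __init__(self, scheme: str):
        if scheme not in GROUPING_SCHEMES:
            raise ValueError(
                f"unknown grouping {scheme!r}; choose from {GROUPING_SCHEMES}")
        self.scheme = scheme

    @property
    def multi_year(self) -> bool:
        return self.scheme in ("MY", "M_plus", "LMY")

    def label(self, location: str, management: str, year) -> str:
        if self.scheme == "LM":
            return f"{location}_{management}"
        if self.scheme == "M":
            return str(management)
        if self.scheme == "MY":
            return f"{management}_{year}"
        if self.scheme == "M_plus":
            return str(management)
        return f"{location}_{management}_{year}"

    def apply(self, df: pd.DataFrame) -> pd.Series:
        """Analysis-environment label for every record."""
        if not self.multi_year and df["year"].nunique() > 1:
            raise ValueError(
                f"grouping {self.scheme!r} is a single-year scheme but the "
                f"data span years {sorted(df['year'].unique())}")
        return df.apply(lambda r: self.label(r["location"], r["management"],
                                             r["year"]), axis=1)

    def __repr__(self) -> str:
        return f"EnvironmentGrouping({self.scheme!r})"


@dataclass
class CovarianceSpec:
    """Genetic covariance structure and, for FA, its number of factors.

    When ``m`` is None it follows the default rule: one factor for fewer
    than four environments, two for four to six (and two beyond that).
    """

    structure: str = "FA"
    m: int | None = None

    def __post_init__(self):
        if self.structure not in ("US", "FA", "DIAG"):
            raise ValueError("structure must be 'US', 'FA' or 'DIAG'")

    def resolve_m(self, v: int) -> int:
        if self.m is not None:
            if not 1 <= self.m < v:
                raise ValueError(f"FA needs 1 <= m < v; got m={self.m}, v={v}")
            return self.m
        return 1 if v < 4 else 2


@dataclass
class DesignMatrices:
    """Response, fixed design and random-effect incidence matrices."""

    y: np.ndarray
    X: sp.csr_matrix
    x_names: list
    env_labels: list          # analysis environments, sorted
    env_index: np.ndarray     # per-record environment position
    Z1: sp.csr_matrix         # line x environment incidence (env-major cols)
    line_ids: list            # column order of lines within an env block
    iid_terms: list           # IIDTerm for tester/trial/rep/block
    records: pd.DataFrame
    dropped: list = field(default_factory=list)


def _incidence(levels: pd.Series) -> tuple[sp.csr_matrix, list]:
    cats = sorted(levels.unique())
    pos = {c: k for k, c in enumerate(cats)}
    rows = np.arange(len(levels))
    cols = levels.map(pos).to_numpy()
    Z = sp.csr_matrix((np.ones(len(levels)), (rows, cols)),
                      shape=(len(levels), len(cats)))
    return Z, cats


def build_design(phenotypes: pd.DataFrame, grouping: EnvironmentGrouping,
                 grm: Grm, random_terms=DEFAULT_RANDOM_TERMS,
                 response: str = "yield") -> DesignMatrices:
    """Assemble fixed and random design matrices from plot records.

    Replicates are keyed within environment and trial (plus year for
    multi-year groupings); blocks within replicate, trial and location.
    Factors left with a single level are dropped with a log notice.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in phenotypes.columns
               and c != "yield"] + ([] if response in phenotypes.columns
                                    else [response])
    if missing:
        raise ValueError(f"phenotype table is missing columns: {missing}")
    df = phenotypes.reset_index(drop=True)
    unknown = sorted(set(df["line_id"]) - set(grm.line_ids))
    if unknown:
        raise ValueError(
            f"{len(unknown)} phenotyped lines are absent from the GRM; "
            f"first offenders: {unknown[:5]}")

    env = grouping.apply(df)
    env_labels = sorted(env.unique())
    env_pos = {e: k for k, e in enumerate(env_labels)}
    env_index = env.map(env_pos).to_numpy()
    n = len(df)
    y = df[response].to_numpy(float)

    # fixed part: intercept + location contrasts (first location as baseline)
    locs = sorted(df["location"].unique())
    x_cols = [np.ones(n)]
    x_names = ["intercept"]
    for loc in locs[1:]:
        x_cols.append((df["location"] == loc).to_numpy(float))
        x_names.append(f"location[{loc}]")
    X = sp.csr_matrix(np.column_stack(x_cols))

    g = grm.n_lines
    line_pos = {lid: k for k, lid in enumerate(grm.line_ids)}
    cols = env_index * g + df["line_id"].map(line_pos).to_numpy()
    Z1 = sp.csr_matrix((np.ones(n), (np.arange(n), cols)),
                       shape=(n, len(env_labels) * g))

    year_key = df["year"].astype(str) if grouping.multi_year else ""
    factor_keys = {
        "tester": df["tester"].astype(str),
        "trial": df["trial"].astype(str),
        "rep": (env.astype(str) + "|" + year_key + "|"
                + df["trial"].astype(str) + "|r" + df["rep"].astype(str)),
        "block": (env.astype(str) + "|" + df["location"].astype(str) + "|"
                  + year_key + "|" + df["trial"].astype(str)
                  + "|r" + df["rep"].astype(str)
                  + "|b" + df["block"].astype(str)),
    }
    iid_terms, dropped = [], []
    for name in random_terms:
        if name not in factor_keys:
            raise ValueError(f"unknown random term {name!r}")
        keys = factor_keys[name]
        if keys.nunique() < 2:
            dropped.append(name)
            logger.info("random term %r has a single level; dropped", name)
            continue
        Z, labels = _incidence(keys)
        iid_terms.append(IIDTerm(name, Z, labels))

    return DesignMatrices(y=y, X=X, x_names=x_names, env_labels=env_labels,
                          env_index=env_index, Z1=Z1,
                          line_ids=list(grm.line_ids), iid_terms=iid_terms,
                          records=df, dropped=dropped)


def _moment_start_go(design: DesignMatrices, grm_values: np.ndarray
                     ) -> np.ndarray:
    """Method-of-moments starting value for Go from per-line cell means."""
    df = design.records
    v = len(design.env_labels)
    env = pd.Series(np.asarray(design.env_index), index=df.index)
    cell = df.assign(_env=env).groupby(["line_id", "_env"])["yield"] \
        .agg(["mean", "size"])
    ybar = cell["mean"].unstack("_env").reindex(columns=range(v))
    reps = cell["size"].groupby("_env").mean().reindex(range(v)).fillna(1.0)
    var_env = df.assign(_env=env).groupby("_env")["yield"].var() \
        .reindex(range(v)).fillna(1.0).to_numpy()
    gbar = float(np.mean(np.diag(grm_values))) or 1.0
    cov = ybar.cov(min_periods=5).to_numpy()
    diag = np.empty(v)
    for e in range(v):
        c = cov[e, e] if np.isfinite(cov[e, e]) else var_env[e]
        diag[e] = max(c - 0.5 * var_env[e] / reps.iloc[e],
                      0.1 * var_env[e]) / gbar
    go = np.zeros((v, v))
    np.fill_diagonal(go, diag)
    for a in range(v):
        for b in range(a + 1, v):
            c = cov[a, b] / gbar if np.isfinite(cov[a, b]) else \
                0.1 * np.sqrt(diag[a] * diag[b])
            cap = 0.85 * np.sqrt(diag[a] * diag[b])
            go[a, b] = go[b, a] = np.clip(0.8 * c, -cap, cap)
    w, vec = np.linalg.eigh(go)
    w = np.clip(w, 1e-3 * diag.mean(), None)
    return vec @ np.diag(w) @ vec.T


class MultiEnvGBLUP:
    """Multi-environment GBLUP model bound to data.

    Parameters
    ----------
    phenotypes : DataFrame of plot records with the standard trial columns
        (line_id, family, year, location, management, environment, tester,
        trial, rep, block, yield).
    grm : Grm over at least all phenotyped lines; regularized automatically
        if its Cholesky factorization fails.
    grouping : scheme name or :class:`EnvironmentGrouping`.
    structure : "US", "FA" or "DIAG" (or a :class:`CovarianceSpec`).
    m : number of FA factors; None applies the environment-count rule.
    random_terms : nuisance factors to include; degenerate ones are dropped.
    """

    def __init__(self, phenotypes: pd.DataFrame, grm: Grm,
                 grouping="LM", structure="FA", m: int | None = None,
                 random_terms=DEFAULT_RANDOM_TERMS, response: str = "yield"):
        if isinstance(grouping, str):
            grouping = EnvironmentGrouping(grouping)
        self.grouping = grouping
        if isinstance(structure, CovarianceSpec):
            self.spec = structure
        else:
            self.spec = CovarianceSpec(structure, m)
        self.grm = self._ensure_invertible(grm)
        self.design = build_design(phenotypes, grouping, self.grm,
                                   random_terms, response)
        v = len(self.design.env_labels)
        if v < 2 and self.spec.structure == "FA":
            raise ValueError("FA requires at least 2 environments; use US")

    @classmethod
    def from_dataframe(cls, phenotypes, grm, **kwargs) -> "MultiEnvGBLUP":
        return cls(phenotypes, grm, **kwargs)

    @staticmethod
    def _ensure_invertible(grm: Grm, max_condition: float = 1e7) -> Grm:
        """Ridge the GRM until its condition number is numerically safe.

        The REML equations use G^-1 directly; a GRM built from fewer
        effective markers than lines (common with close families) is
        numerically singular and destroys the trace computations, so the
        spectrum, not just Cholesky success, decides the ridge.
        """
        w = np.linalg.eigvalsh(grm.values)
        lam_min, lam_max = float(w[0]), float(w[-1])
        if lam_max <= 0:
            raise la.LinAlgError("GRM has no positive eigenvalues")
        target = lam_max / max_condition
        if lam_min < target:
            eps = target - lam_min
            logger.info("GRM condition %.2e; adding %.2e ridge",
                        lam_max / max(lam_min, 1e-300), eps)
            grm = regularize_grm(grm, eps)
        return grm

    def fit(self, method: str = "ai", tol: float = 1e-6, max_iter: int = 200,
            floor_frac: float = 1e-8, start_go: np.ndarray | None = None
            ) -> "MultiEnvGBLUPResults":
        """Estimate all variance components by REML and BLUP the GEBVs."""
        design = self.design
        v = len(design.env_labels)
        go0 = (np.asarray(start_go, float) if start_go is not None
               else _moment_start_go(design, self.grm.values))
        if self.spec.structure == "US":
            structure = USCovariance(go0)
        elif self.spec.structure == "FA":
            structure = FACovariance(go0, self.spec.resolve_m(v))
        else:
            structure = DiagCovariance(go0)
        kron = KroneckerTerm(design.Z1, self.grm.values, structure)
        engine = MixedREML(design.y, design.X, design.iid_terms, kron,
                           design.env_index, n_envs=v)
        state, status = engine.fit(method=method, tol=tol, max_iter=max_iter,
                                   floor_frac=floor_frac)
        if not status.converged:
            logger.warning("REML did not converge after %d iterations (%s)",
                           status.n_iterations, status.message)
        sol = state["sol"]
        sl = engine.slices["genetic"]
        gebv = sol[sl].reshape(v, self.grm.n_lines).T
        beta = pd.Series(sol[:engine.n_fixed], index=design.x_names)
        nuisance = {t.name: engine.iid_var[t.name] for t in design.iid_terms}
        return MultiEnvGBLUPResults(
            model=self,
            structure=self.spec.structure,
            m=self.spec.resolve_m(v) if self.spec.structure == "FA" else None,
            Go=pd.DataFrame(structure.go, index=design.env_labels,
                            columns=design.env_labels),
            Lambda=(pd.DataFrame(structure.lam, index=design.env_labels)
                    if self.spec.structure == "FA" else None),
            Psi=(pd.Series(structure.psi, index=design.env_labels)
                 if self.spec.structure == "FA" else None),
            resid_var=pd.Series(engine.resid_var, index=design.env_labels),
            nuisance_var=nuisance,
            fixed_effects=beta,
            gebv=pd.DataFrame(gebv, index=design.line_ids,
                              columns=design.env_labels),
            loglike=state["loglike"],
            converged=status.converged,
            n_iterations=status.n_iterations,
            loglike_trace=list(status.loglike_trace),
            pinned=list(status.pinned),
        )


@dataclass
class MultiEnvGBLUPResults:
    """REML estimates, GEBVs and diagnostics of a fitted model."""

    model: MultiEnvGBLUP
    structure: str
    m: int | None
    Go: pd.DataFrame
    Lambda: pd.DataFrame | None
    Psi: pd.Series | None
    resid_var: pd.Series
    nuisance_var: dict
    fixed_effects: pd.Series
    gebv: pd.DataFrame
    loglike: float
    converged: bool
    n_iterations: int
    loglike_trace: list
    pinned: list

    def heritability(self) -> pd.Series:
        """Per-environment plot heritability h2 = sg2 / (sg2 + se2)."""
        sg2 = np.diag(self.Go.to_numpy())
        se2 = self.resid_var.to_numpy()
        total = sg2 + se2
        with np.errstate(invalid="ignore", divide="ignore"):
            h2 = np.where(total > 0, sg2 / total, np.nan)
        return pd.Series(h2, index=self.Go.index, name="h2")

    def genetic_correlations(self) -> pd.DataFrame:
        """Between-environment genetic correlation matrix (diagonal 1)."""
        go = self.Go.to_numpy()
        sd = np.sqrt(np.clip(np.diag(go), 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = go / np.outer(sd, sd)
        zero = sd == 0
        corr[zero, :] = np.nan
        corr[:, zero] = np.nan
        np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
        return pd.DataFrame(corr, index=self.Go.index, columns=self.Go.columns)

    def predict_gebv(self, line_ids=None, force: bool = False) -> pd.DataFrame:
        """GEBVs (lines x environments) for every line in G.

        Unphenotyped lines get predictions through relationship propagation.
        Raises for lines absent from G and, unless ``force``, warns loudly on
        a non-converged fit.
        """
        if not self.converged and not force:
            logger.warning("predicting from a non-converged fit "
                           "(pass force=True to silence)")
        if line_ids is None:
            return self.gebv.copy()
        missing = [l for l in line_ids if l not in self.gebv.index]
        if missing:
            raise KeyError(f"lines absent from the GRM: {missing[:5]}")
        return self.gebv.loc[list(line_ids)].copy()

    def summary(self) -> str:
        lines = [
            "Multi-environment GBLUP (REML)",
            "=" * 62,
            f"structure: {self.structure}"
            + (f" (m={self.m})" if self.m is not None else ""),
            f"grouping:  {self.model.grouping.scheme}"
            f"    environments: {len(self.Go)}",
            f"records:   {len(self.model.design.records)}"
            f"    lines in G: {len(self.gebv)}",
            f"logL: {self.loglike:.4f}    converged: {self.converged}"
            f"    iterations: {self.n_iterations}",
        ]
        if self.pinned:
            lines.append(f"components pinned at floor: {self.pinned}")
        lines.append("-" * 62)
        lines.append("variance components")
        for name, val in self.nuisance_var.items():
            lines.append(f"  {name:<10s} {val:12.5f}")
        for env in self.Go.index:
            lines.append(f"  resid[{env}] {self.resid_var[env]:12.5f}")
        lines.append("-" * 62)
        lines.append("genetic covariance Go (diagonal = genetic variances)")
        lines.append(self.Go.round(4).to_string())
        lines.append("-" * 62)
        lines.append("genetic correlations")
        lines.append(self.genetic_correlations().round(3).to_string())
        lines.append("-" * 62)
        lines.append("plot heritability")
        lines.append(self.heritability().round(3).to_string())
        return "\n".join(lines)


def heritability(results: MultiEnvGBLUPResults) -> pd.Series:
    """Per-environment plot heritability of a fitted model."""
    return results.heritability()


def genetic_correlations(results: MultiEnvGBLUPResults) -> pd.DataFrame:
    """Between-environment genetic correlations of a fitted model."""
    return results.genetic_correlations()


def predict_gebv(results: MultiEnvGBLUPResults, line_ids=None) -> pd.DataFrame:
    """GEBV matrix of a fitted model (see Results.predict_gebv)."""
    return results.predict_gebv(line_ids)
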