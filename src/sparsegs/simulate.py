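"""Seeded simulation of multi-environment testcross trials of DH families.

The generator emulates an early-stage maize yield-testing campaign: several
bi-parental doubled-haploid (DH) families, each testcrossed to a single
tester, evaluated under well-watered (WW) and water-stress (WS) management
in alpha-lattice trials with two replications.  Genotypes come from an
explicit meiosis model (interference-free crossovers on a Morgan map, then
chromosome doubling); genetic values are drawn directly from the
multi-environment GBLUP model,

    vec(U) ~ N(0, Go (x) G),

so that the covariance the downstream model fits is exactly the covariance
the data carry, which makes parameter recovery a well-posed test.  Marker
effects are never made explicit.

Default parameter values mirror a single-year campaign of 12 families of 70
DH lines in three environments (two WW locations plus one WS), per-plot
heritabilities of roughly 0.25-0.35 and between-environment genetic
correlations of 0.2-0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import Grm, MarkerMatrix

__all__ = [
    "SimulationConfig",
    "FounderSet",
    "SyntheticDataset",
    "default_true_go",
    "simulate_founders",
    "simulate_dh_family",
    "simulate_genetic_values",
    "simulate_trial_phenotypes",
    "simulate_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


_DEFAULT_ENVS = (("Kiboko", "WW"), ("Kakamega", "WW"), ("Kiboko", "WS"))
# per-plot heritability targets cycled over the environments of a year
_DEFAULT_H2 = (0.25, 0.35, 0.30)
# genetic correlations between the three environments of one year,
# ordered (env1,env2), (env1,env3), (env2,env3)
_DEFAULT_CORR = (0.2, 0.6, 0.3)
_DEFAULT_CROSS_YEAR_CORR = 0.2


def default_true_go(n_envs: int, envs_per_year: int = 3,
                    residual_variances=None) -> np.ndarray:
    """Build the default true genetic covariance for ``n_envs`` environments.

    Variances are chosen so that with the default unit residual variances the
    per-plot heritabilities cycle through ``_DEFAULT_H2``; within-year
    correlations cycle through ``_DEFAULT_CORR`` and across-year correlations
    are a flat 0.2.
    """
    if residual_variances is None:
        residual_variances = np.ones(n_envs)
    h2 = np.array([_DEFAULT_H2[i % len(_DEFAULT_H2)] for i in range(n_envs)])
    sg2 = h2 / (1.0 - h2) * np.asarray(residual_variances, dtype=float)
    corr = np.full((n_envs, n_envs), _DEFAULT_CROSS_YEAR_CORR)
    for y0 in range(0, n_envs, envs_per_year):
        block = corr[y0:y0 + envs_per_year, y0:y0 + envs_per_year]
        k = block.shape[0]
        pair = iter(_DEFAULT_CORR)
        for i in range(k):
            for j in range(i + 1, k):
                block[i, j] = block[j, i] = next(pair, 0.3)
    np.fill_diagonal(corr, 1.0)
    sd = np.sqrt(sg2)
    go = corr * np.outer(sd, sd)
    return (go + go.T) / 2.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic trial generator.

    ``true_Go`` is the v x v genetic covariance across the v analysis
    environments (v = n_years * len(envs_per_year)); ``residual_variances``
    are the per-environment plot residual variances.  ``nuisance_variances``
    holds the iid variances of tester, trial, replicate and incomplete-block
    effects.
    """

    n_families: int = 12
    family_size: int = 70
    n_chromosomes: int = 10
    markers_per_chromosome: int = 100
    chromosome_length_morgans: float = 1.5
    n_years: int = 1
    envs_per_year: tuple = _DEFAULT_ENVS
    n_testers_per_year: int = 3
    n_trials: int | None = None  # per year; None = one trial per family
    n_reps: int = 2
    blocks_per_rep: int = 5
    true_Go: np.ndarray | None = None
    residual_variances: np.ndarray | None = None
    nuisance_variances: dict = field(default_factory=lambda: {
        "tester": 0.05, "trial": 0.05, "rep": 0.02, "block": 0.02})
    mu: float = 5.0
    location_effects: dict | None = None  # location -> fixed offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_size < 4:
            raise ConfigurationError("family_size must be at least 4")
        for name in ("n_families", "n_chromosomes", "markers_per_chromosome",
                     "n_years", "n_testers_per_year", "n_reps",
                     "blocks_per_rep"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.chromosome_length_morgans <= 0:
            raise ConfigurationError("chromosome_length_morgans must be > 0")
        if self.n_trials is None:
            self.n_trials = self.n_families
        if self.n_trials < 1 or self.n_trials > self.n_families:
            raise ConfigurationError(
                "n_trials must be between 1 and n_families")
        v = self.n_envs
        if self.residual_variances is None:
            self.residual_variances = np.ones(v)
        self.residual_variances = np.asarray(self.residual_variances, float)
        if self.residual_variances.shape != (v,):
            raise ConfigurationError(
                f"residual_variances must have length {v}")
        if (self.residual_variances < 0).any():
            raise ConfigurationError("residual variances must be >= 0")
        if self.true_Go is None:
            self.true_Go = default_true_go(
                v, len(self.envs_per_year), self.residual_variances)
        self.true_Go = np.asarray(self.true_Go, float)
        if self.true_Go.shape != (v, v):
            raise ConfigurationError(
                f"true_Go must be {v} x {v} (one row per environment)")
        if np.abs(self.true_Go - self.true_Go.T).max() > 1e-10:
            raise ConfigurationError("true_Go must be symmetric")
        if np.linalg.eigvalsh(self.true_Go).min() < -1e-8:
            raise ConfigurationError("true_Go must be positive semi-definite")
        for key, val in self.nuisance_variances.items():
            if val < 0:
                raise ConfigurationError(f"nuisance variance {key!r} < 0")
        if self.location_effects is None:
            locs = list(dict.fromkeys(loc for loc, _ in self.envs_per_year))
            self.location_effects = {loc: 0.2 * i for i, loc in enumerate(locs)}

    @property
    def n_envs(self) -> int:
        return self.n_years * len(self.envs_per_year)

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def environments(self) -> list[dict]:
        """Environment descriptors in Go order: year-major, env-minor."""
        out = []
        for y in range(self.n_years):
            year = 2017 + y
            for loc, mgmt in self.envs_per_year:
                out.append({
                    "year": year, "location": loc, "management": mgmt,
                    "environment": f"{loc}_{mgmt}_{year}",
                })
        return out


@dataclass
class FounderSet:
    """Inbred founder haplotypes on a shared genetic map.

    ``haplotypes`` has shape (n_founders, 2, n_markers); the two haplotypes
    of each founder are identical because founders are fully inbred lines.
    ``positions`` maps chromosome index -> strictly increasing Morgan
    positions; ``chromosome_of`` gives each marker's chromosome.
    """

    haplotypes: np.ndarray
    positions: list
    chromosome_of: np.ndarray
    marker_ids: list

    def __post_init__(self) -> None:
        for pos in self.positions:
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    "marker positions must be strictly increasing")
        if self.haplotypes.shape[1] != 2:
            raise ConfigurationError("each founder needs two haplotypes")


@dataclass
class SyntheticDataset:
    """Genotypes, phenotypes and the generating truth of one simulation."""

    marker_matrix: MarkerMatrix
    phenotypes: pd.DataFrame
    true_genetic_values: pd.DataFrame  # lines x environment labels
    config: SimulationConfig

    def split_by_year(self, year: int):
        """(records of ``year``, records of all other years) as DataFrames."""
        cur = self.phenotypes[self.phenotypes["year"] == year].reset_index(drop=True)
        rest = self.phenotypes[self.phenotypes["year"] != year].reset_index(drop=True)
        return cur, rest


def simulate_founders(config: SimulationConfig, rng=None) -> FounderSet:
    """Draw inbred founders: two per family, on a fresh genetic map.

    Per-marker presence-allele frequencies are uniform on (0.02, 0.98), so
    the realized MAF spectrum of the DH progeny straddles the 0.05 filter
    threshold.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_founders = 2 * config.n_families * config.n_years
    m = config.n_markers
    freqs = rng.uniform(0.02, 0.98, size=m)
    hap = (rng.random((n_founders, m)) < freqs).astype(np.int8)
    haplotypes = np.repeat(hap[:, None, :], 2, axis=1)
    positions, chrom_of = [], []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, config.chromosome_length_morgans,
                                  size=config.markers_per_chromosome))
        pos += np.arange(len(pos)) * 1e-9  # guard against ties
        positions.append(pos)
        chrom_of.extend([c] * config.markers_per_chromosome)
    marker_ids = [f"M{c + 1}_{i + 1}" for c in range(config.n_chromosomes)
                  for i in range(config.markers_per_chromosome)]
    return FounderSet(haplotypes, positions, np.asarray(chrom_of), marker_ids)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, founders: FounderSet,
            rng) -> np.ndarray:
    """One recombinant F1 gamete under the Haldane (no interference) model."""
    out = np.empty_like(hap_a)
    for c, pos in enumerate(founders.positions):
        sel = founders.chromosome_of == c
        length = pos[-1] - pos[0] if len(pos) > 1 else 0.0
        n_xo = rng.poisson(length)
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_xo))
        phase0 = rng.integers(0, 2)
        # phase at each marker = start phase + number of crossovers before it
        phase = (phase0 + np.searchsorted(xo, pos)) % 2
        chrom = np.where(phase == 0, hap_a[sel], hap_b[sel])
        out[sel] = chrom
    return out


def simulate_dh_family(parent_a: np.ndarray, parent_b: np.ndarray,
                       family_size: int, founders: FounderSet,
                       rng) -> np.ndarray:
    """DH progeny of the cross parent_a x parent_b, coded 0/2.

    Each DH line is a doubled recombinant gamete of the F1: fully homozygous,
    marker value 2 x (allele of the sampled gamete).
    """
    if family_size < 1:
        raise ConfigurationError("family_size must be >= 1")
    hap_a = parent_a[0]
    hap_b = parent_b[0]
    lines = np.empty((family_size, hap_a.shape[0]), dtype=np.int8)
    for i in range(family_size):
        lines[i] = 2 * _gamete(hap_a, hap_b, founders, rng)
    return lines


def simulate_genotypes(config: SimulationConfig, rng=None) -> MarkerMatrix:
    """Founders plus DH families for every family of every year."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    founders = simulate_founders(config, rng)
    ids, fams, blocks = [], {}, []
    f = 0
    for y in range(config.n_years):
        year = 2017 + y
        for k in range(config.n_families):
            fam = f"F{year}_{k + 1:02d}"
            block = simulate_dh_family(
                founders.haplotypes[2 * f], founders.haplotypes[2 * f + 1],
                config.family_size, founders, rng)
            blocks.append(block)
            for i in range(config.family_size):
                lid = f"{fam}_L{i + 1:03d}"
                ids.append(lid)
                fams[lid] = fam
            f += 1
    return MarkerMatrix(ids, fams, np.vstack(blocks), founders.marker_ids)


def simulate_genetic_values(grm: Grm, true_go: np.ndarray, rng) -> np.ndarray:
    """Draw the lines x environments genetic-value matrix U.

    vec-by-environment covariance: Cov(U[:, i], U[:, j]) = true_go[i, j] * G.
    Realized as U = A Z B' with A A' = G, B B' = true_go, Z iid normal.
    """
    true_go = np.asarray(true_go, float)
    if true_go.size == 0 or not np.any(true_go):
        return np.zeros((grm.n_lines, true_go.shape[0]))

    def _psd_root(mat, name):
        w, v = np.linalg.eigh((mat + mat.T) / 2.0)
        if w.min() < -1e-6 * max(1.0, abs(w.max())):
            raise ValueError(f"{name} is not positive semi-definite "
                             f"(min eigenvalue {w.min():.3g})")
        return v * np.sqrt(np.clip(w, 0.0, None))

    A = _psd_root(grm.values, "G")
    B = _psd_root(true_go, "true_Go")
    Z = rng.standard_normal((grm.n_lines, true_go.shape[0]))
    return A @ Z @ B.T


def _pack_trials(families: list, n_trials: int) -> dict:
    """Family-contiguous assignment of families to trials."""
    bounds = np.linspace(0, len(families), n_trials + 1).astype(int)
    out = {}
    for t in range(n_trials):
        for fam in families[bounds[t]:bounds[t + 1]]:
            out[fam] = t + 1
    return out


def simulate_trial_phenotypes(marker_matrix: MarkerMatrix,
                              true_values: pd.DataFrame,
                              config: SimulationConfig,
                              rng) -> pd.DataFrame:
    """Plot-level phenotype records for the alpha-lattice trial campaign.

    y = mu + location + tester + trial + rep-within(env, trial)
        + block-within(rep) + genetic value + plot residual,
    with the residual variance specific to each environment.
    """
    nv = config.nuisance_variances
    envs = config.environments()
    env_labels = [e["environment"] for e in envs]
    missing = [l for l in marker_matrix.line_ids
               if l not in true_values.index]
    if missing:
        raise ValueError(f"no genetic value for lines {missing[:5]}")

    records = []
    fam_lines: dict = {}
    for lid in marker_matrix.line_ids:
        fam_lines.setdefault(marker_matrix.family_of[lid], []).append(lid)

    # effect draws, in a fixed order for determinism
    tester_eff, trial_eff, rep_eff, block_eff = {}, {}, {}, {}
    years = sorted({e["year"] for e in envs})
    fam_year = {fam: int(fam[1:5]) for fam in fam_lines}
    fam_tester, fam_trial = {}, {}
    for year in years:
        fams = [f for f in fam_lines if fam_year[f] == year]
        for i, fam in enumerate(fams):
            t = i % config.n_testers_per_year + 1
            fam_tester[fam] = f"T{year}_{t}"
        fam_trial.update({f: f"TR{year}_{t:02d}" for f, t in
                          _pack_trials(fams, config.n_trials).items()})
    for t in sorted(set(fam_tester.values())):
        tester_eff[t] = rng.normal(0.0, np.sqrt(nv.get("tester", 0.0)))
    for t in sorted(set(fam_trial.values())):
        trial_eff[t] = rng.normal(0.0, np.sqrt(nv.get("trial", 0.0)))

    for ev, env in enumerate(envs):
        sigma_e = np.sqrt(config.residual_variances[ev])
        year_fams = [f for f in fam_lines if fam_year[f] == env["year"]]
        trials: dict = {}
        for fam in year_fams:
            trials.setdefault(fam_trial[fam], []).extend(fam_lines[fam])
        for trial_id in sorted(trials):
            lines = trials[trial_id]
            for rep in range(1, config.n_reps + 1):
                rep_key = (env["environment"], trial_id, rep)
                rep_eff[rep_key] = rng.normal(
                    0.0, np.sqrt(nv.get("rep", 0.0)))
                order = rng.permutation(len(lines))
                bounds = np.linspace(0, len(lines),
                                     config.blocks_per_rep + 1).astype(int)
                for b in range(config.blocks_per_rep):
                    bkey = rep_key + (b + 1,)
                    block_eff[bkey] = rng.normal(
                        0.0, np.sqrt(nv.get("block", 0.0)))
                    for idx in order[bounds[b]:bounds[b + 1]]:
                        lid = lines[idx]
                        fam = marker_matrix.family_of[lid]
                        y = (config.mu
                             + config.location_effects[env["location"]]
                             + tester_eff[fam_tester[fam]]
                             + trial_eff[fam_trial[fam]]
                             + rep_eff[rep_key]
                             + block_eff[bkey]
                             + true_values.loc[lid, env["environment"]]
                             + rng.normal(0.0, sigma_e))
                        records.append({
                            "line_id": lid, "family": fam,
                            "year": env["year"],
                            "location": env["location"],
                            "management": env["management"],
                            "environment": env["environment"],
                            "tester": fam_tester[fam],
                            "trial": fam_trial[fam],
                            "rep": rep, "block": b + 1,
                            "yield": y,
                        })
    df = pd.DataFrame.from_records(records)
    assert set(df["environment"]) <= set(env_labels)
    return df


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full deterministic pipeline: founders -> DH genotypes -> phenotypes."""
    from .genomics import compute_grm

    rng = np.random.default_rng(config.seed)
    markers = simulate_genotypes(config, rng)
    grm = compute_grm(markers)
    env_labels = [e["environment"] for e in config.environments()]
    U = simulate_genetic_values(grm, config.true_Go, rng)
    true_values = pd.DataFrame(U, index=markers.line_ids, columns=env_labels)
    # lines are phenotyped only in their own year's environments
    phenos = simulate_trial_phenotypes(markers, true_values, config, rng)
    return SyntheticDataset(markers, phenos, true_values, config)
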