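"""Calibration-set optimization: per-individual CDmean and Avg_GRM.

CDmean ranks the members of a full-sib family by how reliably each one,
when phenotyped alone, predicts its N-1 sibs.  The reliability of a set of
contrasts K (each column a contrast of one predicted individual against the
family mean, summing to zero) is the coefficient of determination

    CD(K) = diag[ K' (G - lam (Z' D Z + lam G^-1)^-1) K ] / diag[ K' G K ]

with G the family block of the genomic relationship matrix, Z the incidence
of calibration phenotypes onto family members, D = I - X (X'X)^-1 X' the
projection removing the calibration-record mean, and lam the residual to
genetic variance ratio (fixed at 0.5 by default: for untested lines the true
ratio is unknown and the criterion depends mainly on relationship, not
heritability).

With a single calibration record an intercept absorbs all information and
every CD would be identically zero, so mean adjustment is only applied for
calibration sets of two or more records (``mean_adjust="auto"``); singleton
calibration uses D = I.

Avg_GRM scores a candidate historical line by its mean genomic relationship
to the members of a target family — a raw estimate of the shared genome
proportion — and keeps the top ``n_select`` (default 300) candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genomics import Grm

__all__ = [
    "CdScores",
    "CalibrationSplit",
    "HistoricalSelection",
    "contrast_matrix",
    "cd_reliability",
    "cdmean_per_individual",
    "split_family_cv2",
    "avg_grm_select",
]

logger = logging.getLogger(__name__)


@dataclass
class CdScores:
    """Per-individual CDmean values for one full-sib family."""

    family: str
    line_ids: list
    cdmean: np.ndarray
    lam: float

    def ranked(self) -> list:
        """Line ids by descending CDmean, ties broken by line id."""
        order = sorted(range(len(self.line_ids)),
                       key=lambda i: (-self.cdmean[i], self.line_ids[i]))
        return [self.line_ids[i] for i in order]


@dataclass
class CalibrationSplit:
    """CV2 assignment of one family's lines across environments.

    Each line is observed in exactly one of the two WW environments; the
    WS-observed flag marks the subset (half of each WW-observed group) also
    phenotyped under water stress.
    """

    family: str
    ww_envs: tuple
    observed_ww: dict  # line_id -> the WW environment where it is observed
    ws_observed: set   # line ids phenotyped in the WS environment

    def lines_in(self, env: str) -> list:
        return sorted(l for l, e in self.observed_ww.items() if e == env)


@dataclass
class HistoricalSelection:
    """Avg_GRM-ranked historical training individuals for a target family."""

    family: str
    selected: list
    scores: dict  # every candidate -> Avg_GRM score


def contrast_matrix(n: int) -> np.ndarray:
    """n x n matrix whose column j contrasts individual j with the mean.

    Column j has (n-1)/n at position j and -1/n elsewhere, so 1'K = 0.
    """
    if n < 2:
        raise ValueError("a contrast needs a family of at least 2")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def _projection_complement(n_records: int, mean_adjust) -> np.ndarray:
    """D = I - X(X'X)^-1 X' for an intercept X, or I when not adjusted."""
    if mean_adjust == "auto":
        mean_adjust = n_records >= 2
    if mean_adjust:
        return np.eye(n_records) - np.full((n_records, n_records),
                                           1.0 / n_records)
    return np.eye(n_records)


def cd_reliability(g_family: np.ndarray, calibration, K: np.ndarray,
                   lam: float = 0.5, mean_adjust="auto") -> np.ndarray:
    """Reliability CD of each contrast column of K given a calibration set.

    Parameters
    ----------
    g_family : (n, n) relationship block of the family (regularized).
    calibration : indices of the family members with phenotypes.
    K : (n, k) contrast matrix, columns summing to zero.
    lam : residual-to-genetic variance ratio; ``lam = 0`` returns CD = 1
        for every contrast (no shrinkage penalty).
    """
    G = np.asarray(g_family, float)
    n = G.shape[0]
    calibration = np.asarray(list(calibration), dtype=int)
    if calibration.size == 0:
        raise ValueError("calibration set is empty")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    K = np.asarray(K, float)
    denom = np.einsum("ij,jk,ki->i", K.T, G, K)
    if lam == 0.0:
        return np.ones(K.shape[1])
    Z = np.zeros((calibration.size, n))
    Z[np.arange(calibration.size), calibration] = 1.0
    D = _projection_complement(calibration.size, mean_adjust)
    Ginv = np.linalg.inv(G)
    A = Z.T @ D @ Z + lam * Ginv
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Z'DZ + lam G^-1 is singular; regularize the family GRM "
            "(e.g. regularize_grm) or increase lam") from exc
    M = G - lam * Ainv
    numer = np.einsum("ij,jk,ki->i", K.T, M, K)
    return numer / denom


def cdmean_per_individual(g_family, line_ids=None, family: str = "",
                          lam: float = 0.5, mean_adjust="auto",
                          reverse: bool = False) -> CdScores:
    """CDmean score of every member of one full-sib family.

    For each individual g, the reliability of predicting each of the other
    N-1 sibs (contrasts against the family mean) is computed with g alone as
    the calibration set; CDmean(g) is the mean of those N-1 reliabilities.
    With ``reverse=True`` the alternative reading is used: CDmean(g) is the
    mean reliability of g's own contrast when each other sib calibrates.
    """
    if isinstance(g_family, Grm):
        line_ids = list(g_family.line_ids)
        G = g_family.values
    else:
        G = np.asarray(g_family, float)
        if line_ids is None:
            line_ids = [f"L{i + 1:03d}" for i in range(G.shape[0])]
    n = G.shape[0]
    if n < 3:
        raise ValueError("per-individual CDmean needs a family of >= 3")
    K_full = contrast_matrix(n)
    cd_matrix = np.empty((n, n))  # [g, j] = CD of contrast j when g calibrates
    for g in range(n):
        others = [j for j in range(n) if j != g]
        try:
            cd = cd_reliability(G, [g], K_full[:, others], lam, mean_adjust)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"CDmean failed for family {family!r}, individual "
                f"{line_ids[g]!r}: {exc}") from exc
        cd_matrix[g, others] = cd
        cd_matrix[g, g] = np.nan
    if reverse:
        scores = np.nanmean(cd_matrix, axis=0)
    else:
        scores = np.nanmean(cd_matrix, axis=1)
    return CdScores(family, list(line_ids), scores, lam)


def split_family_cv2(scores: CdScores, ww_envs, seed: int | None = None
                     ) -> CalibrationSplit:
    """Split one family across the two WW environments by CDmean rank.

    The top half by CDmean is observed in the first WW environment (masked
    in the second), the bottom half in the second; an odd line goes to the
    first.  The WS calibration set takes the higher-CDmean half of each
    WW-observed group (ceil from the first, floor from the second), so WS
    observes half the family drawn from both WW environments.  Deterministic:
    ties are broken by line id; ``seed`` is accepted for interface symmetry.
    """
    ww_envs = tuple(ww_envs)
    if len(ww_envs) != 2:
        raise ValueError("exactly two WW environments are required")
    ranked = scores.ranked()
    n = len(ranked)
    n_top = (n + 1) // 2
    if n % 2:
        logger.info("family %s has odd size %d; extra line observed in %s",
                    scores.family, n, ww_envs[0])
    top, bottom = ranked[:n_top], ranked[n_top:]
    observed = {l: ww_envs[0] for l in top}
    observed.update({l: ww_envs[1] for l in bottom})
    ws = set(top[:(len(top) + 1) // 2]) | set(bottom[:len(bottom) // 2])
    return CalibrationSplit(scores.family, ww_envs, observed, ws)


def avg_grm_select(g_cross: np.ndarray, historical_ids, family: str = "",
                   n_select: int = 300) -> HistoricalSelection:
    """Select the historical lines most related to a target family.

    ``g_cross`` is the historical x family block of the GRM; each row's mean
    is the Avg_GRM score of that historical candidate.  The ``n_select``
    highest scores win, ties broken by line id.
    """
    g_cross = np.asarray(g_cross, float)
    historical_ids = list(historical_ids)
    if g_cross.ndim != 2 or g_cross.shape[0] != len(historical_ids):
        raise ValueError("g_cross rows must match historical_ids")
    if not historical_ids:
        raise ValueError("historical pool is empty")
    scores = g_cross.mean(axis=1)
    if n_select >= len(historical_ids):
        if n_select > len(historical_ids):
            logger.warning(
                "requested %d historical lines but pool has only %d; "
                "returning the entire pool", n_select, len(historical_ids))
        n_select = len(historical_ids)
    order = sorted(range(len(historical_ids)),
                   key=lambda i: (-scores[i], historical_ids[i]))
    selected = [historical_ids[i] for i in order[:n_select]]
    return HistoricalSelection(
        family, selected, dict(zip(historical_ids, scores)))
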