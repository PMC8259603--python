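"""Marker quality control and genomic relationship matrices.

Markers are dominant presence/absence tags coded 0/2 per line (doubled
haploids are fully homozygous, so no heterozygous dosage of 1 occurs).
The genomic relationship matrix (GRM) follows VanRaden's first method,
treating the 0/2 coding as a biallelic dosage with allele frequencies
estimated from the sample:

    W = M - 2p,    G = W W' / sum_m 2 p_m (1 - p_m)

where ``p_m`` is the frequency of the presence allele at marker m.  The
expected diagonal is ~1 for a non-inbred reference population; fully
homozygous DH lines exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Grm",
    "compute_maf",
    "filter_markers",
    "compute_grm",
    "regularize_grm",
]


class GenomicsError(ValueError):
    """Invalid marker or relationship-matrix input."""


@dataclass
class MarkerMatrix:
    """Lines x markers matrix of dominant 0/2 calls with family labels.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers, one per row.
    family_of : dict
        Mapping line id -> family label.
    values : ndarray of shape (n_lines, n_markers)
        Marker calls, each 0 or 2.
    marker_ids : list of str
        Marker identifiers, one per column.
    """

    line_ids: list
    family_of: dict
    values: np.ndarray
    marker_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GenomicsError("marker values must be a 2-D array")
        if len(self.line_ids) != self.values.shape[0]:
            raise GenomicsError("line_ids length does not match value rows")
        if len(self.marker_ids) != self.values.shape[1]:
            raise GenomicsError("marker_ids length does not match value columns")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenomicsError("line_ids must be unique")
        bad = ~np.isin(self.values, (0, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenomicsError(
                f"marker values must be 0 or 2; found {self.values[i, j]!r} "
                f"at line {self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def families(self) -> list:
        """Family labels in order of first appearance."""
        seen: dict = {}
        for lid in self.line_ids:
            seen.setdefault(self.family_of[lid], None)
        return list(seen)

    def subset_lines(self, line_ids) -> "MarkerMatrix":
        index = {lid: i for i, lid in enumerate(self.line_ids)}
        missing = [lid for lid in line_ids if lid not in index]
        if missing:
            raise GenomicsError(f"unknown line ids: {missing[:5]}")
        rows = [index[lid] for lid in line_ids]
        return MarkerMatrix(
            line_ids=list(line_ids),
            family_of={lid: self.family_of[lid] for lid in line_ids},
            values=self.values[rows],
            marker_ids=list(self.marker_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.copy(), columns=self.marker_ids)
        df.insert(0, "family", [self.family_of[l] for l in self.line_ids])
        df.insert(0, "line_id", self.line_ids)
        return df


@dataclass
class Grm:
    """Symmetric genomic relationship matrix over an ordered set of lines."""

    line_ids: list
    values: np.ndarray
    epsilon: float = 0.0  # ridge added by regularize_grm, 0 if raw

    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise GenomicsError("GRM shape does not match number of line ids")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-8:
            raise GenomicsError(f"GRM is not symmetric (max asymmetry {asym:.3g})")
        self._index = {lid: i for i, lid in enumerate(self.line_ids)}

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def indices(self, line_ids) -> np.ndarray:
        missing = [lid for lid in line_ids if lid not in self._index]
        if missing:
            raise GenomicsError(f"line ids absent from GRM: {missing[:5]}")
        return np.array([self._index[lid] for lid in line_ids], dtype=int)

    def submatrix(self, line_ids) -> "Grm":
        idx = self.indices(line_ids)
        return Grm(list(line_ids), self.values[np.ix_(idx, idx)], self.epsilon)

    def cross(self, row_ids, col_ids) -> np.ndarray:
        """Rectangular relationship block (rows x cols)."""
        ri = self.indices(row_ids)
        ci = self.indices(col_ids)
        return self.values[np.ix_(ri, ci)]


def compute_maf(markers) -> np.ndarray:
    """Per-marker minor allele frequency.

    The frequency of the presence allele is ``p = mean(value) / 2`` and
    MAF = min(p, 1 - p).
    """
    values = markers.values if isinstance(markers, MarkerMatrix) else np.asarray(markers)
    if values.size == 0:
        raise GenomicsError("empty marker matrix")
    p = values.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_markers(markers: MarkerMatrix, threshold: float = 0.05) -> MarkerMatrix:
    """Retain markers with MAF strictly greater than ``threshold``.

    Marker order is preserved.  Raises if no marker survives.
    """
    maf = compute_maf(markers)
    keep = maf > threshold
    if not keep.any():
        raise GenomicsError(
            f"no markers survive the MAF > {threshold} filter "
            f"({markers.n_markers} markers examined)"
        )
    return MarkerMatrix(
        line_ids=list(markers.line_ids),
        family_of=dict(markers.family_of),
        values=markers.values[:, keep],
        marker_ids=[m for m, k in zip(markers.marker_ids, keep) if k],
    )


def compute_grm(markers: MarkerMatrix) -> Grm:
    """VanRaden method-1 GRM from the 0/2 dosage matrix.

    Columns are centered by twice the presence-allele frequency and the
    cross-product is scaled by ``sum 2 p (1 - p)`` over polymorphic markers.
    """
    if markers.n_lines < 2:
        raise GenomicsError("GRM needs at least 2 lines")
    M = markers.values.astype(float)
    p = M.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise GenomicsError("all markers are monomorphic; GRM scale is zero")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return Grm(list(markers.line_ids), G)


def regularize_grm(grm: Grm, epsilon: float = 1e-6) -> Grm:
    """Add ``epsilon`` to the diagonal so the matrix is safely invertible."""
    if epsilon == 0.0:
        return Grm(list(grm.line_ids), grm.values.copy(), grm.epsilon)
    return Grm(
        list(grm.line_ids),
        grm.values + epsilon * np.eye(grm.n_lines),
        grm.epsilon + epsilon,
    )
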