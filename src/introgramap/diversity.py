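"""AFLP diversity: pairwise distances, principal coordinates, and
species-specific locus counting.

Distances over binary presence/absence profiles are computed on jointly
non-missing fragments only (pairwise deletion, no imputation).  Principal
coordinates analysis is classical scaling: double-centre −½D², take the
eigendecomposition, keep the top-k nonnegative eigenvalues; negative
eigenvalues (non-Euclidean distances) are reported but never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import FragmentMatrix

logger = logging.getLogger("introgramap")

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "SpeciesSpecificCounts",
    "pairwise_distance",
    "pcoa",
    "count_species_specific",
]

METRICS = ("jaccard", "dice", "simple_matching")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with line identifiers."""

    ids: list[str]
    d: np.ndarray
    #: pairs of ids with zero jointly non-missing fragments (distance set to 0)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < -1e-12):
            raise ValueError("distances must be nonnegative with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and explained variance fractions."""

    coordinates: pd.DataFrame  # ids × k
    eigenvalues: np.ndarray    # all eigenvalues, descending
    explained_fraction: np.ndarray  # for the k kept axes
    n_negative: int = 0

    def __post_init__(self):
        ef = np.asarray(self.explained_fraction)
        if np.any(np.diff(ef) > 1e-9):
            raise ValueError("explained fractions must be non-increasing")
        if ef.sum() > 1 + 1e-9:
            raise ValueError("explained fractions exceed 1")


def pairwise_distance(m: FragmentMatrix, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise distances between line profiles of a FragmentMatrix.

    jaccard: 1 − a/(a+b+c); dice: 1 − 2a/(2a+b+c); simple_matching:
    1 − (a+d)/(a+b+c+d), with a,b,c,d the 2×2 fragment table over jointly
    non-missing fragments of each line pair.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    X = m.calls.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two lines for pairwise distances")
    P = np.nan_to_num(X, nan=0.0)          # presence, missing as 0
    A = (~np.isnan(X)).astype(float)       # non-missing mask
    a = P @ P.T
    ab = P @ A.T                           # i present, j scored
    ac = A @ P.T                           # j present, i scored
    joint = A @ A.T
    b = ab - a
    c = ac - a
    d = joint - a - b - c

    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "jaccard":
            denom = a + b + c
            sim = np.where(denom > 0, a / np.where(denom > 0, denom, 1), 1.0)
        elif metric == "dice":
            denom = 2 * a + b + c
            sim = np.where(denom > 0, 2 * a / np.where(denom > 0, denom, 1), 1.0)
        else:
            sim = np.where(joint > 0, (a + d) / np.where(joint > 0, joint, 1), 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)

    undefined = []
    ids = m.lines
    for i, j in zip(*np.nonzero(joint == 0)):
        if i < j:
            undefined.append((ids[i], ids[j]))
            dist[i, j] = dist[j, i] = 0.0
    if undefined:
        logger.warning("%d line pairs share no scored fragment", len(undefined))
    return DistanceMatrix(list(ids), dist, undefined)


def pcoa(dm: DistanceMatrix, k: int = 3) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Coordinates come from the top-k nonnegative eigenvalues of the
    double-centred −½D² matrix; explained fractions are eigenvalue / sum of
    positive eigenvalues.  An all-zero distance matrix yields all-zero
    coordinates with explained fractions reported as 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dm.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.where(np.abs(vals) < 1e-10, 0.0, vals)
    pos_sum = vals[vals > 0].sum()
    k = min(k, n)
    coords = np.zeros((n, k))
    explained = np.zeros(k)
    if pos_sum > 0:
        for axis in range(k):
            if vals[axis] > 0:
                coords[:, axis] = vecs[:, axis] * np.sqrt(vals[axis])
                explained[axis] = vals[axis] / pos_sum
    else:
        logger.warning("degenerate distance matrix: all coordinates zero")
    cols = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        pd.DataFrame(coords, index=dm.ids, columns=cols),
        vals,
        explained,
        n_negative=int((vals < 0).sum()),
    )


@dataclass
class SpeciesSpecificCounts:
    """Polymorphic fragment totals and per-group species-specific counts."""

    n_polymorphic: int
    n_specific: dict[str, int]
    specific_fragments: dict[str, list[str]] = field(default_factory=dict)


def count_species_specific(
    m: FragmentMatrix,
    group_of_line: Mapping[str, str],
    excluded_lines: Sequence[str] = (),
) -> SpeciesSpecificCounts:
    """Count fragments polymorphic overall and specific to each of two groups.

    A fragment is specific to group 1 when present in ≥1 group-1 line and
    absent in every non-excluded group-2 line (missing calls are ignored);
    excluded lines — e.g. intermediate accessions carrying both species'
    fragments — are removed before counting.  Symmetric for group 2.
    """
    excluded = set(excluded_lines)
    groups = sorted({g for l, g in group_of_line.items() if l not in excluded})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups after exclusions, got {groups}")
    lines_of = {
        g: [l for l in m.lines if l not in excluded and group_of_line.get(l) == g]
        for g in groups
    }
    for g, ls in lines_of.items():
        if not ls:
            raise ValueError(f"group {g!r} empty after exclusions")

    calls = m.calls
    sub = calls.loc[lines_of[groups[0]] + lines_of[groups[1]]]
    present_any = (sub == 1).any(axis=0)
    absent_any = (sub == 0).any(axis=0)
    polymorphic = present_any & absent_any

    specific: dict[str, list[str]] = {g: [] for g in groups}
    for g_own, g_other in ((groups[0], groups[1]), (groups[1], groups[0])):
        own = calls.loc[lines_of[g_own]]
        other = calls.loc[lines_of[g_other]]
        mask = ((own == 1).any(axis=0)) & (~(other == 1).any(axis=0)) & polymorphic
        specific[g_own] = list(calls.columns[mask])
    return SpeciesSpecificCounts(
        int(polymorphic.sum()),
        {g: len(v) for g, v in specific.items()},
        specific,
    )
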