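"""Two-point linkage estimation for F2 populations and the Kosambi function.

Recombination fractions are estimated by maximum likelihood: EM over the
double-heterozygote phase ambiguity for codominant marker pairs, and direct
1-D likelihood maximisation under the dominant two-locus class probabilities
for presence/absence pairs (coupling: P(both absent) = (1−r)²/4,
P(one absent) = (1−(1−r)²)/4 each, P(both present) = (2+(1−r)²)/4; repulsion
replaces (1−r)² by r²).  LOD scores compare the likelihood at r̂ against
independence (r = 0.5).  Grouping scans recombination-fraction thresholds
from loose to strict, forming single-linkage connected components over pairs
passing both an rf and a LOD gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TwoPointEstimate",
    "LinkageSubgroup",
    "estimate_rf_codominant",
    "estimate_rf_dominant",
    "group_loci",
    "kosambi_cM",
    "kosambi_inverse",
]

EM_TOL = 1e-8
EM_MAX_ITER = 500
_LN10 = math.log(10.0)


@dataclass
class TwoPointEstimate:
    """Maximum-likelihood two-point result for one marker pair."""

    locus_a: str
    locus_b: str
    r_hat: float
    lod: float
    phase: str  # coupling | repulsion | unknown
    n_informative: int
    at_boundary: bool = False
    low_information: bool = False

    def __post_init__(self):
        if not 0.0 <= self.r_hat <= 0.5:
            raise ValueError("r_hat outside [0, 0.5]")


@dataclass(frozen=True)
class LinkageSubgroup:
    """Markers mutually connected at a given rf threshold and LOD gate."""

    members: frozenset[str]
    formed_at_rf: float
    min_lod: float


# ----------------------------------------------------------------------
# codominant (3x3) estimation
# ----------------------------------------------------------------------

# donor-allele dose classes 0/1/2 at each locus; recombinant gamete count of
# each class is fixed except for the double heterozygote (1,1)
_REC_GAMETES = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)


def _codominant_class_probs(r: float) -> np.ndarray:
    """3x3 F2 genotype class probabilities for a coupling-phase F1 (AB/ab)."""
    # gamete haplotype frequencies: parental (1-r)/2 each, recombinant r/2 each
    hap = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2, (0, 1): r / 2, (1, 0): r / 2}
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in hap.items():
        for (a2, b2), p2 in hap.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


def _loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(np.where(probs > 0, probs, 1e-300))
    return float((counts[mask] * lp[mask]).sum())


def estimate_rf_codominant(counts) -> TwoPointEstimate:
    """Estimate r from a 3×3 two-locus F2 genotype table (donor-dose order
    0,1,2 on both axes).

    EM: all classes except the double heterozygote carry a known number of
    recombinant gametes; the (1,1) class is split between the parental
    (AB/ab) and recombinant (Ab/aB) phase configurations at their posterior
    ratio.  Falls back to a 0.001 grid search on non-convergence.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype count table")
    n = counts.sum()
    if n < 1:
        raise ValueError("empty genotype table")

    fixed_rec = float((counts * _REC_GAMETES).sum())  # (1,1) weight is 0
    n11 = counts[1, 1]
    r = 0.25
    converged = False
    for _ in range(EM_MAX_ITER):
        # posterior expected recombinant gametes in the ambiguous class
        denom = (1 - r) ** 2 + r ** 2
        e11 = 0.0 if denom == 0 else 2 * r ** 2 / denom
        r_new = (fixed_rec + n11 * e11) / (2 * n)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < EM_TOL:
            r = r_new
            converged = True
            break
        r = r_new
    ll_hat = _loglik(counts, _codominant_class_probs(r))
    if not converged:
        converged_ll = -np.inf
    else:
        converged_ll = ll_hat
    # EM ascends monotonically but a coarse probe guards the rare case of a
    # boundary/plateau start; refine by fine grid only when it wins
    coarse = np.arange(0.0, 0.5 + 1e-12, 0.01)
    coarse_lls = [_loglik(counts, _codominant_class_probs(g)) for g in coarse]
    if not converged or max(coarse_lls) > converged_ll + 1e-9:
        grid = np.arange(0.0, 0.5 + 1e-12, 0.001)
        lls = [_loglik(counts, _codominant_class_probs(g)) for g in grid]
        r_grid = float(grid[int(np.argmax(lls))])
        if max(lls) > ll_hat + 1e-9:
            r = r_grid
            ll_hat = max(lls)
    ll_null = _loglik(counts, _codominant_class_probs(0.5))
    lod = max((ll_hat - ll_null) / _LN10, 0.0)
    return TwoPointEstimate(
        "a", "b", float(r), lod, "coupling", int(n),
        at_boundary=r in (0.0, 0.5),
    )


# ----------------------------------------------------------------------
# dominant (2x2) estimation
# ----------------------------------------------------------------------

def dominant_class_probs(r: float, phase: str) -> np.ndarray:
    """2×2 F2 class probabilities for dominant pairs, indexed
    [A present?][B present?] with row/col 0 = present, 1 = absent."""
    k = (1 - r) ** 2 if phase == "coupling" else r ** 2
    return np.array([[(2 + k) / 4, (1 - k) / 4], [(1 - k) / 4, k / 4]])


def _fit_dominant_phase(counts: np.ndarray, phase: str) -> tuple[float, float]:
    def nll(r):
        return -_loglik(counts, dominant_class_probs(r, phase))

    res = minimize_scalar(nll, bounds=(0.0, 0.5), method="bounded",
                          options={"xatol": 1e-10})
    r = float(np.clip(res.x, 0.0, 0.5))
    # the bounded optimiser never lands exactly on the ends; probe them
    cands = [(r, -nll(r)), (0.0, -nll(0.0)), (0.5, -nll(0.5))]
    r, ll = max(cands, key=lambda t: t[1])
    return r, ll


def estimate_rf_dominant(counts, phase: str = "unknown") -> TwoPointEstimate:
    """Estimate r from a 2×2 presence/absence table of two dominant markers
    in an F2 ([A present][B present] in row/col 0).

    With ``phase='unknown'`` both phase models are maximised and the
    higher-likelihood one is returned; an exact tie yields phase
    ``'unknown'`` (such pairs carry no usable phase signal).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 presence/absence table")
    n = counts.sum()
    if n < 1:
        raise ValueError("empty presence/absence table")

    if phase in ("coupling", "repulsion"):
        r, ll = _fit_dominant_phase(counts, phase)
        best_phase = phase
    elif phase == "unknown":
        rc, llc = _fit_dominant_phase(counts, "coupling")
        rr, llr = _fit_dominant_phase(counts, "repulsion")
        if abs(llc - llr) < 1e-9:
            best_phase, r, ll = "unknown", rc if llc >= llr else rr, max(llc, llr)
        elif llc > llr:
            best_phase, r, ll = "coupling", rc, llc
        else:
            best_phase, r, ll = "repulsion", rr, llr
    else:
        raise ValueError(f"unknown phase {phase!r}")

    null_ll = _loglik(counts, dominant_class_probs(0.5, "coupling"))
    lod = max((ll - null_ll) / _LN10, 0.0)
    low_info = bool((counts > 0).sum() == 1 and n < 10)
    return TwoPointEstimate(
        "a", "b", r, lod, best_phase, int(n),
        at_boundary=r in (0.0, 0.5), low_information=low_info,
    )


# ----------------------------------------------------------------------
# grouping
# ----------------------------------------------------------------------

def group_loci(
    estimates: Iterable[TwoPointEstimate],
    markers: Sequence[str] | None = None,
    rf_start: float = 0.250,
    rf_end: float = 0.050,
    rf_step: float = 0.050,
    min_lod: float = 3.0,
) -> dict[float, list[LinkageSubgroup]]:
    """Single-linkage grouping over a descending rf threshold scan.

    For each threshold from ``rf_start`` down to ``rf_end`` in steps of
    ``rf_step``, markers joined by an edge with r̂ ≤ threshold and
    LOD ≥ ``min_lod`` fall in one subgroup.  The result is the nested
    grouping trajectory (stricter thresholds refine looser ones).
    """
    estimates = list(estimates)
    nodes = set(markers or ())
    for e in estimates:
        nodes.update((e.locus_a, e.locus_b))
    thresholds = np.arange(rf_start, rf_end - 1e-9, -rf_step)
    out: dict[float, list[LinkageSubgroup]] = {}
    for thr in thresholds:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            (e.locus_a, e.locus_b)
            for e in estimates
            if e.r_hat <= thr + 1e-12 and e.lod >= min_lod
        )
        out[round(float(thr), 6)] = [
            LinkageSubgroup(frozenset(c), round(float(thr), 6), min_lod)
            for c in nx.connected_components(g)
        ]
    return out


# ----------------------------------------------------------------------
# Kosambi mapping function
# ----------------------------------------------------------------------

def kosambi_cM(r: float) -> float:
    """Map a recombination fraction to Kosambi cM: d = 25·ln((1+2r)/(1−2r))."""
    if not 0.0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    # 25·ln((1+2r)/(1−2r)) = 50·atanh(2r); atanh keeps precision near 0
    return 50.0 * math.atanh(2.0 * r)


def kosambi_inverse(d_cM: float) -> float:
    """Inverse Kosambi: r = 0.5·tanh(2d/100)."""
    if d_cM < 0:
        raise ValueError("distance must be nonnegative")
    return 0.5 * math.tanh(d_cM / 50.0)
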