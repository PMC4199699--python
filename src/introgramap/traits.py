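"""Fertility arithmetic, fertility distributions, and the transgressive test.

Fertility of a cross is seeds set over florets available (2 florets per
spikelet by convention), as a percentage.  The transgressive test follows
the classical one-way ANOVA / pooled-error protocol: for each trait, the
residual mean square over all entries gives a general standard error; each
introgression line is compared to the better parent with a pooled-SE t-test
on the ANOVA residual degrees of freedom, one-sided for "greater than the
best parent", while the two parents are compared two-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FertilityRecord, TraitTable

logger = logging.getLogger("introgramap")

__all__ = [
    "FertilitySummary",
    "TraitTestResult",
    "TransgressiveResult",
    "fertility_percent",
    "fertility_histogram",
    "transgressive_test",
]


def fertility_percent(rec: FertilityRecord) -> float:
    """Percent fertility: 100 × seeds / (florets_per_spikelet × spikelets),
    reported to one decimal."""
    if rec.n_spikelets == 0:
        raise ValueError("cannot compute fertility with zero spikelets")
    pct = 100.0 * rec.n_seeds / (rec.florets_per_spikelet * rec.n_spikelets)
    return round(pct, 1)


@dataclass
class FertilitySummary:
    """Decile histogram of fertility percentages with mode class(es)."""

    mean: float
    histogram: dict[tuple[float, float], int]
    mode_class: list[tuple[float, float]]
    bimodal: bool

    @property
    def percent(self) -> float:
        return self.mean


def fertility_histogram(values, bin_width: float = 10.0) -> FertilitySummary:
    """Bin fertility percentages into [0,10), …, [90,100] classes.

    The top bin is closed so 100% falls in (90, 100].  All bins sharing the
    maximal count are reported as mode classes; two or more set the bimodal
    flag.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no fertility values")
    if np.any((values < 0) | (values > 100)):
        raise ValueError("fertility percentages must be within [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the top bin
    hist = {(float(edges[i]), float(edges[i + 1])): int(counts[i])
            for i in range(len(counts))}
    peak = max(hist.values())
    modes = [b for b, c in hist.items() if c == peak]
    return FertilitySummary(float(values.mean()), hist, modes, len(modes) >= 2)


@dataclass
class TraitTestResult:
    """Per-trait outcome of the transgressive analysis."""

    trait: str
    parent_means: dict[str, float]
    best_parent: str
    parents_p_two_sided: float
    pooled_se: float
    df_resid: int
    line_stats: pd.DataFrame  # line, mean, n, t, p_one_sided, transgressive
    n_transgressive: int
    skipped: bool = False
    warning: str = ""


@dataclass
class TransgressiveResult:
    per_trait: dict[str, TraitTestResult] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {t: r.n_transgressive for t, r in self.per_trait.items()}


def transgressive_test(
    table: TraitTable,
    parent_ids: tuple[str, str],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> TransgressiveResult:
    """Count lines significantly exceeding the best parent, per trait.

    One-way ANOVA across all entries yields the pooled within-entry mean
    square; each line's t statistic against the best (larger-mean) parent is
    (mean_line − mean_parent) / (s_pooled √(1/n_line + 1/n_parent)) on the
    ANOVA residual degrees of freedom.  Traits with zero residual degrees of
    freedom, or zero pooled variance, are skipped with a warning.
    """
    pa, pb = parent_ids
    result = TransgressiveResult()
    for trait in table.traits:
        reps = {e: table.replicates(e, trait) for e in table.entries}
        reps = {e: v for e, v in reps.items() if v.size > 0}
        if pa not in reps or pb not in reps:
            raise ValueError(f"parents {parent_ids} missing for trait {trait!r}")
        n_total = sum(v.size for v in reps.values())
        k = len(reps)
        df_resid = n_total - k
        if df_resid <= 0:
            logger.warning("trait %s: zero residual degrees of freedom, skipped", trait)
            result.per_trait[trait] = TraitTestResult(
                trait, {pa: float(np.mean(reps[pa])), pb: float(np.mean(reps[pb]))},
                pa, np.nan, np.nan, df_resid, pd.DataFrame(), 0,
                skipped=True, warning="zero residual degrees of freedom",
            )
            continue
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in reps.values())
        mse = ss_within / df_resid
        s = math.sqrt(mse)
        warning = ""
        if mse == 0:
            warning = "zero pooled variance: no line can be declared transgressive"
            logger.warning("trait %s: %s", trait, warning)

        means = {e: float(v.mean()) for e, v in reps.items()}
        best = pa if means[pa] >= means[pb] else pb
        n_best = reps[best].size

        # parent vs parent, two-sided on the pooled error
        if mse > 0:
            t_pp = (means[pa] - means[pb]) / (s * math.sqrt(1 / reps[pa].size + 1 / reps[pb].size))
            p_pp = float(2 * stats.t.sf(abs(t_pp), df_resid))
        else:
            p_pp = 1.0 if means[pa] == means[pb] else 0.0

        lines = [e for e in reps if e not in (pa, pb)]
        thr = alpha / max(len(lines), 1) if bonferroni else alpha
        rows = []
        for e in lines:
            n_e = reps[e].size
            if mse > 0:
                t_e = (means[e] - means[best]) / (s * math.sqrt(1 / n_e + 1 / n_best))
                p_e = float(stats.t.sf(t_e, df_resid))  # one-sided: greater
            else:
                t_e, p_e = 0.0, 1.0
            rows.append((e, means[e], n_e, t_e, p_e, p_e < thr))
        line_stats = pd.DataFrame(
            rows, columns=["line", "mean", "n", "t", "p_one_sided", "transgressive"]
        )
        result.per_trait[trait] = TraitTestResult(
            trait, {pa: means[pa], pb: means[pb]}, best, p_pp, s, df_resid,
            line_stats, int(line_stats["transgressive"].sum()), warning=warning,
        )
    return result
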