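"""Macrocolinearity comparison of two linkage maps sharing locus names.

Shared loci are matched by exact name.  Each is classified homeologous when
its linkage group in map B is the declared homeolog of its group in map A
(identity 1→1 … 7→7 by default, the two A genomes sharing chromosome
numbering), otherwise non-homeologous — the translocation signal.  For each
homeologous chromosome pair a Kendall tau rank concordance over the shared
loci summarises within-chromosome marker-order conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import LinkageMap

logger = logging.getLogger("introgramap")

__all__ = ["ColinearityTable", "compare_maps"]


@dataclass
class ColinearityTable:
    """Per-locus classification plus per-chromosome summaries."""

    table: pd.DataFrame          # locus, group_a, position_a, group_b, position_b, klass
    per_chromosome: pd.DataFrame  # group_a, n_shared, n_homeologous, n_non_homeologous, tau
    excluded_loci: list[str]

    @property
    def n_homeologous(self) -> int:
        return int((self.table["klass"] == "homeologous").sum())

    @property
    def n_non_homeologous(self) -> int:
        return int((self.table["klass"] == "non_homeologous").sum())


def compare_maps(
    map_a: LinkageMap,
    map_b: LinkageMap,
    homeology: dict[int, int] | None = None,
) -> ColinearityTable:
    """Classify every shared locus of two maps as homeologous or not.

    ``homeology`` maps group-in-A → homeologous group-in-B (identity by
    default).  Loci present twice in either map never arise (map invariant);
    loci missing from one map are simply not shared.  Raises when the maps
    share no locus.
    """
    names_a = {l.name for l in map_a.loci()}
    names_b = {l.name for l in map_b.loci()}
    shared = sorted(names_a & names_b)
    if not shared:
        raise ValueError("maps share no locus name")
    if homeology is None:
        homeology = {g: g for g in map_a.groups}

    rows = []
    for name in shared:
        la, lb = map_a.locus(name), map_b.locus(name)
        klass = ("homeologous"
                 if homeology.get(la.linkage_group) == lb.linkage_group
                 else "non_homeologous")
        rows.append((name, la.linkage_group, la.position_cM,
                     lb.linkage_group, lb.position_cM, klass))
    table = pd.DataFrame(
        rows, columns=["locus", "group_a", "position_a", "group_b", "position_b", "klass"]
    )

    summary = []
    for g, sub in table.groupby("group_a"):
        hom = sub[sub["klass"] == "homeologous"]
        tau = np.nan
        if len(hom) >= 2 and hom["position_a"].nunique() > 1 and hom["position_b"].nunique() > 1:
            tau = float(stats.kendalltau(hom["position_a"], hom["position_b"]).statistic)
        summary.append((g, len(sub), len(hom), len(sub) - len(hom), tau))
    per_chrom = pd.DataFrame(
        summary,
        columns=["group_a", "n_shared", "n_homeologous", "n_non_homeologous", "tau"],
    )
    return ColinearityTable(table, per_chrom, [])
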