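"""Introgression-line panel construction and coverage accounting.

Donor segments are called from codominant (SSR-like) fingerprints as maximal
runs of donor-carrying calls, with segment borders placed at the midpoint
between the outermost donor locus and the nearest flanking recurrent-type
locus (terminal runs extend to the linkage-group end).  Missing calls bridge
a run up to a configurable cM gap.  Panel selection is greedy
maximum-new-coverage; coverage reports give per-group covered cM, fragment
counts and percentages against the backbone map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import LinkageMap, SSRGenotypeMatrix

__all__ = [
    "Segment",
    "IntrogressionLine",
    "PanelReport",
    "call_donor_segments",
    "call_panel",
    "select_nonredundant",
    "coverage_report",
    "interval_union_length",
]


@dataclass(frozen=True)
class Segment:
    linkage_group: int
    start_cM: float
    end_cM: float
    zygosity: str  # homozygous_donor | heterozygous

    def __post_init__(self):
        if self.end_cM < self.start_cM:
            raise ValueError("segment end before start")
        if self.zygosity not in ("homozygous_donor", "heterozygous"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def length(self) -> float:
        return self.end_cM - self.start_cM


@dataclass
class IntrogressionLine:
    """One line's donor segments; the unit of panel selection."""

    line_id: str
    segments: list[Segment]
    generation: str = ""
    uncalled_groups: list[int] = field(default_factory=list)

    def n_segments(self) -> int:
        return len(self.segments)

    def segments_on(self, group: int) -> list[Segment]:
        return [s for s in self.segments if s.linkage_group == group]


def interval_union_length(intervals: Iterable[tuple[float, float]]) -> float:
    """Total length of the union of closed cM intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    total, cur_s, cur_e = 0.0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def call_donor_segments(
    calls: Mapping[str, object] | pd.Series,
    gmap: LinkageMap,
    line_id: str = "",
    max_gap_cM: float = 20.0,
    generation: str = "",
) -> IntrogressionLine:
    """Call donor segments for one line from its codominant fingerprint.

    ``calls`` maps backbone locus name → RR/DD/RD/missing.  Maximal runs of
    donor calls (DD or RD) become segments; missing calls are bridged up to
    ``max_gap_cM`` between donor loci, beyond which the run splits.  A
    segment is heterozygous when any of its loci is RD.  Groups with no
    scored locus are reported uncalled.
    """
    calls = dict(calls) if not isinstance(calls, pd.Series) else calls.to_dict()
    segments: list[Segment] = []
    uncalled: list[int] = []
    for g in gmap.groups:
        loci = [(l.position_cM, str(calls.get(l.name)) if not pd.isna(calls.get(l.name)) else None)
                for l in gmap.groups[g]]
        scored = [(p, c) for p, c in loci if c in ("RR", "DD", "RD")]
        if not scored:
            uncalled.append(g)
            continue
        lo, hi = gmap.group_span(g)
        runs: list[list[tuple[float, str]]] = []
        for p, c in scored:
            if c == "RR":
                continue
            if runs and runs[-1] and p - runs[-1][-1][0] <= max_gap_cM:
                # same run unless an RR call sits between the donor calls
                prev_p = runs[-1][-1][0]
                broken = any(prev_p < q < p and cc == "RR" for q, cc in scored)
                if broken:
                    runs.append([])
            elif runs and runs[-1]:
                runs.append([])
            if not runs:
                runs.append([])
            runs[-1].append((p, c))
        for idx, run in enumerate(runs):
            if not run:
                continue
            first, last = run[0][0], run[-1][0]
            # flank = nearest recurrent-type locus, or the neighbouring run's
            # donor locus when a gap split leaves no RR call between runs
            left = [p for p, c in scored if c == "RR" and p < first]
            if idx > 0:
                left.append(runs[idx - 1][-1][0])
            right = [p for p, c in scored if c == "RR" and p > last]
            if idx + 1 < len(runs):
                right.append(runs[idx + 1][0][0])
            start = 0.5 * (max(left) + first) if left else lo
            end = 0.5 * (min(right) + last) if right else hi
            zyg = "heterozygous" if any(c == "RD" for _, c in run) else "homozygous_donor"
            segments.append(Segment(g, start, end, zyg))
    return IntrogressionLine(line_id, segments, generation, uncalled)


def call_panel(matrix: SSRGenotypeMatrix, gmap: LinkageMap,
               max_gap_cM: float = 20.0) -> list[IntrogressionLine]:
    """Call donor segments for every line of a codominant matrix."""
    return [
        call_donor_segments(matrix.calls.loc[lid], gmap, line_id=str(lid),
                            max_gap_cM=max_gap_cM)
        for lid in matrix.lines
    ]


def _new_coverage(line: IntrogressionLine,
                  covered: dict[int, list[tuple[float, float]]]) -> float:
    gain = 0.0
    for seg in line.segments:
        have = covered.get(seg.linkage_group, [])
        before = interval_union_length(have)
        after = interval_union_length(have + [(seg.start_cM, seg.end_cM)])
        gain += after - before
    return gain


def select_nonredundant(
    lines: Sequence[IntrogressionLine],
    single_fragment_only: bool = False,
    min_gain_cM: float = 1.0,
) -> list[IntrogressionLine]:
    """Greedy panel selection maximising newly covered cM per added line.

    Lines with two or more segments are excluded first when
    ``single_fragment_only`` is set (the nonredundant-panel convention:
    each line carries a single introgressed fragment).  Selection stops when
    no remaining line adds more than ``min_gain_cM``; ties break on
    lexicographic line id, so the result is deterministic.
    """
    pool = [l for l in lines if not (single_fragment_only and l.n_segments() >= 2)]
    covered: dict[int, list[tuple[float, float]]] = {}
    selected: list[IntrogressionLine] = []
    pool = sorted(pool, key=lambda l: l.line_id)
    while pool:
        gains = [(_new_coverage(l, covered), l) for l in pool]
        best_gain = max(g for g, _ in gains)
        if best_gain <= min_gain_cM:
            break
        best = min((l for g, l in gains if g == best_gain), key=lambda l: l.line_id)
        selected.append(best)
        pool.remove(best)
        for seg in best.segments:
            covered.setdefault(seg.linkage_group, []).append((seg.start_cM, seg.end_cM))
    return selected


@dataclass
class PanelReport:
    """Per-group and total coverage of a panel against the backbone map."""

    per_group: pd.DataFrame  # columns: group, covered_cM, n_fragments, percent_covered
    total_covered_cM: float
    total_length_cM: float
    total_fragments: int

    @property
    def total_percent(self) -> float:
        return round(100.0 * self.total_covered_cM / self.total_length_cM, 1)


def coverage_report(panel: Sequence[IntrogressionLine], gmap: LinkageMap) -> PanelReport:
    """Coverage of the union of panel segments, per linkage group.

    covered_cM is the length of the union of donor segments on the group;
    n_fragments counts segments; percent is covered/length × 100 to one
    decimal.
    """
    rows = []
    total_cov = total_frag = 0
    for g in gmap.groups:
        lo, hi = gmap.group_span(g)
        length = hi - lo
        segs = [s for l in panel for s in l.segments_on(g)]
        for s in segs:
            if s.start_cM < lo - 1e-9 or s.end_cM > hi + 1e-9:
                raise ValueError(
                    f"segment ({s.start_cM},{s.end_cM}) off group {g} span ({lo},{hi})"
                )
        cov = interval_union_length((s.start_cM, s.end_cM) for s in segs)
        pct = round(100.0 * cov / length, 1) if length else 0.0
        rows.append((g, round(cov, 4), len(segs), pct))
        total_cov += cov
        total_frag += len(segs)
    df = pd.DataFrame(rows, columns=["group", "covered_cM", "n_fragments",
                                     "percent_covered"])
    return PanelReport(df, float(total_cov), gmap.total_length_cM, int(total_frag))
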