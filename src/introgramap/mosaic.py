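"""Reconstruction of mosaic chromosome founders from dominant-fragment
segregation.

A selfed founder plant derived from a wide interspecific cross carries, on
each linkage group, two homologs that are mosaics of the two parental
genomes (Am / Au).  Its selfed offspring segregate for every
species-specific fragment sitting on exactly one homolog, while fragments
carried by both homologs (or neither) are monomorphic.  The pipeline:

1. assign each fragment to a species from reference parent profiles;
2. split fragments into monomorphic and segregating classes from their
   presence frequency in the offspring;
3. form linkage subgroups — runs of co-anchored fragments joined by
   two-point estimates passing an rf and LOD gate;
4. classify each subgroup: homozygous (one species only), heterozygous
   (both species, all Am–Au pairs in repulsion), or mosaic (Am and Au
   fragments in coupling on one homolog), with internal breakpoints counted
   as phase transitions along the anchored order;
5. assemble the anchored intervals into a founder painting and count
   homolog exchange (crossover) events.

Event multiplicity follows the homolog-level accounting: a boundary between
a homozygous and a heterozygous interval is one exchange, between the two
homozygous classes two exchanges (both homologs switch), and each internal
phase transition of a mixed subgroup is one exchange on the affected
homolog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import FragmentMatrix, LinkageMap
from .linkage import LinkageSubgroup, TwoPointEstimate, estimate_rf_dominant

logger = logging.getLogger("introgramap")

__all__ = [
    "Anchor",
    "SubgroupCall",
    "CrossoverEvent",
    "FounderReconstruction",
    "ConflictError",
    "assign_fragment_species",
    "anchor_subgroup",
    "classify_subgroup",
    "reconstruct_founder",
    "reconstruct_population",
]


class ConflictError(ValueError):
    """Raised when anchored intervals overlap with contradictory labels."""


@dataclass(frozen=True)
class Anchor:
    """Smallest closed backbone interval containing a subgroup's members."""

    linkage_group: int
    start_cM: float
    end_cM: float


@dataclass
class SubgroupCall:
    """A classified linkage subgroup with its backbone anchor.

    Invariants: heterozygous requires mixed composition with repulsion
    phase; mosaic requires mixed composition with coupling; single-species
    subgroups are homozygous for that species.
    """

    subgroup: LinkageSubgroup
    composition: str        # Am_only | Au_only | mixed
    phase_relation: str     # coupling | repulsion | not_applicable
    label: str              # homozygous_Am | homozygous_Au | heterozygous | mosaic | unresolved
    anchor: Anchor | None
    conflict: bool = False
    internal_breakpoints: list[float] = field(default_factory=list)

    def __post_init__(self):
        ok = {
            "homozygous_Am": self.composition == "Am_only",
            "homozygous_Au": self.composition == "Au_only",
            "heterozygous": self.composition == "mixed" and self.phase_relation == "repulsion",
            "mosaic": self.composition == "mixed" and self.phase_relation == "coupling",
            "unresolved": True,
        }
        if self.label not in ok or not ok[self.label]:
            raise ValueError(
                f"label {self.label!r} inconsistent with composition "
                f"{self.composition!r} / phase {self.phase_relation!r}"
            )


@dataclass(frozen=True)
class CrossoverEvent:
    """An inferred Am/Au exchange point: cM position and number of homolog
    switches it accounts for (1, or 2 when both homologs switch)."""

    linkage_group: int
    position_cM: float
    n_exchanges: int = 1


@dataclass
class FounderReconstruction:
    """Anchored founder painting plus homolog exchange events."""

    paintings: dict[int, list[tuple[float, float, str]]]  # label Am|Au|Het
    events: list[CrossoverEvent]
    crossover_events: dict[int, int]
    anchored_fraction: float


# ----------------------------------------------------------------------
# Step 1: species assignment
# ----------------------------------------------------------------------

def assign_fragment_species(
    parents: FragmentMatrix,
    am_references: Sequence[str],
    au_references: Sequence[str],
) -> dict[str, str]:
    """Label each fragment from reference parent profiles.

    Am_specific: present in ≥1 Am reference and in no Au reference (and
    symmetrically); present in both species → shared; scored present in no
    reference → unassigned.
    """
    if not am_references or not au_references:
        raise ValueError("need at least one reference line per species")
    calls = parents.calls
    missing = [l for l in (*am_references, *au_references) if l not in calls.index]
    if missing:
        raise ValueError(f"reference lines absent from matrix: {missing}")
    am = (calls.loc[list(am_references)] == 1).any(axis=0)
    au = (calls.loc[list(au_references)] == 1).any(axis=0)
    out = {}
    for f in parents.fragments:
        if am[f] and au[f]:
            out[f] = "shared"
        elif am[f]:
            out[f] = "Am_specific"
        elif au[f]:
            out[f] = "Au_specific"
        else:
            out[f] = "unassigned"
    return out


# ----------------------------------------------------------------------
# Step 2: anchoring
# ----------------------------------------------------------------------

def anchor_subgroup(
    sg: LinkageSubgroup,
    backbone: LinkageMap,
    anchor_names: Mapping[str, str],
) -> tuple[Anchor | None, bool]:
    """Anchor a subgroup to the backbone map.

    Returns (anchor, conflict).  The anchor is the smallest closed interval
    on one linkage group containing every anchored member; members anchoring
    to two or more groups flag a conflict (duplicated chromosome blocks are
    a real possibility in these genomes) and the subgroup stays unanchored.
    """
    positions: dict[int, list[float]] = {}
    for member in sg.members:
        locus_name = anchor_names.get(member)
        if locus_name is None or locus_name not in backbone:
            continue
        loc = backbone.locus(locus_name)
        positions.setdefault(loc.linkage_group, []).append(loc.position_cM)
    if not positions:
        return None, False
    if len(positions) > 1:
        logger.warning(
            "subgroup anchors to %d linkage groups %s: reported unanchored with conflict",
            len(positions), sorted(positions),
        )
        return None, True
    (group, pos), = positions.items()
    return Anchor(group, min(pos), max(pos)), False


# ----------------------------------------------------------------------
# Step 3: classification
# ----------------------------------------------------------------------

def classify_subgroup(
    members_ordered: Sequence[tuple[str, float]],
    species_of: Mapping[str, str],
    phases: Mapping[frozenset, str],
    anchor: Anchor | None,
    conflict: bool = False,
    subgroup: LinkageSubgroup | None = None,
) -> SubgroupCall:
    """Classify a subgroup from its species composition and pairwise phases.

    ``members_ordered`` lists (fragment, anchor position) along the backbone;
    ``phases`` maps frozenset({a, b}) of adjacent members to their inferred
    phase.  Mixed subgroups are phased into two homolog chains: coupling
    keeps a member on the current homolog, repulsion switches it.  Each
    species change along one homolog chain is an internal breakpoint (a
    crossover on that homolog); a mixed subgroup with no breakpoint is a
    heterozygous region.
    """
    members = [m for m, _ in members_ordered]
    sg = subgroup or LinkageSubgroup(frozenset(members), np.nan, np.nan)
    species = {species_of.get(m, "unassigned") for m in members}
    species &= {"Am_specific", "Au_specific"}

    if species == {"Am_specific"}:
        return SubgroupCall(sg, "Am_only", "not_applicable", "homozygous_Am",
                            anchor, conflict)
    if species == {"Au_specific"}:
        return SubgroupCall(sg, "Au_only", "not_applicable", "homozygous_Au",
                            anchor, conflict)
    if not species:
        return SubgroupCall(sg, "mixed", "not_applicable", "unresolved",
                            anchor, conflict)

    # mixed: walk adjacent pairs, maintaining the homolog sign of each member
    informative = [(m, p) for m, p in members_ordered
                   if species_of.get(m) in ("Am_specific", "Au_specific")]
    chains: list[list[tuple[str, float, int]]] = [[]]
    sign = 1
    for i, (m, p) in enumerate(informative):
        if i > 0:
            prev = informative[i - 1][0]
            ph = phases.get(frozenset((prev, m)))
            if ph == "coupling":
                pass
            elif ph == "repulsion":
                sign = -sign
            else:  # unknown or missing: phase chain breaks here
                chains.append([])
                sign = 1
        chains[-1].append((m, p, sign))

    if all(len(c) < 2 for c in chains):
        return SubgroupCall(sg, "mixed", "not_applicable", "unresolved",
                            anchor, conflict)

    breakpoints: list[float] = []
    any_cross_coupling = False
    for chain in chains:
        for s in (1, -1):
            on_hom = [(m, p) for m, p, sg_ in chain if sg_ == s]
            for (m1, p1), (m2, p2) in zip(on_hom, on_hom[1:]):
                if species_of[m1] != species_of[m2]:
                    breakpoints.append(0.5 * (p1 + p2))
                    any_cross_coupling = True

    if breakpoints:
        return SubgroupCall(sg, "mixed", "coupling", "mosaic", anchor, conflict,
                            internal_breakpoints=sorted(breakpoints))
    return SubgroupCall(sg, "mixed", "repulsion", "heterozygous", anchor, conflict)


# ----------------------------------------------------------------------
# Step 4: assembly
# ----------------------------------------------------------------------

_DIPLOTYPE = {
    "homozygous_Am": "Am",
    "homozygous_Au": "Au",
    "heterozygous": "Het",
    "mosaic": "Het",
}


def reconstruct_founder(
    calls: Sequence[SubgroupCall],
    backbone: LinkageMap,
) -> FounderReconstruction:
    """Assemble anchored subgroup calls into a founder painting.

    Anchored intervals are painted in map order; exchange events are counted
    between adjacent anchored intervals of different diplotype state (one
    exchange when one side is heterozygous, two between the opposite
    homozygous states) plus the internal breakpoints of mosaic subgroups.
    Unanchored or unresolved subgroups leave gaps which are excluded from
    both the painting and the event count.
    """
    by_group: dict[int, list[SubgroupCall]] = {}
    for c in calls:
        if c.anchor is not None and c.label in _DIPLOTYPE:
            by_group.setdefault(c.anchor.linkage_group, []).append(c)

    paintings: dict[int, list[tuple[float, float, str]]] = {}
    events: list[CrossoverEvent] = []
    for g in backbone.groups:
        group_calls = sorted(by_group.get(g, []),
                             key=lambda c: (c.anchor.start_cM, c.anchor.end_cM))
        # contradictory overlaps are an assembly error, not a warning
        for c1, c2 in zip(group_calls, group_calls[1:]):
            if c2.anchor.start_cM < c1.anchor.end_cM - 1e-9 and c1.label != c2.label:
                raise ConflictError(
                    f"group {g}: overlapping intervals "
                    f"({c1.anchor.start_cM},{c1.anchor.end_cM})={c1.label} and "
                    f"({c2.anchor.start_cM},{c2.anchor.end_cM})={c2.label}"
                )
        segs = []
        for c in group_calls:
            state = _DIPLOTYPE[c.label]
            if segs and segs[-1][2] == state and c.anchor.start_cM <= segs[-1][1] + 1e-9:
                segs[-1] = (segs[-1][0], max(segs[-1][1], c.anchor.end_cM), state)
            else:
                segs.append((c.anchor.start_cM, c.anchor.end_cM, state))
            for bp in c.internal_breakpoints:
                events.append(CrossoverEvent(g, bp, 1))
        paintings[g] = segs
        for c1, c2 in zip(group_calls, group_calls[1:]):
            s1, s2 = _DIPLOTYPE[c1.label], _DIPLOTYPE[c2.label]
            if s1 == s2:
                continue
            mult = 2 if {s1, s2} == {"Am", "Au"} else 1
            pos = 0.5 * (c1.anchor.end_cM + c2.anchor.start_cM)
            events.append(CrossoverEvent(g, pos, mult))

    total = backbone.total_length_cM
    painted = sum(e - s for segs in paintings.values() for s, e, _ in segs)
    per_group = {g: sum(ev.n_exchanges for ev in events if ev.linkage_group == g)
                 for g in backbone.groups}
    return FounderReconstruction(
        paintings, sorted(events, key=lambda e: (e.linkage_group, e.position_cM)),
        per_group, painted / total if total else 0.0,
    )


# ----------------------------------------------------------------------
# end-to-end pipeline
# ----------------------------------------------------------------------

def _dominant_pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2×2 joint presence table over jointly scored individuals."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok] == 1, y[ok] == 1
    return np.array([
        [np.sum(x & y), np.sum(x & ~y)],
        [np.sum(~x & y), np.sum(~x & ~y)],
    ], dtype=float)


def reconstruct_population(
    offspring: FragmentMatrix,
    species_of: Mapping[str, str],
    backbone: LinkageMap,
    anchor_names: Mapping[str, str],
    min_lod: float = 3.0,
    rf_link: float = 0.25,
    mono_tol: float = 0.02,
) -> tuple[FounderReconstruction, list[SubgroupCall]]:
    """Reconstruct the founder of a selfed segregating population.

    ``offspring`` is the dominant fragment matrix of the population,
    ``species_of`` the fragment species labels (from
    :func:`assign_fragment_species`), ``anchor_names`` the fragment→backbone
    locus anchoring.  Fragments present in (almost) every line are
    monomorphic evidence of homozygous regions; segregating fragments are
    grouped by adjacent two-point linkage (r̂ ≤ ``rf_link``, LOD ≥
    ``min_lod``) and classified by their phase structure.
    """
    freq = offspring.presence_fraction()
    calls_arr = offspring.calls

    # order informative anchored fragments along each group
    per_group: dict[int, list[tuple[float, str]]] = {}
    for f in offspring.fragments:
        sp = species_of.get(f, "unassigned")
        if sp not in ("Am_specific", "Au_specific"):
            continue
        locus_name = anchor_names.get(f)
        if locus_name is None or locus_name not in backbone:
            continue
        loc = backbone.locus(locus_name)
        per_group.setdefault(loc.linkage_group, []).append((loc.position_cM, f))

    subgroup_calls: list[SubgroupCall] = []
    for g, items in sorted(per_group.items()):
        items.sort()
        classified = []
        for pos, f in items:
            fr = freq.get(f, np.nan)
            if np.isnan(fr):
                continue
            if fr >= 1.0 - mono_tol:
                classified.append((pos, f, "mono"))
            elif fr <= mono_tol:
                continue  # fragment origin absent from founder: no direct evidence
            else:
                classified.append((pos, f, "seg"))

        # maximal runs of same class (mono runs also split on species change)
        runs: list[tuple[str, list[tuple[float, str]]]] = []
        for pos, f, cls in classified:
            if (not runs or runs[-1][0] != cls
                    or (cls == "mono" and species_of[runs[-1][1][-1][1]] != species_of[f])):
                runs.append((cls, []))
            runs[-1][1].append((pos, f))

        for cls, run in runs:
            if cls == "mono":
                members = [(f, p) for p, f in run]
                sg = LinkageSubgroup(frozenset(f for f, _ in members), rf_link, min_lod)
                anchor, conflict = anchor_subgroup(sg, backbone, anchor_names)
                subgroup_calls.append(
                    classify_subgroup(members, species_of, {}, anchor, conflict, sg)
                )
                continue
            # segregating run: estimate adjacent-pair linkage, split on gate failure
            pieces: list[list[tuple[float, str]]] = [[run[0]]]
            phases: dict[frozenset, str] = {}
            for (p1, f1), (p2, f2) in zip(run, run[1:]):
                est = estimate_rf_dominant(
                    _dominant_pair_counts(
                        calls_arr[f1].to_numpy(float), calls_arr[f2].to_numpy(float)
                    ),
                    phase="unknown",
                )
                if est.r_hat <= rf_link and est.lod >= min_lod:
                    phases[frozenset((f1, f2))] = est.phase
                    pieces[-1].append((p2, f2))
                else:
                    pieces.append([(p2, f2)])
            for piece in pieces:
                members = [(f, p) for p, f in piece]
                sg = LinkageSubgroup(frozenset(f for f, _ in members), rf_link, min_lod)
                anchor, conflict = anchor_subgroup(sg, backbone, anchor_names)
                subgroup_calls.append(
                    classify_subgroup(members, species_of, phases, anchor, conflict, sg)
                )

    recon = reconstruct_founder(subgroup_calls, backbone)
    return recon, subgroup_calls
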