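"""Forward simulator of wide interspecific crosses with known ground truth.

Emulates the genetics of a *T. monococcum* (A^m) × *T. urartu* (A^u) style
cross: two founder genomes on a 7-linkage-group map, meiosis with map-driven
crossovers (Poisson, no interference), selfing and backcross pedigrees,
per-region transmission distortion of the donor genome up to complete
elimination, and marker scoring with dominance masking for AFLP-like
fragments.  Every simulated individual carries its true chromosome painting,
so inference stages downstream can be validated against planted crossovers.

Origins are the two founder species, coded ``"Am"`` (recurrent side) and
``"Au"`` (donor side).  Codominant calls translate Am→R, Au→D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import FragmentMatrix, LinkageMap, MarkerLocus, SSRGenotypeMatrix, FertilityRecord

__all__ = [
    "ChromosomePainting",
    "DistortionModel",
    "PedigreeSpec",
    "PedigreeStep",
    "FertilityModel",
    "pure_painting",
    "simulate_gamete",
    "simulate_pedigree",
    "genotype_from_painting",
    "genotype_population",
    "simulate_fertility",
    "default_backbone_map",
    "dense_fragment_map",
    "fragment_loci_for_map",
]

ORIGINS = ("Am", "Au")

# A homolog is an ordered list of (start_cM, end_cM, origin) tiling [0, L].
Homolog = list[tuple[float, float, str]]


def _merge(segments: Homolog) -> Homolog:
    out: Homolog = []
    for s, e, o in segments:
        if out and out[-1][2] == o:
            out[-1] = (out[-1][0], e, o)
        else:
            out.append((s, e, o))
    return out


class ChromosomePainting:
    """True parental origin of both homologs of every linkage group.

    ``homologs[group]`` is a pair of segment lists, each tiling ``[0, length]``
    contiguously with alternating origins.  The derived diplotype collapses
    the pair into segments labelled ``Am`` / ``Au`` / ``Het``.
    """

    def __init__(self, homologs: Mapping[int, tuple[Homolog, Homolog]],
                 lengths: Mapping[int, float]):
        self.lengths = dict(lengths)
        self.homologs = {g: (_merge(list(h1)), _merge(list(h2)))
                         for g, (h1, h2) in homologs.items()}
        self.validate()

    def validate(self) -> None:
        for g, pair in self.homologs.items():
            L = self.lengths[g]
            for hom in pair:
                if not hom:
                    raise ValueError(f"empty homolog on group {g}")
                if abs(hom[0][0]) > 1e-9 or abs(hom[-1][1] - L) > 1e-9:
                    raise ValueError(f"homolog does not span [0, {L}] on group {g}")
                for (s1, e1, o1), (s2, e2, o2) in zip(hom, hom[1:]):
                    if abs(e1 - s2) > 1e-9:
                        raise ValueError(f"gap/overlap at {e1} on group {g}")
                    if o1 == o2:
                        raise ValueError(f"adjacent segments share origin on group {g}")
                for s, e, o in hom:
                    if e < s - 1e-12 or o not in ORIGINS:
                        raise ValueError(f"bad segment ({s},{e},{o}) on group {g}")

    # -- queries ---------------------------------------------------------
    def origin_at(self, group: int, pos: float, homolog: int) -> str:
        for s, e, o in self.homologs[group][homolog]:
            if s - 1e-9 <= pos <= e + 1e-9:
                return o
        raise ValueError(f"position {pos} outside group {group}")

    def diplotype(self, group: int) -> list[tuple[float, float, str]]:
        """Collapse the homolog pair into Am/Au/Het segments tiling the group."""
        h1, h2 = self.homologs[group]
        cuts = sorted({s for s, _, _ in h1} | {s for s, _, _ in h2}
                      | {self.lengths[group]})
        segs = []
        prev = 0.0
        for c in cuts:
            if c <= prev + 1e-12:
                continue
            mid = 0.5 * (prev + c)
            o1, o2 = self.origin_at(group, mid, 0), self.origin_at(group, mid, 1)
            state = o1 if o1 == o2 else "Het"
            segs.append((prev, c, state))
            prev = c
        out = []
        for s, e, st in segs:
            if out and out[-1][2] == st:
                out[-1] = (out[-1][0], e, st)
            else:
                out.append((s, e, st))
        return out

    def breakpoints(self, group: int) -> list[float]:
        """Positions of all homolog exchange (crossover) points on a group."""
        pts = []
        for hom in self.homologs[group]:
            pts.extend(e for _, e, _ in hom[:-1])
        return sorted(pts)

    def n_breakpoints(self) -> int:
        return sum(len(self.breakpoints(g)) for g in self.homologs)

    def origin_fraction(self, origin: str = "Au") -> float:
        """Length-weighted fraction of the diploid genome with the given origin."""
        tot = 2 * sum(self.lengths.values())
        if tot == 0:
            return 0.0
        am = sum(e - s for pair in self.homologs.values()
                 for hom in pair for s, e, o in hom if o == origin)
        return am / tot

    def heterozygous_fraction(self) -> float:
        tot = sum(self.lengths.values())
        het = sum(e - s for g in self.homologs
                  for s, e, st in self.diplotype(g) if st == "Het")
        return het / tot if tot else 0.0


def pure_painting(lengths: Mapping[int, float], origin: str) -> ChromosomePainting:
    """Fully homozygous founder genome of one species."""
    return ChromosomePainting(
        {g: ([(0.0, L, origin)], [(0.0, L, origin)]) for g, L in lengths.items()},
        lengths,
    )


@dataclass
class DistortionModel:
    """Per-region transmission probability of the donor (Au) origin.

    Each region is (linkage_group, start_cM, end_cM, donor_transmission_prob).
    A probability of 0 eliminates the donor origin there entirely; 0.5 is
    Mendelian.  Applied by rejection sampling of gametes, emulating gametic
    selection in interspecific hybrids.
    """

    regions: list[tuple[int, float, float, float]] = field(default_factory=list)

    def validate(self, lengths: Mapping[int, float]) -> None:
        for g, s, e, p in self.regions:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transmission probability {p} outside [0,1]")
            if g not in lengths or s < 0 or e > lengths[g] + 1e-9 or s > e:
                raise ValueError(f"distortion region ({g},{s},{e}) outside map")

    def by_group(self, group: int) -> list[tuple[float, float, float]]:
        return [(s, e, p) for g, s, e, p in self.regions if g == group]


def _lengths_from_map(gmap: LinkageMap) -> dict[int, float]:
    # simulation coordinates run [0, max position]; generated maps start at 0
    return {g: gmap.group_span(g)[1] for g in gmap.groups}


def _recombine(h1: Homolog, h2: Homolog, L: float, rng: np.random.Generator) -> Homolog:
    """One meiotic product: Poisson(L/100) crossovers, uniform positions."""
    n_xo = rng.poisson(L / 100.0)
    cuts = np.sort(rng.uniform(0.0, L, size=n_xo))
    cur = int(rng.integers(2))
    homs = (h1, h2)
    out: Homolog = []
    prev = 0.0
    for c in list(cuts) + [L]:
        if c > prev:
            for s, e, o in homs[cur]:
                lo, hi = max(s, prev), min(e, c)
                if hi > lo + 1e-12:
                    out.append((lo, hi, o))
        prev = c
        cur ^= 1
    return _merge(out)


def simulate_gamete(
    parent: ChromosomePainting,
    gmap: LinkageMap,
    distortion: DistortionModel | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 10000,
) -> dict[int, Homolog]:
    """Draw one gamete from a parent painting.

    Crossover counts per group are Poisson with mean group_length/100 (no
    interference), breakpoints uniform.  Under distortion, gametes carrying
    the donor origin at a region midpoint are accepted with odds p/(1−p)
    relative to non-carriers (rejection sampling), so from a heterozygous
    parent the donor origin is transmitted with the stated probability.
    """
    rng = np.random.default_rng() if rng is None else rng
    lengths = _lengths_from_map(gmap)
    if distortion is not None:
        distortion.validate(lengths)
    gamete: dict[int, Homolog] = {}
    for g, L in lengths.items():
        h1, h2 = parent.homologs[g]
        regions = distortion.by_group(g) if distortion else []
        for attempt in range(max_tries):
            hom = _recombine(h1, h2, L, rng)
            accept = 1.0
            for s, e, p in regions:
                mid = 0.5 * (s + e)
                carrier = _origin_on(hom, mid) == "Au"
                if p >= 0.5:
                    accept *= 1.0 if carrier else (1.0 - p) / p if p > 0 else 0.0
                else:
                    accept *= (p / (1.0 - p)) if carrier else 1.0
            if rng.random() < accept:
                gamete[g] = hom
                break
        else:
            raise RuntimeError(f"gamete rejection did not terminate on group {g}")
    return gamete


def _origin_on(hom: Homolog, pos: float) -> str:
    for s, e, o in hom:
        if s - 1e-9 <= pos <= e + 1e-9:
            return o
    raise ValueError(f"position {pos} off homolog")


def _child(mother: ChromosomePainting, father: ChromosomePainting,
           gmap: LinkageMap, distortion, rng) -> ChromosomePainting:
    gm = simulate_gamete(mother, gmap, distortion, rng)
    gf = simulate_gamete(father, gmap, distortion, rng)
    lengths = _lengths_from_map(gmap)
    return ChromosomePainting({g: (gm[g], gf[g]) for g in lengths}, lengths)


@dataclass
class PedigreeStep:
    """One pedigree operation: 'cross', 'self' or 'backcross'."""

    op: str  # cross | self | backcross
    n_generations: int = 1
    population_size: int = 1
    recurrent: str = "Am"  # backcross only

    def __post_init__(self):
        if self.op not in ("cross", "self", "backcross"):
            raise ValueError(f"unknown pedigree op {self.op!r}")
        if self.population_size < 1 or self.n_generations < 1:
            raise ValueError("population sizes and generation counts must be >= 1")


@dataclass
class PedigreeSpec:
    """Ordered pedigree starting from a cross of the two founder species."""

    steps: list[PedigreeStep]
    seed: int = 0

    def __post_init__(self):
        if not self.steps or self.steps[0].op != "cross":
            raise ValueError("pedigree must start with a cross of the two founders")


@dataclass
class PedigreePopulation:
    """Result of a pedigree simulation: final population plus per-step log."""

    paintings: list[ChromosomePainting]
    log: list[dict]
    generations: dict[str, list[ChromosomePainting]] = field(default_factory=dict)


def simulate_pedigree(
    spec: PedigreeSpec,
    gmap: LinkageMap,
    distortion: DistortionModel | None = None,
) -> PedigreePopulation:
    """Run a pedigree forward from the two pure founders.

    Selfing: each offspring takes two gametes from one parent drawn uniformly
    from the current population.  Backcrossing: one gamete from a current
    individual, one from the pure recurrent founder.  Reproducible given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _lengths_from_map(gmap)
    founders = {o: pure_painting(lengths, o) for o in ORIGINS}
    pop: list[ChromosomePainting] = []
    log: list[dict] = []
    generations: dict[str, list[ChromosomePainting]] = {}
    gen_label = ""
    for step in spec.steps:
        if step.op == "cross":
            pop = [
                _child(founders["Am"], founders["Au"], gmap, distortion, rng)
                for _ in range(step.population_size)
            ]
            gen_label = "F1"
        elif step.op == "self":
            for _ in range(step.n_generations):
                pop = [
                    _child(p, p, gmap, distortion, rng)
                    for p in (pop[rng.integers(len(pop))]
                              for _ in range(step.population_size))
                ]
                gen_label = _advance_self(gen_label)
        else:  # backcross
            rec = founders[step.recurrent]
            for _ in range(step.n_generations):
                pop = [
                    _child(pop[rng.integers(len(pop))], rec, gmap, distortion, rng)
                    for _ in range(step.population_size)
                ]
                gen_label = _advance_bc(gen_label)
        generations[gen_label] = pop
        log.append({
            "op": step.op,
            "n_generations": step.n_generations,
            "population_size": step.population_size,
            "generation": gen_label,
            "mean_donor_fraction": float(np.mean([p.origin_fraction("Au") for p in pop])),
        })
    return PedigreePopulation(pop, log, generations)


def _advance_self(label: str) -> str:
    if label.startswith("F") and label[1:].isdigit():
        return f"F{int(label[1:]) + 1}"
    return label + "S1" if not label.rpartition("S")[2].isdigit() else _bump(label, "S")


def _advance_bc(label: str) -> str:
    if label.rpartition("BC")[2].isdigit():
        return _bump(label, "BC")
    return label + "BC1"


def _bump(label: str, tag: str) -> str:
    head, _, num = label.rpartition(tag)
    return f"{head}{tag}{int(num) + 1}"


# ----------------------------------------------------------------------
# marker scoring
# ----------------------------------------------------------------------

def genotype_from_painting(
    painting: ChromosomePainting,
    markers: Sequence[MarkerLocus],
    species_of: Mapping[str, str] | None = None,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, object]:
    """Score one individual at the given markers.

    Codominant loci report RR/DD/RD from the two homolog origins (R=Am,
    D=Au).  Dominant fragments labelled Am_specific are present iff at least
    one homolog has Am origin at the fragment position (dominance masking);
    Au_specific symmetrically; shared fragments are always present.  Calls
    are flipped (dominant) or re-drawn (codominant) independently with
    probability ``error_rate``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    species_of = species_of or {}
    calls: dict[str, object] = {}
    for m in markers:
        if m.linkage_group not in painting.homologs:
            raise ValueError(f"marker {m.name} off-map group {m.linkage_group}")
        L = painting.lengths[m.linkage_group]
        if not -1e-9 <= m.position_cM <= L + 1e-9:
            raise ValueError(f"marker {m.name} at {m.position_cM} outside [0,{L}]")
        o1 = painting.origin_at(m.linkage_group, m.position_cM, 0)
        o2 = painting.origin_at(m.linkage_group, m.position_cM, 1)
        if m.system == "codominant":
            dose = (o1 == "Au") + (o2 == "Au")
            call = ("RR", "RD", "DD")[dose]
            if error_rate and rng.random() < error_rate:
                call = str(rng.choice([c for c in ("RR", "RD", "DD") if c != call]))
            calls[m.name] = call
        else:
            label = species_of.get(m.name, "shared")
            if label == "shared":
                present = 1.0
            elif label == "Am_specific":
                present = 1.0 if ("Am" in (o1, o2)) else 0.0
            elif label == "Au_specific":
                present = 1.0 if ("Au" in (o1, o2)) else 0.0
            else:
                present = np.nan
            if error_rate and not np.isnan(present) and rng.random() < error_rate:
                present = 1.0 - present
            calls[m.name] = present
    return calls


def genotype_population(
    paintings: Sequence[ChromosomePainting],
    markers: Sequence[MarkerLocus],
    species_of: Mapping[str, str] | None = None,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    line_ids: Sequence[str] | None = None,
):
    """Vectorised scoring of a whole population; returns FragmentMatrix or
    SSRGenotypeMatrix depending on the (uniform) marker system."""
    rng = np.random.default_rng() if rng is None else rng
    species_of = species_of or {}
    systems = {m.system for m in markers}
    if len(systems) != 1:
        raise ValueError("genotype_population needs a uniform marker system")
    system = systems.pop()
    line_ids = list(line_ids) if line_ids is not None else [
        f"L{i:04d}" for i in range(len(paintings))
    ]

    by_group: dict[int, list[MarkerLocus]] = {}
    for m in markers:
        by_group.setdefault(m.linkage_group, []).append(m)

    n, p = len(paintings), len(markers)
    col_of = {m.name: j for j, m in enumerate(markers)}
    dose = np.zeros((n, p), dtype=np.int8)  # donor (Au) allele dose 0/1/2
    for g, ms in by_group.items():
        pos = np.array([m.position_cM for m in ms])
        cols = np.array([col_of[m.name] for m in ms])
        for i, pt in enumerate(paintings):
            if g not in pt.homologs:
                raise ValueError(f"marker group {g} off painting")
            d = np.zeros(len(ms), dtype=np.int8)
            for hom in pt.homologs[g]:
                ends = np.array([e for _, e, _ in hom])
                origins = np.array([o == "Au" for _, _, o in hom])
                idx = np.minimum(np.searchsorted(ends, pos, side="left"), len(hom) - 1)
                d += origins[idx]
            dose[i, cols] = d

    if system == "codominant":
        lut = np.array(["RR", "RD", "DD"], dtype=object)
        calls = lut[dose]
        if error_rate:
            flip = rng.random((n, p)) < error_rate
            shift = rng.integers(1, 3, size=(n, p))
            calls = np.where(flip, lut[(dose + shift) % 3], calls)
        return SSRGenotypeMatrix(
            pd.DataFrame(calls, index=line_ids, columns=[m.name for m in markers])
        )

    present = np.ones((n, p))
    for j, m in enumerate(markers):
        label = species_of.get(m.name, "shared")
        if label == "Am_specific":
            present[:, j] = (dose[:, j] < 2).astype(float)   # >=1 Am homolog
        elif label == "Au_specific":
            present[:, j] = (dose[:, j] > 0).astype(float)   # >=1 Au homolog
        elif label == "unassigned":
            present[:, j] = np.nan
    if error_rate:
        flip = rng.random((n, p)) < error_rate
        present = np.where(flip & ~np.isnan(present), 1.0 - present, present)
    fm = FragmentMatrix(
        pd.DataFrame(present, index=line_ids, columns=[m.name for m in markers]),
        {m.name: species_of.get(m.name, "shared") for m in markers},
    )
    return fm


@dataclass
class FertilityModel:
    """Linear fertility penalty on donor genome dosage.

    Expected fertility = clamp(baseline − penalty × donor genome fraction,
    0, 1); seeds are binomial over florets (beta-binomial when
    ``dispersion`` > 0).  A stand-in model: the source study reports
    fertility empirically and gives no quantitative genotype–fertility law.
    """

    baseline: float = 0.9
    penalty: float = 0.9
    dispersion: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must be in [0,1]")


def simulate_fertility(
    painting: ChromosomePainting,
    model: FertilityModel,
    rng: np.random.Generator | None = None,
    n_spikelets: int = 100,
    florets_per_spikelet: int = 2,
    female: str = "sim_female",
    male: str = "sim_male",
) -> FertilityRecord:
    """Draw one fertility record for an individual painting."""
    rng = np.random.default_rng() if rng is None else rng
    frac = painting.origin_fraction("Au")
    f = float(np.clip(model.baseline - model.penalty * frac, 0.0, 1.0))
    n_florets = n_spikelets * florets_per_spikelet
    if model.dispersion > 0 and 0.0 < f < 1.0:
        a = f * (1.0 - model.dispersion) / model.dispersion
        b = (1.0 - f) * (1.0 - model.dispersion) / model.dispersion
        f = float(rng.beta(a, b))
    seeds = int(rng.binomial(n_florets, f))
    return FertilityRecord(female, male, n_spikelets, seeds, florets_per_spikelet)


# ----------------------------------------------------------------------
# bundled demo maps
# ----------------------------------------------------------------------

#: per-group SSR locus counts and cM spans of the demo backbone map
#: (seven linkage groups totalling exactly 984 cM, 155 loci)
BACKBONE_LOCUS_COUNTS = (23, 29, 22, 14, 30, 17, 20)
BACKBONE_LENGTHS_CM = (128.0, 208.2, 151.4, 75.8, 229.4, 85.3, 105.9)


def default_backbone_map() -> LinkageMap:
    """The bundled 155-locus, 984-cM SSR backbone map (7 linkage groups).

    Loci are evenly spaced within each group and named ``ssr<g>_<i>``.
    """
    loci = []
    for g, (n, L) in enumerate(zip(BACKBONE_LOCUS_COUNTS, BACKBONE_LENGTHS_CM), start=1):
        for i, pos in enumerate(np.linspace(0.0, L, n), start=1):
            loci.append(MarkerLocus(f"ssr{g}_{i:02d}", "codominant", g, float(pos)))
    return LinkageMap(loci)


def dense_fragment_map(spacing_cM: float = 2.0,
                       lengths: Sequence[float] = BACKBONE_LENGTHS_CM) -> LinkageMap:
    """A dense anchor map with codominant backbone loci every ``spacing_cM``."""
    loci = []
    for g, L in enumerate(lengths, start=1):
        n = int(np.floor(L / spacing_cM)) + 1
        pos = list(np.arange(n) * spacing_cM)
        if L - pos[-1] > 1e-9:
            pos.append(L)
        for i, p in enumerate(pos, start=1):
            loci.append(MarkerLocus(f"a{g}_{i:03d}", "codominant", g, float(p)))
    return LinkageMap(loci)


def fragment_loci_for_map(gmap: LinkageMap):
    """Species-specific dominant fragment pair co-located with every backbone
    locus: returns (fragment loci, species labels, fragment→anchor mapping)."""
    frags: list[MarkerLocus] = []
    species: dict[str, str] = {}
    anchors: dict[str, str] = {}
    for loc in gmap.loci():
        for sp, tag in (("Am_specific", "m"), ("Au_specific", "u")):
            name = f"f{tag}_{loc.name}"
            frags.append(MarkerLocus(name, "dominant", loc.linkage_group, loc.position_cM))
            species[name] = sp
            anchors[name] = loc.name
    return frags, species, anchors


# ----------------------------------------------------------------------
# output plumbing for the CLI
# ----------------------------------------------------------------------

def write_truth_paintings(paintings: Iterable[ChromosomePainting],
                          line_ids: Sequence[str], path: str | Path) -> None:
    rows = []
    for lid, pt in zip(line_ids, paintings):
        for g, pair in pt.homologs.items():
            for h, hom in enumerate(pair):
                for s, e, o in hom:
                    rows.append((lid, g, h, round(s, 4), round(e, 4), o))
    pd.DataFrame(rows, columns=["line", "group", "homolog", "start", "end", "origin"]
                 ).to_csv(path, sep="\t", index=False)


def write_pedigree_log(log: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2))
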