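"""Shared data model and tabular readers/writers.

The pipeline anchors everything to a genetic (linkage) map in centimorgans:
seven linkage groups for a diploid wheat A genome, real-valued positions,
closed intervals.  Marker systems are either *dominant* (AFLP-like
presence/absence fragments, heterozygote indistinguishable from the presence
homozygote) or *codominant* (SSR-like, three distinguishable genotypes).

File formats are plain TSV/CSV with the separator sniffed from the header
line.  Missing-data symbols are configurable; unknown symbols are mapped to
missing with a logged warning so no cell is silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("introgramap")

__all__ = [
    "MarkerLocus",
    "LinkageMap",
    "FragmentMatrix",
    "SSRGenotypeMatrix",
    "FertilityRecord",
    "TraitTable",
    "FormatError",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_fertility_records",
    "read_trait_table",
]

#: default symbols interpreted as missing data in genotype files
DEFAULT_MISSING = ("", "NA", "?", "-")

SPECIES_LABELS = ("Am_specific", "Au_specific", "shared", "unassigned")


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


@dataclass(frozen=True)
class MarkerLocus:
    """A mapped marker: name, marker system, linkage group and cM position."""

    name: str
    system: str  # "dominant" | "codominant"
    linkage_group: int
    position_cM: float

    def __post_init__(self):
        if self.system not in ("dominant", "codominant"):
            raise ValueError(f"unknown marker system {self.system!r}")
        if self.position_cM < 0:
            raise FormatError(f"negative map position for {self.name}")


class LinkageMap:
    """Ordered loci per linkage group; the cM coordinate backbone.

    Loci are stored sorted by position within each group.  Group length is
    the span ``max position − min position``; the total map length is the sum
    of group lengths.
    """

    def __init__(self, loci: Iterable[MarkerLocus]):
        groups: dict[int, list[MarkerLocus]] = {}
        seen: set[str] = set()
        for loc in loci:
            if loc.name in seen:
                raise FormatError(f"duplicate locus name {loc.name!r}")
            seen.add(loc.name)
            groups.setdefault(loc.linkage_group, []).append(loc)
        self.groups: dict[int, list[MarkerLocus]] = {
            g: sorted(v, key=lambda l: (l.position_cM, l.name))
            for g, v in sorted(groups.items())
        }
        self._by_name = {l.name: l for v in self.groups.values() for l in v}

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def locus(self, name: str) -> MarkerLocus:
        return self._by_name[name]

    def loci(self) -> list[MarkerLocus]:
        return [l for v in self.groups.values() for l in v]

    def group_span(self, group: int) -> tuple[float, float]:
        pos = [l.position_cM for l in self.groups[group]]
        return (min(pos), max(pos))

    def group_length(self, group: int) -> float:
        lo, hi = self.group_span(group)
        return hi - lo

    @property
    def lengths_cM(self) -> dict[int, float]:
        return {g: self.group_length(g) for g in self.groups}

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.lengths_cM.values()))

    def positions(self, group: int) -> np.ndarray:
        return np.array([l.position_cM for l in self.groups[group]])

    def marker_density_cM(self) -> float:
        """Average map interval per locus (total cM / number of loci)."""
        if not len(self):
            raise ValueError("empty map")
        return self.total_length_cM / len(self)

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (l.name, l.linkage_group, l.position_cM, l.system) for l in self.loci()
        ]
        return pd.DataFrame(rows, columns=["locus", "group", "position_cM", "system"])

    def __eq__(self, other) -> bool:
        return isinstance(other, LinkageMap) and self.to_frame().equals(other.to_frame())


def read_map(path: str | Path, default_system: str = "codominant") -> LinkageMap:
    """Read a linkage map from TSV/CSV with columns locus, group, position_cM."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"locus", "group", "position_cM"}
    if not required.issubset(df.columns):
        raise FormatError(f"map file needs columns {sorted(required)}")
    loci = []
    for row in df.itertuples(index=False):
        system = getattr(row, "system", default_system)
        if not isinstance(system, str):
            system = default_system
        loci.append(
            MarkerLocus(str(row.locus), system, int(row.group), float(row.position_cM))
        )
    return LinkageMap(loci)


def write_map(gmap: LinkageMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


class _GenotypeMatrix:
    """Common behaviour of lines × markers call matrices backed by pandas."""

    def __init__(self, calls: pd.DataFrame):
        self.calls = calls

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.calls.equals(other.calls)


class FragmentMatrix(_GenotypeMatrix):
    """Binary presence/absence calls for dominant fragments.

    ``calls`` holds 1.0 (present), 0.0 (absent) or NaN (missing).
    ``species_label`` maps each fragment to one of Am_specific / Au_specific /
    shared / unassigned — which parental species' genome carries the
    amplifiable allele.
    """

    def __init__(self, calls: pd.DataFrame, species_label: Mapping[str, str] | None = None):
        super().__init__(calls.astype(float))
        self.species_label: dict[str, str] = {
            f: (species_label or {}).get(f, "unassigned") for f in calls.columns
        }
        bad = set(self.species_label.values()) - set(SPECIES_LABELS)
        if bad:
            raise ValueError(f"unknown species labels {bad}")

    @property
    def fragments(self) -> list[str]:
        return self.markers

    def presence_fraction(self) -> pd.Series:
        """Fraction of non-missing calls that are 'present', per fragment."""
        return self.calls.mean(axis=0, skipna=True)


class SSRGenotypeMatrix(_GenotypeMatrix):
    """Codominant calls in {RR, DD, RD} (R recurrent, D donor) with NaN missing."""

    STATES = ("RR", "DD", "RD")

    def __init__(self, calls: pd.DataFrame):
        bad = set(calls.stack().dropna().unique()) - set(self.STATES)
        if bad:
            raise FormatError(f"invalid codominant calls {sorted(bad)}")
        super().__init__(calls)

    @property
    def loci(self) -> list[str]:
        return self.markers


#: default mapping from file symbols to internal calls
DOMINANT_SYMBOLS = {"1": 1.0, "0": 0.0}
CODOMINANT_SYMBOLS = {"A": "RR", "B": "DD", "H": "RD"}


def read_genotypes(
    path: str | Path,
    system: str,
    symbols: Mapping[str, object] | None = None,
    missing: Sequence[str] = DEFAULT_MISSING,
):
    """Read a lines × markers genotype file.

    First column is the line identifier, header row carries marker names.
    Unknown symbols become missing and are counted in a logged warning; the
    count is exposed on the returned matrix as ``unknown_symbol_count``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty genotype file {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    df.index = df.index.astype(str)
    if system == "dominant":
        table = dict(DOMINANT_SYMBOLS)
    elif system == "codominant":
        table = dict(CODOMINANT_SYMBOLS)
        table.update({s: s for s in SSRGenotypeMatrix.STATES})
    else:
        raise ValueError(f"unknown marker system {system!r}")
    if symbols:
        table.update(symbols)

    unknown = 0

    def convert(cell):
        nonlocal unknown
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        cell = str(cell).strip()
        if cell in missing:
            return np.nan
        if cell in table:
            return table[cell]
        unknown += 1
        return np.nan

    converted = df.map(convert)
    if unknown:
        logger.warning("%d unknown genotype symbols mapped to missing in %s", unknown, path)
    out = FragmentMatrix(converted) if system == "dominant" else SSRGenotypeMatrix(converted)
    out.unknown_symbol_count = unknown
    return out


def write_genotypes(matrix: _GenotypeMatrix, path: str | Path) -> None:
    df = matrix.calls
    if isinstance(matrix, FragmentMatrix):
        df = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    else:
        df = df.fillna("")
    df.to_csv(path, sep="\t")


@dataclass
class FertilityRecord:
    """Seed set of one cross: spikelets tested, seeds obtained.

    Fertility is seeds over available florets (``florets_per_spikelet`` per
    spikelet, 2 by convention for these wheats).  An over-count
    (seeds > florets) is flagged with a warning, not an error, since spikelet
    counts in crossing records are sometimes lower bounds.
    """

    female: str
    male: str
    n_spikelets: int
    n_seeds: int
    florets_per_spikelet: int = 2

    def __post_init__(self):
        if self.n_spikelets < 0 or self.n_seeds < 0:
            raise ValueError("negative counts in fertility record")
        if self.florets_per_spikelet <= 0:
            raise ValueError("florets_per_spikelet must be positive")
        if self.n_seeds > self.florets_per_spikelet * self.n_spikelets:
            logger.warning(
                "cross %s x %s: %d seeds exceed %d available florets",
                self.female, self.male, self.n_seeds,
                self.florets_per_spikelet * self.n_spikelets,
            )


def read_fertility_records(path: str | Path) -> list[FertilityRecord]:
    """Read fertility records from TSV/CSV with columns female, male, n_spikelets, n_seeds
    and optional florets_per_spikelet."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            FertilityRecord(
                str(row.female),
                str(row.male),
                int(row.n_spikelets),
                int(row.n_seeds),
                int(getattr(row, "florets_per_spikelet", 2)),
            )
        )
    return recs


@dataclass
class TraitTable:
    """Replicate trait measurements per entry (line or parent), long format.

    ``data`` has columns entry, trait, value — one row per replicate
    measurement, values in mg/kg dry matter.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        required = {"entry", "trait", "value"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"trait table needs columns {sorted(required)}")
        self.data = self.data.astype({"entry": str, "trait": str, "value": float})

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def entries(self) -> list[str]:
        return sorted(self.data["entry"].unique())

    def replicates(self, entry: str, trait: str) -> np.ndarray:
        sel = (self.data["entry"] == entry) & (self.data["trait"] == trait)
        return self.data.loc[sel, "value"].to_numpy()

    def mean(self, entry: str, trait: str) -> float:
        return float(self.replicates(entry, trait).mean())


def read_trait_table(path: str | Path) -> TraitTable:
    path = Path(path)
    return TraitTable(pd.read_csv(path, sep=_sniff_sep(path)))
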