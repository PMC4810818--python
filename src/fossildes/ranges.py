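"""Coding of fossil occurrences into binned observed geographic ranges.

A taxon's geographic history in a two-area system (areas ``A`` and ``B``)
is observed only through dated fossil occurrences and its present-day
range.  This module turns a table of occurrences (each with a
stratigraphic age range) plus present-day range codes into the taxa x
time-bin matrix of *observed* ranges that the likelihood consumes.

Observed codes per bin:

====  =========================================
code  meaning
====  =========================================
NA    lineage has not yet appeared in the record
0     observed empty (no occurrence in the bin;
      may be a true absence or a sampling gap)
1     sampled in A only
2     sampled in B only
3     sampled in both areas
====  =========================================

Ages are in Ma before present.  Bins are half-open ``[older, younger)``:
an occurrence exactly on a bin edge belongs to the *younger* bin; the
present (age 0) is the closed terminal point and carries the known
present-day range rather than a sampled code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AREAS",
    "CODE_NOT_YET",
    "CODE_EMPTY",
    "CODE_A",
    "CODE_B",
    "CODE_AB",
    "FossilOccurrence",
    "PresentRange",
    "TimeGrid",
    "ObservedRangeMatrix",
    "assign_point_ages",
    "build_time_grid",
    "code_ranges",
    "read_occurrences",
    "read_present_ranges",
]

AREAS = ("A", "B")

# observed / true range codes share the same integer alphabet; NA applies
# to observed codes only (before a lineage's first appearance)
CODE_NOT_YET = -1
CODE_EMPTY = 0
CODE_A = 1
CODE_B = 2
CODE_AB = 3

_STATE_LABELS = {CODE_NOT_YET: "NA", CODE_EMPTY: "0", CODE_A: "1",
                 CODE_B: "2", CODE_AB: "3"}


@dataclass(frozen=True)
class FossilOccurrence:
    """One dated fossil occurrence of a taxon in one area.

    ``min_age``/``max_age`` bound the stratigraphic age uncertainty (Ma);
    ``point_age`` is a single age drawn from that range (see
    :func:`assign_point_ages`), or fixed when the occurrence is
    exactly dated.
    """

    taxon: str
    area: str
    min_age: float
    max_age: float
    point_age: float | None = None

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(
                f"occurrence of {self.taxon!r}: unknown area {self.area!r} "
                f"(expected one of {AREAS})")
        if not (0.0 <= self.min_age <= self.max_age):
            raise ValueError(
                f"occurrence of {self.taxon!r}: invalid age range "
                f"[{self.min_age}, {self.max_age}] (need 0 <= min <= max)")
        if self.point_age is not None and not (
                self.min_age <= self.point_age <= self.max_age):
            raise ValueError(
                f"occurrence of {self.taxon!r}: point age {self.point_age} "
                f"outside [{self.min_age}, {self.max_age}]")


@dataclass(frozen=True)
class PresentRange:
    """Known present-day range of a taxon (0=extinct, 1=A, 2=B, 3=AB)."""

    taxon: str
    range_code: int

    def __post_init__(self) -> None:
        if self.range_code not in (CODE_EMPTY, CODE_A, CODE_B, CODE_AB):
            raise ValueError(
                f"present range of {self.taxon!r}: invalid code "
                f"{self.range_code} (expected 0, 1, 2 or 3)")

    @property
    def extant(self) -> bool:
        return self.range_code != CODE_EMPTY


@dataclass(frozen=True)
class TimeGrid:
    """Uniform discretisation of time from ``root_age`` to the present.

    ``edges`` is the descending array of bin boundaries (Ma), ending at 0.
    Bin ``k`` spans ``[edges[k], edges[k+1])``; it *includes* its older
    edge and excludes its younger edge, so that an occurrence sitting
    exactly on an edge falls in the younger bin.
    """

    bin_size: float
    root_age: float
    edges: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, age: float) -> int:
        """Index (0 = oldest bin) of the bin containing ``age``."""
        if age < 0 or age > self.edges[0]:
            raise ValueError(f"age {age} outside grid [0, {self.edges[0]}]")
        if age == 0.0:
            return self.n_bins - 1
        # bin k covers (edges[k+1], edges[k]]
        ascending = self.edges[::-1]
        pos = int(np.searchsorted(ascending, age, side="left"))
        return len(self.edges) - 1 - pos

    def frame_index(self, shift_times: np.ndarray) -> np.ndarray:
        """Frame index per bin for shift times given in Ma (descending)."""
        mids = (self.edges[:-1] + self.edges[1:]) / 2.0
        shifts = np.sort(np.asarray(shift_times, dtype=float))[::-1]
        # frame f (0 = oldest) covers ages in (shifts[f], shifts[f-1]]
        idx = np.zeros(self.n_bins, dtype=np.int64)
        for shift in shifts:
            idx[mids < shift] += 1
        return idx


def build_time_grid(root_age: float, bin_size: float) -> TimeGrid:
    """Build a uniform grid of ``ceil(root_age / bin_size)`` bins ending at 0.

    The oldest edge is rounded up to a multiple of ``bin_size`` so it is
    never younger than ``root_age``.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if root_age <= 0:
        raise ValueError(f"root_age must be positive, got {root_age}")
    n = int(np.ceil(round(root_age / bin_size, 9)))
    edges = np.linspace(n * bin_size, 0.0, n + 1)
    return TimeGrid(bin_size=float(bin_size), root_age=float(root_age),
                    edges=edges)


@dataclass(frozen=True)
class ObservedRangeMatrix:
    """Taxa x time-bin matrix of observed range codes (the data **O**).

    ``codes[i, k]`` is the observed code of taxon ``i`` in bin ``k``
    (0 = oldest); ``present[i]`` is the known present-day range code.
    Cells before a taxon's first appearance are ``CODE_NOT_YET``.
    """

    taxa: tuple[str, ...]
    grid: TimeGrid
    codes: np.ndarray = field(repr=False)
    present: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        present = np.asarray(self.present, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "present", present)
        if codes.shape != (len(self.taxa), self.grid.n_bins):
            raise ValueError("codes shape does not match taxa x bins")
        for i, taxon in enumerate(self.taxa):
            row = codes[i]
            observed = np.nonzero(row != CODE_NOT_YET)[0]
            if len(observed) == 0:
                raise ValueError(f"taxon {taxon!r} has no observed bins")
            first = observed[0]
            if np.any(row[first:] == CODE_NOT_YET):
                raise ValueError(
                    f"taxon {taxon!r}: NA cell after first appearance")
            if row[first] == CODE_EMPTY:
                raise ValueError(
                    f"taxon {taxon!r}: first coded state is empty")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def first_bin(self) -> np.ndarray:
        """Index of the first-appearance bin for each taxon."""
        return np.asarray(
            [np.nonzero(row != CODE_NOT_YET)[0][0] for row in self.codes])

    def to_frame(self) -> pd.DataFrame:
        """One row per taxon; one column per bin's older edge, plus the
        present (column '0.0') holding the present-day range code."""
        cols = [f"{e:g}" for e in self.grid.edges[:-1]] + ["0.0"]
        body = [[_STATE_LABELS[int(c)] for c in row] + [str(int(p))]
                for row, p in zip(self.codes, self.present)]
        return pd.DataFrame(body, index=list(self.taxa), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ObservedRangeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        edges = np.array([float(c) for c in df.columns])
        if edges[-1] != 0.0:
            raise ValueError("last column of a binned matrix must be 0.0")
        bin_size = float(edges[0] - edges[1])
        grid = build_time_grid(edges[0], bin_size)
        raw = df.to_numpy()
        codes = np.empty((len(df), len(edges) - 1), dtype=np.int8)
        for i in range(len(df)):
            for k in range(len(edges) - 1):
                cell = raw[i, k]
                codes[i, k] = (CODE_NOT_YET if (pd.isna(cell) or cell == "NA")
                               else int(cell))
        present = np.array([int(p) for p in raw[:, -1]], dtype=np.int8)
        return cls(taxa=tuple(df.index), grid=grid, codes=codes,
                   present=present)


def assign_point_ages(occurrences: list[FossilOccurrence],
                      seed: int | np.random.Generator,
                      ) -> list[FossilOccurrence]:
    """Draw a point age uniformly within each occurrence's age range.

    Deterministic given ``seed``; degenerate ranges (min == max) map to
    that exact age.
    """
    rng = np.random.default_rng(seed)
    out = []
    for occ in occurrences:
        age = float(rng.uniform(occ.min_age, occ.max_age))
        out.append(replace(occ, point_age=age))
    return out


def code_ranges(occurrences: list[FossilOccurrence],
                present: list[PresentRange],
                grid: TimeGrid) -> ObservedRangeMatrix:
    """Bin point-dated occurrences into an :class:`ObservedRangeMatrix`.

    Per taxon and bin the code is the union of areas with at least one
    occurrence whose point age falls in the bin; bins between the first
    appearance and the present with no occurrence are coded observed-empty;
    bins older than the first appearance are NA.  Taxon order follows the
    ``present`` list (taxa without occurrences are dropped — they have no
    first appearance and carry no information).
    """
    present_by_taxon = {p.taxon: p for p in present}
    if len(present_by_taxon) != len(present):
        raise ValueError("duplicate taxon in present-range list")
    occs_by_taxon: dict[str, list[FossilOccurrence]] = {}
    for occ in occurrences:
        if occ.point_age is None:
            raise ValueError(
                f"occurrence of {occ.taxon!r} has no point age; run "
                "assign_point_ages first")
        if occ.taxon not in present_by_taxon:
            raise ValueError(
                f"occurrence of {occ.taxon!r} has no present-range entry")
        if occ.point_age > grid.edges[0]:
            raise ValueError(
                f"occurrence of {occ.taxon!r} at {occ.point_age} Ma is older "
                f"than the grid root {grid.edges[0]} Ma")
        occs_by_taxon.setdefault(occ.taxon, []).append(occ)

    taxa = [p.taxon for p in present if p.taxon in occs_by_taxon]
    codes = np.full((len(taxa), grid.n_bins), CODE_NOT_YET, dtype=np.int8)
    pres = np.empty(len(taxa), dtype=np.int8)
    for i, taxon in enumerate(taxa):
        pres[i] = present_by_taxon[taxon].range_code
        in_a = np.zeros(grid.n_bins, dtype=bool)
        in_b = np.zeros(grid.n_bins, dtype=bool)
        for occ in occs_by_taxon[taxon]:
            k = grid.bin_of(occ.point_age)
            (in_a if occ.area == "A" else in_b)[k] = True
        sampled = in_a | in_b
        first = int(np.nonzero(sampled)[0][0])
        codes[i, first:] = (CODE_A * in_a + CODE_B * in_b)[first:]
    return ObservedRangeMatrix(taxa=tuple(taxa), grid=grid, codes=codes,
                               present=pres)


def read_occurrences(path: str | Path,
                     area_map: dict[str, str] | None = None,
                     ) -> list[FossilOccurrence]:
    """Read an occurrence TSV with columns taxon, area, min_age, max_age.

    ``area_map`` translates user labels (e.g. continent names) to A/B.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "area", "min_age", "max_age"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"occurrence file {path} must have columns {sorted(required)}")
    out = []
    for rec in df.itertuples(index=False):
        area = str(rec.area)
        if area_map is not None:
            area = area_map.get(area, area)
        out.append(FossilOccurrence(taxon=str(rec.taxon), area=area,
                                    min_age=float(rec.min_age),
                                    max_age=float(rec.max_age)))
    return out


def read_present_ranges(path: str | Path) -> list[PresentRange]:
    """Read a present-range TSV with columns taxon, range_code (0..3)."""
    df = pd.read_csv(path, sep="\t")
    if not {"taxon", "range_code"}.issubset(df.columns):
        raise ValueError(
            f"present-range file {path} must have columns taxon, range_code")
    return [PresentRange(taxon=str(r.taxon), range_code=int(r.range_code))
            for r in df.itertuples(index=False)]
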