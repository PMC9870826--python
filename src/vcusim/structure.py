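"""Skeleton generator for multi-year variety registration (VCU) trial series.

German VCU trials are organised in overlapping three-year cycles: every year a
new cohort of candidate genotypes enters, is tested at a set of locations, and
is culled after the first and second year.  Long-running check varieties are
grown in every trial to connect cycles across years.  This module generates
such an observation skeleton from summary parameters alone (cohort sizes,
culling fractions, locations per series-year, within-cycle location overlap,
check panel size and lifespan) without any real trial data.

The skeleton distinguishes *entries* (the candidates that start a cycle) from
*survivor slots* (the pre-planned number of year-2 and year-3 positions).
Which entry fills which slot is decided later by the selection step; the
skeleton only fixes how many survive and where they are grown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureParams",
    "CycleInfo",
    "TrialStructure",
    "build_structure",
    "structure_summary",
    "scaled_params",
]

CANDIDATE = "candidate"
CHECK = "check"

#: column order of the cell table
CELL_COLUMNS = [
    "genotype_slot",
    "role",
    "cycle",
    "series_year",
    "year",
    "location",
    "trial",
]


class StructureConfigError(ValueError):
    """Raised when structure parameters are infeasible (e.g. overlaps exceed
    the per-series location counts or the location pool)."""


@dataclass(frozen=True)
class StructureParams:
    """Summary parameters of a VCU-like trial system.

    Defaults describe the German winter-wheat series 1983-2016: 34 years,
    a pool of 120 locations, cohorts growing from ~60 to ~120 entries,
    51% / 26% culled after years 1 / 2, series grown at 11 / 13 / 24
    locations with small within-cycle location carry-over, and a panel of
    48 check varieties each active for ~7 years.
    """

    n_years: int = 34
    n_locations: int = 120
    entries_start: int = 60
    entries_end: int = 120
    entries_per_cycle: Sequence[int] | None = None
    cull_frac_y1: float = 0.51
    cull_frac_y2: float = 0.26
    locs_y1: int = 11
    locs_y2: int = 13
    locs_y3: int = 24
    overlap_y1y2: int = 2
    overlap_y1y3: int = 1
    overlap_y2y3: int = 8
    n_checks: int = 48
    check_span_years: float = 7.0
    seed: int = 0

    @property
    def n_cycles(self) -> int:
        # last cycle starts so its third series-year is still inside the window
        return self.n_years - 2

    def entry_counts(self) -> list[int]:
        """Entries per cycle: explicit schedule, or linear ramp start -> end."""
        if self.entries_per_cycle is not None:
            sched = [int(e) for e in self.entries_per_cycle]
            if len(sched) != self.n_cycles:
                raise StructureConfigError(
                    f"entries_per_cycle has {len(sched)} values, need {self.n_cycles}"
                )
            return sched
        if self.n_cycles == 1:
            return [self.entries_start]
        ramp = np.linspace(self.entries_start, self.entries_end, self.n_cycles)
        return [int(round(e)) for e in ramp]

    def survivor_counts(self, entries: int) -> tuple[int, int]:
        n2 = int(round(entries * (1.0 - self.cull_frac_y1)))
        n3 = int(round(entries * (1.0 - self.cull_frac_y1 - self.cull_frac_y2)))
        return n2, n3

    def validate(self) -> None:
        if self.n_years < 3:
            raise StructureConfigError("need at least 3 years for one full cycle")
        if self.cull_frac_y1 < 0.0 or self.cull_frac_y2 < 0.0:
            raise StructureConfigError("culling fractions must be nonnegative")
        if self.cull_frac_y1 + self.cull_frac_y2 >= 1.0:
            raise StructureConfigError("culling fractions must sum to < 1")
        for e in self.entry_counts():
            n2, n3 = self.survivor_counts(e)
            if not 1 <= n3 <= n2 <= e:
                raise StructureConfigError(
                    f"survivor counts infeasible for cycle of {e} entries: {n2}, {n3}"
                )
        locs = (self.locs_y1, self.locs_y2, self.locs_y3)
        if max(locs) > self.n_locations:
            raise StructureConfigError("per-series location count exceeds the pool")
        o12, o13, o23 = self.overlap_y1y2, self.overlap_y1y3, self.overlap_y2y3
        if o12 + o13 > self.locs_y1 or o12 + o23 > self.locs_y2 or o13 + o23 > self.locs_y3:
            raise StructureConfigError("overlaps exceed per-series location counts")
        # the union of one cycle's three location sets must fit in the pool
        union = sum(locs) - o12 - o13 - o23
        if union > self.n_locations:
            raise StructureConfigError("cycle location union exceeds the pool")
        if self.n_checks < 1:
            raise StructureConfigError("need at least one check variety")


@dataclass(frozen=True)
class CycleInfo:
    """Registry entry for one cycle: its candidate population, the planned
    survivor counts, and the three series-year location sets."""

    cycle: int
    start_year: int
    entries: tuple[str, ...]
    n_keep_y2: int
    n_keep_y3: int
    locs: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]


@dataclass
class TrialStructure:
    """Observation skeleton of a VCU-like trial system.

    ``cells`` holds one row per planned observation slot.  Year-1 rows name
    the entry directly; year-2/3 candidate rows carry survivor-slot ids of
    the form ``c{cycle}y{series}s{index}`` that the assembly step later maps
    to selected entries.  Check rows name the check variety.
    """

    params: StructureParams
    cells: pd.DataFrame
    cycles: dict[int, CycleInfo]
    check_years: dict[str, tuple[int, int]]
    first_test_year: dict[str, int]

    # -- convenience ----------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        """All real genotype ids (entries of every cycle, then checks)."""
        out: list[str] = []
        for c in sorted(self.cycles):
            out.extend(self.cycles[c].entries)
        out.extend(sorted(self.check_years))
        return out

    def full_candidate_grid(self) -> pd.DataFrame:
        """Every entry of every cycle at all three series-years' locations.

        This is the pre-selection layout: the simulation first generates
        complete three-year data for each cohort, and the selection step then
        decides which entries' year-2/3 rows are actually observed.
        """
        rows: list[tuple] = []
        for c in sorted(self.cycles):
            info = self.cycles[c]
            for sy in (1, 2, 3):
                year = info.start_year + sy - 1
                for loc in info.locs[sy - 1]:
                    trial = _trial_id(year, loc, c)
                    for g in info.entries:
                        rows.append((g, CANDIDATE, c, sy, year, loc, trial))
        return pd.DataFrame(rows, columns=CELL_COLUMNS)

    # -- serialization --------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(path / "cells.csv", index=False)
        meta = {
            "params": asdict(self.params),
            "cycles": {
                str(c): {
                    "start_year": info.start_year,
                    "entries": list(info.entries),
                    "n_keep_y2": info.n_keep_y2,
                    "n_keep_y3": info.n_keep_y3,
                    "locs": [list(l) for l in info.locs],
                }
                for c, info in self.cycles.items()
            },
            "check_years": {k: list(v) for k, v in self.check_years.items()},
            "first_test_year": self.first_test_year,
        }
        if meta["params"]["entries_per_cycle"] is not None:
            meta["params"]["entries_per_cycle"] = list(meta["params"]["entries_per_cycle"])
        (path / "structure.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "TrialStructure":
        path = Path(path)
        meta = json.loads((path / "structure.json").read_text())
        p = meta["params"]
        if p["entries_per_cycle"] is not None:
            p["entries_per_cycle"] = tuple(p["entries_per_cycle"])
        params = StructureParams(**p)
        cells = pd.read_csv(path / "cells.csv")
        cycles = {
            int(c): CycleInfo(
                cycle=int(c),
                start_year=d["start_year"],
                entries=tuple(d["entries"]),
                n_keep_y2=d["n_keep_y2"],
                n_keep_y3=d["n_keep_y3"],
                locs=tuple(tuple(l) for l in d["locs"]),
            )
            for c, d in meta["cycles"].items()
        }
        check_years = {k: (v[0], v[1]) for k, v in meta["check_years"].items()}
        return cls(params, cells, cycles, check_years, dict(meta["first_test_year"]))


def _trial_id(year: int, location: int, cycle: int) -> str:
    return f"t{year:03d}_{location:03d}_{cycle:03d}"


def slot_id(cycle: int, series_year: int, index: int) -> str:
    return f"c{cycle:03d}y{series_year}s{index:03d}"


def _draw_cycle_locations(
    rng: np.random.Generator, params: StructureParams
) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
    """Draw the three series-year location sets of one cycle.

    The expected within-cycle carry-over of locations between series-years is
    enforced by drawing the shared subsets first and topping up each set with
    locations not otherwise used by the cycle.
    """
    o12, o13, o23 = params.overlap_y1y2, params.overlap_y1y3, params.overlap_y2y3
    fresh1 = params.locs_y1 - o12 - o13
    fresh2 = params.locs_y2 - o12 - o23
    fresh3 = params.locs_y3 - o13 - o23
    n_draw = o12 + o13 + o23 + fresh1 + fresh2 + fresh3
    pool = rng.choice(params.n_locations, size=n_draw, replace=False)
    s12, s13, s23, f1, f2, f3 = np.split(pool, np.cumsum([o12, o13, o23, fresh1, fresh2]))
    l1 = tuple(sorted(int(x) for x in np.concatenate([s12, s13, f1])))
    l2 = tuple(sorted(int(x) for x in np.concatenate([s12, s23, f2])))
    l3 = tuple(sorted(int(x) for x in np.concatenate([s13, s23, f3])))
    return l1, l2, l3


def _schedule_checks(rng: np.random.Generator, params: StructureParams) -> dict[str, tuple[int, int]]:
    """Staggered check panels.

    Checks are distributed over parallel panel slots; within a slot they run
    back to back, so at any time roughly n_checks * mean_span / n_years checks
    are concurrently active, each grown in every trial of its active years.
    Spans are geometric-ish with the configured mean, truncated to the window.
    """
    mean_span = max(1.0, float(params.check_span_years))
    n_slots = max(1, int(round(params.n_checks * mean_span / params.n_years)))
    next_start = [1] * n_slots
    out: dict[str, tuple[int, int]] = {}
    for i in range(params.n_checks):
        if mean_span >= params.n_years:
            span = params.n_years  # a check cannot outlive the window
        else:
            span = int(min(rng.geometric(1.0 / mean_span), 3 * mean_span))
            span = max(2, span)
        slot = int(np.argmin(next_start))
        start = next_start[slot]
        if start > params.n_years - 1:
            # panel budget exhausted; keep the check active at the tail so
            # every check variety exists somewhere in the window
            start = max(1, params.n_years - span + 1)
        else:
            next_start[slot] = start + span
        end = min(params.n_years, start + span - 1)
        out[f"chk{i:03d}"] = (start, end)
    return out


def build_structure(params: StructureParams | None = None, **overrides) -> TrialStructure:
    """Generate a trial skeleton from summary parameters.

    Deterministic given ``params.seed``.  Survivor-slot counts follow
    ``round(entries * (1 - cull_frac_y1))`` after year 1 and
    ``round(entries * (1 - cull_frac_y1 - cull_frac_y2))`` after year 2.
    """
    if params is None:
        params = StructureParams(**overrides)
    elif overrides:
        params = StructureParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)

    check_years = _schedule_checks(rng, params)
    entry_counts = params.entry_counts()

    cycles: dict[int, CycleInfo] = {}
    rows: list[tuple] = []
    first_test_year: dict[str, int] = {}

    for c in range(params.n_cycles):
        start_year = c + 1
        n_entries = entry_counts[c]
        entries = tuple(f"g{c:03d}_{j:03d}" for j in range(n_entries))
        n2, n3 = params.survivor_counts(n_entries)
        locs = _draw_cycle_locations(rng, params)
        cycles[c] = CycleInfo(c, start_year, entries, n2, n3, locs)
        for g in entries:
            first_test_year[g] = start_year
        # year 1: all entries; years 2-3: survivor slots
        for sy, slots in ((1, entries), (2, None), (3, None)):
            year = start_year + sy - 1
            if slots is None:
                n_keep = n2 if sy == 2 else n3
                slots = tuple(slot_id(c, sy, j) for j in range(n_keep))
            for loc in locs[sy - 1]:
                trial = _trial_id(year, loc, c)
                for g in slots:
                    rows.append((g, CANDIDATE, c, sy, year, loc, trial))

    # checks: one row in every trial of every active year
    trials = {}
    for c, info in cycles.items():
        for sy in (1, 2, 3):
            year = info.start_year + sy - 1
            for loc in info.locs[sy - 1]:
                trials.setdefault(year, []).append((loc, c, sy))
    for chk, (start, end) in check_years.items():
        first_test_year[chk] = start
        for year in range(start, end + 1):
            for loc, c, sy in trials.get(year, ()):
                rows.append((chk, CHECK, c, sy, year, loc, _trial_id(year, loc, c)))

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return TrialStructure(params, cells, cycles, check_years, first_test_year)


def structure_summary(structure: TrialStructure) -> pd.Series:
    """Aggregate counts of the skeleton, split candidate/check.

    Survivor slots are counted as the genotypes that will fill them; because
    every entry of a cycle is tested at *all* year-1 locations, the counts of
    distinct genotype-by-x combinations do not depend on which entries are
    selected, so they are computable from the skeleton alone.
    """
    cells = structure.cells
    cand = cells[cells["role"] == CANDIDATE]
    chk = cells[cells["role"] == CHECK]

    n_entries = sum(len(i.entries) for i in structure.cycles.values())
    n_genotypes = n_entries + len(structure.check_years)

    gy_cand = gl_cand = 0
    for info in structure.cycles.values():
        e = len(info.entries)
        l1, l2, l3 = (set(l) for l in info.locs)
        gy_cand += e + info.n_keep_y2 + info.n_keep_y3
        gl_cand += (
            e * len(l1)
            + info.n_keep_y2 * len(l2 - l1)
            + info.n_keep_y3 * len(l3 - l1 - l2)
        )
    gy_chk = chk.groupby("genotype_slot")["year"].nunique().sum()
    gl_chk = chk.groupby("genotype_slot")["location"].nunique().sum()
    gyl_chk = chk.drop_duplicates(["genotype_slot", "year", "location"]).shape[0]

    return pd.Series(
        {
            "observations": len(cells),
            "observations_candidates": len(cand),
            "observations_checks": len(chk),
            "years": cells["year"].nunique(),
            "locations": cells["location"].nunique(),
            "year_by_location": cells.drop_duplicates(["year", "location"]).shape[0],
            "trials": cells["trial"].nunique(),
            "genotypes": n_genotypes,
            "genotype_by_year": int(gy_cand + gy_chk),
            "genotype_by_location": int(gl_cand + gl_chk),
            "genotype_by_year_by_location": int(len(cand) + gyl_chk),
        }
    )


def scaled_params(scale: float, seed: int = 0, **overrides) -> StructureParams:
    """Shrink the default trial system by a linear factor for desk-scale runs.

    Years, the location pool, cohort sizes, per-series locations, overlaps and
    the check panel all scale linearly (with small floors keeping the design
    connected); culling fractions are scale-free.  Check lifespan scales with
    the square root of the factor so that panels still span several cycles.
    """
    if not 0 < scale <= 1:
        raise StructureConfigError("scale must be in (0, 1]")
    d = StructureParams()
    locs_y1 = max(2, round(d.locs_y1 * scale))
    locs_y2 = max(2, round(d.locs_y2 * scale))
    locs_y3 = max(3, round(d.locs_y3 * scale))
    base = dict(
        n_years=max(6, round(d.n_years * scale)),
        n_locations=max(8, round(d.n_locations * scale)),
        entries_start=max(6, round(d.entries_start * scale)),
        entries_end=max(8, round(d.entries_end * scale)),
        locs_y1=locs_y1,
        locs_y2=locs_y2,
        locs_y3=locs_y3,
        overlap_y1y2=min(round(d.overlap_y1y2 * scale), locs_y1 - 1),
        overlap_y1y3=min(round(d.overlap_y1y3 * scale), locs_y1 - 1),
        overlap_y2y3=min(round(d.overlap_y2y3 * scale), locs_y2 - 1),
        n_checks=max(4, round(d.n_checks * scale)),
        check_span_years=max(3.0, round(d.check_span_years * scale**0.5, 1)),
        seed=seed,
    )
    base.update(overrides)
    return StructureParams(**base)
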