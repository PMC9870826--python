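"""Simulation of phenotypic trial means on a VCU-like skeleton.

One observation is the mean yield of a genotype in one trial.  It decomposes
additively into an intercept, two linear trends (a non-genetic trend on the
calendar year of testing ``t`` and a genetic trend on the year of first
testing ``r``) and mutually independent zero-mean normal effects for year,
location, genotype, their two- and three-way interactions, the trial within a
year-by-location combination, and a residual:

    y = mu + gamma*t + Z_year + L_loc + beta*r + H_geno
        + (LY) + (LYT) + (GL) + (GY) + (GLY) + e

Year, location, year-by-location and trial effects are drawn once per run and
shared by all cohorts and checks.  Genotype-level effects are drawn for the
*complete* three-year layout of every cohort; the selection step then decides
which entries' year-2/3 rows become part of the observed dataset.  Duplicate
check rows within a year-by-location combination (one per parallel series)
share their (GLY) value and differ only in trial effect and residual -- this
is the covariance that distinguishes the full model from the single-mean
analysis model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import TrialStructure, CANDIDATE, CHECK

__all__ = [
    "VarianceComponents",
    "EffectSet",
    "SimulatedDataset",
    "draw_effects",
    "simulate_cycle_full",
    "transfer_check_effects",
    "assemble_dataset",
]

#: factor name -> key columns, in the order effects enter the response
RANDOM_FACTORS: dict[str, tuple[str, ...]] = {
    "year": ("year",),
    "location": ("location",),
    "year_location": ("year", "location"),
    "trial": ("trial",),
    "genotype": ("genotype",),
    "genotype_location": ("genotype", "location"),
    "genotype_year": ("genotype", "year"),
    "genotype_year_location": ("genotype", "year", "location"),
    "residual": ("genotype", "trial"),
}


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components (dt^2 ha^-2) and trend slopes (dt ha^-1 year^-1).

    Defaults are the estimates from 34 years of German winter-wheat VCU
    trials, with zero trends: simulating zero slopes loses no generality for
    bias assessment, and any estimated trend is then pure bias.
    """

    sigma2_Y: float = 25.13
    sigma2_L: float = 53.15
    sigma2_G: float = 13.27
    sigma2_LY: float = 74.14
    sigma2_LYT: float = 8.83
    sigma2_GL: float = 2.25
    sigma2_GY: float = 3.16
    sigma2_GLY: float = 9.62
    sigma2_e: float = 9.36
    beta: float = 0.0
    gamma: float = 0.0
    mu: float = 80.0

    def validate(self) -> None:
        for name, v in self.by_factor().items():
            if v < 0:
                raise ValueError(f"variance for {name} is negative: {v}")

    def by_factor(self) -> dict[str, float]:
        return {
            "year": self.sigma2_Y,
            "location": self.sigma2_L,
            "year_location": self.sigma2_LY,
            "trial": self.sigma2_LYT,
            "genotype": self.sigma2_G,
            "genotype_location": self.sigma2_GL,
            "genotype_year": self.sigma2_GY,
            "genotype_year_location": self.sigma2_GLY,
            "residual": self.sigma2_e,
        }

    @classmethod
    def inflated_gxy(cls, sigma2_GY: float = 55.75, **kw) -> "VarianceComponents":
        """Scenario with the genotype-by-year variance raised from 3.16 to
        55.75 (the genotype : genotype-by-year ratio flipped from 4.2 : 1 to
        1 : 4.2)."""
        return cls(sigma2_GY=sigma2_GY, **kw)


@dataclass
class EffectSet:
    """Realised random effects for one simulation run.

    ``values[factor]`` is a Series of N(0, sigma2_factor) draws indexed by
    the factor's observed levels (tuples for interactions).  All factors are
    mutually independent; each is drawn from its own RNG substream so that,
    e.g., changing the residual draw does not perturb genotype effects.
    """

    values: dict[str, pd.Series]
    vc: VarianceComponents
    seed: int
    transferred: dict[str, str] = field(default_factory=dict)

    def genotype_truth(self) -> pd.Series:
        """True genotype deviations H_i, indexed by genotype id."""
        h = self.values["genotype"].copy()
        h.index = [k[0] for k in h.index]
        return h


def _level_frame(structure: TrialStructure) -> pd.DataFrame:
    """All cells whose effects may be observed: the complete candidate grid
    plus every check cell."""
    full = structure.full_candidate_grid()
    checks = structure.cells[structure.cells["role"] == CHECK]
    frame = pd.concat([full, checks], ignore_index=True)
    return frame.rename(columns={"genotype_slot": "genotype"})


def draw_effects(structure: TrialStructure, vc: VarianceComponents, seed: int) -> EffectSet:
    """Draw every random effect needed for one run, deterministically."""
    vc.validate()
    frame = _level_frame(structure)
    variances = vc.by_factor()
    streams = np.random.SeedSequence(seed).spawn(len(RANDOM_FACTORS))
    values: dict[str, pd.Series] = {}
    for (factor, keys), ss in zip(RANDOM_FACTORS.items(), streams):
        levels = sorted(set(map(tuple, frame[list(keys)].itertuples(index=False))))
        rng = np.random.default_rng(ss)
        draws = rng.normal(0.0, np.sqrt(variances[factor]), size=len(levels))
        values[factor] = pd.Series(
            draws, index=pd.MultiIndex.from_tuples(levels, names=list(keys))
        )
    return EffectSet(values=values, vc=vc, seed=seed)


def transfer_check_effects(effects: EffectSet, candidate: str, check: str) -> EffectSet:
    """Give a check variety the genotype and genotype-by-location effects of
    the candidate it descends from (checks are former successful candidates).

    The check's genotype effect and its genotype-by-location effects at the
    candidate's tested locations are overwritten by the candidate's values;
    genotype-by-year, three-way and residual effects stay fresh per year.
    """
    if check in effects.transferred:
        raise ValueError(
            f"check {check!r} already carries effects of {effects.transferred[check]!r}"
        )
    g = effects.values["genotype"]
    if (candidate,) not in g.index or (check,) not in g.index:
        raise KeyError("both candidate and check must have genotype effects")
    g.loc[(check,)] = g.loc[(candidate,)]
    gl = effects.values["genotype_location"]
    cand_locs = {k[1] for k in gl.index if k[0] == candidate}
    for loc in cand_locs:
        if (check, loc) in gl.index:
            gl.loc[(check, loc)] = gl.loc[(candidate, loc)]
    effects.transferred[check] = candidate
    return effects


def compose_response(
    frame: pd.DataFrame, effects: EffectSet, first_test_year: dict[str, int]
) -> pd.DataFrame:
    """Attach covariates t, r and the simulated response y to cell rows."""
    vc = effects.vc
    out = frame.copy()
    out["t"] = out["year"].astype(int)
    out["r"] = out["genotype"].map(first_test_year).astype(int)
    y = np.full(len(out), vc.mu, dtype=float)
    y += vc.gamma * out["t"].to_numpy(float) + vc.beta * out["r"].to_numpy(float)
    for factor, keys in RANDOM_FACTORS.items():
        idx = pd.MultiIndex.from_frame(out[list(keys)])
        vals = effects.values[factor].reindex(idx).to_numpy()
        if np.isnan(vals).any():
            raise KeyError(f"missing effect levels for factor {factor}")
        y += vals
    out["y"] = y
    return out


@dataclass
class SimulatedDataset:
    """One simulated trial dataset plus the truth that generated it."""

    data: pd.DataFrame
    effects: EffectSet
    vc: VarianceComponents
    structure: TrialStructure
    variant: str = "C"

    def truth_H(self) -> pd.Series:
        return self.effects.genotype_truth()

    def with_data(self, data: pd.DataFrame, variant: str) -> "SimulatedDataset":
        return SimulatedDataset(data, self.effects, self.vc, self.structure, variant)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path / f"dataset_{self.variant}.csv", index=False)
        truth = pd.concat(
            {f: s.reset_index(drop=False) for f, s in self.effects.values.items()},
            names=["factor"],
        )
        truth.to_csv(path / "truth_effects.csv")


def simulate_cycle_full(
    structure: TrialStructure,
    cycle_id: int,
    vc: VarianceComponents,
    effects: EffectSet,
    include_checks: bool = True,
) -> pd.DataFrame:
    """Complete three-year data of one cohort: every entry at every location
    of all three series-years, plus the check rows of the cohort's trials."""
    if cycle_id not in structure.cycles:
        raise KeyError(f"unknown cycle {cycle_id}")
    info = structure.cycles[cycle_id]
    rows = []
    for sy in (1, 2, 3):
        year = info.start_year + sy - 1
        for loc in info.locs[sy - 1]:
            trial = f"t{year:03d}_{loc:03d}_{cycle_id:03d}"
            for g in info.entries:
                rows.append((g, CANDIDATE, cycle_id, sy, year, loc, trial))
    frame = pd.DataFrame(
        rows,
        columns=["genotype", "role", "cycle", "series_year", "year", "location", "trial"],
    )
    if include_checks:
        chk = structure.cells[
            (structure.cells["role"] == CHECK) & (structure.cells["cycle"] == cycle_id)
        ].rename(columns={"genotype_slot": "genotype"})
        frame = pd.concat([frame, chk], ignore_index=True)
    return compose_response(frame, effects, structure.first_test_year)


class AssemblyError(ValueError):
    """Selection outcome does not cover the structure's survivor slots."""


def assemble_dataset(
    structure: TrialStructure,
    vc: VarianceComponents,
    seed: int,
    selection_outcome,
    effects: EffectSet | None = None,
) -> SimulatedDataset:
    """Build the observed dataset: full year-1 data of every cohort, plus the
    year-2/3 data of the entries the selection kept, plus all check rows.

    Restricting the complete simulated cohort data to the selected entries is
    exactly the label exchange: the survivor slots of the skeleton carry the
    selected entries' genotype-level effects while years, locations and trials
    stay fixed.  Row count equals the skeleton's cell count.
    """
    if effects is None:
        effects = draw_effects(structure, vc, seed)
    pieces = []
    for c, info in structure.cycles.items():
        full = simulate_cycle_full(structure, c, vc, effects, include_checks=False)
        kept2, kept3 = selection_outcome.kept(c)
        if len(kept2) != info.n_keep_y2 or len(kept3) != info.n_keep_y3:
            raise AssemblyError(
                f"cycle {c}: selection sizes {len(kept2)}/{len(kept3)} do not match "
                f"survivor slots {info.n_keep_y2}/{info.n_keep_y3}"
            )
        keep = (
            (full["series_year"] == 1)
            | ((full["series_year"] == 2) & full["genotype"].isin(set(kept2)))
            | ((full["series_year"] == 3) & full["genotype"].isin(set(kept3)))
        )
        pieces.append(full[keep])
    checks = structure.cells[structure.cells["role"] == CHECK].rename(
        columns={"genotype_slot": "genotype"}
    )
    pieces.append(compose_response(checks, effects, structure.first_test_year))
    data = pd.concat(pieces, ignore_index=True)
    if len(data) != len(structure.cells):
        raise AssemblyError(
            f"assembled {len(data)} rows, skeleton has {len(structure.cells)} cells"
        )
    return SimulatedDataset(data, effects, vc, structure)
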