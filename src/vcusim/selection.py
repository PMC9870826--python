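"""Within-cycle selection of candidates: informative (BLUP-based) or random.

After the first series-year of a cycle, candidates are ranked by their BLUPs
of the genotype effect from a location + genotype model fitted to the cycle's
year-1 data (checks included); the best enter year 2.  After year 2 the
ranking uses both years' data under the within-cycle two-year model.  Because
a single year cannot separate a genotype effect from its genotype-by-year
interaction, selection acts on the *confounded* effect -- which is exactly
what makes the resulting drop-out informative for the downstream trend model.

Ranking uses the true simulation variances mapped onto the confounded
effects of the within-cycle models (no per-cycle re-estimation): this
isolates the selection-induced bias from small-sample variance-estimation
noise and yields the strongest, upper-bound form of selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import ModelSpec, build_design, solve_mme
from .simulate import VarianceComponents, EffectSet, simulate_cycle_full
from .structure import TrialStructure, CANDIDATE

__all__ = [
    "SelectionOutcome",
    "select_year1",
    "select_year2",
    "select_random",
    "run_selection",
    "year1_variances",
    "year2_variances",
]

BLUP = "blup"
RANDOM = "random"


class SelectionError(ValueError):
    pass


@dataclass
class SelectionOutcome:
    """Entries selected into year 2 and, from those, into year 3, per cycle."""

    mode: str
    kept_y2: dict[int, tuple[str, ...]] = field(default_factory=dict)
    kept_y3: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def kept(self, cycle: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
        if cycle not in self.kept_y2:
            raise SelectionError(f"no selection recorded for cycle {cycle}")
        return self.kept_y2[cycle], self.kept_y3[cycle]

    def validate_nesting(self) -> None:
        for c, k3 in self.kept_y3.items():
            if not set(k3) <= set(self.kept_y2[c]):
                raise SelectionError(f"cycle {c}: year-3 selection not nested in year-2")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.kept_y2):
            k2, k3 = set(self.kept_y2[c]), set(self.kept_y3[c])
            for g in sorted(k2):
                rows.append((c, g, True, g in k3))
        return pd.DataFrame(rows, columns=["cycle", "entry", "kept_y2", "kept_y3"])


def year1_variances(vc: VarianceComponents) -> tuple[dict[str, float], float]:
    """Variances of the single-year model's confounded effects.

    With one year of data: the genotype effect absorbs genotype-by-year, the
    location effect absorbs year-by-location and trial, and the residual
    absorbs genotype-by-location, the three-way term and the plot error.
    """
    variances = {
        "location": vc.sigma2_L + vc.sigma2_LY + vc.sigma2_LYT,
        "genotype": vc.sigma2_G + vc.sigma2_GY,
    }
    resid = vc.sigma2_GL + vc.sigma2_GLY + vc.sigma2_e
    return variances, resid


def year2_variances(vc: VarianceComponents) -> tuple[dict[str, float], float]:
    """Variances of the within-cycle two-year model's confounded effects:
    year-by-location absorbs the trial effect (one trial per year-location
    inside a cycle), the residual absorbs the three-way term."""
    variances = {
        "year": vc.sigma2_Y,
        "location": vc.sigma2_L,
        "year_location": vc.sigma2_LY + vc.sigma2_LYT,
        "genotype": vc.sigma2_G,
        "genotype_location": vc.sigma2_GL,
        "genotype_year": vc.sigma2_GY,
    }
    resid = vc.sigma2_GLY + vc.sigma2_e
    return variances, resid


def _rank_candidates(
    data: pd.DataFrame,
    spec: ModelSpec,
    variances: dict[str, float],
    resid: float,
    n_keep: int,
) -> list[str]:
    candidates = sorted(data.loc[data["role"] == CANDIDATE, "genotype"].unique())
    if n_keep > len(candidates):
        raise SelectionError(f"cannot keep {n_keep} of {len(candidates)} candidates")
    design = build_design(data, spec)
    _, blups = solve_mme(design, variances, resid)
    g = blups["genotype"]
    if isinstance(g.index, pd.MultiIndex):
        g.index = [k[0] for k in g.index]
    # quantize away solver noise so exact ties resolve by entry id
    tol = 1e-9 * max(1.0, float(np.std(data["y"])))
    scored = sorted((-int(round(g[c] / tol)), c) for c in candidates)
    return [c for _, c in scored[:n_keep]]


def select_year1(
    cycle_year1_data: pd.DataFrame, n_keep: int, vc: VarianceComponents
) -> list[str]:
    """Rank candidates by genotype BLUP from the year-1 model and keep the
    best ``n_keep``; ties broken by entry id."""
    variances, resid = year1_variances(vc)
    spec = ModelSpec(fixed=(), random=("location", "genotype"))
    return _rank_candidates(cycle_year1_data, spec, variances, resid, n_keep)


def select_year2(
    cycle_years12_data: pd.DataFrame, n_keep: int, vc: VarianceComponents
) -> list[str]:
    """Rank year-2 survivors by genotype BLUP from the two-year model."""
    variances, resid = year2_variances(vc)
    spec = ModelSpec(
        fixed=(),
        random=(
            "year",
            "location",
            "year_location",
            "genotype",
            "genotype_location",
            "genotype_year",
        ),
    )
    return _rank_candidates(cycle_years12_data, spec, variances, resid, n_keep)


def select_random(entries, n_keep: int, rng: np.random.Generator) -> list[str]:
    """Uniform sample without replacement (the MCAR benchmark)."""
    entries = list(entries)
    if n_keep > len(entries):
        raise SelectionError(f"cannot keep {n_keep} of {len(entries)} entries")
    idx = rng.choice(len(entries), size=n_keep, replace=False)
    return [entries[i] for i in sorted(idx)]


def run_selection(
    structure: TrialStructure,
    vc: VarianceComponents,
    effects: EffectSet,
    mode: str = BLUP,
    seed: int = 0,
) -> SelectionOutcome:
    """Perform both selection steps in every cycle on the simulated data."""
    if mode not in (BLUP, RANDOM):
        raise SelectionError(f"unknown selection mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = SelectionOutcome(mode=mode)
    for c, info in structure.cycles.items():
        if mode == RANDOM:
            kept2 = select_random(info.entries, info.n_keep_y2, rng)
            kept3 = select_random(kept2, info.n_keep_y3, rng)
        else:
            full = simulate_cycle_full(structure, c, vc, effects)
            y1 = full[full["series_year"] == 1]
            kept2 = select_year1(y1, info.n_keep_y2, vc)
            y12 = full[
                (full["series_year"] <= 2)
                & (full["genotype"].isin(set(kept2)) | (full["role"] != CANDIDATE))
            ]
            kept3 = select_year2(y12, info.n_keep_y3, vc)
        out.kept_y2[c] = tuple(kept2)
        out.kept_y3[c] = tuple(kept3)
    out.validate_nesting()
    return out
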