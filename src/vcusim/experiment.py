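"""End-to-end simulation experiments.

One *run* is: draw all random effects on the trial skeleton, perform the
two-stage within-cycle selection, assemble the observed dataset, build the
requested reduced variants, fit the trend-decomposition model to each, and
record estimates, genotype-BLUP MSE and rank correlation.  An *experiment*
repeats this for a number of runs and aggregates per variant.

Four scenarios are wired:

==================  ============================================================
selection           BLUP-based selection; variants C (complete, duplicate check
                    rows kept), C-1 and C-2 (candidates tested in <=1 / <=2
                    years dropped)
single-mean         as above, but duplicates within genotype-by-year-by-location
                    are first removed at random (variants SM, SM-1, SM-2); the
                    analysis model then equals the generating model
random-selection    survivors drawn at random instead of by BLUP (MCAR
                    benchmark; variants R, R-1, R-2)
inflated-gxy        BLUP selection with the genotype-by-year variance raised to
                    55.75 (variants I, I-1, I-2)
==================  ============================================================

The skeleton is built once per experiment (the historical layout is fixed);
effects, selection and the check de-duplication are re-drawn every run from
per-run substreams of the experiment seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import RunSummary, eligible_genotypes, mse_H, rank_corr_H, summarize
from .reduction import dedup_checks, drop_short_tested
from .reml import MODEL5_RANDOM, ModelFit, ModelSpec, reml_fit
from .selection import BLUP, RANDOM, run_selection
from .simulate import SimulatedDataset, VarianceComponents, assemble_dataset, draw_effects
from .structure import StructureParams, TrialStructure, build_structure, scaled_params

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "simulate_one_run",
    "make_fixture",
    "SCENARIOS",
]

SCENARIOS = ("selection", "single-mean", "random-selection", "inflated-gxy")

_VARIANT_PREFIX = {
    "selection": "C",
    "single-mean": "SM",
    "random-selection": "R",
    "inflated-gxy": "I",
}


@dataclass
class ExperimentConfig:
    scenario: str = "selection"
    runs: int = 10
    scale: float = 1.0
    seed: int = 0
    min_years_eligible: int = 3
    structure_overrides: dict = field(default_factory=dict)
    vc_overrides: dict = field(default_factory=dict)
    reml_tol: float = 1e-8
    reml_max_iter: int = 200

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; pick from {SCENARIOS}")
        if self.runs < 2:
            raise ValueError("need at least 2 runs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def structure_params(self) -> StructureParams:
        if self.scale == 1.0 and not self.structure_overrides:
            return StructureParams(seed=self.seed)
        return scaled_params(self.scale, seed=self.seed, **self.structure_overrides)

    def variance_components(self) -> VarianceComponents:
        if self.scenario == "inflated-gxy":
            return VarianceComponents.inflated_gxy(**self.vc_overrides)
        return VarianceComponents(**self.vc_overrides)

    def variant_names(self) -> list[str]:
        p = _VARIANT_PREFIX[self.scenario]
        return [p, f"{p}-1", f"{p}-2"]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    summaries: dict[str, RunSummary]
    truth: VarianceComponents
    log: pd.DataFrame  # one row per run x variant

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(path / "config.yaml")
        self.log.to_csv(path / "runs.csv", index=False)
        tables = pd.concat([s.to_frame() for s in self.summaries.values()])
        tables.index.name = "parameter"
        tables.to_csv(path / "summary.csv")
        record = {
            v: {
                "n_runs": s.n_runs,
                "n_failed": s.n_failed,
                "params": {k: list(map(float, row)) for k, row in s.params.iterrows()},
                "mse": list(map(float, s.mse)) if s.mse else None,
                "rank_corr": s.mean_rank_corr,
            }
            for v, s in self.summaries.items()
        }
        (path / "summary.json").write_text(json.dumps(record, indent=1))


def _reduce_variants(
    dataset: SimulatedDataset, scenario: str, seed: int
) -> dict[str, pd.DataFrame]:
    prefix = _VARIANT_PREFIX[scenario]
    base = dataset.data
    if scenario == "single-mean":
        base = dedup_checks(base, seed=seed)
    return {
        prefix: base,
        f"{prefix}-1": drop_short_tested(base, 1),
        f"{prefix}-2": drop_short_tested(base, 2),
    }


def simulate_one_run(
    structure: TrialStructure,
    vc: VarianceComponents,
    scenario: str,
    run_seed: int,
) -> tuple[SimulatedDataset, dict[str, pd.DataFrame]]:
    """Simulate, select and reduce one run; no model fitting."""
    ss = np.random.SeedSequence(run_seed).generate_state(3) % (2**31)
    effects = draw_effects(structure, vc, int(ss[0]))
    mode = RANDOM if scenario == "random-selection" else BLUP
    outcome = run_selection(structure, vc, effects, mode=mode, seed=int(ss[1]))
    dataset = assemble_dataset(structure, vc, int(ss[0]), outcome, effects=effects)
    variants = _reduce_variants(dataset, scenario, seed=int(ss[2]))
    return dataset, variants


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    variants: "list[str] | None" = None,
    progress: bool = False,
) -> ExperimentResult:
    """Run a full scenario and aggregate across runs.

    ``variants`` restricts which reduced datasets are fitted (default: all
    three of the scenario).  Fit failures are recorded in the run log and
    excluded from the averages, never silently dropped.
    """
    structure = build_structure(config.structure_params())
    vc = config.variance_components()
    wanted = variants or config.variant_names()
    unknown = set(wanted) - set(config.variant_names())
    if unknown:
        raise ValueError(f"unknown variants {sorted(unknown)}")
    spec = ModelSpec(fixed=("t", "r"), random=MODEL5_RANDOM)

    run_seeds = np.random.SeedSequence(config.seed).generate_state(config.runs) % (2**31)
    fits: dict[str, list[ModelFit]] = {v: [] for v in wanted}
    mses: dict[str, list[tuple[float, float]]] = {v: [] for v in wanted}
    rcs: dict[str, list[float]] = {v: [] for v in wanted}
    failed: dict[str, int] = {v: 0 for v in wanted}
    log_rows = []
    for i, rs in enumerate(run_seeds):
        dataset, variant_data = simulate_one_run(structure, vc, config.scenario, int(rs))
        truth_H = dataset.truth_H()
        for v in wanted:
            data = variant_data[v]
            row = {"run": i, "variant": v, "n_obs": len(data), "seed": int(rs)}
            try:
                fit = reml_fit(
                    data, spec, tol=config.reml_tol, max_iter=config.reml_max_iter
                )
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                failed[v] += 1
                row.update(converged=False, error=str(exc))
                log_rows.append(row)
                continue
            if not fit.converged:
                failed[v] += 1
                row.update(converged=False, error="; ".join(fit.notes))
                log_rows.append(row)
                continue
            eligible = eligible_genotypes(data, config.min_years_eligible)
            m, se, n_el = mse_H(fit, truth_H, eligible)
            rc = rank_corr_H(fit, truth_H, eligible)
            fits[v].append(fit)
            mses[v].append((m, se))
            rcs[v].append(rc)
            row.update(
                converged=True,
                loglik=fit.loglik,
                iters=fit.n_iter,
                beta_hat=fit.beta_hat,
                gamma_hat=fit.gamma_hat,
                sigma2_G_hat=fit.vc.get("genotype"),
                mse=m,
                rank_corr=rc,
                n_eligible=n_el,
            )
            log_rows.append(row)
        if progress:
            print(f"run {i + 1}/{config.runs} done", flush=True)

    summaries = {
        v: summarize(fits[v], variant=v, mses=mses[v], rank_corrs=rcs[v], n_failed=failed[v])
        for v in wanted
        if len(fits[v]) >= 2
    }
    all_failed = [v for v in wanted if v not in summaries]
    if all_failed:
        raise RuntimeError(f"fewer than two converged runs for variants {all_failed}")
    result = ExperimentResult(
        config=config,
        summaries=summaries,
        truth=vc,
        log=pd.DataFrame(log_rows),
    )
    if out_dir is not None:
        result.to_dir(out_dir)
    return result


def make_fixture(size: str = "tiny", seed: int = 0):
    """Deterministic toy instances for tests and documentation.

    ``tiny``: two 3-year cycles of 4 entries at 2 locations with one check
    (small enough to cross-check against dense linear algebra).  ``small``:
    three cycles of ~24 entries, a four-check panel, roughly 600 observations;
    the full pipeline runs on it in seconds.  Returns (structure, dataset)
    where the dataset carries its generating truth, built with BLUP selection
    under the default variance components.
    """
    if size == "tiny":
        params = StructureParams(
            n_years=4,
            n_locations=5,
            entries_start=4,
            entries_end=4,
            locs_y1=2,
            locs_y2=2,
            locs_y3=2,
            overlap_y1y2=0,
            overlap_y1y3=0,
            overlap_y2y3=1,
            n_checks=1,
            check_span_years=4,
            seed=seed,
        )
    elif size == "small":
        params = StructureParams(
            n_years=5,
            n_locations=12,
            entries_start=20,
            entries_end=28,
            locs_y1=3,
            locs_y2=3,
            locs_y3=5,
            overlap_y1y2=1,
            overlap_y1y3=0,
            overlap_y2y3=2,
            n_checks=4,
            check_span_years=4,
            seed=seed,
        )
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    structure = build_structure(params)
    vc = VarianceComponents()
    effects = draw_effects(structure, vc, seed)
    outcome = run_selection(structure, vc, effects, mode=BLUP, seed=seed)
    dataset = assemble_dataset(structure, vc, seed, outcome, effects=effects)
    return structure, dataset
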