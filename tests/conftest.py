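import numpy as np
import pandas as pd
import pytest

from vcusim import (
    StructureParams,
    VarianceComponents,
    build_structure,
    draw_effects,
    make_fixture,
)


@pytest.fixture(scope="session")
def tiny_structure():
    structure, _ = make_fixture("tiny")
    return structure


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture("small")


@pytest.fixture(scope="session")
def one_cycle_toy():
    """The minimal cycle: 4 entries culled 4 -> 2 -> 1, two locations per
    series-year, one check."""
    params = StructureParams(
        n_years=3,
        n_locations=6,
        entries_start=4,
        entries_end=4,
        cull_frac_y1=0.5,
        cull_frac_y2=0.25,
        locs_y1=2,
        locs_y2=2,
        locs_y3=2,
        overlap_y1y2=0,
        overlap_y1y3=0,
        overlap_y2y3=0,
        n_checks=1,
        check_span_years=3,  # >= n_years: the check spans the whole window
        seed=7,
    )
    return build_structure(params)


@pytest.fixture(scope="session")
def default_vc():
    return VarianceComponents()


def random_crossed_dataset(rng, n=None, factors=("year", "location", "genotype")):
    """A small random crossed dataset for REML tests."""
    n = n or int(rng.integers(25, 50))
    df = pd.DataFrame(
        {
            "year": rng.integers(1, rng.integers(3, 6), n),
            "location": rng.integers(1, rng.integers(3, 7), n),
            "genotype": [f"g{i}" for i in rng.integers(0, rng.integers(4, 9), n)],
        }
    )
    df["trial"] = df["year"].astype(str) + "_" + df["location"].astype(str)
    df["t"] = df["year"]
    df["r"] = df["genotype"].map(lambda g: int(g[1:]) % 3 + 1)
    geno_eff = {g: rng.normal(0, 1.5) for g in df["genotype"].unique()}
    year_eff = {y: rng.normal(0, 1.0) for y in df["year"].unique()}
    df["y"] = (
        50.0
        + 0.3 * df["t"]
        + rng.normal(0, 2.0, n)
        + df["genotype"].map(geno_eff)
        + df["year"].map(year_eff)
    )
    return df
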