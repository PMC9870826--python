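"""Systematic reduction of simulated trial datasets.

Two reductions are studied:

* dropping all data of candidates tested in at most one or two distinct
  years -- after performance-based selection this is an informative (MNAR)
  reduction, because short-tested candidates are exactly the culled ones;
* keeping a single mean per genotype-by-year-by-location combination by
  randomly dropping the duplicate check rows that arise when parallel series
  share a location -- a completely-at-random (MCAR) step that makes the
  analysis model identical to the generating model.

Check varieties are never dropped by the years-tested filter.  Both filters
are idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure import CANDIDATE

__all__ = ["drop_short_tested", "dedup_checks", "years_tested"]


def years_tested(data: pd.DataFrame) -> pd.Series:
    """Distinct calendar years with at least one observation, per genotype."""
    return data.groupby("genotype")["year"].nunique()


def drop_short_tested(data: pd.DataFrame, max_years_dropped: int) -> pd.DataFrame:
    """Remove all rows of candidates tested in <= ``max_years_dropped``
    distinct years; check rows always stay."""
    if max_years_dropped < 0:
        raise ValueError("max_years_dropped must be >= 0")
    ny = years_tested(data)
    short = set(ny[ny <= max_years_dropped].index)
    drop = (data["role"] == CANDIDATE) & data["genotype"].isin(short)
    return data[~drop].reset_index(drop=True)


def dedup_checks(data: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one row per (genotype, year, location), chosen uniformly
    at random among duplicates.  Row order of survivors is preserved."""
    keys = ["genotype", "year", "location"]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(len(data))
    shuffled = data.iloc[perm]
    kept_pos = shuffled.index[~shuffled.duplicated(keys)]
    return data.loc[data.index.isin(set(kept_pos))].reset_index(drop=True)
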