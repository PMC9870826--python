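import numpy as np
import pandas as pd
import pytest

from vcusim.simulate import (
    RANDOM_FACTORS,
    VarianceComponents,
    assemble_dataset,
    compose_response,
    draw_effects,
    simulate_cycle_full,
    transfer_check_effects,
)
from vcusim.selection import run_selection
from vcusim.structure import CANDIDATE, CHECK


def zero_vc(**kw):
    zeros = {
        "sigma2_Y": 0, "sigma2_L": 0, "sigma2_G": 0, "sigma2_LY": 0,
        "sigma2_LYT": 0, "sigma2_GL": 0, "sigma2_GY": 0, "sigma2_GLY": 0,
        "sigma2_e": 0, "beta": 0.0, "gamma": 0.0,
    }
    zeros.update(kw)
    return VarianceComponents(**zeros)


class TestCycleSimulation:
    def test_all_zero_variances_give_constant_response(self, one_cycle_toy):
        vc = zero_vc(mu=200.0)
        effects = draw_effects(one_cycle_toy, vc, seed=1)
        data = simulate_cycle_full(one_cycle_toy, 0, vc, effects)
        assert np.allclose(data["y"], 200.0)

    def test_genetic_slope_arithmetic(self, small_fixture):
        """With only a genetic slope, responses differ by beta times the gap
        in first test year."""
        structure, _ = small_fixture
        vc = zero_vc(beta=0.5, mu=100.0)
        effects = draw_effects(structure, vc, seed=1)
        d0 = simulate_cycle_full(structure, 0, vc, effects)
        d2 = simulate_cycle_full(structure, 2, vc, effects)
        y0 = d0[d0["role"] == CANDIDATE]["y"].iloc[0]
        y2 = d2[d2["role"] == CANDIDATE]["y"].iloc[0]
        r_gap = (
            structure.cycles[2].start_year - structure.cycles[0].start_year
        )
        assert y2 - y0 == pytest.approx(0.5 * r_gap)

    def test_unknown_cycle_rejected(self, one_cycle_toy, default_vc):
        effects = draw_effects(one_cycle_toy, default_vc, seed=0)
        with pytest.raises(KeyError):
            simulate_cycle_full(one_cycle_toy, 99, default_vc, effects)

    def test_genotype_effect_variance_recovers_parameter(self, one_cycle_toy):
        """Empirical variance of simulated genotype effects matches the
        genotype variance component within Monte-Carlo error."""
        vc = VarianceComponents()
        draws = []
        for seed in range(400):
            eff = draw_effects(one_cycle_toy, vc, seed=seed)
            draws.append(eff.values["genotype"].to_numpy())
        draws = np.concatenate(draws)  # 400 runs x 5 genotypes
        n = len(draws)
        est = draws.var(ddof=0)
        se = vc.sigma2_G * np.sqrt(2.0 / n)
        assert abs(est - vc.sigma2_G) < 3 * se


class TestSharedEffects:
    def test_cells_share_year_location_effects(self, small_fixture, default_vc):
        structure, _ = small_fixture
        effects = draw_effects(structure, default_vc, seed=3)
        d0 = simulate_cycle_full(structure, 0, default_vc, effects)
        d1 = simulate_cycle_full(structure, 1, default_vc, effects)
        merged = d0.merge(d1, on=["year", "location"], suffixes=("_a", "_b"))
        assert len(merged) > 0  # overlapping year-location combinations exist
        z = effects.values["year"]
        for y in merged["year"].unique():
            assert z.loc[(y,)] == z.loc[(y,)]  # same draw by construction

    def test_duplicate_check_rows_share_three_way_effect(self, default_vc):
        """Check rows from parallel series in one year-location share their
        genotype-by-year-by-location effect but not their residual."""
        from vcusim.structure import StructureParams, build_structure

        params = StructureParams(
            n_years=5, n_locations=6, entries_start=3, entries_end=3,
            cull_frac_y1=0.34, cull_frac_y2=0.33,
            locs_y1=3, locs_y2=3, locs_y3=3,
            overlap_y1y2=1, overlap_y1y3=1, overlap_y2y3=1,
            n_checks=1, check_span_years=5, seed=0,
        )
        structure = build_structure(params)
        chk = structure.cells[structure.cells["role"] == CHECK]
        dup = chk[chk.duplicated(["genotype_slot", "year", "location"], keep=False)]
        assert len(dup) > 0
        effects = draw_effects(structure, default_vc, seed=2)
        data = compose_response(
            chk.rename(columns={"genotype_slot": "genotype"}),
            effects,
            structure.first_test_year,
        )
        dups = data[data.duplicated(["genotype", "year", "location"], keep=False)]
        grp = dups.groupby(["genotype", "year", "location"])["y"]
        assert (grp.nunique() > 1).any()  # residuals differ
        gly = effects.values["genotype_year_location"]
        key = dups.iloc[0][["genotype", "year", "location"]]
        assert gly.loc[tuple(key)] == gly.loc[tuple(key)]


class TestTransfer:
    def test_transfer_copies_genotype_and_location_effects(self, small_fixture, default_vc):
        structure, _ = small_fixture
        effects = draw_effects(structure, default_vc, seed=5)
        cand = structure.cycles[0].entries[0]
        chk = sorted(structure.check_years)[0]
        h_cand = effects.values["genotype"].loc[(cand,)]
        transfer_check_effects(effects, cand, chk)
        assert effects.values["genotype"].loc[(chk,)] == h_cand
        gl = effects.values["genotype_location"]
        shared = [
            k[1] for k in gl.index if k[0] == cand and (chk, k[1]) in gl.index
        ]
        for loc in shared:
            assert gl.loc[(chk, loc)] == gl.loc[(cand, loc)]

    def test_double_transfer_rejected(self, small_fixture, default_vc):
        structure, _ = small_fixture
        effects = draw_effects(structure, default_vc, seed=5)
        c0, c1 = structure.cycles[0].entries[:2]
        chk = sorted(structure.check_years)[0]
        transfer_check_effects(effects, c0, chk)
        with pytest.raises(ValueError):
            transfer_check_effects(effects, c1, chk)

    def test_transfer_preserves_marginal_variance_and_induces_correlation(
        self, one_cycle_toy
    ):
        """Across runs the transferred check effect keeps variance sigma2_G
        and is perfectly correlated with its source candidate; without
        transfer the correlation is near zero."""
        vc = VarianceComponents()
        with_t, cand_vals, without_t = [], [], []
        for seed in range(300):
            eff = draw_effects(one_cycle_toy, vc, seed=seed)
            cand = one_cycle_toy.cycles[0].entries[0]
            chk = sorted(one_cycle_toy.check_years)[0]
            without_t.append(eff.values["genotype"].loc[(chk,)])
            transfer_check_effects(eff, cand, chk)
            with_t.append(eff.values["genotype"].loc[(chk,)])
            cand_vals.append(eff.values["genotype"].loc[(cand,)])
        with_t, cand_vals, without_t = map(np.asarray, (with_t, cand_vals, without_t))
        assert np.corrcoef(with_t, cand_vals)[0, 1] == pytest.approx(1.0)
        assert abs(np.corrcoef(without_t, cand_vals)[0, 1]) < 0.2
        est = with_t.var(ddof=1)
        se = vc.sigma2_G * np.sqrt(2.0 / len(with_t))
        assert abs(est - vc.sigma2_G) < 3 * se


class TestAssembly:
    def test_row_count_equals_skeleton(self, small_fixture, default_vc):
        structure, dataset = small_fixture
        assert len(dataset.data) == len(structure.cells)

    def test_exact_reconstruction(self, small_fixture):
        """Subtracting every truth component from y leaves exactly zero."""
        structure, dataset = small_fixture
        data, eff, vc = dataset.data, dataset.effects, dataset.vc
        resid = data["y"].to_numpy() - vc.mu
        resid = resid - vc.gamma * data["t"].to_numpy() - vc.beta * data["r"].to_numpy()
        for factor, keys in RANDOM_FACTORS.items():
            idx = pd.MultiIndex.from_frame(data[list(keys)])
            resid = resid - eff.values[factor].reindex(idx).to_numpy()
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_selected_entries_fill_survivor_slots(self, small_fixture):
        structure, dataset = small_fixture
        for c, info in structure.cycles.items():
            d = dataset.data
            y2 = d[(d["cycle"] == c) & (d["series_year"] == 2) & (d["role"] == CANDIDATE)]
            assert y2["genotype"].nunique() == info.n_keep_y2

    def test_missing_selection_raises(self, one_cycle_toy, default_vc):
        from vcusim.selection import SelectionOutcome
        from vcusim.simulate import AssemblyError

        empty = SelectionOutcome(mode="blup")
        with pytest.raises(Exception):
            assemble_dataset(one_cycle_toy, default_vc, 0, empty)

    def test_wrong_selection_size_raises(self, one_cycle_toy, default_vc):
        from vcusim.selection import SelectionOutcome
        from vcusim.simulate import AssemblyError

        info = one_cycle_toy.cycles[0]
        bad = SelectionOutcome(
            mode="blup",
            kept_y2={0: info.entries},  # too many
            kept_y3={0: info.entries[:1]},
        )
        with pytest.raises(AssemblyError):
            assemble_dataset(one_cycle_toy, default_vc, 0, bad)

    def test_same_seed_reproduces_dataset(self, one_cycle_toy, default_vc):
        effects = draw_effects(one_cycle_toy, default_vc, seed=9)
        sel = run_selection(one_cycle_toy, default_vc, effects, seed=4)
        a = assemble_dataset(one_cycle_toy, default_vc, 9, sel)
        b = assemble_dataset(one_cycle_toy, default_vc, 9, sel)
        pd.testing.assert_frame_equal(a.data, b.data)
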