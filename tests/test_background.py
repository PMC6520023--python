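"""Target groups, T x MLD stratification, and quota-based background draws."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phytosdm import (
    bin_presences,
    build_target_group,
    sample_background,
    stratify,
)
from phytosdm.background import TargetGroup, largest_remainder_quotas
from phytosdm.prep import GriddedPresences


def _presences(rows):
    return GriddedPresences(
        pd.DataFrame(rows, columns=["species_id", "month", "lat_idx", "lon_idx"])
    )


class TestTargetGroups:
    @pytest.fixture()
    def mixed_presences(self):
        rows = []
        for i, (sp, tax) in enumerate([
            ("d1", "Bacillariophyceae"), ("d2", "Bacillariophyceae"),
            ("f1", "Dinoflagellata"), ("h1", "Haptophyta"),
            ("c1", "Chlorophyta"),
        ]):
            for k in range(3):
                rows.append((sp, 1 + k, i, k))
        gm = {"d1": "Bacillariophyceae", "d2": "Bacillariophyceae",
              "f1": "Dinoflagellata", "h1": "Haptophyta", "c1": "Chlorophyta"}
        return _presences(rows), gm

    def test_group_specific_diatoms_use_own_pool(self, mixed_presences):
        pres, gm = mixed_presences
        groups = build_target_group(pres, gm, mode="group-specific")
        assert set(groups["d1"].species_ids) == {"d1", "d2"}

    def test_other_taxa_pool_excludes_diatoms(self, mixed_presences):
        pres, gm = mixed_presences
        groups = build_target_group(pres, gm, mode="group-specific")
        assert set(groups["c1"].species_ids) == {"f1", "h1", "c1"}

    def test_total_mode_shares_one_pool(self, mixed_presences):
        pres, gm = mixed_presences
        groups = build_target_group(pres, gm, mode="total")
        ids = {id(g) for g in groups.values()}
        assert len(ids) == 1
        assert set(groups["d1"].species_ids) == set(gm)

    def test_unknown_taxon_falls_back_to_total(self, mixed_presences):
        pres, gm = mixed_presences
        gm = dict(gm)
        del gm["c1"]
        with pytest.warns(UserWarning, match="unknown taxon"):
            groups = build_target_group(pres, gm, mode="group-specific")
        assert set(groups["c1"].species_ids) == {"d1", "d2", "f1", "h1", "c1"}


class TestStratify:
    def test_nine_by_nine_gives_81_strata(self, small_presences, tiny_env):
        group = build_target_group(
            small_presences,
            {s: "virtual" for s in small_presences.table["species_id"].unique()},
            mode="total",
        )
        g = next(iter(group.values()))
        strata = stratify(g, tiny_env, n_bins=9)
        assert strata.n_strata == 81
        assert strata.cells["stratum"].between(1, 81).all()

    def test_equal_width_edges_and_inclusive_max(self, tiny_env):
        # craft a group whose T spans [0, 27] exactly
        import xarray as xr

        env = xr.Dataset(coords={"month": np.arange(1, 13),
                                 "lat": [0.5, 1.5, 2.5], "lon": [0.5, 1.5, 2.5]})
        T = np.zeros((12, 3, 3))
        T[0] = [[0, 3, 6], [9, 12, 15], [18, 21, 27]]
        MLD = np.full((12, 3, 3), 50.0)
        MLD[0, 2, 2] = 150.0
        env["T"] = (("month", "lat", "lon"), T)
        env["MLD"] = (("month", "lat", "lon"), MLD)
        cells = pd.DataFrame(
            [(1, i, j) for i in range(3) for j in range(3)],
            columns=["month", "lat_idx", "lon_idx"],
        )
        cells["multiplicity"] = 1
        group = TargetGroup(("a",), cells)
        strata = stratify(group, env, n_bins=9)
        np.testing.assert_allclose(strata.t_edges, np.arange(0, 28, 3))
        at_max = strata.cells[strata.cells["T"] == 27.0]
        assert (at_max["t_bin"] == 9).all()

    def test_degenerate_mld_axis(self, tiny_env):
        import xarray as xr

        env = xr.Dataset(coords={"month": np.arange(1, 13),
                                 "lat": [0.5, 1.5], "lon": [0.5, 1.5]})
        env["T"] = (("month", "lat", "lon"),
                    np.arange(48, dtype=float).reshape(12, 2, 2))
        env["MLD"] = (("month", "lat", "lon"), np.full((12, 2, 2), 30.0))
        cells = pd.DataFrame(
            [(m, i, j) for m in range(1, 13) for i in range(2) for j in range(2)],
            columns=["month", "lat_idx", "lon_idx"],
        )
        cells["multiplicity"] = 1
        with pytest.warns(UserWarning, match="degenerate"):
            strata = stratify(TargetGroup(("a",), cells), env, n_bins=9)
        assert strata.n_strata == 9


class TestSampleBackground:
    @pytest.fixture()
    def world(self, small_presences, tiny_env):
        groups = build_target_group(
            small_presences,
            {s: "virtual" for s in small_presences.table["species_id"].unique()},
            mode="total",
        )
        g = next(iter(groups.values()))
        return small_presences, g, stratify(g, tiny_env)

    def test_ten_to_one_ratio(self, world):
        pres, group, strata = world
        sp = pres.counts.idxmin()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bg = sample_background(sp, pres, group, strata, ratio=10, seed=0)
        assert bg.target_size == 10 * pres.counts[sp]
        # availability caps the draw; all eligible cells are used if short
        own = set(map(tuple, pres.for_species(sp)[
            ["month", "lat_idx", "lon_idx"]].values))
        eligible = len(strata.cells) - sum(
            1 for k in map(tuple, strata.cells[
                ["month", "lat_idx", "lon_idx"]].values) if k in own
        )
        assert bg.realized_size == min(bg.target_size, eligible)

    def test_background_never_hits_own_presences(self, world):
        pres, group, strata = world
        sp = pres.counts.idxmax()
        bg = sample_background(sp, pres, group, strata, seed=1)
        own = set(map(tuple, pres.for_species(sp)[
            ["month", "lat_idx", "lon_idx"]].values))
        drawn = set(map(tuple, bg.table[["month", "lat_idx", "lon_idx"]].values))
        assert not (own & drawn)

    def test_quota_proportionality_and_empty_stratum(self):
        weights = np.array([50.0, 30.0, 20.0, 0.0])
        q = largest_remainder_quotas(weights, 100)
        assert list(q) == [50, 30, 20, 0]
        assert largest_remainder_quotas(np.array([1.0, 1.0, 1.0]), 100).sum() == 100

    def test_quota_conservation_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            w = rng.random(rng.integers(1, 12))
            total = int(rng.integers(0, 500))
            q = largest_remainder_quotas(w, total)
            assert q.sum() == total
            assert (q >= 0).all()

    def test_determinism(self, world):
        pres, group, strata = world
        sp = pres.counts.index[0]
        a = sample_background(sp, pres, group, strata, seed=3)
        b = sample_background(sp, pres, group, strata, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_background_density_tracks_sampling_effort(self):
        """The bias-matching purpose: pooled background density follows the
        raw sampling effort, checked on 1-degree latitude bands as in the
        effort-proxy validation of the method (sparse sampling, so species'
        own-presence exclusions stay negligible)."""
        from phytosdm import (
            GridSpec, NicheConfig, biased_effort, generate_environment,
            generate_species_pool, sample_occurrences,
        )
        from phytosdm import bin_presences

        spec = GridSpec(n_lat=40, n_lon=60, lat_min=-20.0)
        env = generate_environment(spec, seed=0)
        t = env["T"].values
        t = t[np.isfinite(t)]
        pool = generate_species_pool(
            30,
            NicheConfig(optima={"T": (t.min() + 2, t.max() - 2)},
                        breadths={"T": (2.5, 4.0)}, p_max=0.25),
            seed=1,
        )
        effort = biased_effort(spec, env, seed=2)
        rec = sample_occurrences(pool, env, effort, 15000, seed=3)
        pres = bin_presences(rec, spec)
        groups = build_target_group(
            pres, {s: "virtual" for s in pres.table["species_id"].unique()},
            mode="total",
        )
        g = next(iter(groups.values()))
        strata = stratify(g, env)
        parts = [
            sample_background(sp, pres, g, strata, seed=100 + i).table
            for i, sp in enumerate(pres.counts.index)
        ]
        bg = pd.concat(parts)
        li, _ = spec.cell_index(rec["lat"].values, rec["lon"].values)
        bg_lat = bg.groupby("lat_idx").size()
        raw_lat = pd.Series(li).value_counts()
        idx = sorted(set(bg_lat.index) | set(raw_lat.index))
        rho = spearmanr(
            bg_lat.reindex(idx, fill_value=0),
            raw_lat.reindex(idx, fill_value=0),
        ).statistic
        assert rho >= 0.9

    def test_species_without_presences_rejected(self, world):
        pres, group, strata = world
        with pytest.raises(ValueError):
            sample_background("no_such_species", pres, group, strata)
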